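"""Fourth-order stiffness tensor algebra in Kelvin (normalized Voigt) notation.

All fourth-order tensors with minor symmetries are represented as symmetric
6x6 matrices in the orthonormal Kelvin basis, ordering
``(11, 22, 33, 23, 13, 12)`` with factors ``(1, 1, 1, sqrt2, sqrt2, sqrt2)``
on the mixed components.  In this basis the tensor double contraction is the
plain matrix product, tensor inversion is matrix inversion, and frame
rotations act by congruence with an orthogonal 6x6 matrix -- which is why
Kelvin is used here instead of engineering Voigt.

Printed stiffness matrices in the biomechanics literature usually follow the
"2C" tensor-component convention (off-diagonal blocks and the shear diagonal
carry ``2 C_ijkl``).  :func:`stiffness_from_printed_voigt` converts such a
table into the Kelvin representation; it is the single place where that
conversion lives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SQRT2",
    "KELVIN_INDEX",
    "I6",
    "P_VOL",
    "P_DEV",
    "IsotropicModuli",
    "Stiffness",
    "iso_stiffness",
    "iso_project",
    "rotation_to_kelvin",
    "rotate_stiffness",
    "axis_rotation_matrix",
    "axis_rotation_average",
    "stiffness_from_printed_voigt",
    "stiffness_to_printed_voigt",
]

SQRT2 = float(np.sqrt(2.0))

#: Kelvin component ordering: (11, 22, 33, 23, 13, 12)
KELVIN_INDEX = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))
_KELVIN_FACTOR = np.array([1.0, 1.0, 1.0, SQRT2, SQRT2, SQRT2])

#: identity on the space of symmetric second-order tensors
I6 = np.eye(6)

#: volumetric projector: P_VOL : e = (tr e / 3) * I
P_VOL = np.zeros((6, 6))
P_VOL[:3, :3] = 1.0 / 3.0

#: deviatoric projector, orthogonal complement of P_VOL
P_DEV = I6 - P_VOL


@dataclass(frozen=True)
class IsotropicModuli:
    """A (bulk, shear) modulus pair, the currency passed between scales.

    Units are GPa throughout the package unless a caller explicitly works
    in MPa.
    """

    k: float
    mu: float

    def __post_init__(self) -> None:
        if self.k < 0 or self.mu < 0:
            raise ValueError(f"moduli must be non-negative, got k={self.k}, mu={self.mu}")

    @classmethod
    def from_E_nu(cls, E: float, nu: float) -> "IsotropicModuli":
        """Build from Young's modulus and Poisson's ratio."""
        if not -1.0 < nu < 0.5:
            raise ValueError(f"Poisson's ratio {nu} outside (-1, 0.5)")
        return cls(k=E / (3.0 * (1.0 - 2.0 * nu)), mu=E / (2.0 * (1.0 + nu)))

    @property
    def E(self) -> float:
        """Young's modulus, E = 9 k mu / (3 k + mu)."""
        d = 3.0 * self.k + self.mu
        return 9.0 * self.k * self.mu / d if d > 0 else 0.0

    @property
    def nu(self) -> float:
        """Poisson's ratio, nu = (3k - 2mu) / (6k + 2mu)."""
        d = 6.0 * self.k + 2.0 * self.mu
        return (3.0 * self.k - 2.0 * self.mu) / d if d > 0 else 0.0


@dataclass(frozen=True)
class Stiffness:
    """A fourth-order elasticity tensor as a symmetric 6x6 Kelvin matrix."""

    matrix: np.ndarray
    frame_label: str = "cartesian-123"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (6, 6):
            raise ValueError(f"stiffness matrix must be 6x6, got {m.shape}")
        scale = max(np.abs(m).max(), 1.0)
        if np.abs(m - m.T).max() > 1e-12 * scale:
            raise ValueError("stiffness matrix is not symmetric")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))

    def __matmul__(self, other: "Stiffness") -> "Stiffness":
        return Stiffness(self.matrix @ other.matrix, self.frame_label)

    def inv(self) -> "Stiffness":
        return Stiffness(np.linalg.inv(self.matrix), self.frame_label)

    def is_positive_semidefinite(self, tol: float = 1e-10) -> bool:
        w = np.linalg.eigvalsh(self.matrix)
        return bool(w.min() >= -tol * max(abs(w.max()), 1.0))


def iso_stiffness(moduli: IsotropicModuli, frame_label: str = "cartesian-123") -> Stiffness:
    """Isotropic stiffness 3k P_vol + 2mu P_dev.

    The zero tensor (k = mu = 0) is admitted: it represents a drained pore
    phase.
    """
    return Stiffness(3.0 * moduli.k * P_VOL + 2.0 * moduli.mu * P_DEV, frame_label)


def iso_project(C: Stiffness) -> tuple[IsotropicModuli, float]:
    """Project a stiffness tensor onto its closest isotropic tensor.

    Returns the (k, mu) of the isotropic part together with a relative
    anisotropy residual ``||C - C_iso|| / ||C||`` (0 for isotropic input,
    0 by convention for the zero tensor).  The projection uses the
    orthogonality of the volumetric and deviatoric projectors in the Kelvin
    inner product: J::C = 3k and K::C = 10 mu.
    """
    m = C.matrix
    k = float(np.sum(P_VOL * m)) / 3.0
    mu = float(np.sum(P_DEV * m)) / 10.0
    norm = np.linalg.norm(m)
    if norm == 0.0:
        return IsotropicModuli(0.0, 0.0), 0.0
    iso = 3.0 * k * P_VOL + 2.0 * mu * P_DEV
    residual = float(np.linalg.norm(m - iso) / norm)
    # tiny negative round-off is clipped so the result stays a valid moduli pair
    return IsotropicModuli(max(k, 0.0), max(mu, 0.0)), residual


def rotation_to_kelvin(R: np.ndarray) -> np.ndarray:
    """6x6 Kelvin representation of a 3x3 rotation.

    The returned matrix Q is orthogonal and satisfies
    ``rotate(C) = Q C Q^T`` for any Kelvin stiffness matrix C.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-10 \
            or abs(np.linalg.det(R) - 1.0) > 1e-10:
        raise ValueError("R must be a proper orthonormal rotation matrix")
    Q = np.empty((6, 6))
    for a, (i, j) in enumerate(KELVIN_INDEX):
        for b, (k, l) in enumerate(KELVIN_INDEX):
            Q[a, b] = (_KELVIN_FACTOR[a] * _KELVIN_FACTOR[b]
                       * 0.5 * (R[i, k] * R[j, l] + R[i, l] * R[j, k]))
    return Q


def rotate_stiffness(C: Stiffness, R: np.ndarray) -> Stiffness:
    """Rotate a stiffness tensor: C'_ijkl = R_ia R_jb R_kc R_ld C_abcd."""
    Q = rotation_to_kelvin(R)
    return Stiffness(Q @ C.matrix @ Q.T, C.frame_label)


def axis_rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about ``axis`` by ``angle`` (radians)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def axis_rotation_average(C: Stiffness, axis: np.ndarray, n_angles: int = 16) -> Stiffness:
    """Average of C over all rotations about ``axis``.

    A fourth-order tensor contains angular harmonics up to order 4 about any
    fixed axis, so the discrete average over ``n_angles >= 5`` equally spaced
    angles equals the continuous integral (1/2pi) int_0^2pi C(theta) dtheta
    exactly; the default of 16 angles is therefore exact to round-off.  The
    result is transversely isotropic about ``axis``.
    """
    if n_angles < 5:
        raise ValueError("need at least 5 equally spaced angles for an exact average")
    acc = np.zeros((6, 6))
    for theta in np.arange(n_angles) * (2.0 * np.pi / n_angles):
        Q = rotation_to_kelvin(axis_rotation_matrix(axis, theta))
        acc += Q @ C.matrix @ Q.T
    return Stiffness(acc / n_angles, C.frame_label)


def stiffness_from_printed_voigt(M: np.ndarray, frame_label: str = "cartesian-123") -> Stiffness:
    """Convert a printed "2C" Voigt table into the Kelvin representation.

    The printed convention lists tensor components C_ijkl in the upper-left
    3x3 normal block and 2*C_ijkl everywhere a shear index pair (23, 13, 12)
    is involved.  In Kelvin notation the normal block is unchanged, the mixed
    normal/shear entries carry sqrt(2)*C (= printed/2 * sqrt2), and the
    shear/shear block carries 2*C (= printed value, unchanged).
    """
    M = np.asarray(M, dtype=float)
    out = M.copy()
    out[:3, 3:] *= SQRT2 / 2.0
    out[3:, :3] *= SQRT2 / 2.0
    return Stiffness(out, frame_label)


def stiffness_to_printed_voigt(C: Stiffness) -> np.ndarray:
    """Inverse of :func:`stiffness_from_printed_voigt`."""
    out = C.matrix.copy()
    out[:3, 3:] *= 2.0 / SQRT2
    out[3:, :3] *= 2.0 / SQRT2
    return out
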