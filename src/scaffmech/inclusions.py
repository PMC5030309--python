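"""Hill (morphology) and Eshelby tensors for inclusions in an isotropic matrix.

Covers the inclusion shapes needed by the three homogenization levels:
spheres (pores at every scale), infinite cylinders (hydroxyapatite needles),
and general spheroids (used as the oracle for both the needle and the
penny-crack limits).  All matrices are isotropic here; the anisotropic bone
coating never acts as a matrix phase.

Shapes are axisymmetric about their local 3-axis; ``orientation`` carries the
polar/azimuthal angles (theta, phi) of that axis, and the returned tensors
are rotated into the global frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensors import (
    I6,
    P_DEV,
    P_VOL,
    IsotropicModuli,
    KELVIN_INDEX,
    SQRT2,
    Stiffness,
    iso_stiffness,
    rotate_stiffness,
)

__all__ = [
    "InclusionShape",
    "OrientationGrid",
    "orientation_rotation",
    "gauss_orientation_grid",
    "orientation_grid",
    "orientation_average",
    "eshelby_factors_sphere",
    "hill_sphere",
    "eshelby_sphere",
    "hill_cylinder",
    "hill_spheroid",
]


@dataclass(frozen=True)
class InclusionShape:
    """Shape descriptor: kind, aspect ratio and symmetry-axis orientation."""

    kind: str  # sphere | cylinder | spheroid | penny
    aspect_ratio: float = 1.0
    orientation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cylinder", "spheroid", "penny"):
            raise ValueError(f"unknown inclusion kind {self.kind!r}")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect_ratio must be positive")


@dataclass(frozen=True)
class OrientationGrid:
    """Quadrature nodes/weights for averaging over the unit sphere.

    ``points`` holds (theta, phi) pairs; weights are normalized so that the
    integral of a constant is that constant, i.e. they implement
    (1/4pi) int int f sin(theta) dtheta dphi.
    """

    points: np.ndarray  # (n, 2)
    weights: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("orientation weights must sum to 1")
        if (w < 0).any():
            raise ValueError("orientation weights must be non-negative")

    def integrate(self, f) -> float:
        vals = np.array([f(t, p) for t, p in self.points])
        return float(np.tensordot(self.weights, vals, axes=1))


def orientation_rotation(theta: float, phi: float) -> np.ndarray:
    """Rotation mapping the local 3-axis onto the direction (theta, phi)."""
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    Rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    Ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
    return Rz @ Ry


def gauss_orientation_grid(n_polar: int = 16, n_azimuthal: int = 32) -> OrientationGrid:
    """Gauss-product grid: Gauss-Legendre in cos(theta), uniform in phi.

    The uniform (trapezoidal) rule in phi is exact for trigonometric
    polynomials of degree < n_azimuthal, and Gauss-Legendre in cos(theta) is
    exact for polynomial degree < 2 n_polar, which covers the smooth,
    low-harmonic integrands arising from fourth-order tensor orientation
    averages already at modest orders.
    """
    if n_polar < 2 or n_azimuthal < 2:
        raise ValueError("need at least 2 nodes per direction")
    x, wx = np.polynomial.legendre.leggauss(n_polar)
    thetas = np.arccos(x)
    phis = np.arange(n_azimuthal) * (2.0 * np.pi / n_azimuthal)
    pts = np.array([(t, p) for t in thetas for p in phis])
    w = np.array([wt / 2.0 / n_azimuthal for wt in wx for _ in phis])
    return OrientationGrid(pts, w)


def orientation_grid(n_polar: int = 16, n_azimuthal: int = 32,
                     scheme: str = "gauss") -> OrientationGrid:
    """Factory for orientation grids; ``scheme`` currently 'gauss'."""
    if scheme != "gauss":
        raise ValueError(f"unknown scheme {scheme!r}")
    return gauss_orientation_grid(n_polar, n_azimuthal)


def _kelvin_rotations(grid: OrientationGrid) -> np.ndarray:
    from .tensors import rotation_to_kelvin

    return np.array([rotation_to_kelvin(orientation_rotation(t, p))
                     for t, p in grid.points])


def orientation_average(C: Stiffness, grid: OrientationGrid,
                        _op_cache: dict = {}) -> Stiffness:
    """Average of the rotated tensor over all orientations of its 3-axis.

    Averaging is a fixed linear operator on the Kelvin matrix,
    ``avg(C) = sum_n w_n Q_n C Q_n^T``; the operator is assembled once per
    grid as a 36x36 matrix and cached, so repeated averaging inside
    fixed-point iterations costs a single small mat-vec.
    """
    key = id(grid)
    M = _op_cache.get(key)
    if M is None:
        Q = _kelvin_rotations(grid)
        # M[(a,d),(b,c)] = sum_n w_n Q_n[a,b] Q_n[d,c]
        M = np.einsum("n,nab,ndc->adbc", grid.weights, Q, Q).reshape(36, 36)
        _op_cache.clear()  # keep exactly one grid hot; sweeps reuse a single grid
        _op_cache[key] = M
    avg = (M @ C.matrix.reshape(36)).reshape(6, 6)
    return Stiffness(0.5 * (avg + avg.T), C.frame_label)


# ---------------------------------------------------------------------------
# closed-form tensors
# ---------------------------------------------------------------------------

def eshelby_factors_sphere(matrix: IsotropicModuli) -> tuple[float, float]:
    """Volumetric/deviatoric eigenvalues (alpha, beta) of the spherical
    Eshelby tensor: alpha = 3k/(3k+4mu), beta = 6(k+2mu)/(5(3k+4mu))."""
    k, mu = matrix.k, matrix.mu
    d = 3.0 * k + 4.0 * mu
    if d <= 0:
        raise ValueError("matrix stiffness must be positive definite")
    return 3.0 * k / d, 6.0 * (k + 2.0 * mu) / (5.0 * d)


def hill_sphere(matrix: IsotropicModuli) -> Stiffness:
    """Hill tensor P of a spherical inclusion, P = S : C^-1.

    Isotropic with volumetric part alpha/(3k) and deviatoric part beta/(2mu),
    alpha and beta being the spherical Eshelby factors.
    """
    if matrix.k <= 0 or matrix.mu <= 0:
        raise ValueError("matrix stiffness must be positive definite")
    alpha, beta = eshelby_factors_sphere(matrix)
    return Stiffness((alpha / (3.0 * matrix.k)) * P_VOL
                     + (beta / (2.0 * matrix.mu)) * P_DEV)


def eshelby_sphere(matrix: IsotropicModuli) -> Stiffness:
    """Eshelby tensor S of a spherical inclusion in an isotropic matrix."""
    alpha, beta = eshelby_factors_sphere(matrix)
    return Stiffness(alpha * P_VOL + beta * P_DEV)


def _tensor_to_kelvin(S: np.ndarray) -> np.ndarray:
    f = np.array([1.0, 1.0, 1.0, SQRT2, SQRT2, SQRT2])
    M = np.empty((6, 6))
    for a, (i, j) in enumerate(KELVIN_INDEX):
        for b, (k, l) in enumerate(KELVIN_INDEX):
            M[a, b] = f[a] * f[b] * S[i, j, k, l]
    return M


def _eshelby_cylinder_kelvin(nu: float) -> np.ndarray:
    """Eshelby tensor of an infinite circular cylinder along the 3-axis."""
    S = np.zeros((3, 3, 3, 3))
    d = 1.0 / (8.0 * (1.0 - nu))

    def put(i, j, k, l, v):
        S[i, j, k, l] = v
        S[j, i, k, l] = v
        S[i, j, l, k] = v
        S[j, i, l, k] = v

    put(0, 0, 0, 0, (5.0 - 4.0 * nu) * d)
    put(1, 1, 1, 1, (5.0 - 4.0 * nu) * d)
    put(0, 0, 1, 1, (4.0 * nu - 1.0) * d)
    put(1, 1, 0, 0, (4.0 * nu - 1.0) * d)
    put(0, 0, 2, 2, nu / (2.0 * (1.0 - nu)))
    put(1, 1, 2, 2, nu / (2.0 * (1.0 - nu)))
    put(0, 1, 0, 1, (3.0 - 4.0 * nu) * d)
    put(0, 2, 0, 2, 0.25)
    put(1, 2, 1, 2, 0.25)
    return _tensor_to_kelvin(S)


def hill_cylinder(matrix: IsotropicModuli,
                  orientation: tuple[float, float] = (0.0, 0.0)) -> Stiffness:
    """Hill tensor of an infinite cylinder (needle) in an isotropic matrix."""
    if matrix.k <= 0 or matrix.mu <= 0:
        raise ValueError("matrix stiffness must be positive definite")
    Sk = _eshelby_cylinder_kelvin(matrix.nu)
    Cinv = np.linalg.inv(iso_stiffness(matrix).matrix)
    P = Stiffness(0.5 * ((Sk @ Cinv) + (Sk @ Cinv).T))
    theta, phi = orientation
    if theta == 0.0 and phi == 0.0:
        return P
    return rotate_stiffness(P, orientation_rotation(theta, phi))


def _spheroid_I_integrals(omega: float) -> tuple[float, float, float, float, float]:
    """Carlson-type I integrals for a spheroid with semi-axes (1, 1, omega).

    Returns (I1, I3, I11, I13, I33); I2 = I1 and I12 = I11 by axial symmetry.
    """
    if omega > 1.0:  # prolate
        e = np.sqrt(omega * omega - 1.0)
        I1 = 2.0 * np.pi * omega / e ** 3 * (omega * e - np.arccosh(omega))
    elif omega < 1.0:  # oblate
        e = np.sqrt(1.0 - omega * omega)
        I1 = 2.0 * np.pi * omega / e ** 3 * (np.arccos(omega) - omega * e)
    else:
        I1 = 4.0 * np.pi / 3.0
    I3 = 4.0 * np.pi - 2.0 * I1
    if omega == 1.0:
        I11 = I13 = I33 = 4.0 * np.pi / 5.0
    else:
        I13 = (I1 - I3) / (omega * omega - 1.0)
        I11 = (4.0 * np.pi - I13) / 4.0  # 3*I11 + I12 + I13 = 4pi with I12 = I11
        I33 = (4.0 * np.pi / omega ** 2 - 2.0 * I13) / 3.0
    return I1, I3, I11, I13, I33


def hill_spheroid(matrix: IsotropicModuli, aspect_ratio: float,
                  orientation: tuple[float, float] = (0.0, 0.0)) -> Stiffness:
    """Hill tensor of a spheroid (symmetry axis = local 3-axis).

    ``aspect_ratio`` is c/a, the symmetry semi-axis over the equatorial one;
    values above 1 are prolate (needle-like as ratio -> infinity), values
    below 1 oblate (penny-like as ratio -> 0).  Admissible range is
    [1e-6, 1e6]; beyond it the dedicated cylinder / crack-limit routes must
    be used.
    """
    if not 1e-6 <= aspect_ratio <= 1e6:
        raise ValueError("aspect_ratio outside the supported range [1e-6, 1e6]")
    if matrix.k <= 0 or matrix.mu <= 0:
        raise ValueError("matrix stiffness must be positive definite")
    nu = matrix.nu
    om = float(aspect_ratio)
    I1, I3, I11, I13, I33 = _spheroid_I_integrals(om)
    a1sq, a3sq = 1.0, om * om
    c0 = 1.0 / (8.0 * np.pi * (1.0 - nu))
    c1 = (1.0 - 2.0 * nu)

    S = np.zeros((3, 3, 3, 3))

    def put(i, j, k, l, v):
        for (a, b) in ((i, j), (j, i)):
            for (c, d) in ((k, l), (l, k)):
                S[a, b, c, d] = v

    # Eshelby's closed forms for an ellipsoid in an isotropic matrix,
    # specialized to a1 = a2 = 1, a3 = omega (I2 = I1, I12 = I11, I23 = I13).
    put(0, 0, 0, 0, c0 * (3.0 * a1sq * I11 + c1 * I1))
    put(1, 1, 1, 1, c0 * (3.0 * a1sq * I11 + c1 * I1))
    put(2, 2, 2, 2, c0 * (3.0 * a3sq * I33 + c1 * I3))
    put(0, 0, 1, 1, c0 * (a1sq * I11 - c1 * I1))
    put(1, 1, 0, 0, c0 * (a1sq * I11 - c1 * I1))
    put(0, 0, 2, 2, c0 * (a3sq * I13 - c1 * I1))
    put(1, 1, 2, 2, c0 * (a3sq * I13 - c1 * I1))
    put(2, 2, 0, 0, c0 * (a1sq * I13 - c1 * I3))
    put(2, 2, 1, 1, c0 * (a1sq * I13 - c1 * I3))
    put(0, 1, 0, 1, c0 * (0.5 * (a1sq + a1sq) * I11 + 0.5 * c1 * (I1 + I1)))
    put(0, 2, 0, 2, c0 * (0.5 * (a1sq + a3sq) * I13 + 0.5 * c1 * (I1 + I3)))
    put(1, 2, 1, 2, c0 * (0.5 * (a1sq + a3sq) * I13 + 0.5 * c1 * (I1 + I3)))

    Sk = _tensor_to_kelvin(S)
    Cinv = np.linalg.inv(iso_stiffness(matrix).matrix)
    Pm = Sk @ Cinv
    P = Stiffness(0.5 * (Pm + Pm.T))
    theta, phi = orientation
    if theta == 0.0 and phi == 0.0:
        return P
    return rotate_stiffness(P, orientation_rotation(theta, phi))
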