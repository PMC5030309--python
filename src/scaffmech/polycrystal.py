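"""Level I: self-consistent elasticity of the microporous hydroxyapatite polycrystal.

The polycrystal is modelled as infinitely many needle-shaped (cylindrical)
hydroxyapatite phases oriented uniformly in all space directions, mutually
interacting with one spherical, drained pore phase; every phase is embedded
in a fictitious matrix carrying the (unknown) homogenized stiffness itself.
The scheme is the classical self-consistent estimate for porous polycrystals
with elongated solid elements and yields an isotropic stiffness.

Drained pores are handled by writing their strain concentration factor as
``[I - P_sph : C_est]^-1`` so that a zero pore stiffness never needs to be
inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .inclusions import (
    OrientationGrid,
    eshelby_factors_sphere,
    gauss_orientation_grid,
    hill_cylinder,
    orientation_average,
)
from .tensors import I6, IsotropicModuli, P_DEV, P_VOL, Stiffness, iso_project, iso_stiffness

__all__ = [
    "E_HA",
    "NU_HA",
    "PolycrystalComposition",
    "PolycrystalResult",
    "ConvergenceError",
    "homogenize_polycrystal",
    "polycrystal_moduli",
]

#: Young's modulus of hydroxyapatite crystals, GPa (ultrasonic data)
E_HA = 114.0
#: Poisson's ratio of hydroxyapatite crystals
NU_HA = 0.27


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class PolycrystalComposition:
    """Composition of the polycrystal RVE.

    ``phi_micro`` is the microporosity; the needle volume fraction is its
    complement, f_HA = 1 - phi_micro.
    """

    phi_micro: float
    E_HA: float = E_HA
    nu_HA: float = NU_HA

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_micro < 1.0:
            raise ValueError(f"phi_micro must lie in [0, 1), got {self.phi_micro}")

    @property
    def f_HA(self) -> float:
        return 1.0 - self.phi_micro

    @property
    def crystal_moduli(self) -> IsotropicModuli:
        return IsotropicModuli.from_E_nu(self.E_HA, self.nu_HA)


@dataclass(frozen=True)
class PolycrystalResult:
    moduli: IsotropicModuli
    anisotropy_residual: float
    fixed_point_residual: float
    iterations: int


_DEFAULT_GRID: OrientationGrid | None = None


def _default_grid() -> OrientationGrid:
    global _DEFAULT_GRID
    if _DEFAULT_GRID is None:
        _DEFAULT_GRID = gauss_orientation_grid(16, 32)
    return _DEFAULT_GRID


def _rhs(comp: PolycrystalComposition, est: IsotropicModuli,
         grid: OrientationGrid) -> IsotropicModuli:
    """One evaluation of the self-consistent right-hand side at estimate `est`."""
    C_HA = iso_stiffness(comp.crystal_moduli).matrix
    C = iso_stiffness(est).matrix
    P_cyl = hill_cylinder(est)  # needle along the 3-axis; other orientations by rotation
    A0 = np.linalg.inv(I6 + P_cyl.matrix @ (C_HA - C))
    # C_HA and C_est are isotropic, so the orientation-dependent concentration
    # factor is the rigid rotation of A0; the double integral over needle
    # orientations reduces to an orientation average of A0.
    A_cyl = orientation_average(Stiffness(0.5 * (A0 + A0.T)), grid).matrix
    A_cyl = 0.5 * (A_cyl + A_cyl.T)
    alpha, beta = eshelby_factors_sphere(est)
    A_pore = (1.0 / (1.0 - alpha)) * P_VOL + (1.0 / (1.0 - beta)) * P_DEV
    f = comp.f_HA
    num = f * C_HA @ A_cyl
    den = f * A_cyl + comp.phi_micro * A_pore
    C_new = num @ np.linalg.inv(den)
    moduli, _ = iso_project(Stiffness(0.5 * (C_new + C_new.T)))
    return moduli


def homogenize_polycrystal(comp: PolycrystalComposition,
                           grid: OrientationGrid | None = None,
                           *, tol: float = 1e-10, max_iter: int = 500,
                           damping: float = 0.5) -> PolycrystalResult:
    """Solve the self-consistent fixed point for the porous polycrystal.

    Damped fixed-point iteration on (k, mu), initialized at the porosity-scaled
    crystal moduli (1 - phi_micro) * (k_HA, mu_HA); this start lies on the
    Voigt side of the solution and reaches the positive-semi-definite branch
    for all porosities of practical interest.

    Raises :class:`ConvergenceError` if the iteration does not reach the
    relative tolerance within ``max_iter`` steps.
    """
    grid = grid or _default_grid()
    cm = comp.crystal_moduli
    if comp.phi_micro == 0.0:
        return PolycrystalResult(cm, 0.0, 0.0, 0)
    k, mu = comp.f_HA * cm.k, comp.f_HA * cm.mu
    trace: list[tuple[float, float]] = []
    for it in range(1, max_iter + 1):
        new = _rhs(comp, IsotropicModuli(k, mu), grid)
        trace.append((new.k, new.mu))
        dk = abs(new.k - k) / max(new.k, 1e-300)
        dmu = abs(new.mu - mu) / max(new.mu, 1e-300)
        k = damping * k + (1.0 - damping) * new.k
        mu = damping * mu + (1.0 - damping) * new.mu
        if dk < tol and dmu < tol:
            est = IsotropicModuli(k, mu)
            final = _rhs(comp, est, grid)
            res = max(abs(final.k - k) / max(k, 1e-300),
                      abs(final.mu - mu) / max(mu, 1e-300))
            # anisotropy of the converged estimate (rotation-averaged scheme
            # is isotropic by construction; report the numerical residual)
            aniso = _anisotropy_residual(comp, est, grid)
            return PolycrystalResult(est, aniso, res, it)
    raise ConvergenceError(
        f"self-consistent iteration did not converge in {max_iter} steps "
        f"(phi_micro={comp.phi_micro})", trace)


def _anisotropy_residual(comp: PolycrystalComposition, est: IsotropicModuli,
                         grid: OrientationGrid) -> float:
    C_HA = iso_stiffness(comp.crystal_moduli).matrix
    C = iso_stiffness(est).matrix
    A0 = np.linalg.inv(I6 + hill_cylinder(est).matrix @ (C_HA - C))
    A_cyl = orientation_average(Stiffness(0.5 * (A0 + A0.T)), grid).matrix
    alpha, beta = eshelby_factors_sphere(est)
    A_pore = (1.0 / (1.0 - alpha)) * P_VOL + (1.0 / (1.0 - beta)) * P_DEV
    f = comp.f_HA
    C_new = (f * C_HA @ A_cyl) @ np.linalg.inv(f * A_cyl + comp.phi_micro * A_pore)
    _, residual = iso_project(Stiffness(0.5 * (C_new + C_new.T)))
    return residual


@lru_cache(maxsize=4096)
def _cached_moduli(phi_micro: float, E: float, nu: float) -> tuple[float, float]:
    res = homogenize_polycrystal(PolycrystalComposition(phi_micro, E, nu))
    return res.moduli.k, res.moduli.mu


def polycrystal_moduli(phi_micro: float, E: float = E_HA,
                       nu: float = NU_HA) -> IsotropicModuli:
    """Memoized level-I moduli; the workhorse entry point for sweeps.

    Results depend only on (phi_micro, E_HA, nu_HA) at the default grid and
    tolerances, so the cache key is exactly that triple (rounded to 12
    significant digits to absorb float noise in time-grid arithmetic).
    """
    k, mu = _cached_moduli(round(float(phi_micro), 12), float(E), float(nu))
    return IsotropicModuli(k, mu)
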