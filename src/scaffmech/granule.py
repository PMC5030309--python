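"""Level II: Mori-Tanaka stiffness of the mesoporous, pre-cracked granule.

Two inclusion families are embedded in the polycrystal matrix of level I:
spherical drained mesopores of finite volume fraction, and randomly oriented
open penny-shaped cracks of vanishing volume fraction.  The cracks enter the
estimate only through the dimensionless crack density eps = N r_cr^3
multiplying a compliance-contribution tensor Q that depends solely on the
Poisson's ratio of the matrix:

    Q_vol = (16/9) (1 - nu^2) / (1 - 2 nu)
    Q_dev = (32/45) (1 - nu) (5 - nu) / (2 - nu)

Q arises as the limit lim_{w->0} (4/3) pi w <[I - S_penny(w)]^-1> of oblate
spheroidal voids with aspect ratio w -> 0 at fixed crack density, averaged
over all orientations; the oblate-void route is kept in the test suite as an
independent oracle for this closed form.

The resulting Mori-Tanaka estimate is isotropic:

    k_gran  = (1-phi) k_m  / [(1-phi) + phi/(1-alpha) + eps Q_vol]
    mu_gran = (1-phi) mu_m / [(1-phi) + phi/(1-beta)  + eps Q_dev]

with (alpha, beta) the spherical Eshelby factors of the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .inclusions import eshelby_factors_sphere
from .polycrystal import polycrystal_moduli
from .tensors import IsotropicModuli, P_DEV, P_VOL, Stiffness

__all__ = [
    "GranuleComposition",
    "crack_density",
    "crack_influence_factors",
    "crack_influence_tensor",
    "granule_stiffness",
    "granule_moduli",
]


def crack_density(N: float, r_cr: float) -> float:
    """Crack density parameter eps = N * r_cr^3.

    ``N`` is the number of penny cracks per volume (1/um^3), ``r_cr`` the
    crack radius (um); eps is dimensionless.
    """
    if N < 0 or r_cr < 0:
        raise ValueError("crack number density and radius must be non-negative")
    return N * r_cr ** 3


@dataclass(frozen=True)
class GranuleComposition:
    """Mesoporosity, crack density and level-I matrix of one granule."""

    phi_meso: float
    epsilon: float
    matrix: IsotropicModuli

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_meso < 1.0:
            raise ValueError(f"phi_meso must lie in [0, 1), got {self.phi_meso}")
        if self.epsilon < 0:
            raise ValueError("crack density must be non-negative")
        if self.matrix.k <= 0 or self.matrix.mu <= 0:
            raise ValueError("granule matrix must be positive definite")

    @property
    def f_polyHA(self) -> float:
        return 1.0 - self.phi_meso


def crack_influence_factors(nu: float) -> tuple[float, float]:
    """(Q_vol, Q_dev) of randomly oriented drained penny cracks."""
    if not -1.0 < nu < 0.5:
        raise ValueError(f"Poisson's ratio {nu} outside (-1, 0.5)")
    q_vol = (16.0 / 9.0) * (1.0 - nu * nu) / (1.0 - 2.0 * nu)
    q_dev = (32.0 / 45.0) * (1.0 - nu) * (5.0 - nu) / (2.0 - nu)
    return q_vol, q_dev


def crack_influence_tensor(nu: float) -> Stiffness:
    """The isotropic fourth-order tensor Q = Q_vol J + Q_dev K."""
    q_vol, q_dev = crack_influence_factors(nu)
    return Stiffness(q_vol * P_VOL + q_dev * P_DEV)


def granule_stiffness(comp: GranuleComposition) -> IsotropicModuli:
    """Mori-Tanaka moduli of the cracked, mesoporous granule material."""
    k_m, mu_m = comp.matrix.k, comp.matrix.mu
    nu = comp.matrix.nu
    alpha, beta = eshelby_factors_sphere(comp.matrix)
    q_vol, q_dev = crack_influence_factors(nu)
    f = comp.f_polyHA
    k = f * k_m / (f + comp.phi_meso / (1.0 - alpha) + comp.epsilon * q_vol)
    mu = f * mu_m / (f + comp.phi_meso / (1.0 - beta) + comp.epsilon * q_dev)
    return IsotropicModuli(k, mu)


@lru_cache(maxsize=65536)
def _cached(phi_micro: float, phi_meso: float, epsilon: float) -> tuple[float, float]:
    matrix = polycrystal_moduli(phi_micro)
    m = granule_stiffness(GranuleComposition(phi_meso, epsilon, matrix))
    return m.k, m.mu


def granule_moduli(phi_micro: float, phi_meso: float, epsilon: float) -> IsotropicModuli:
    """Memoized level-I + level-II chain for sweep workloads."""
    k, mu = _cached(round(float(phi_micro), 12), round(float(phi_meso), 12),
                    round(float(epsilon), 12))
    return IsotropicModuli(k, mu)
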