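"""Bone-ingrowth and scaffold-resorption kinetics.

Two composition variables evolve after implantation:

* the bone coating grows on the granule surfaces at a constant thickness
  rate ``k_growth`` (um/week), so the bone volume fraction follows the
  shell-volume law
  ``f_bone(t) = [((r_gran + k_growth t)/r_gran)^3 - 1] f_gran``
  until the macropore space is exhausted (f_bone capped at phi_macro_0);
* hydroxyapatite dissolution enlarges the micropores linearly,
  ``phi_micro(t) = phi_micro_0 + k_res t`` with resorption rate ``k_res``
  (1/week); larger pores are unaffected by resorption.

Both laws are linear in time, which matches observations over roughly the
first ten weeks; in vivo kinetics are expected to flatten later, so the two
laws are injected as replaceable callables where the design pipeline allows
it.  The dissolution experiment underlying the resorption rate is summarized
by an empirical rational fit of the calcium concentration released by
granules into a buffer over a 21-day window; its time axis is in days and it
is never mixed with the week-based laws in one computation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "K_GROWTH_DEFAULT",
    "K_RES_DEFAULT",
    "PHI_MICRO_0_DEFAULT",
    "KineticsParams",
    "MicrostructureState",
    "bone_fraction",
    "microporosity_at",
    "dissolution_curve",
    "state_at",
]

#: bone apposition rate observed histologically, um/week (reported 7 +- 3)
K_GROWTH_DEFAULT = 7.0
#: hydroxyapatite resorption rate back-calculated from the dissolution
#: experiment at its start, 1/week
K_RES_DEFAULT = 0.016
#: initial microporosity of the granule base material
PHI_MICRO_0_DEFAULT = 0.445


@dataclass(frozen=True)
class KineticsParams:
    """Rates and initial composition driving the time evolution."""

    k_growth: float = K_GROWTH_DEFAULT
    k_res: float = 0.0
    r_gran: float = 500.0
    phi_macro_0: float = 0.4
    phi_micro_0: float = PHI_MICRO_0_DEFAULT

    def __post_init__(self) -> None:
        if self.k_growth < 0 or self.k_res < 0:
            raise ValueError("rates must be non-negative")
        if self.r_gran <= 0:
            raise ValueError("granule radius must be positive")
        if not 0.0 < self.phi_macro_0 < 1.0:
            raise ValueError("phi_macro_0 must lie in (0, 1)")
        if not 0.0 <= self.phi_micro_0 < 1.0:
            raise ValueError("phi_micro_0 must lie in [0, 1)")


@dataclass(frozen=True)
class MicrostructureState:
    """All composition/design parameters of the conglomerate at one time."""

    t: float
    phi_micro: float
    phi_meso: float
    epsilon: float
    phi_macro: float
    f_gran: float
    f_bone: float
    r_gran: float
    r_bone: float

    def __post_init__(self) -> None:
        s = self.f_gran + self.f_bone + self.phi_macro
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"volume fractions sum to {s}, not 1")
        if not 0.0 <= self.phi_micro <= 1.0:
            raise ValueError("phi_micro outside [0, 1]")


def bone_fraction(t: float, params: KineticsParams) -> float:
    """Bone volume fraction at time t (weeks), capped at phi_macro_0."""
    if t < 0:
        raise ValueError("time must be non-negative")
    f_gran = 1.0 - params.phi_macro_0
    growth = ((params.r_gran + params.k_growth * t) / params.r_gran) ** 3 - 1.0
    return min(growth * f_gran, params.phi_macro_0)


def microporosity_at(t: float, params: KineticsParams) -> float:
    """Microporosity at time t (weeks): linear growth, capped at 1."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return min(params.phi_micro_0 + params.k_res * t, 1.0)


def dissolution_curve(t_days: float) -> float:
    """Empirical calcium-release fit of the granule dissolution experiment.

    ``t_days`` is in days; the returned concentration carries the units of
    the underlying spectrometry calibration and is used only as a shape
    descriptor (its initial slope fixes the default resorption rate).
    """
    if t_days < 0:
        raise ValueError("time must be non-negative")
    t = float(t_days)
    return ((0.1073 * t * t + 5.18 * t + 0.3093)
            / (t * t + 44.11 * t + 42.61))


def state_at(t: float, design) -> MicrostructureState:
    """Microstructure state at time t (weeks) for a design point.

    Mesoporosity, crack density and granule radius stay constant; resorption
    acts on the microporosity only.  After the bone cap is reached the
    coating radius freezes while microporosity keeps growing.
    """
    params = KineticsParams(k_growth=design.k_growth, k_res=design.k_res,
                            r_gran=design.r_gran, phi_macro_0=design.phi_macro_0,
                            phi_micro_0=design.phi_micro_0)
    f_bone = bone_fraction(t, params)
    f_gran = 1.0 - params.phi_macro_0
    phi_macro = params.phi_macro_0 - f_bone
    r_bone = params.r_gran * ((f_gran + f_bone) / f_gran) ** (1.0 / 3.0)
    return MicrostructureState(
        t=t,
        phi_micro=microporosity_at(t, params),
        phi_meso=design.phi_meso,
        epsilon=design.epsilon,
        phi_macro=phi_macro,
        f_gran=f_gran,
        f_bone=f_bone,
        r_gran=params.r_gran,
        r_bone=r_bone,
    )
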