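"""Design studio: compose the three homogenization levels over time.

This is the user-facing pipeline: a :class:`DesignPoint` fixes the scaffold
design parameters (crack density, granule radius, initial macroporosity,
resorption and ingrowth rates, porosities); the pipeline evolves the
microstructure with the kinetics laws, chains the level-I polycrystal, the
level-II granule and the level-III conglomerate schemes at every time step,
and reports the conglomerate Young's modulus

    E_congl = 9 k mu / (3 k + mu)

against the mandibular target stiffness band (5-19 GPa by default).
Level-I results are memoized on the microporosity and level-II results on
(phi_micro, phi_meso, epsilon), so factorial sweeps reuse every repeated
subproblem.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bone import BONE_STIFFNESS_SPHERICAL
from .conglomerate import (
    CoatedSphereGeometry,
    ConglomerateConvergenceError,
    homogenize_conglomerate,
)
from .granule import granule_moduli
from .kinetics import MicrostructureState, state_at
from .tensors import IsotropicModuli, Stiffness, iso_stiffness

__all__ = [
    "TARGET_BAND",
    "DesignPoint",
    "SweepResult",
    "young_modulus",
    "stiffness_at_state",
    "stiffness_history",
    "factorial_study",
    "rate_map",
]

#: mandibular-bone Young's modulus target band, GPa
TARGET_BAND = (5.0, 19.0)

#: parameter grids of the factorial design study
FACTORIAL_GRIDS = {
    "epsilon": (0.0, 10.0, 100.0),
    "r_gran": (300.0, 500.0, 1000.0),
    "phi_macro_0": (0.3, 0.4, 0.5),
    "k_res": (0.0, 0.008, 0.016),
    "k_growth": (4.0, 7.0, 10.0),
}


@dataclass(frozen=True)
class DesignPoint:
    """One scaffold design: geometry, crack state and kinetics rates."""

    epsilon: float = 10.0
    r_gran: float = 500.0
    phi_macro_0: float = 0.4
    k_res: float = 0.0
    k_growth: float = 7.0
    phi_micro_0: float = 0.445
    phi_meso: float = 0.189

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("crack density must be non-negative")
        if not 0.0 < self.phi_macro_0 < 1.0:
            raise ValueError("phi_macro_0 must lie in (0, 1)")
        if not 0.0 <= self.phi_meso < 1.0:
            raise ValueError("phi_meso must lie in [0, 1)")


@dataclass(frozen=True)
class SweepResult:
    """Tabular sweep output with the target band used to classify rows."""

    table: pd.DataFrame
    band: tuple[float, float] = TARGET_BAND


def young_modulus(moduli: IsotropicModuli) -> float:
    """E = 9 k mu / (3 k + mu); zero if either modulus vanishes."""
    return moduli.E


def stiffness_at_state(state: MicrostructureState,
                       initial: tuple[float, float] | None = None
                       ) -> IsotropicModuli:
    """Three-level homogenization chain for one microstructure state.

    ``initial`` optionally warm-starts the level-III fixed point (used by
    the time-marching history, where consecutive states are close).
    """
    if state.phi_micro >= 1.0:
        return IsotropicModuli(0.0, 0.0)
    gran = granule_moduli(state.phi_micro, state.phi_meso, state.epsilon)
    if state.phi_macro <= 1e-12 and state.f_bone <= 1e-12:
        return gran
    geometry = CoatedSphereGeometry.from_fractions(
        state.r_gran, state.f_gran, state.f_bone, state.phi_macro)
    est = homogenize_conglomerate(iso_stiffness(gran), BONE_STIFFNESS_SPHERICAL,
                                  geometry, initial=initial)
    return est.moduli


def stiffness_history(design: DesignPoint,
                      times: np.ndarray | None = None,
                      band: tuple[float, float] = TARGET_BAND) -> SweepResult:
    """E_congl(t) over a time grid (weeks; default 0..30 in 0.5 steps)."""
    if times is None:
        times = np.arange(0.0, 30.0 + 1e-9, 0.5)
    rows = []
    warm: tuple[float, float] | None = None
    for t in times:
        state = state_at(float(t), design)
        row = {"t": float(t), **_design_columns(design)}
        try:
            m = stiffness_at_state(state, initial=warm)
            if m.k > 0 and m.mu > 0:
                warm = (m.k, m.mu)
            row.update(k_congl=m.k, mu_congl=m.mu, E_congl=m.E,
                       in_target_band=bool(band[0] <= m.E <= band[1]),
                       error="")
        except (ConglomerateConvergenceError, ValueError) as err:
            row.update(k_congl=np.nan, mu_congl=np.nan, E_congl=np.nan,
                       in_target_band=False, error=str(err))
        rows.append(row)
    return SweepResult(pd.DataFrame(rows), band)


def _design_columns(design: DesignPoint) -> dict:
    return {
        "epsilon": design.epsilon, "r_gran": design.r_gran,
        "phi_macro_0": design.phi_macro_0, "k_res": design.k_res,
        "k_growth": design.k_growth, "phi_micro_0": design.phi_micro_0,
        "phi_meso": design.phi_meso,
    }


def factorial_study(grids: dict | None = None,
                    times: np.ndarray | None = None,
                    band: tuple[float, float] = TARGET_BAND,
                    eval_times: tuple[float, ...] = (5.0, 20.0),
                    base: DesignPoint = DesignPoint()) -> dict:
    """Full-factorial design study.

    ``grids`` maps DesignPoint field names to value tuples (defaults to the
    five-parameter, three-level grid of the published study, 3^5 = 243
    combinations).  A combination counts as successful at an evaluation time
    if its Young's modulus has entered the target band at any grid time up
    to and including that time.

    Returns a dict with the full time table (``table``), one row per
    combination with first-entry times (``combinations``), and per-parameter
    and parameter-pair success tallies per evaluation time (``tallies``).
    """
    grids = dict(FACTORIAL_GRIDS) if grids is None else grids
    if times is None:
        times = np.arange(0.0, 30.0 + 1e-9, 0.5)
    names = list(grids)
    all_rows = []
    combos = []
    for combo_id, values in enumerate(itertools.product(*grids.values())):
        design = replace(base, **dict(zip(names, values)))
        res = stiffness_history(design, times, band).table
        res.insert(0, "combo", combo_id)
        all_rows.append(res)
        ok = res[res.in_target_band]
        combos.append({"combo": combo_id, **dict(zip(names, values)),
                       "t_first_in_band": float(ok.t.min()) if len(ok) else np.inf,
                       "n_errors": int((res.error != "").sum())})
    table = pd.concat(all_rows, ignore_index=True)
    combos = pd.DataFrame(combos)

    tallies = {}
    for t_eval in eval_times:
        success = combos.t_first_in_band <= t_eval
        per_value = {
            name: {val: int(((combos[name] == val) & success).sum())
                   for val in grids[name]}
            for name in names
        }
        per_pair = {}
        for a, b in itertools.combinations(names, 2):
            for va in grids[a]:
                for vb in grids[b]:
                    per_pair[(a, va, b, vb)] = int(
                        ((combos[a] == va) & (combos[b] == vb) & success).sum())
        tallies[t_eval] = {"per_value": per_value, "per_pair": per_pair,
                           "n_success": int(success.sum())}
    return {"table": table, "combinations": combos, "tallies": tallies,
            "band": band}


def rate_map(base: DesignPoint = DesignPoint(epsilon=10.0, r_gran=500.0,
                                             phi_macro_0=0.4),
             k_res_values: np.ndarray | None = None,
             k_growth_values: np.ndarray | None = None,
             times: np.ndarray | None = None,
             threshold: float = TARGET_BAND[0]) -> pd.DataFrame:
    """Time-to-target surface over the two kinetics rates.

    For every (k_res, k_growth) cell, the earliest grid time at which
    E_congl first reaches ``threshold`` (GPa) is reported; inf if the
    threshold is never reached on the grid.
    """
    if k_res_values is None:
        k_res_values = np.linspace(0.0, 0.016, 5)
    if k_growth_values is None:
        k_growth_values = np.linspace(4.0, 10.0, 4)
    if times is None:
        times = np.arange(0.0, 30.0 + 1e-9, 0.5)
    rows = []
    for k_res in k_res_values:
        for k_growth in k_growth_values:
            design = replace(base, k_res=float(k_res), k_growth=float(k_growth))
            hist = stiffness_history(design, times).table
            hit = hist[hist.E_congl >= threshold]
            rows.append({"k_res": float(k_res), "k_growth": float(k_growth),
                         "t_reach": float(hit.t.min()) if len(hit) else np.inf})
    return pd.DataFrame(rows)
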