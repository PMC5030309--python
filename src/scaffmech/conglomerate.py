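"""Level III: macroporous conglomerate of bone-coated granules.

A spherical granule (isotropic, level-II stiffness) carries a concentric
bone coating whose stiffness is transversely isotropic in the spherical
frame (isotropy plane tangential).  The coated sphere is embedded in an
infinite effective medium with the (unknown) isotropic conglomerate
stiffness, loaded at infinity by a purely volumetric or purely deviatoric
homogeneous strain.  Macropores are treated as spherical drained inclusions
in the same effective medium (Eshelby problem).  Volume-fraction weighted
phase averages of mean/deviatoric stress and strain then define the bulk
and shear modulus implicitly; a damped fixed point solves for (k, mu).

Displacement solutions
----------------------
Volumetric load: the radial displacement in each shell is a combination of
``r**(-1/2 + n)`` and ``r**(-1/2 - n)`` with n the radial exponent of the
shell material (3/2 when isotropic), and the radial stress of a branch
``xi_r = r**s`` is ``(Crr s + 2 Crt) r**(s-1)``.

Deviatoric load: with the classical pure-shear angular dependence
(xi_r ~ sin^2(th) cos(2phi), xi_th ~ sin(th) cos(th) cos(2phi),
xi_phi = -xi_th with sin(2phi)), equilibrium reduces per shell to a coupled
pair of Euler-type ODEs for the radial amplitudes (U_r, U_t).  A power-law
branch U = v r^s exists where the 2x2 matrix

    P(s) = [ Crr s(s+1) + 2Crt - 2Ctp - 2Ctt - 6G   -3(Crt+G)s - 3(Crt-Ctp-Ctt-G) ]
           [ 2(Crt+G)s + 2(Ctp+Ctt+2G)               G s(s+1) - Ctp - 5Ctt - 2G   ]

is singular; the four admissible exponents are the roots of det P(s) = 0
(a quartic) and beta(s) = -P11/P12 fixes the tangential/radial amplitude
ratio.  For isotropic shells this machinery reproduces the classical
coated-sphere exponents s = 1, 3, -2, -4 and amplitude ratios exactly; the
classical closed forms are kept in the test suite as an independent oracle.

Phase averages are evaluated exactly from boundary terms: because the
fields satisfy equilibrium, volume averages of strain (stress) over a shell
reduce by the divergence theorem to surface integrals of sym(xi (x) n)
(sym(t (x) x)) over the shell boundaries, which are closed-form in the
angular variables and involve only the radial functions at the interface
radii:

    <tr eps> V        = 4 pi [r^2 xi_r]                 (volumetric)
    <sig_m> V         = (4 pi / 3) [r^3 sig_rr]
    <e_xx - e_yy> V   = (8 pi / 15) [r^2 (2 U_r + 3 U_t)]   (deviatoric)
    <s_xx - s_yy> V   = (8 pi / 15) [r^3 (2 S_rr + 3 S_rt)]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize

from .bone import spherical_ti_constants
from .tensors import IsotropicModuli, Stiffness, iso_project

__all__ = [
    "CoatedSphereGeometry",
    "CoatedSphereSolution",
    "ConglomerateEstimate",
    "ConglomerateConvergenceError",
    "solve_volumetric",
    "solve_deviatoric",
    "macropore_fields",
    "homogenize_conglomerate",
]

#: moduli below this (GPa) are treated as a fully percolated, zero-stiffness
#: conglomerate (drained macropores at and beyond the percolation porosity)
ZERO_STIFFNESS_FLOOR = 1e-9


class ConglomerateConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoatedSphereGeometry:
    """Radii and conglomerate volume fractions of the coated-granule motif.

    Consistency between radii and fractions, (r_bone/r_gran)^3 =
    (f_gran + f_bone)/f_gran, is enforced at construction.
    """

    r_gran: float
    r_bone: float
    f_gran: float
    f_bone: float
    phi_macro: float

    def __post_init__(self) -> None:
        if self.r_gran <= 0 or self.r_bone < self.r_gran:
            raise ValueError("need 0 < r_gran <= r_bone")
        s = self.f_gran + self.f_bone + self.phi_macro
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"volume fractions sum to {s}, not 1")
        if min(self.f_gran, self.f_bone, self.phi_macro) < -1e-12:
            raise ValueError("volume fractions must be non-negative")
        lhs = (self.r_bone / self.r_gran) ** 3
        rhs = (self.f_gran + self.f_bone) / self.f_gran
        if abs(lhs - rhs) > 1e-8 * max(rhs, 1.0):
            raise ValueError(
                f"radii inconsistent with fractions: (r_bone/r_gran)^3={lhs}, "
                f"(f_gran+f_bone)/f_gran={rhs}")

    @classmethod
    def from_fractions(cls, r_gran: float, f_gran: float, f_bone: float,
                       phi_macro: float | None = None) -> "CoatedSphereGeometry":
        if phi_macro is None:
            phi_macro = 1.0 - f_gran - f_bone
        r_bone = r_gran * ((f_gran + f_bone) / f_gran) ** (1.0 / 3.0)
        return cls(r_gran, r_bone, f_gran, f_bone, phi_macro)

    @property
    def is_two_layer(self) -> bool:
        """True when there is no bone coating shell."""
        return self.f_bone <= 1e-14 or self.r_bone <= self.r_gran * (1.0 + 1e-14)


# ---------------------------------------------------------------------------
# per-shell material description: ph = (Crr, Crt, Ctt, Ctp, G_rt)
# ---------------------------------------------------------------------------

def _iso_ph(k: float, mu: float) -> tuple[float, float, float, float, float]:
    return (k + 4.0 * mu / 3.0, k - 2.0 * mu / 3.0,
            k + 4.0 * mu / 3.0, k - 2.0 * mu / 3.0, mu)


def _is_iso(ph) -> bool:
    crr, crt, ctt, ctp, g = ph
    scale = max(abs(crr), abs(g), 1e-300)
    return (abs(crr - ctt) < 1e-11 * scale and abs(crt - ctp) < 1e-11 * scale
            and abs(crr - crt - 2.0 * g) < 1e-11 * scale)


def _radial_exponent(ph) -> float:
    crr, crt, ctt, ctp, _ = ph
    return float(np.sqrt(0.25 + 2.0 * (ctt + ctp - crt) / crr))


def _vol_srr_coeff(ph, s: float) -> float:
    crr, crt, _, _, _ = ph
    return crr * s + 2.0 * crt


def _dev_P(ph, s: float) -> np.ndarray:
    crr, crt, ctt, ctp, g = ph
    return np.array([
        [crr * s * (s + 1.0) + 2.0 * crt - 2.0 * ctp - 2.0 * ctt - 6.0 * g,
         -3.0 * (crt + g) * s - 3.0 * (crt - ctp - ctt - g)],
        [2.0 * (crt + g) * s + 2.0 * (ctp + ctt + 2.0 * g),
         g * s * (s + 1.0) - ctp - 5.0 * ctt - 2.0 * g],
    ])


def _beta_of(ph, s: float) -> float:
    P = _dev_P(ph, s)
    if abs(P[0, 1]) >= abs(P[1, 1]):
        return -P[0, 0] / P[0, 1]
    return -P[1, 0] / P[1, 1]


@lru_cache(maxsize=4096)
def _dev_exponents_cached(ph) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Roots s of det P(s) = 0 (ascending) and amplitude ratios beta(s).

    Isotropic shells short-circuit to the classical exponents (-4, -2, 1, 3).
    For anisotropic shells the quartic det P is reconstructed exactly from
    five samples and solved by companion-matrix eigenvalues.
    """
    if _is_iso(ph):
        roots = (-4.0, -2.0, 1.0, 3.0)
        return roots, tuple(_beta_of(ph, s) for s in roots)
    ss = np.array([-3.0, -1.0, 0.0, 1.0, 2.0])
    dets = np.array([np.linalg.det(_dev_P(ph, s)) for s in ss])
    coeffs = np.polynomial.polynomial.polyfit(ss, dets, 4)
    roots = np.polynomial.polynomial.polyroots(coeffs)
    if np.abs(roots.imag).max() > 1e-8 * max(np.abs(roots.real).max(), 1.0):
        raise ValueError(f"complex displacement exponents {roots} (unphysical stiffness)")
    roots = np.sort(roots.real)
    if np.min(np.diff(roots)) < 1e-8:
        raise ValueError(f"degenerate (repeated) displacement exponents {roots}")
    return tuple(roots.tolist()), tuple(_beta_of(ph, s) for s in roots)


def _dev_exponents(ph) -> tuple[tuple[float, ...], tuple[float, ...]]:
    return _dev_exponents_cached(tuple(round(float(x), 14) for x in ph))


def _dev_srr_coeff(ph, s: float, beta: float) -> float:
    crr, crt, _, _, _ = ph
    return crr * s + crt * (2.0 - 3.0 * beta)


def _dev_srt_coeff(ph, s: float, beta: float) -> float:
    return ph[4] * (2.0 + beta * (s - 1.0))


# ---------------------------------------------------------------------------
# internal solvers on phase-constant tuples (fast path)
# ---------------------------------------------------------------------------

def _vol_solve(ph_g, ph_b, ph_c, r1, r2, two_layer, E0):
    """Returns (amps, strain_avg, stress_avg) dicts keyed gran/bone/congl."""
    a0 = E0 / 3.0
    ng = _radial_exponent(ph_g)
    nc = _radial_exponent(ph_c)
    sg = -0.5 + ng
    sc_grow, sc_dec = -0.5 + nc, -0.5 - nc
    if two_layer:
        sb = (0.0, 0.0)
        A = np.array([
            [r1 ** sg, -r1 ** sc_dec],
            [_vol_srr_coeff(ph_g, sg) * r1 ** (sg - 1.0),
             -_vol_srr_coeff(ph_c, sc_dec) * r1 ** (sc_dec - 1.0)],
        ])
        rhs = np.array([a0 * r1,
                        _vol_srr_coeff(ph_c, sc_grow) * a0 * r1 ** (sc_grow - 1.0)])
        gg, gc = np.linalg.solve(A, rhs)
        amps = {"gran": (gg,), "bone": (0.0, 0.0), "congl": (a0, gc)}
    else:
        nb = _radial_exponent(ph_b)
        sb = (-0.5 + nb, -0.5 - nb)
        A = np.zeros((4, 4))
        rhs = np.zeros(4)
        A[0] = [r1 ** sg, -r1 ** sb[0], -r1 ** sb[1], 0.0]
        A[1] = [_vol_srr_coeff(ph_g, sg) * r1 ** (sg - 1.0),
                -_vol_srr_coeff(ph_b, sb[0]) * r1 ** (sb[0] - 1.0),
                -_vol_srr_coeff(ph_b, sb[1]) * r1 ** (sb[1] - 1.0), 0.0]
        A[2] = [0.0, r2 ** sb[0], r2 ** sb[1], -r2 ** sc_dec]
        rhs[2] = a0 * r2
        A[3] = [0.0, _vol_srr_coeff(ph_b, sb[0]) * r2 ** (sb[0] - 1.0),
                _vol_srr_coeff(ph_b, sb[1]) * r2 ** (sb[1] - 1.0),
                -_vol_srr_coeff(ph_c, sc_dec) * r2 ** (sc_dec - 1.0)]
        rhs[3] = _vol_srr_coeff(ph_c, sc_grow) * a0 * r2 ** (sc_grow - 1.0)
        gg, gb1, gb2, gc = np.linalg.solve(A, rhs)
        amps = {"gran": (gg,), "bone": (gb1, gb2), "congl": (a0, gc)}

    strain, stress = {}, {}
    xi1 = amps["gran"][0] * r1 ** sg
    srr1 = _vol_srr_coeff(ph_g, sg) * amps["gran"][0] * r1 ** (sg - 1.0)
    strain["gran"] = 3.0 * xi1 / r1
    stress["gran"] = srr1
    if two_layer:
        strain["bone"] = stress["bone"] = 0.0
    else:
        gb1, gb2 = amps["bone"]

        def xib(r):
            return gb1 * r ** sb[0] + gb2 * r ** sb[1]

        def srrb(r):
            return (_vol_srr_coeff(ph_b, sb[0]) * gb1 * r ** (sb[0] - 1.0)
                    + _vol_srr_coeff(ph_b, sb[1]) * gb2 * r ** (sb[1] - 1.0))

        dv = r2 ** 3 - r1 ** 3
        strain["bone"] = 3.0 * (r2 ** 2 * xib(r2) - r1 ** 2 * xib(r1)) / dv
        stress["bone"] = (r2 ** 3 * srrb(r2) - r1 ** 3 * srrb(r1)) / dv
    exps = {"gran": (sg,), "bone": sb, "congl": (sc_grow, sc_dec)}
    return exps, amps, strain, stress


def _dev_solve(ph_g, ph_b, ph_c, r1, r2, two_layer, gamma):
    sg, bg = _dev_exponents(ph_g)
    sc, bc = _dev_exponents(ph_c)
    keep_g = [i for i in range(4) if sg[i] > -1e-9]
    keep_c = [i for i in range(4) if sc[i] < -1e-9]
    if len(keep_g) != 2 or len(keep_c) != 2:
        raise ValueError("unexpected exponent pattern; cannot classify branches")
    i_rem = int(np.argmin(np.abs(np.array(sc) - 1.0)))

    def col(ph, s, beta, r, sign=1.0):
        rs = r ** s
        return sign * np.array([
            rs, beta * rs,
            _dev_srr_coeff(ph, s, beta) * rs / r,
            _dev_srt_coeff(ph, s, beta) * rs / r,
        ])

    if two_layer:
        sb, bb = (0.0,) * 4, (0.0,) * 4
        A = np.empty((4, 4))
        for j, i in enumerate(keep_g):
            A[:, j] = col(ph_g, sg[i], bg[i], r1)
        for j, i in enumerate(keep_c):
            A[:, 2 + j] = col(ph_c, sc[i], bc[i], r1, sign=-1.0)
        x = np.linalg.solve(A, col(ph_c, sc[i_rem], bc[i_rem], r1) * gamma)
        amps_g, amps_b, amps_c = x[:2], np.zeros(4), x[2:]
    else:
        sb, bb = _dev_exponents(ph_b)
        A = np.zeros((8, 8))
        rhs = np.zeros(8)
        for j, i in enumerate(keep_g):
            A[:4, j] = col(ph_g, sg[i], bg[i], r1)
        for j in range(4):
            A[:4, 2 + j] = col(ph_b, sb[j], bb[j], r1, sign=-1.0)
            A[4:, 2 + j] = col(ph_b, sb[j], bb[j], r2)
        for j, i in enumerate(keep_c):
            A[4:, 6 + j] = col(ph_c, sc[i], bc[i], r2, sign=-1.0)
        rhs[4:] = col(ph_c, sc[i_rem], bc[i_rem], r2) * gamma
        x = np.linalg.solve(A, rhs)
        amps_g, amps_b, amps_c = x[:2], x[2:6], x[6:]

    def shell_avgs(ph, exps, betas, amps, r_in, r_out):
        def F(r):
            ur = sum(a * r ** s for a, s in zip(amps, exps))
            ut = sum(a * b * r ** s for a, b, s in zip(amps, betas, exps))
            return r ** 2 * (2.0 * ur + 3.0 * ut)

        def H(r):
            srr = sum(a * _dev_srr_coeff(ph, s, b) * r ** (s - 1.0)
                      for a, b, s in zip(amps, betas, exps))
            srt = sum(a * _dev_srt_coeff(ph, s, b) * r ** (s - 1.0)
                      for a, b, s in zip(amps, betas, exps))
            return r ** 3 * (2.0 * srr + 3.0 * srt)

        dv = r_out ** 3 - r_in ** 3
        Fin = F(r_in) if r_in > 0 else 0.0
        Hin = H(r_in) if r_in > 0 else 0.0
        return (0.4 * (F(r_out) - Fin) / dv, 0.4 * (H(r_out) - Hin) / dv)
        # 0.4 = (8 pi / 15) / (4 pi / 3)

    strain, stress = {}, {}
    strain["gran"], stress["gran"] = shell_avgs(
        ph_g, [sg[i] for i in keep_g], [bg[i] for i in keep_g], amps_g, 0.0, r1)
    if two_layer:
        strain["bone"] = stress["bone"] = 0.0
    else:
        strain["bone"], stress["bone"] = shell_avgs(ph_b, sb, bb, amps_b, r1, r2)

    exps = {"gran": tuple(sg[i] for i in keep_g), "bone": tuple(sb),
            "congl": (sc[i_rem],) + tuple(sc[i] for i in keep_c)}
    bets = {"gran": tuple(bg[i] for i in keep_g), "bone": tuple(bb),
            "congl": (bc[i_rem],) + tuple(bc[i] for i in keep_c)}
    amps = {"gran": tuple(amps_g), "bone": tuple(amps_b),
            "congl": (gamma,) + tuple(amps_c)}
    return exps, bets, amps, strain, stress


# ---------------------------------------------------------------------------
# public coated-sphere solutions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoatedSphereSolution:
    """Coefficients and phase averages of one load case.

    ``coefficients`` maps phase name -> (exponents, betas, amplitudes);
    betas is None for the volumetric case.  ``strain_avg``/``stress_avg``
    map phase name -> scalar measure: volumetric strain / mean stress for
    the volumetric case, the (xx - yy) strain / stress component for the
    deviatoric case (the remote strain has (xx - yy) = 2*amplitude).
    """

    load_case: str
    amplitude: float
    geometry: CoatedSphereGeometry
    coefficients: dict
    strain_avg: dict
    stress_avg: dict
    phase_constants: dict = field(default_factory=dict, repr=False)

    def radial_functions(self, phase: str):
        """Displacement/traction radial functions of one phase.

        Volumetric case: (xi_r, sigma_rr); deviatoric case:
        (U_r, U_t, S_rr, S_rt) with the angular carriers factored out.
        """
        ph = self.phase_constants[phase]
        exps, betas, amps = self.coefficients[phase]
        if self.load_case == "volumetric":
            def xi(r):
                return sum(a * r ** s for a, s in zip(amps, exps))

            def srr(r):
                return sum(a * _vol_srr_coeff(ph, s) * r ** (s - 1.0)
                           for a, s in zip(amps, exps))

            return xi, srr

        def ur(r):
            return sum(a * r ** s for a, s in zip(amps, exps))

        def ut(r):
            return sum(a * b * r ** s for a, b, s in zip(amps, betas, exps))

        def srr(r):
            return sum(a * _dev_srr_coeff(ph, s, b) * r ** (s - 1.0)
                       for a, b, s in zip(amps, betas, exps))

        def srt(r):
            return sum(a * _dev_srt_coeff(ph, s, b) * r ** (s - 1.0)
                       for a, b, s in zip(amps, betas, exps))

        return ur, ut, srr, srt

    def interface_residual(self) -> float:
        """Max relative displacement/traction jump across the interfaces."""
        geo = self.geometry
        pairs = ([("gran", "congl", geo.r_gran)] if geo.is_two_layer
                 else [("gran", "bone", geo.r_gran),
                       ("bone", "congl", geo.r_bone)])
        res = 0.0
        for inner, outer, r in pairs:
            vi = np.array([f(r) for f in self.radial_functions(inner)])
            vo = np.array([f(r) for f in self.radial_functions(outer)])
            scale = np.maximum(np.maximum(np.abs(vi), np.abs(vo)),
                               1e-12 * max(abs(self.amplitude), 1e-300))
            res = max(res, float(np.max(np.abs(vi - vo) / scale)))
        return res


def _stiffness_to_ph(C: Stiffness):
    return spherical_ti_constants(C)


def solve_volumetric(C_gran: Stiffness, C_bone_spherical: Stiffness,
                     C_congl: Stiffness, geometry: CoatedSphereGeometry,
                     E_vol0: float = 1.0) -> CoatedSphereSolution:
    """Solve the coated-sphere problem under remote hydrostatic strain.

    The remote condition fixes the amplitude of the linearly growing branch
    in the outer medium at E_vol0/3; regularity at the origin removes the
    singular branch in the granule; the remaining coefficients follow from
    displacement and radial-traction continuity at the interfaces.
    """
    ph_g, ph_b, ph_c = (_stiffness_to_ph(C) for C in
                        (C_gran, C_bone_spherical, C_congl))
    try:
        exps, amps, strain, stress = _vol_solve(
            ph_g, ph_b, ph_c, geometry.r_gran, geometry.r_bone,
            geometry.is_two_layer, E_vol0)
    except np.linalg.LinAlgError as err:
        raise ConglomerateConvergenceError(
            f"singular volumetric interface system: {err}", []) from err
    coeff = {name: (exps[name], None, amps[name]) for name in exps}
    return CoatedSphereSolution(
        "volumetric", E_vol0, geometry, coeff, strain, stress,
        {"gran": ph_g, "bone": ph_b, "congl": ph_c})


def solve_deviatoric(C_gran: Stiffness, C_bone_spherical: Stiffness,
                     C_congl: Stiffness, geometry: CoatedSphereGeometry,
                     gamma: float = 1.0) -> CoatedSphereSolution:
    """Solve the coated-sphere problem under remote pure shear
    gamma (e_x e_x - e_y e_y).

    Regularity keeps the two non-singular branches in the granule; the
    remote condition pins the linear branch of the outer medium at amplitude
    gamma and removes its r^3 branch; the remaining 8 coefficients solve the
    8 continuity conditions (xi_r, xi_theta, sigma_rr, sigma_rtheta at both
    interfaces).
    """
    ph_g, ph_b, ph_c = (_stiffness_to_ph(C) for C in
                        (C_gran, C_bone_spherical, C_congl))
    try:
        exps, bets, amps, strain, stress = _dev_solve(
            ph_g, ph_b, ph_c, geometry.r_gran, geometry.r_bone,
            geometry.is_two_layer, gamma)
    except np.linalg.LinAlgError as err:
        raise ConglomerateConvergenceError(
            f"singular deviatoric interface system: {err}", []) from err
    coeff = {name: (exps[name], bets[name], amps[name]) for name in exps}
    return CoatedSphereSolution(
        "deviatoric", gamma, geometry, coeff, strain, stress,
        {"gran": ph_g, "bone": ph_b, "congl": ph_c})


def macropore_fields(C_congl: Stiffness, load_case: str,
                     amplitude: float = 1.0) -> tuple[float, float]:
    """Average strain/stress measures in a drained spherical macropore.

    Returns (strain_measure, stress_measure): volumetric strain and mean
    stress for ``load_case='volumetric'`` (remote tr E = amplitude), or the
    (xx - yy) strain/stress components for ``'deviatoric'`` (remote
    (xx - yy) = 2*amplitude).  The pore is drained, so its stress vanishes
    identically; the strain concentration follows the spherical Eshelby
    problem with zero inclusion stiffness:

        volumetric: (3k + 4mu) / (4mu)
        deviatoric: 5 (3k + 4mu) / (9k + 8mu)
    """
    moduli, _ = iso_project(C_congl)
    return _macropore(moduli.k, moduli.mu, load_case, amplitude)


def _macropore(k: float, mu: float, load_case: str, amplitude: float):
    if mu <= 1e-12 * max(k, 1.0):
        raise ValueError("macropore concentration undefined for zero shear stiffness")
    if load_case == "volumetric":
        return (3.0 * k + 4.0 * mu) / (4.0 * mu) * amplitude, 0.0
    if load_case == "deviatoric":
        return 5.0 * (3.0 * k + 4.0 * mu) / (9.0 * k + 8.0 * mu) * 2.0 * amplitude, 0.0
    raise ValueError(f"unknown load case {load_case!r}")


# ---------------------------------------------------------------------------
# implicit homogenization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConglomerateEstimate:
    moduli: IsotropicModuli
    iterations: int
    residual: float


def _update_map(ph_g, ph_b, geometry, k, mu):
    """One evaluation of the implicit (k, mu) -> (k', mu') map."""
    ph_c = _iso_ph(k, mu)
    fg, fb, phi = geometry.f_gran, geometry.f_bone, geometry.phi_macro
    r1, r2, two = geometry.r_gran, geometry.r_bone, geometry.is_two_layer
    _, _, ve, vs = _vol_solve(ph_g, ph_b, ph_c, r1, r2, two, 1.0)
    _, _, _, de, ds = _dev_solve(ph_g, ph_b, ph_c, r1, r2, two, 1.0)
    if phi > 0:
        pe, ps = _macropore(k, mu, "volumetric", 1.0)
        pde, pds = _macropore(k, mu, "deviatoric", 1.0)
    else:
        pe = ps = pde = pds = 0.0
    E_vol = fg * ve["gran"] + fb * ve["bone"] + phi * pe
    S_m = fg * vs["gran"] + fb * vs["bone"] + phi * ps
    E_dev = fg * de["gran"] + fb * de["bone"] + phi * pde
    S_dev = fg * ds["gran"] + fb * ds["bone"] + phi * pds
    return S_m / E_vol, S_dev / (2.0 * E_dev)


def homogenize_conglomerate(C_gran: Stiffness, C_bone_spherical: Stiffness,
                            geometry: CoatedSphereGeometry, *,
                            tol: float = 1e-9, max_iter: int = 200,
                            damping: float = 0.5,
                            initial: tuple[float, float] | None = None
                            ) -> ConglomerateEstimate:
    """Fixed point for the conglomerate bulk and shear moduli.

    Damped iteration starting from the macroporosity-scaled Voigt mixture
    of granule and bone moduli (or the caller-provided ``initial`` warm
    start); if the iteration stalls, a derivative-free root solve on the
    two-component residual finishes the job.  Iterates that decay below
    ``ZERO_STIFFNESS_FLOOR`` are classified as a percolated, zero-stiffness
    conglomerate (the drained macropores disconnect the load path), which
    is a regular model outcome, not a failure.
    """
    g_mod, _ = iso_project(C_gran)
    b_mod, _ = iso_project(C_bone_spherical)
    ph_g = _stiffness_to_ph(C_gran)
    ph_b = _stiffness_to_ph(C_bone_spherical)
    fg, fb, phi = geometry.f_gran, geometry.f_bone, geometry.phi_macro
    if phi <= 1e-14 and fb <= 1e-14:
        return ConglomerateEstimate(g_mod, 0, 0.0)
    if initial is None:
        k = fg * g_mod.k + fb * b_mod.k
        mu = fg * g_mod.mu + fb * b_mod.mu
    else:
        k, mu = initial
    k, mu = max(k, 1e-6), max(mu, 1e-6)
    trace: list[tuple[float, float]] = []
    for it in range(1, max_iter + 1):
        try:
            k_new, mu_new = _update_map(ph_g, ph_b, geometry, k, mu)
        except np.linalg.LinAlgError as err:
            raise ConglomerateConvergenceError(
                f"singular interface system at iterate {it}: {err}", trace) from err
        k_new, mu_new = max(k_new, 0.0), max(mu_new, 0.0)
        trace.append((k_new, mu_new))
        if k_new < ZERO_STIFFNESS_FLOOR or mu_new < ZERO_STIFFNESS_FLOOR:
            return ConglomerateEstimate(IsotropicModuli(0.0, 0.0), it, 0.0)
        dk = abs(k_new - k) / k_new
        dmu = abs(mu_new - mu) / mu_new
        k = damping * k + (1.0 - damping) * k_new
        mu = damping * mu + (1.0 - damping) * mu_new
        if dk < tol and dmu < tol:
            return ConglomerateEstimate(IsotropicModuli(k, mu), it, max(dk, dmu))
    # At the percolation porosity the iterates decay sublinearly (~1/n) to
    # zero and never meet a relative tolerance.  A long, strictly monotone
    # decay tail with substantial total decrease is classified as the
    # zero-stiffness outcome; a positive fixed point cannot sustain this,
    # since the damped map contracts geometrically near any positive root.
    tail = min(150, len(trace) - 1)
    mus = [m for _, m in trace[-tail - 1:]]
    monotone = all(b <= a * (1.0 + 1e-12) for a, b in zip(mus, mus[1:]))
    if monotone and mus[-1] < mus[0] / 1.5:
        return ConglomerateEstimate(IsotropicModuli(0.0, 0.0), max_iter, 0.0)

    def residual(x):
        kk, mm = np.exp(x)
        try:
            kn, mn = _update_map(ph_g, ph_b, geometry, kk, mm)
        except (np.linalg.LinAlgError, ValueError):
            return [10.0, 10.0]
        if kn <= 0 or mn <= 0:
            return [10.0, 10.0]
        return [np.log(kn / kk), np.log(mn / mm)]

    sol = optimize.root(residual, np.log([k, mu]), method="hybr",
                        options={"xtol": tol})
    if not sol.success:
        raise ConglomerateConvergenceError(
            f"conglomerate fixed point did not converge: {sol.message}", trace)
    k, mu = np.exp(sol.x)
    res = max(abs(r) for r in residual(sol.x))
    return ConglomerateEstimate(IsotropicModuli(float(k), float(mu)),
                                max_iter, float(res))
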