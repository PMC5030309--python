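"""Shared fixtures and independent oracles for the test suite.

The spherical-field evaluator here is an independent implementation path:
strain components are assembled directly from the spherical-coordinate
kinematic relations for the two load-case ansatz families, stresses follow
from the constitutive law, and tensors are rotated to Cartesian axes with
explicit basis vectors.  It deliberately does not reuse the package's
boundary-term average formulas, so it can serve as the oracle for them.
"""

from __future__ import annotations

import numpy as np
import pytest

from scaffmech.tensors import IsotropicModuli


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160921)


def iso_phase_constants(k: float, mu: float):
    """(Crr, Crt, Ctt, Ctp, G) of an isotropic shell material."""
    return (k + 4 * mu / 3, k - 2 * mu / 3, k + 4 * mu / 3, k - 2 * mu / 3, mu)


def spherical_basis(theta: float, phi: float):
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    e_r = np.array([st * cp, st * sp, ct])
    e_t = np.array([ct * cp, ct * sp, -st])
    e_p = np.array([-sp, cp, 0.0])
    return e_r, e_t, e_p


class FieldEvaluator:
    """Pointwise strain/stress fields of one shell of a coated-sphere solution.

    Built from the branch data (exponents, betas, amplitudes) and the shell's
    spherical-frame constants (Crr, Crt, Ctt, Ctp, G).
    """

    def __init__(self, ph, exps, betas, amps, load_case):
        self.ph = ph
        self.exps = np.atleast_1d(np.asarray(exps, float))
        self.betas = None if betas is None else np.atleast_1d(np.asarray(betas, float))
        self.amps = np.atleast_1d(np.asarray(amps, float))
        self.load_case = load_case

    def _radials(self, r):
        rs = r ** self.exps
        u_r = float(np.sum(self.amps * rs))
        du_r = float(np.sum(self.amps * self.exps * rs / r))
        if self.betas is None:
            return u_r, du_r, 0.0, 0.0
        u_t = float(np.sum(self.amps * self.betas * rs))
        du_t = float(np.sum(self.amps * self.betas * self.exps * rs / r))
        return u_r, du_r, u_t, du_t

    def strain_spherical(self, r, theta, phi):
        """Strain components in the (r, theta, phi) basis at one point."""
        u_r, du_r, u_t, du_t = self._radials(r)
        if self.load_case == "volumetric":
            e = np.zeros((3, 3))
            e[0, 0] = du_r
            e[1, 1] = e[2, 2] = u_r / r
            return e
        st, ct = np.sin(theta), np.cos(theta)
        c2p, s2p = np.cos(2 * phi), np.sin(2 * phi)
        e = np.zeros((3, 3))
        e[0, 0] = du_r * st ** 2 * c2p
        e[1, 1] = (u_t * (ct ** 2 - st ** 2) + u_r * st ** 2) * c2p / r
        e[2, 2] = (u_r * st ** 2 + u_t * ct ** 2 - 2 * u_t) * c2p / r
        e_rt = 0.5 * st * ct * c2p * (2 * u_r / r + du_t - u_t / r)
        e_rp = -0.5 * st * s2p * (2 * u_r / r + du_t - u_t / r)
        e_tp = -(u_t / r) * ct * s2p
        e[0, 1] = e[1, 0] = e_rt
        e[0, 2] = e[2, 0] = e_rp
        e[1, 2] = e[2, 1] = e_tp
        return e

    def stress_spherical(self, r, theta, phi):
        crr, crt, ctt, ctp, g = self.ph
        gtp = 0.5 * (ctt - ctp)
        e = self.strain_spherical(r, theta, phi)
        s = np.zeros((3, 3))
        s[0, 0] = crr * e[0, 0] + crt * (e[1, 1] + e[2, 2])
        s[1, 1] = crt * e[0, 0] + ctt * e[1, 1] + ctp * e[2, 2]
        s[2, 2] = crt * e[0, 0] + ctp * e[1, 1] + ctt * e[2, 2]
        s[0, 1] = s[1, 0] = 2 * g * e[0, 1]
        s[0, 2] = s[2, 0] = 2 * g * e[0, 2]
        s[1, 2] = s[2, 1] = 2 * gtp * e[1, 2]
        return s

    def tensor_cartesian(self, which, r, theta, phi):
        t = (self.strain_spherical if which == "strain"
             else self.stress_spherical)(r, theta, phi)
        basis = np.column_stack(spherical_basis(theta, phi))  # columns e_r,e_t,e_p
        return basis @ t @ basis.T

    def shell_average(self, which, r_in, r_out, n_r=24, n_t=24, n_p=24):
        """Volume average over the shell by Gauss-product quadrature."""
        xr, wr = np.polynomial.legendre.leggauss(n_r)
        xt, wt = np.polynomial.legendre.leggauss(n_t)
        rr = 0.5 * (r_out - r_in) * xr + 0.5 * (r_out + r_in)
        wrr = 0.5 * (r_out - r_in) * wr
        tt = np.arccos(xt)
        pp = np.arange(n_p) * 2 * np.pi / n_p
        acc = np.zeros((3, 3))
        vol = 0.0
        for r, w_r in zip(rr, wrr):
            for t, w_t in zip(tt, wt):
                for p in pp:
                    w = w_r * w_t * (2 * np.pi / n_p) * r ** 2
                    acc += w * self.tensor_cartesian(which, r, t, p)
                    vol += w
        return acc / vol


def classical_iso_branches(nu: float):
    """Deviatoric displacement branches of an isotropic shell, classical form.

    Returns (exponents, beta ratios) for the branch set (r, r^3, r^-4, r^-2)
    as published for the coated-sphere (shear) problem:
      xi_r ~ [G1 r, -6nu/(1-2nu) G2 r^3, 3 G3 / r^4, (5-4nu)/(1-2nu) G4 / r^2]
      xi_t ~ [G1 r, -(7-4nu)/(1-2nu) G2 r^3, -2 G3 / r^4, 2 G4 / r^2]
    """
    exps = np.array([1.0, 3.0, -4.0, -2.0])
    betas = np.array([
        1.0,
        (7.0 - 4.0 * nu) / (6.0 * nu) if nu != 0 else np.inf,
        -2.0 / 3.0,
        2.0 * (1.0 - 2.0 * nu) / (5.0 - 4.0 * nu),
    ])
    return exps, betas


@pytest.fixture
def sample_moduli():
    return IsotropicModuli(k=10.0, mu=6.0)
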