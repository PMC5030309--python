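"""Generalized coated-sphere scheme and the level-III fixed point."""

import numpy as np
import pytest

from conftest import FieldEvaluator, classical_iso_branches, iso_phase_constants

from scaffmech.bone import BONE_STIFFNESS_SPHERICAL
from scaffmech.conglomerate import (
    CoatedSphereGeometry,
    _dev_exponents,
    homogenize_conglomerate,
    macropore_fields,
    solve_deviatoric,
    solve_volumetric,
)
from scaffmech.granule import granule_moduli
from scaffmech.tensors import IsotropicModuli, iso_stiffness


@pytest.fixture(scope="module")
def cracked_granule():
    return granule_moduli(0.445, 0.189, 66.85)


@pytest.fixture(scope="module")
def mild_granule():
    return granule_moduli(0.445, 0.189, 10.0)


@pytest.fixture(scope="module")
def geometry():
    return CoatedSphereGeometry.from_fractions(500.0, 0.6, 0.2, 0.2)


class TestGeometry:
    def test_fraction_radius_consistency_enforced(self):
        with pytest.raises(ValueError):
            CoatedSphereGeometry(500.0, 700.0, 0.6, 0.2, 0.2)

    def test_from_fractions(self):
        g = CoatedSphereGeometry.from_fractions(500.0, 0.6, 0.2)
        assert g.phi_macro == pytest.approx(0.2)
        assert (g.r_bone / g.r_gran) ** 3 == pytest.approx(0.8 / 0.6)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CoatedSphereGeometry(500.0, 550.0, 0.5, 0.2, 0.2)


class TestDeviatoricExponents:
    def test_isotropic_reproduces_classical_set(self):
        ph = iso_phase_constants(10.0, 6.0)
        exps, betas = _dev_exponents(ph)
        assert np.allclose(sorted(exps), [-4.0, -2.0, 1.0, 3.0], atol=1e-10)
        nu = IsotropicModuli(10.0, 6.0).nu
        ref_e, ref_b = classical_iso_branches(nu)
        order = np.argsort(ref_e)
        assert np.allclose(np.sort(ref_e), np.array(exps), atol=1e-10)
        assert np.allclose(np.array(ref_b)[order], np.array(betas), rtol=1e-9)

    def test_bone_exponents_real_and_distinct(self):
        from scaffmech.bone import spherical_ti_constants

        ph = spherical_ti_constants(BONE_STIFFNESS_SPHERICAL)
        exps, _ = _dev_exponents(ph)
        assert len(set(np.round(exps, 6))) == 4
        # two regular, two decaying branches
        assert sum(e > 0 for e in exps) == 2


class TestVolumetricSolution:
    def test_homogeneous_medium(self, geometry):
        C = iso_stiffness(IsotropicModuli(10.0, 6.0))
        sol = solve_volumetric(C, C, C, geometry, E_vol0=0.9)
        for phase in ("gran", "bone"):
            assert sol.strain_avg[phase] == pytest.approx(0.9, rel=1e-10)
            assert sol.stress_avg[phase] == pytest.approx(10.0 * 0.9, rel=1e-10)
        # decaying coefficients vanish
        assert abs(sol.coefficients["congl"][2][1]) < 1e-12 * geometry.r_bone ** 3

    def test_zero_load_gives_zero_fields(self, geometry, mild_granule):
        sol = solve_volumetric(iso_stiffness(mild_granule), BONE_STIFFNESS_SPHERICAL,
                               iso_stiffness(IsotropicModuli(1.0, 1.0)),
                               geometry, E_vol0=0.0)
        assert all(v == 0.0 for v in sol.strain_avg.values())
        assert all(v == 0.0 for v in sol.stress_avg.values())

    def test_two_phase_limit_matches_eshelby_concentration(self, mild_granule):
        # no coating: the granule is a plain spherical inclusion in the outer
        # medium, whose uniform strain follows the classical Eshelby solution
        geo = CoatedSphereGeometry.from_fractions(500.0, 0.7, 0.0, 0.3)
        outer = IsotropicModuli(2.0, 1.5)
        sol = solve_volumetric(iso_stiffness(mild_granule), BONE_STIFFNESS_SPHERICAL,
                               iso_stiffness(outer), geo, E_vol0=1.0)
        alpha = 3.0 * outer.k / (3.0 * outer.k + 4.0 * outer.mu)
        expected = 1.0 / (1.0 + alpha * (mild_granule.k / outer.k - 1.0))
        assert sol.strain_avg["gran"] == pytest.approx(expected, rel=1e-10)

    def test_interface_continuity(self, geometry, cracked_granule):
        sol = solve_volumetric(iso_stiffness(cracked_granule),
                               BONE_STIFFNESS_SPHERICAL,
                               iso_stiffness(IsotropicModuli(0.5, 0.3)),
                               geometry, E_vol0=1.0)
        assert sol.interface_residual() < 1e-9


class TestDeviatoricSolution:
    def test_homogeneous_medium(self, geometry):
        C = iso_stiffness(IsotropicModuli(10.0, 6.0))
        sol = solve_deviatoric(C, C, C, geometry, gamma=0.7)
        for phase in ("gran", "bone"):
            assert sol.strain_avg[phase] == pytest.approx(1.4, rel=1e-9)
            assert sol.stress_avg[phase] == pytest.approx(2 * 6.0 * 1.4, rel=1e-9)

    def test_isotropic_coating_matches_classical_branch_functions(self,
                                                                  mild_granule):
        """The generalized machinery fed an isotropic coating must reproduce
        the classical isotropic coated-sphere displacement fields."""
        bone_iso = IsotropicModuli(12.0, 5.0)
        outer = IsotropicModuli(3.0, 2.0)
        geo = CoatedSphereGeometry.from_fractions(1.0, 0.6, 0.2, 0.2)
        sol = solve_deviatoric(iso_stiffness(mild_granule),
                               iso_stiffness(bone_iso), iso_stiffness(outer),
                               geo, gamma=1.0)
        # bone branch structure equals the classical set
        exps, betas, amps = sol.coefficients["bone"]
        ref_e, ref_b = classical_iso_branches(bone_iso.nu)
        order = np.argsort(ref_e)
        assert np.allclose(np.array(exps), np.sort(ref_e), atol=1e-9)
        assert np.allclose(np.array(betas), np.array(ref_b)[order], rtol=1e-9)
        # and the fields are continuous to solver precision
        assert sol.interface_residual() < 1e-9

    def test_interface_continuity_anisotropic_coating(self, geometry,
                                                      cracked_granule):
        sol = solve_deviatoric(iso_stiffness(cracked_granule),
                               BONE_STIFFNESS_SPHERICAL,
                               iso_stiffness(IsotropicModuli(0.5, 0.3)),
                               geometry, gamma=1.0)
        assert sol.interface_residual() < 1e-9

    def test_remote_strain_measure(self, geometry, mild_granule):
        sol = solve_deviatoric(iso_stiffness(mild_granule),
                               BONE_STIFFNESS_SPHERICAL,
                               iso_stiffness(IsotropicModuli(1.0, 0.7)),
                               geometry, gamma=0.5)
        # the outer medium's linear branch carries exactly gamma
        exps, betas, amps = sol.coefficients["congl"]
        assert amps[0] == pytest.approx(0.5)
        assert exps[0] == pytest.approx(1.0, abs=1e-10)


class TestPhaseAverageOracle:
    """Boundary-term phase averages vs direct 3-D quadrature of the fields."""

    @pytest.mark.parametrize("load_case", ["volumetric", "deviatoric"])
    def test_shell_averages_match_quadrature(self, load_case, cracked_granule,
                                             geometry):
        solver = solve_volumetric if load_case == "volumetric" else solve_deviatoric
        sol = solver(iso_stiffness(cracked_granule), BONE_STIFFNESS_SPHERICAL,
                     iso_stiffness(IsotropicModuli(0.8, 0.5)), geometry, 1.0)
        for phase, (r_in, r_out) in (("gran", (0.0, geometry.r_gran)),
                                     ("bone", (geometry.r_gran, geometry.r_bone))):
            exps, betas, amps = sol.coefficients[phase]
            ev = FieldEvaluator(sol.phase_constants[phase], exps, betas, amps,
                                load_case)
            # quadrature avoids r = 0 (fields are regular; integrand ~ r^2)
            eps_q = ev.shell_average("strain", max(r_in, 1e-3 * r_out), r_out)
            sig_q = ev.shell_average("stress", max(r_in, 1e-3 * r_out), r_out)
            if load_case == "volumetric":
                strain_measure = np.trace(eps_q)
                stress_measure = np.trace(sig_q) / 3.0
            else:
                strain_measure = eps_q[0, 0] - eps_q[1, 1]
                stress_measure = sig_q[0, 0] - sig_q[1, 1]
            assert strain_measure == pytest.approx(sol.strain_avg[phase],
                                                   rel=1e-7, abs=1e-9)
            assert stress_measure == pytest.approx(sol.stress_avg[phase],
                                                   rel=1e-7, abs=1e-9)


class TestMacroporeFields:
    def test_volumetric_concentration_factor(self):
        C = iso_stiffness(IsotropicModuli(1.0, 1.0))
        strain, stress = macropore_fields(C, "volumetric", 1.0)
        assert strain == pytest.approx(7.0 / 4.0, abs=1e-14)
        assert stress == 0.0

    def test_deviatoric_concentration_factor(self):
        C = iso_stiffness(IsotropicModuli(1.0, 1.0))
        strain, stress = macropore_fields(C, "deviatoric", 1.0)
        assert strain == pytest.approx(2.0 * 35.0 / 17.0, abs=1e-13)
        assert stress == 0.0

    def test_zero_shear_rejected(self):
        with pytest.raises(ValueError):
            macropore_fields(iso_stiffness(IsotropicModuli(1.0, 0.0)),
                             "volumetric")


class TestHomogenization:
    def test_homogeneous_identity_in_one_iteration(self):
        m = IsotropicModuli(10.0, 7.0)
        geo = CoatedSphereGeometry.from_fractions(1.0, 0.6, 0.4, 0.0)
        est = homogenize_conglomerate(iso_stiffness(m), iso_stiffness(m), geo)
        assert est.iterations == 1
        assert est.moduli.k == pytest.approx(10.0, rel=1e-12)
        assert est.moduli.mu == pytest.approx(7.0, rel=1e-12)

    def test_no_pores_no_bone_returns_granule(self, mild_granule):
        geo = CoatedSphereGeometry.from_fractions(500.0, 1.0, 0.0, 0.0)
        est = homogenize_conglomerate(iso_stiffness(mild_granule),
                                      BONE_STIFFNESS_SPHERICAL, geo)
        assert est.moduli.k == pytest.approx(mild_granule.k, rel=1e-12)
        assert est.moduli.mu == pytest.approx(mild_granule.mu, rel=1e-12)

    def test_percolation_at_half_macroporosity(self, mild_granule):
        """Drained macropores at 50% disconnect the load path; the stiffness
        is quasi-zero compared to the 30% case."""
        C = iso_stiffness(mild_granule)
        geo3 = CoatedSphereGeometry.from_fractions(500.0, 0.7, 0.0, 0.3)
        geo5 = CoatedSphereGeometry.from_fractions(500.0, 0.5, 0.0, 0.5)
        E3 = homogenize_conglomerate(C, BONE_STIFFNESS_SPHERICAL, geo3).moduli.E
        E5 = homogenize_conglomerate(C, BONE_STIFFNESS_SPHERICAL, geo5).moduli.E
        assert E5 < 0.1 * E3

    def test_stiffness_increases_with_bone_fill(self, mild_granule):
        C = iso_stiffness(mild_granule)
        Es = []
        for f_bone in (0.0, 0.1, 0.2, 0.3, 0.4):
            geo = CoatedSphereGeometry.from_fractions(500.0, 0.6, f_bone,
                                                      0.4 - f_bone)
            Es.append(homogenize_conglomerate(C, BONE_STIFFNESS_SPHERICAL,
                                              geo).moduli.E)
        assert all(b > a for a, b in zip(Es, Es[1:]))

    def test_initialization_independence(self, cracked_granule):
        C = iso_stiffness(cracked_granule)
        geo = CoatedSphereGeometry.from_fractions(500.0, 0.6, 0.2, 0.2)
        a = homogenize_conglomerate(C, BONE_STIFFNESS_SPHERICAL, geo,
                                    initial=(1e-3, 1e-3)).moduli
        b = homogenize_conglomerate(C, BONE_STIFFNESS_SPHERICAL, geo,
                                    initial=(5.0, 3.0)).moduli
        assert a.k == pytest.approx(b.k, rel=1e-7)
        assert a.mu == pytest.approx(b.mu, rel=1e-7)

    def test_isotropic_coating_full_pipeline_vs_independent_solver(self):
        """With an isotropic coating, the package's fixed point must agree
        with an independently coded classical isotropic three-phase solver
        (classical branch exponents/ratios, own assembly, scipy root)."""
        from scipy import optimize

        gran = IsotropicModuli(1.0, 0.6)
        bone = IsotropicModuli(12.0, 5.0)
        geo = CoatedSphereGeometry.from_fractions(1.0, 0.6, 0.2, 0.2)
        est = homogenize_conglomerate(iso_stiffness(gran), iso_stiffness(bone),
                                      geo).moduli

        def classical(k, mu):
            return _classical_iso_update(gran, bone, geo, k, mu)

        sol = optimize.root(lambda x: np.array(classical(*x)) - x,
                            np.array([est.k, est.mu]) * 1.3, method="hybr",
                            options={"xtol": 1e-12})
        assert sol.success
        assert est.k == pytest.approx(sol.x[0], rel=1e-6)
        assert est.mu == pytest.approx(sol.x[1], rel=1e-6)


def _classical_iso_update(gran, bone, geo, k, mu):
    """Independent coding path: classical isotropic coated-sphere solution
    (hard-coded exponents/amplitude ratios, explicit field formulas through
    the FieldEvaluator) and surface-free volume averaging by quadrature."""
    outer = IsotropicModuli(k, mu)
    r1, r2 = geo.r_gran, geo.r_bone

    # volumetric: xi = a r + b / r^2 per phase
    def vol_cols(m, r, signs=1.0):
        # displacement and sigma_rr columns for branches (r, r^-2)
        return np.array([[r, r ** -2],
                         [3 * m.k, -4 * m.mu * r ** -3]]) * signs

    A = np.zeros((4, 4))
    rhs = np.zeros(4)
    cg = vol_cols(gran, r1)
    cb1 = vol_cols(bone, r1)
    cb2 = vol_cols(bone, r2)
    co = vol_cols(outer, r2)
    A[0:2, 0] = cg[:, 0]
    A[0:2, 1:3] = -cb1
    A[2:4, 1:3] = cb2
    A[2:4, 3] = -co[:, 1]
    rhs[2:4] = co[:, 0] / 3.0  # remote amplitude E_vol0/3 with E_vol0 = 1
    x = np.linalg.solve(A, rhs)
    eps_g = 3.0 * (x[0] * r1) / r1  # <tr eps> = 3 a (uniform in the core)
    sig_g = 3.0 * gran.k * x[0]
    xi_b = lambda r: x[1] * r + x[2] * r ** -2
    dv = r2 ** 3 - r1 ** 3
    eps_b = 3.0 * (r2 ** 2 * xi_b(r2) - r1 ** 2 * xi_b(r1)) / dv
    sig_b = 3.0 * bone.k * x[1]  # the 1/r^2 branch is traceless
    pe = (3 * k + 4 * mu) / (4 * mu)
    E_vol = geo.f_gran * eps_g + geo.f_bone * eps_b + geo.phi_macro * pe
    S_m = geo.f_gran * sig_g + geo.f_bone * sig_b
    k_new = S_m / E_vol

    # deviatoric: classical four-branch solution per phase via FieldEvaluator
    def branches(m):
        e, b = classical_iso_branches(m.nu)
        return e, b

    def cols(m, r):
        e, b = branches(m)
        ph = iso_phase_constants(m.k, m.mu)
        out = np.zeros((4, 4))
        for j, (s, beta) in enumerate(zip(e, b)):
            ev = FieldEvaluator(ph, [s], [beta], [1.0], "deviatoric")
            th, php = 0.8, 0.3
            strain = ev.strain_spherical(r, th, php)
            stress = ev.stress_spherical(r, th, php)
            ur = r ** s
            ut = beta * r ** s
            srr = stress[0, 0] / (np.sin(th) ** 2 * np.cos(2 * php))
            srt = stress[0, 1] / (np.sin(th) * np.cos(th) * np.cos(2 * php))
            out[:, j] = [ur, ut, srr, srt]
        return out

    eg, bg = branches(gran)
    keep_g = [0, 1]  # r and r^3 are regular
    eo, bo = branches(outer)
    keep_o = [2, 3]  # r^-4 and r^-2 decay
    Cg = cols(gran, r1)[:, keep_g]
    Cb1, Cb2 = cols(bone, r1), cols(bone, r2)
    Co = cols(outer, r2)[:, keep_o]
    A = np.zeros((8, 8))
    rhs = np.zeros(8)
    A[0:4, 0:2] = Cg
    A[0:4, 2:6] = -Cb1
    A[4:8, 2:6] = Cb2
    A[4:8, 6:8] = -Co
    rhs[4:8] = cols(outer, r2)[:, 0]  # remote linear branch, gamma = 1
    x = np.linalg.solve(A, rhs)

    def phase_avg(m, e, b, amps, r_in, r_out):
        ph = iso_phase_constants(m.k, m.mu)
        ev = FieldEvaluator(ph, e, b, amps, "deviatoric")
        epsq = ev.shell_average("strain", max(r_in, 1e-3 * r_out), r_out,
                                n_r=16, n_t=16, n_p=16)
        sigq = ev.shell_average("stress", max(r_in, 1e-3 * r_out), r_out,
                                n_r=16, n_t=16, n_p=16)
        return epsq[0, 0] - epsq[1, 1], sigq[0, 0] - sigq[1, 1]

    de_g, ds_g = phase_avg(gran, eg[keep_g], np.array(bg)[keep_g], x[0:2], 0, r1)
    eb, bb = branches(bone)
    de_b, ds_b = phase_avg(bone, eb, bb, x[2:6], r1, r2)
    pde = 5 * (3 * k + 4 * mu) / (9 * k + 8 * mu) * 2.0
    E_dev = geo.f_gran * de_g + geo.f_bone * de_b + geo.phi_macro * pde
    S_dev = geo.f_gran * ds_g + geo.f_bone * ds_b
    mu_new = S_dev / (2.0 * E_dev)
    return k_new, mu_new
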