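# Methods

This note documents the model equations as implemented, the numerical
choices behind them, and the limits of what the package's tests establish.

## Representation and conventions

All fourth-order stiffness tensors live in the orthonormal Kelvin 6×6
representation (ordering 11, 22, 33, 23, 13, 12; factors √2 on mixed
components), so contraction, inversion and rotation are ordinary matrix
operations and rotation matrices are orthogonal.  Printed stiffness tables
in the bone-elasticity literature follow the "2C" component convention
(entries 2·C_ijkl wherever a shear pair is involved); the conversion lives
in one documented function (`stiffness_from_printed_voigt`) and is tested
on the bone tissue tensor.  Isotropic tensors are handled as
3k·P_vol + 2µ·P_dev with the explicit volumetric/deviatoric projectors;
the implementation never relies on symbol conventions for the two
projectors, which differ between sources.

Units: GPa for stiffness, µm for lengths, weeks for regeneration time.
The dissolution fit is the single exception (days; never mixed with the
week-based laws).

## Level I — self-consistent porous polycrystal

Phases: hydroxyapatite needles (volume fraction 1−φ_micro, isotropic,
E = 114 GPa, ν = 0.27) uniformly oriented over the sphere, and drained
spherical micropores (ℂ_pore = 0).  Every phase is embedded in the
homogenized medium itself (self-consistent scheme), giving a fixed-point
problem that is isotropic by construction.  Numerical choices:

* The needle concentration factor for one orientation is the rigid
  rotation of the axis-aligned factor, because crystal and matrix are
  isotropic; the orientation integral is therefore a rotation average of a
  single 6×6 matrix.  It is evaluated on a Gauss product grid
  (Gauss–Legendre in cos ϑ × uniform in φ, default 16×32) assembled once
  into a 36×36 averaging operator.  Grid refinement changes the moduli by
  less than 10⁻⁶ relative (tested), so the result is
  integration-scheme independent at the reported precision.
* Drained pores use concentration factors in the form [I − ℙ_sph : ℂ_est]⁻¹,
  so a zero stiffness is never inverted.
* Damped fixed point on (k, µ): start (1−φ_micro)·(k_HA, µ_HA), damping
  0.5, relative tolerance 10⁻¹⁰, at most 500 iterations.  The start lies on
  the Voigt side and reaches the positive-semi-definite branch for all
  porosities used here; the self-consistency residual of the converged
  estimate is below 10⁻⁸ (tested).

Closed-form Hill tensors: sphere (volumetric factor 3k/(3k+4µ), deviatoric
6(k+2µ)/(5(3k+4µ))), infinite circular cylinder (classical Eshelby
components), and general spheroids via the elliptic I-integrals.  The
cylinder expressions are cross-validated against the spheroid route at
aspect ratio 10⁴, and the spheroid route degenerates to the sphere at
aspect ratio 1 (both tested).  The cylinder Hill tensor is positive
*semi*-definite — the infinite cylinder carries a zero eigenvalue along its
axis — which is the expected structure, not a defect.

## Level II — Mori-Tanaka cracked mesoporous granule

With drained spherical mesopores (φ_meso) and randomly oriented open penny
cracks of vanishing volume fraction, the Mori-Tanaka estimate reduces to
two scalar relations,

    k_gran  = (1−φ) k_m  / [(1−φ) + φ/(1−α) + ε·Q_vol],
    µ_gran = (1−φ) µ_m / [(1−φ) + φ/(1−β)  + ε·Q_dev],

with (α, β) the spherical Eshelby factors of the matrix and the crack
influence factors

    Q_vol = (16/9)(1−ν²)/(1−2ν),   Q_dev = (32/45)(1−ν)(5−ν)/(2−ν),

functions of the matrix Poisson's ratio only.  ℚ is the limit of randomly
oriented oblate spheroidal voids as the aspect ratio ω → 0 at fixed crack
density ε = N·r_cr³ (crack porosity (4/3)πεω → 0); the test suite verifies
this limit independently with the spheroid Hill tensor, and the chained
level-I/level-II computation reproduces the published worked value
µ_gran = 78.50 MPa at (φ_micro, φ_meso, ε) = (0.445, 0.189, 66.85) to
better than 0.1 %.  Cracks are open and frictionless; no crack-closure
branch is modelled.  The printed crack inputs N ≈ 3.80·10⁻⁶ µm⁻³ and
r_cr ≈ 260 µm give ε = 66.79; the published rounded value 66.85 is treated
as the authoritative downstream input because it is the number inserted
into the granule estimate.

## Bone-coating stiffness

The coating tensor starts from the orthotropic ultrasound stiffness of
mandibular bone tissue (axes: 1 radial, 2 circumferential, 3 axial/fibril).
On a granule surface the fibrils lie in the tangent plane with no preferred
in-plane direction, which is realized by rotation-averaging the tissue
tensor about the radial axis.  Averaging about a fixed axis is performed
discretely: a fourth-order tensor carries angular harmonics up to order 4,
so the average over ≥ 5 equally spaced angles equals the continuous
integral exactly (the default uses 16 angles and is tested against a
720-angle average).

Two routes are implemented.  The default is a single average about the
radial axis (= tissue axis 1), which leaves the radial-radial entry
untouched.  A two-step route (first about the fibril axis 3, then about an
orthogonal axis — the choice among orthogonal axes is immaterial by the
intermediate transverse isotropy, which is tested) additionally randomizes
the radial/circumferential axes about the fibril.  The single-step route is
the default because it reproduces the published spherical-frame coating
tensor much more closely (max entry deviation 0.235 GPa vs ≈ 1.1 GPa) and
matches the published radial exponent: the printed spherical-frame matrix
gives n = 1.788 and the single-step average of the printed ultrasound
matrix gives n = 1.797, both rounding to the published 1.79, whereas the
two-step average gives 1.706.  The two printed matrices are in fact
mutually inconsistent under *any* composition of stiffness rotation
averages — rotation averaging preserves the Kelvin trace, and the printed
traces differ by 0.64 GPa — so exact reproduction of every printed entry
from the printed inputs is impossible; the residual 0.06–0.24 GPa entry
deviations are attributed to rounding in the printed source table.  The
published spherical-frame matrix itself is shipped as a constant
(`BONE_STIFFNESS_SPHERICAL`) and is what the level-III scheme consumes by
default, so downstream results do not depend on the averaging route.

The radial exponent of the spherically symmetric displacement solution,
n = √(1/4 + 2(C_ϑϑϑϑ + C_ϑϑφφ − C_rrϑϑ)/C_rrrr), is 3/2 for any isotropic
tensor (tested exactly) and 1.79 for the coating.

Maturation-dependent stiffening of the new bone is not modelled; one fixed
tensor is used at all times.

## Level III — generalized coated-sphere scheme

The three-domain problem (granule core r ≤ r_gran, spherically transversely
isotropic coating r_gran ≤ r ≤ r_bone, effective medium outside) is solved
for a purely volumetric and a purely deviatoric remote strain.

*Volumetric case.*  Radial displacement per shell:
ξ_r = Γ₁ r^(−1/2+n) + Γ₂ r^(−1/2−n) with the shell's radial exponent n;
σ_rr of a branch r^s is (C_rrrr·s + 2C_rrϑϑ) r^(s−1).  Regularity at the
origin removes one granule branch, the remote condition pins the growing
outer branch at E_vol,0/3, and displacement/traction continuity at the two
interfaces closes a 4×4 linear system.

*Deviatoric case.*  With the classical pure-shear angular carriers, the
equilibrium equations reduce per shell to two coupled Euler-type ODEs for
the radial amplitudes (U_r, U_ϑ).  The coefficient matrices were derived
symbolically from the spherical-coordinate kinematics, the transversely
isotropic constitutive law and the equilibrium divergence (the third,
azimuthal equation is redundant, as verified in the derivation); a
power-law branch r^s exists where the 2×2 matrix P(s) is singular.  The
four exponents are the roots of the quartic det P(s) = 0, reconstructed
exactly from five samples and solved by companion-matrix eigenvalues;
repeated or complex roots raise an error (none occur for the stiffnesses
used).  The amplitude ratio is β(s) = −P₁₁/P₁₂.  For isotropic shells this
machinery reproduces the classical exponents (1, 3, −2, −4) and amplitude
ratios exactly, and isotropic shells short-circuit to those closed forms;
one code path serves all phases, with the classical isotropic branch
functions kept in the test suite as an independent oracle.  Eight
continuity conditions (ξ_r, ξ_ϑ, σ_rr, σ_rϑ at both interfaces) determine
the remaining coefficients.

*Phase averages.*  Because the fields satisfy equilibrium identically,
shell averages of strain and stress reduce by the divergence theorem to
surface integrals of sym(ξ⊗n) and sym(t⊗x); the angular integrals are
closed-form, leaving boundary terms in the radial functions only:
⟨tr ε⟩V = 4π[r²ξ_r], ⟨σ_m⟩V = (4π/3)[r³σ_rr],
⟨ε_xx−ε_yy⟩V = (8π/15)[r²(2U_r+3U_ϑ)],
⟨σ_xx−σ_yy⟩V = (8π/15)[r³(2S_rr+3S_rϑ)].  These closed forms are verified
against direct 3-D Gauss quadrature of the fields to 10⁻⁷.

*Macropores.*  Drained spherical Eshelby inclusions in the effective
medium: volumetric strain concentration (3k+4µ)/(4µ), deviatoric
5(3k+4µ)/(9k+8µ), zero stress.  The printed volumetric concentration
formula carries the pore moduli in its denominator, which is zero for
drained pores and inconsistent with the deviatoric counterpart; the
standard spherical-inclusion factor, which reduces to (3k+4µ)/(4µ) in the
drained limit, is implemented instead.

*Implicit solve.*  k_congl = Σ_m/E_vol and µ_congl = Σ_d/(2E_d) with
volume-fraction-weighted phase averages form a damped fixed point
(damping 0.5, relative tolerance 10⁻⁹, max 200 iterations), started from
the porosity-scaled Voigt mixture of granule and bone moduli, with a
derivative-free root solve as fallback.  The scheme is
initialization-independent (tested from two distant starts, 10⁻⁷
agreement).  At 50 % drained macroporosity without bone the scheme
percolates: the only fixed point is zero stiffness and the iterates decay
sublinearly (~1/n).  A long, strictly monotone decay tail is classified as
the zero-stiffness outcome — a regular model prediction ("quasi-zero"
stiffness), not a numerical failure.  A coating of zero thickness
(f_bone = 0) uses a dedicated two-layer assembly, avoiding an
ill-conditioned zero-thickness shell; the granule then reduces to a plain
Eshelby inclusion, and the level-III scheme becomes the classical
self-consistent estimate for solid spheres plus spherical pores.

## Regeneration kinetics

f_bone(t) follows the shell-volume law with rate k_growth (default 7
µm/week, the histology mid-range) until the macropore space is exhausted,
after which the coating radius freezes; φ_micro(t) grows linearly with
k_res (resorption acts on the micropores only; meso- and macropores are
unaffected).  The dissolution experiment's rational calcium-release fit is
evaluated as published (time in days, concentration in the calibration's
units); its initial slope underlies the default maximal resorption rate
0.016 week⁻¹, which is shipped as a documented constant rather than
re-derived from stoichiometry.  Both laws are linear by design; in vivo
kinetics are expected to flatten at later times, so the kinetics functions
are deliberately small and replaceable.  φ_micro is capped at 1 and f_bone
at the initial macroporosity.

## Design studio

`stiffness_history` marches a design through time (default 0–30 weeks,
Δt = 0.5), reusing level-I results per microporosity and level-II results
per (φ_micro, φ_meso, ε) via memoization and warm-starting the level-III
fixed point from the previous time step.  `factorial_study` enumerates the
3⁵ = 243 design grid (ε ∈ {0, 10, 100}, r_gran ∈ {300, 500, 1000} µm,
φ_macro,0 ∈ {0.3, 0.4, 0.5}, k_res ∈ {0, 0.008, 0.016} week⁻¹,
k_growth ∈ {4, 7, 10} µm/week) and tallies, per evaluation time, how often
each parameter value and each parameter pair appears among designs whose
modulus has entered the 5–19 GPa band by that time; a design counts as
successful once any earlier grid time is in band.  Failed solver cells are
recorded with an error tag and excluded rather than aborting the sweep.
`rate_map` reports the earliest in-band time over a (k_res, k_growth)
rectangle at the reference setting ε = 10, φ_macro,0 = 0.4,
r_gran = 500 µm.

The model is fully deterministic: identical configurations give
bit-identical results, which the test suite asserts.

## Known limitations

* The two printed bone-tissue matrices are mutually inconsistent (see
  above); entries of the spherical-frame tensor are reproduced from the
  ultrasound inputs to 0.24 GPa, not to the printed 0.01 GPa.
* With the crack influence tensor as implemented, the reference cracked
  design (ε = 10, φ_macro,0 = 0.4, r_gran = 500 µm) saturates near
  4 GPa after complete bone filling and does not cross the 5 GPa threshold
  for any rate combination; early-time behaviour (no design reaches the
  band within five weeks unless uncracked) is reproduced.  Uncracked
  designs cross into the band between roughly 2 and 10 weeks depending on
  geometry and rates.
* Single granule radius (no polydispersity), linear kinetics, fixed bone
  tissue stiffness, no crack propagation, no fluid pressurization (all
  pores drained), and no mechanobiological feedback.
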