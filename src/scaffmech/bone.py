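"""Stiffness of the newly grown bone tissue coating the granules.

Starting point is the orthotropic stiffness of mandibular cortical bone
tissue measured by ultrasound, with axes 1 = radial, 2 = circumferential,
3 = axial (collagen fibril direction).  On a granule surface the fibrils lie
in the tangent plane without preferred in-plane direction, so the tissue
tensor is rotation-averaged such that the fibril axis sweeps the tangent
plane; the result is transversely isotropic with the plane of isotropy equal
to the tangent (theta-phi) plane of a spherical frame attached to the
granule, the radial direction r carrying the tissue's radial axis 1.

Two averaging routes are provided:

* ``two_step=False`` (default): one rotation average about the radial axis 1.
  This leaves the radial-radial stiffness untouched and best reproduces the
  published spherical-frame bone tensor and its radial exponent n = 1.79.
* ``two_step=True``: first average about the fibril axis 3, then about an
  axis orthogonal to it (axis 1; by the intermediate transverse isotropy the
  choice among orthogonal axes is immaterial).  This adds a randomization of
  the radial/circumferential axes about the fibril before tangential
  averaging.

Both give a tensor satisfying the spherical-frame transverse-isotropy
relations; they differ in the tangential entries because rotation averaging
does not commute with itself about different axes.
"""

from __future__ import annotations

import numpy as np

from .tensors import (
    Stiffness,
    axis_rotation_average,
    stiffness_from_printed_voigt,
)

__all__ = [
    "BONE_STIFFNESS_US",
    "BONE_STIFFNESS_SPHERICAL",
    "bone_stiffness_ultrasound",
    "bone_stiffness_spherical",
    "tangential_isotropize",
    "spherical_ti_constants",
    "radial_exponent_n",
]

#: Ultrasound stiffness of mandibular bone tissue, printed "2C" Voigt table, GPa.
#: Axes: 1 radial, 2 circumferential, 3 axial (fibril direction).
_BONE_US_PRINTED = np.array([
    [15.90, 8.33, 9.79, 0.0, 0.0, 0.0],
    [8.33, 18.80, 9.79, 0.0, 0.0, 0.0],
    [9.79, 9.79, 27.10, 0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, 9.26, 0.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 8.24, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.0, 7.62],
])

#: Published spherical-frame coating stiffness, printed "2C" Voigt table, GPa,
#: ordering (rr, tt, pp, tp, rp, rt).  This is the tensor the downstream
#: coated-sphere level consumes by default.
_BONE_SPH_PRINTED = np.array([
    [15.90, 9.00, 9.00, 0.0, 0.0, 0.0],
    [9.00, 21.74, 10.70, 0.0, 0.0, 0.0],
    [9.00, 10.70, 21.74, 0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, 11.04, 0.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 7.93, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.0, 7.93],
])

BONE_STIFFNESS_US = stiffness_from_printed_voigt(_BONE_US_PRINTED, "cartesian-123")
BONE_STIFFNESS_SPHERICAL = stiffness_from_printed_voigt(_BONE_SPH_PRINTED, "spherical-rtp")


def bone_stiffness_ultrasound() -> Stiffness:
    """The orthotropic ultrasound tissue tensor (Kelvin, GPa)."""
    return BONE_STIFFNESS_US


def bone_stiffness_spherical() -> Stiffness:
    """The published spherical-frame coating tensor (Kelvin, GPa)."""
    return BONE_STIFFNESS_SPHERICAL


def tangential_isotropize(C_us: Stiffness, two_step: bool = False) -> Stiffness:
    """Rotation-average the tissue tensor into the spherical coating frame.

    See the module docstring for the two routes.  The output frame ordering
    is (r, theta, phi) with r = tissue axis 1, so the matrix can be consumed
    directly by the coated-sphere level.
    """
    C = C_us
    if two_step:
        C = axis_rotation_average(C, np.array([0.0, 0.0, 1.0]))
    C = axis_rotation_average(C, np.array([1.0, 0.0, 0.0]))
    return Stiffness(C.matrix, "spherical-rtp")


def spherical_ti_constants(C: Stiffness, tol: float = 5e-3) -> tuple[float, float, float, float, float]:
    """Extract (C_rrrr, C_rrtt, C_tttt, C_ttpp, C_rtrt) from a spherical-frame
    transversely isotropic Kelvin matrix, checking the TI structure.

    ``tol`` is the admitted relative asymmetry between entries that transverse
    isotropy requires to coincide (printed tensors are rounded to 0.01 GPa).
    """
    m = C.matrix
    scale = max(abs(m).max(), 1e-300)

    def close(a, b):
        return abs(a - b) <= tol * scale

    if not (close(m[1, 1], m[2, 2]) and close(m[0, 1], m[0, 2])
            and close(m[4, 4], m[5, 5])
            and close(m[3, 3], m[1, 1] - m[1, 2])):
        raise ValueError("matrix is not transversely isotropic about the radial axis")
    c_rrrr = m[0, 0]
    c_rrtt = 0.5 * (m[0, 1] + m[0, 2])
    c_tttt = 0.5 * (m[1, 1] + m[2, 2])
    c_ttpp = m[1, 2]
    c_rtrt = 0.25 * (m[4, 4] + m[5, 5])  # Kelvin shear entries are 2*C_rtrt
    return c_rrrr, c_rrtt, c_tttt, c_ttpp, c_rtrt


def radial_exponent_n(C_spherical: Stiffness) -> float:
    """Radial exponent of the spherically symmetric displacement solution.

    For a spherical shell with transversely isotropic stiffness (isotropy
    plane tangential), the radial equilibrium ODE under hydrostatic remote
    load has power-law solutions r^(-1/2 +- n) with

        n = sqrt(1/4 + 2 (C_tttt + C_ttpp - C_rrtt) / C_rrrr).

    Any isotropic tensor gives n = 3/2.
    """
    c_rrrr, c_rrtt, c_tttt, c_ttpp, _ = spherical_ti_constants(C_spherical)
    if c_rrrr <= 0:
        raise ValueError("C_rrrr must be positive")
    radicand = 0.25 + 2.0 * (c_tttt + c_ttpp - c_rrtt) / c_rrrr
    if radicand < 0:
        raise ValueError(f"negative radicand {radicand}: unphysical stiffness")
    return float(np.sqrt(radicand))
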