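"""Homogenized gyroid-foam material laws.

The porous implant is modeled as a continuum whose apparent stiffness and
apparent yield stress follow cubic scaling laws in the local solid volume
fraction ``vf`` (the gyroid sheet's relative density), obtained by numerical
homogenization of the sheet-gyroid unit cell:

    E*/Es      = f1(vf) = 0.1018 vf^3 + 0.4388 vf^2 + 0.2405 vf
    sigma*/ss  = g1(vf) = 0.5545 vf^3 + 0.1250 vf^2 + 0.4666 vf

Both laws vanish at vf = 0 and are strictly increasing on [0, 1].  Note that
g1(1) = 1.1461 > 1, i.e. the fitted law slightly exceeds the solid yield at
full density; the law is applied as published (see docs/methods.md).

The density *update* map of the remodeling loop is the numerical inverse of
g1: given a stress ratio r = sigma_vm/sigma_s it returns the volume fraction
whose apparent yield matches that stress, clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SolidMaterial",
    "TI6AL4V",
    "STIFFNESS_COEFFS",
    "YIELD_COEFFS",
    "stiffness_ratio",
    "apparent_modulus",
    "yield_ratio",
    "yield_ratio_derivative",
    "vf_from_stress_ratio",
]

#: (cubic, quadratic, linear) coefficients of the stiffness law f1.
STIFFNESS_COEFFS = (0.1018, 0.4388, 0.2405)

#: (cubic, quadratic, linear) coefficients of the yield law g1.
YIELD_COEFFS = (0.5545, 0.1250, 0.4666)


@dataclass(frozen=True)
class SolidMaterial:
    """Bulk material of the printed lattice (units: MPa, dimensionless).

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus of the fully dense material, MPa.
    yield_stress : float
        Yield stress of the fully dense material, MPa.
    poisson_ratio : float
        Poisson's ratio, in (0, 0.5).
    """

    youngs_modulus: float
    yield_stress: float
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if self.yield_stress <= 0:
            raise ValueError("yield_stress must be positive")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in (0, 0.5)")


#: Ti-6Al-4V: E = 110 GPa, sigma_y = 850 MPa, nu = 0.3.
TI6AL4V = SolidMaterial(youngs_modulus=110_000.0, yield_stress=850.0, poisson_ratio=0.3)


def _check_vf(vf):
    vf = np.asarray(vf, dtype=float)
    if np.any(vf < 0) or np.any(vf > 1):
        raise ValueError("volume fraction must lie in [0, 1]")
    return vf


def _cubic(coeffs, vf):
    a, b, c = coeffs
    return ((a * vf + b) * vf + c) * vf


def stiffness_ratio(vf):
    """Apparent-to-solid stiffness ratio E*/Es of the gyroid foam.

    Accepts scalars or arrays; the volume fraction must lie in [0, 1].
    """
    return _cubic(STIFFNESS_COEFFS, _check_vf(vf))


def apparent_modulus(vf, solid: SolidMaterial):
    """Apparent Young's modulus E* = f1(vf) * Es in MPa."""
    return stiffness_ratio(vf) * solid.youngs_modulus


def yield_ratio(vf):
    """Apparent-to-solid yield stress ratio sigma*/sigma_s of the gyroid foam."""
    return _cubic(YIELD_COEFFS, _check_vf(vf))


def yield_ratio_derivative(vf):
    """d(g1)/d(vf); strictly positive on [0, 1] (min 0.4666 at vf=0)."""
    a, b, c = YIELD_COEFFS
    vf = np.asarray(vf, dtype=float)
    return (3 * a * vf + 2 * b) * vf + c


def vf_from_stress_ratio(r, tol: float = 1e-12, max_iter: int = 100):
    """Invert the yield law: volume fraction whose apparent yield matches ``r``.

    ``r`` is a stress ratio sigma/sigma_s >= 0.  Ratios above g1(1) clamp to
    vf = 1 (full density); r = 0 maps to 0.  The root of the monotone cubic is
    found by safeguarded Newton iteration to ``|g1(vf) - r| <= tol`` (well
    below the 1e-10 bracket the remodeling update requires).

    Accepts scalars or arrays; negative ratios raise ``ValueError``.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r < 0):
        raise ValueError("stress ratio must be non-negative")

    r_max = yield_ratio(1.0)
    rc = np.clip(r, 0.0, r_max)

    # Newton from a linear initial guess; g1' >= 0.4666 keeps steps bounded.
    v = np.clip(rc / r_max, 0.0, 1.0)
    for _ in range(max_iter):
        f = _cubic(YIELD_COEFFS, v) - rc
        if np.all(np.abs(f) <= tol):
            break
        v = np.clip(v - f / yield_ratio_derivative(v), 0.0, 1.0)
    return float(v[0]) if scalar else v
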