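"""Radiative conversions for single-direction low-cost sensing.

The device senses radiation with two upward-facing channels: a lux meter
used as a shortwave surrogate and an IR thermopile giving incident longwave
irradiance.  This module holds the constants and the three conversions built
on them:

* lux -> shortwave irradiance (linear fit with a saturation cap),
* longwave irradiance <-> blackbody brightness temperature,
* the one-directional mean radiant flux density
  ``S_str = F * alpha_k * SW + eps_p * LW``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SIGMA",
    "RadiationConstants",
    "lux_to_sw",
    "brightness_temperature",
    "lw_from_brightness",
    "mean_radiant_flux",
]

#: Stefan-Boltzmann constant [W m-2 K-4]
SIGMA = 5.67e-8

#: angular weighting for one direction of a sphere / of a standing person
F_SPHERE = 0.167
F_PERSON = 0.06


@dataclass(frozen=True)
class RadiationConstants:
    """Constants of the radiant-flux model.

    ``F`` weights the single upward direction: 0.167 for a sphere, 0.06 for
    a standing person.  ``lux_slope`` is the pyranometer-regression slope of
    the lux surrogate; above ``lux_saturation_lx`` the light sensor
    saturates and SW is set to ``sw_cap``.
    """

    sigma: float = SIGMA
    eps_p: float = 0.97      # human-body emissivity
    alpha_k: float = 0.7     # shortwave absorption coefficient
    F: float = F_SPHERE
    lux_slope: float = 0.03887       # W m-2 per lx
    lux_saturation_lx: float = 15_000.0
    sw_cap: float = 600.0            # W m-2

    def __post_init__(self) -> None:
        for name in ("sigma", "eps_p", "alpha_k", "F", "lux_slope", "lux_saturation_lx", "sw_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def lux_to_sw(light_lx, constants: RadiationConstants | None = None):
    """Approximate shortwave irradiance [W/m2] from light level [lx].

    Piecewise as calibrated: ``0.03887 * L`` up to and including 15,000 lx,
    constant 600 W/m2 strictly above it.  The cap is applied per sample and
    the small jump at the threshold (583.05 -> 600) is kept as calibrated
    rather than smoothed.
    """
    if constants is None:
        constants = RadiationConstants()
    light = np.asarray(light_lx, dtype=float)
    if np.any(light[~np.isnan(light)] < 0):
        raise ValueError("light level must be >= 0 lx")
    out = np.where(light > constants.lux_saturation_lx, constants.sw_cap, constants.lux_slope * light)
    return float(out) if out.ndim == 0 else out


def sw_to_lux(sw_wm2, constants: RadiationConstants | None = None):
    """Inverse of :func:`lux_to_sw` on the linear branch (SW below the cap)."""
    if constants is None:
        constants = RadiationConstants()
    sw = np.asarray(sw_wm2, dtype=float)
    linear_max = constants.lux_slope * constants.lux_saturation_lx
    if np.any(sw[~np.isnan(sw)] > linear_max):
        raise ValueError(f"SW above the invertible linear branch (> {linear_max:.2f} W/m2)")
    out = sw / constants.lux_slope
    return float(out) if out.ndim == 0 else out


def brightness_temperature(lw_wm2):
    """Blackbody brightness temperature [degC] of longwave irradiance [W/m2].

    Inverts the Stefan-Boltzmann law, T = (LW / sigma)^(1/4).  Deliberately
    uses emissivity 1 (brightness, not surface, temperature).
    """
    lw = np.asarray(lw_wm2, dtype=float)
    if np.any(lw[~np.isnan(lw)] < 0):
        raise ValueError("longwave irradiance must be >= 0")
    out = (lw / SIGMA) ** 0.25 - 273.15
    return float(out) if out.ndim == 0 else out


def lw_from_brightness(tirt_c):
    """Longwave irradiance [W/m2] emitted by a blackbody at ``tirt_c`` [degC]."""
    t = np.asarray(tirt_c, dtype=float)
    out = SIGMA * (t + 273.15) ** 4
    return float(out) if out.ndim == 0 else out


def mean_radiant_flux(sw_wm2, lw_wm2, constants: RadiationConstants | None = None):
    """One-directional mean radiant flux density S_str [W/m2].

    ``S_str = F * alpha_k * SW + eps_p * LW`` — the six-directional integral
    collapsed to the single upward-facing sensor pair.
    """
    if constants is None:
        constants = RadiationConstants()
    sw = np.asarray(sw_wm2, dtype=float)
    lw = np.asarray(lw_wm2, dtype=float)
    if np.any(sw[~np.isnan(sw)] < 0) or np.any(lw[~np.isnan(lw)] < 0):
        raise ValueError("irradiances must be >= 0")
    out = constants.F * constants.alpha_k * sw + constants.eps_p * lw
    return float(out) if out.ndim == 0 else out
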