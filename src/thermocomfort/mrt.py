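"""Mean radiant temperature estimation.

Five estimation routes are supported, mirroring the sensor combinations a
device can carry:

``globe``            black globe thermometer + air temperature + wind
``ir_l_sphere``      IR thermopile + lux surrogate, sphere weighting (F=0.167)
``ir_l_person``      IR thermopile + lux surrogate, person weighting (F=0.06)
``ir_only``          IR thermopile alone (T_mrt = brightness temperature)
``air_temperature``  T_mrt = T_a fallback

The globe route uses the standard forced-convection globe equation
(ISO 7726 form) and is paired with its numerical inverse so synthetic globe
channels can be generated from a known radiant field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .radiation import (
    F_PERSON,
    F_SPHERE,
    RadiationConstants,
    brightness_temperature,
    mean_radiant_flux,
)

__all__ = [
    "GlobeSpec",
    "MrtEstimate",
    "METHODS",
    "mrt_from_globe",
    "globe_from_mrt",
    "estimate_mrt",
    "estimate_mrt_with_fallback",
    "add_mrt_columns",
    "ChannelMissingError",
]

#: stable method identifiers, in preference order of decreasing fidelity
METHODS = ("globe", "ir_l_sphere", "ir_l_person", "ir_only", "air_temperature")

_REQUIRED_CHANNELS = {
    "globe": ("tg_c", "ta_c", "v_eff_ms"),
    "ir_l_sphere": ("lw_wm2", "sw_wm2"),
    "ir_l_person": ("lw_wm2", "sw_wm2"),
    "ir_only": ("lw_wm2",),
    "air_temperature": ("ta_c",),
}


class ChannelMissingError(ValueError):
    """A channel required by the requested estimation method is absent."""


@dataclass(frozen=True)
class GlobeSpec:
    """Geometry and convection constants of a black globe thermometer.

    Defaults describe a 0.05 m matte-black globe; the forced-convection
    correction constant 1.1e8 with exponents v^0.6 / D^0.4 is the standard
    globe equation's.
    """

    diameter_m: float = 0.05
    emissivity: float = 0.95
    convection_coefficient: float = 1.1e8
    v_exponent: float = 0.6
    d_exponent: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.diameter_m <= 0.2:
            raise ValueError("globe diameter must be in (0, 0.2] m")
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError("globe emissivity must be in (0, 1]")

    @property
    def convective_factor(self) -> float:
        """Coefficient multiplying v^0.6 (tg - ta) in the globe equation."""
        return self.convection_coefficient / (self.emissivity * self.diameter_m**self.d_exponent)


@dataclass(frozen=True)
class MrtEstimate:
    method: str
    tmrt_c: float


def mrt_from_globe(tg_c, ta_c, v_eff_ms, globe: GlobeSpec | None = None):
    """Mean radiant temperature [degC] from globe temperature.

    T_mrt = [ (T_g+273.15)^4 + C v^0.6 (T_g - T_a) ]^(1/4) - 273.15 with
    C = 1.1e8 / (eps_g D^0.4).  A bracket driven negative by an extreme
    convective term is clamped to zero with a warning rather than producing
    a complex result.
    """
    if globe is None:
        globe = GlobeSpec()
    tg = np.asarray(tg_c, dtype=float)
    ta = np.asarray(ta_c, dtype=float)
    v = np.asarray(v_eff_ms, dtype=float)
    if np.any(tg[~np.isnan(tg)] <= -273.15) or np.any(ta[~np.isnan(ta)] <= -273.15):
        raise ValueError("non-physical temperature below absolute zero")
    bracket = (tg + 273.15) ** 4 + globe.convective_factor * v**globe.v_exponent * (tg - ta)
    if np.any(bracket[~np.isnan(bracket)] < 0):
        warnings.warn(
            "convective term drove the globe equation bracket negative; clamped to 0 K",
            RuntimeWarning,
            stacklevel=2,
        )
        bracket = np.clip(bracket, 0.0, None)
    out = bracket**0.25 - 273.15
    return float(out) if out.ndim == 0 else out


def globe_from_mrt(tmrt_c: float, ta_c: float, v_eff_ms: float, globe: GlobeSpec | None = None) -> float:
    """Globe temperature [degC] that would be observed in a known radiant field.

    Numerical inverse of :func:`mrt_from_globe` by bracketed root finding on
    tg in [-60, 120] degC; residual below 1e-6.  Primarily a synthetic
    ground-truth construction and a round-trip testing oracle.
    """
    if globe is None:
        globe = GlobeSpec()

    target = (tmrt_c + 273.15) ** 4

    def residual(tg: float) -> float:
        return (tg + 273.15) ** 4 + globe.convective_factor * v_eff_ms**globe.v_exponent * (tg - ta_c) - target

    lo, hi = -60.0, 120.0
    if residual(lo) * residual(hi) > 0:
        raise RuntimeError(
            f"no globe temperature in [{lo}, {hi}] degC matches tmrt={tmrt_c}, ta={ta_c}, v={v_eff_ms}"
        )
    return float(brentq(residual, lo, hi, xtol=1e-9))


def _get(record, key):
    """Channel lookup on a mapping/Series; NaN counts as absent."""
    try:
        val = record[key]
    except (KeyError, IndexError):
        return None
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    return val


def estimate_mrt(
    record,
    method: str,
    constants: RadiationConstants | None = None,
    globe: GlobeSpec | None = None,
) -> MrtEstimate:
    """Estimate T_mrt for one derived record by the named method.

    ``record`` is any mapping (dict, pandas Series) exposing the derived
    canonical columns.  A channel the method needs but the record lacks
    raises :class:`ChannelMissingError`; there is no silent fallback.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if constants is None:
        constants = RadiationConstants()
    missing = [ch for ch in _REQUIRED_CHANNELS[method] if _get(record, ch) is None]
    if missing:
        raise ChannelMissingError(f"channel(s) {missing} missing for method {method!r}")

    if method == "globe":
        tmrt = mrt_from_globe(_get(record, "tg_c"), _get(record, "ta_c"), _get(record, "v_eff_ms"), globe)
    elif method in ("ir_l_sphere", "ir_l_person"):
        F = F_SPHERE if method == "ir_l_sphere" else F_PERSON
        c = RadiationConstants(
            sigma=constants.sigma,
            eps_p=constants.eps_p,
            alpha_k=constants.alpha_k,
            F=F,
            lux_slope=constants.lux_slope,
            lux_saturation_lx=constants.lux_saturation_lx,
            sw_cap=constants.sw_cap,
        )
        s_str = mean_radiant_flux(_get(record, "sw_wm2"), _get(record, "lw_wm2"), c)
        tmrt = (s_str / (c.eps_p * c.sigma)) ** 0.25 - 273.15
    elif method == "ir_only":
        tmrt = brightness_temperature(_get(record, "lw_wm2"))
    else:  # air_temperature
        tmrt = float(_get(record, "ta_c"))
    return MrtEstimate(method=method, tmrt_c=float(tmrt))


def estimate_mrt_with_fallback(
    record,
    preference: tuple[str, ...] = METHODS,
    constants: RadiationConstants | None = None,
    globe: GlobeSpec | None = None,
) -> MrtEstimate:
    """First method in ``preference`` whose channels are available.

    ``air_temperature`` always succeeds, so appending it guarantees an
    estimate; the method actually used is recorded on the result.
    """
    last_err: Exception | None = None
    for method in preference:
        try:
            return estimate_mrt(record, method, constants, globe)
        except ChannelMissingError as exc:
            last_err = exc
    raise ChannelMissingError(f"no method in {preference} had its channels present") from last_err


def add_mrt_columns(
    df: pd.DataFrame,
    methods: tuple[str, ...] = METHODS,
    constants: RadiationConstants | None = None,
    globe: GlobeSpec | None = None,
) -> pd.DataFrame:
    """Vectorised per-method T_mrt columns ``tmrt_<method>_c`` on a derived frame.

    Methods whose channels are absent from the frame are skipped silently
    here (frame-level enrichment); per-record estimation with explicit
    errors is :func:`estimate_mrt`.
    """
    if constants is None:
        constants = RadiationConstants()
    out = df.copy()
    for method in methods:
        if any(ch not in out.columns for ch in _REQUIRED_CHANNELS[method]):
            continue
        if method == "globe":
            vals = mrt_from_globe(
                out["tg_c"].to_numpy(float), out["ta_c"].to_numpy(float), out["v_eff_ms"].to_numpy(float), globe
            )
        elif method in ("ir_l_sphere", "ir_l_person"):
            F = F_SPHERE if method == "ir_l_sphere" else F_PERSON
            s_str = F * constants.alpha_k * out["sw_wm2"].to_numpy(float) + constants.eps_p * out[
                "lw_wm2"
            ].to_numpy(float)
            vals = (s_str / (constants.eps_p * constants.sigma)) ** 0.25 - 273.15
        elif method == "ir_only":
            vals = brightness_temperature(out["lw_wm2"].to_numpy(float))
        else:
            vals = out["ta_c"].to_numpy(float)
        out[f"tmrt_{method}_c"] = vals
    return out
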