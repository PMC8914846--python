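"""Sensor record I/O, validation, humidity conversion and time alignment.

A sensor stream is carried as a :class:`pandas.DataFrame` with the canonical
columns below (one row per timestamped reading of one device).  Optional
channels that a site does not measure are simply absent, or present with
missing values — never encoded as sentinel numbers.

Canonical input columns
    ``timestamp``   ISO-8601 UTC instant
    ``device_id``   device identifier (string)
    ``ta_c``        air temperature [degC]
    ``rh_pct``      relative humidity [%]
    ``tg_c``        globe temperature [degC]            (optional)
    ``lw_wm2``      incident longwave irradiance [W/m2] (optional)
    ``tirt_c``      brightness temperature [degC]       (optional)
    ``light_lx``    light level [lx]
    ``wind_ms``     wind speed [m/s]                    (optional, indoor
                    sites have no anemometer)

Derived columns (added by :func:`derive_records`)
    ``vp_hpa``      vapor pressure [hPa]
    ``sw_wm2``      approximated shortwave irradiance [W/m2]
    ``v_eff_ms``    effective wind speed after the indoor floor rule [m/s]
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SensorRecord",
    "CANONICAL_COLUMNS",
    "OPTIONAL_CHANNELS",
    "read_records",
    "write_records",
    "derive_records",
    "saturation_vapor_pressure",
    "vapor_pressure_from_rh",
    "effective_wind",
    "align_series",
    "RecordValidationError",
]

CANONICAL_COLUMNS = [
    "timestamp",
    "device_id",
    "ta_c",
    "rh_pct",
    "tg_c",
    "lw_wm2",
    "tirt_c",
    "light_lx",
    "wind_ms",
]

#: channels a record may legitimately lack
OPTIONAL_CHANNELS = ("tg_c", "lw_wm2", "tirt_c", "wind_ms")

#: decimal places preserved by write_records (lossless round-trip contract)
CSV_PRECISION = 3

ABSOLUTE_ZERO_C = -273.15

#: wind speed substituted indoors / floored everywhere [m/s]
WIND_FLOOR_MS = 0.1


class RecordValidationError(ValueError):
    """A sensor record violates a physical-range invariant."""


@dataclass(frozen=True)
class SensorRecord:
    """One timestamped multi-channel reading of a single device.

    ``None`` marks a channel the site does not measure.  Exactly one of
    ``lw`` / ``tirt`` needs to be stored; the other is derivable through the
    Stefan-Boltzmann law (see :mod:`thermocomfort.radiation`).
    """

    timestamp: pd.Timestamp
    device_id: str
    ta: float
    rh: float
    light: float
    tg: float | None = None
    lw: float | None = None
    tirt: float | None = None
    v: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh <= 100.0:
            raise RecordValidationError(f"rh={self.rh} outside [0, 100] %")
        if self.light < 0:
            raise RecordValidationError(f"light={self.light} lx is negative")
        if self.ta <= ABSOLUTE_ZERO_C:
            raise RecordValidationError(f"ta={self.ta} degC below absolute zero")
        if self.tg is not None and self.tg <= ABSOLUTE_ZERO_C:
            raise RecordValidationError(f"tg={self.tg} degC below absolute zero")
        if self.lw is not None and self.lw < 0:
            raise RecordValidationError(f"lw={self.lw} W/m2 is negative")
        if self.v is not None and self.v < 0:
            raise RecordValidationError(f"v={self.v} m/s is negative")


def _validate_frame(df: pd.DataFrame, path: str = "<frame>") -> None:
    rh = df["rh_pct"]
    bad = rh.notna() & ((rh < 0) | (rh > 100))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RecordValidationError(
            f"{path}, row {row}: rh_pct={rh.iloc[row]} outside [0, 100]"
        )
    checks = [
        ("light_lx", lambda s: s < 0, "negative light level"),
        ("lw_wm2", lambda s: s < 0, "negative longwave irradiance"),
        ("wind_ms", lambda s: s < 0, "negative wind speed"),
        ("ta_c", lambda s: s <= ABSOLUTE_ZERO_C, "air temperature below absolute zero"),
        ("tg_c", lambda s: s <= ABSOLUTE_ZERO_C, "globe temperature below absolute zero"),
    ]
    for col, pred, msg in checks:
        if col not in df.columns:
            continue
        s = df[col]
        bad = s.notna() & pred(s)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RecordValidationError(f"{path}, row {row}: {msg} ({s.iloc[row]})")


def read_records(
    path,
    schema: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a sensor CSV into a validated, time-sorted DataFrame.

    Parameters
    ----------
    path
        CSV file with a header row and ISO-8601 UTC timestamps.
    schema
        Optional mapping ``{file column -> canonical column}`` for files
        whose headers differ from the canonical names.

    Returns
    -------
    DataFrame sorted by timestamp.  Optional channels missing from the file
    are represented as absent columns, not zeros.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    unknown = [c for c in df.columns if c not in CANONICAL_COLUMNS and not c.startswith(("vp_", "sw_", "v_eff", "tmrt_", "pet", "stress"))]
    if unknown:
        raise RecordValidationError(f"{path}: unrecognized columns {unknown}")
    required = {"timestamp", "device_id", "ta_c", "rh_pct", "light_lx"}
    missing = required - set(df.columns)
    if missing:
        raise RecordValidationError(f"{path}: missing required columns {sorted(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, pd.errors.ParserError) as exc:
        raise RecordValidationError(f"{path}: malformed timestamp ({exc})") from exc
    _validate_frame(df, str(path))
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    # drop all-missing optional channels so "absent" stays distinguishable
    for col in OPTIONAL_CHANNELS:
        if col in df.columns and df[col].isna().all():
            df = df.drop(columns=col)
    return df


def write_records(df: pd.DataFrame, path) -> None:
    """Write a sensor frame as canonical CSV (absent channels -> empty cells).

    Round-trips through :func:`read_records` losslessly at 3-decimal
    precision; derived/output columns are appended after the canonical ones
    in their declared order.
    """
    out = df.copy()
    ordered = [c for c in CANONICAL_COLUMNS if c in out.columns]
    ordered += [c for c in out.columns if c not in ordered]
    out = out[ordered]
    if "timestamp" in out.columns and len(out):
        out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        )
    out.to_csv(path, index=False, float_format=f"%.{CSV_PRECISION}f")


def saturation_vapor_pressure(ta_c):
    """Magnus saturation vapor pressure over water, e_s(t) [hPa].

    WMO Magnus form: ``6.112 * exp(17.62 t / (243.12 + t))`` with t in degC.
    """
    ta_c = np.asarray(ta_c, dtype=float)
    return 6.112 * np.exp(17.62 * ta_c / (243.12 + ta_c))


def vapor_pressure_from_rh(ta_c, rh_pct):
    """Vapor pressure [hPa] from air temperature [degC] and RH [%]."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise RecordValidationError("rh outside [0, 100] %")
    return rh / 100.0 * saturation_vapor_pressure(ta_c)


def effective_wind(v=None, site: str = "indoor"):
    """Effective wind speed with the indoor substitution / floor rule [m/s].

    Indoor sites carry no anemometer: an absent reading becomes 0.1 m/s.
    Where wind is measured, readings below 0.1 m/s (including a stalled cup
    anemometer reading exactly 0) are floored to 0.1 m/s.
    """
    if site not in ("indoor", "semi-outdoor"):
        raise ValueError(f"unknown site kind {site!r}")
    if v is None:
        return WIND_FLOOR_MS
    arr = np.asarray(v, dtype=float)
    filled = np.where(np.isnan(arr), WIND_FLOOR_MS, arr)
    if np.any(filled < 0):
        raise RecordValidationError("negative wind speed")
    out = np.maximum(filled, WIND_FLOOR_MS)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def derive_records(df: pd.DataFrame, constants=None) -> pd.DataFrame:
    """Add derived channels ``vp_hpa``, ``sw_wm2`` and ``v_eff_ms``.

    ``sw_wm2`` comes from the lux surrogate conversion; ``lw_wm2`` and
    ``tirt_c`` are completed from one another where only one is stored.
    """
    from . import radiation  # local import avoids cycle

    if constants is None:
        constants = radiation.RadiationConstants()
    out = df.copy()
    out["vp_hpa"] = vapor_pressure_from_rh(out["ta_c"], out["rh_pct"])
    out["sw_wm2"] = radiation.lux_to_sw(out["light_lx"].to_numpy(float), constants)
    if "lw_wm2" not in out.columns and "tirt_c" in out.columns:
        out["lw_wm2"] = radiation.lw_from_brightness(out["tirt_c"].to_numpy(float))
    elif "lw_wm2" in out.columns and "tirt_c" not in out.columns:
        out["tirt_c"] = radiation.brightness_temperature(out["lw_wm2"].to_numpy(float))
    wind = out["wind_ms"].to_numpy(float) if "wind_ms" in out.columns else None
    if wind is None:
        out["v_eff_ms"] = WIND_FLOOR_MS
    else:
        out["v_eff_ms"] = np.maximum(np.where(np.isnan(wind), WIND_FLOOR_MS, wind), WIND_FLOOR_MS)
    return out


def align_series(
    a: pd.DataFrame,
    b: pd.DataFrame,
    tolerance: pd.Timedelta = pd.Timedelta(minutes=2.5),
) -> pd.DataFrame:
    """Pair each reference (``b``) record with its nearest ``a`` record.

    Nearest-neighbour matching within ``tolerance``, the reference series
    driving the pairing; every record is used at most once and unmatched
    records are dropped.  Returns a frame with ``a``-columns suffixed
    ``_a`` and ``b``-columns suffixed ``_b`` plus the shared ``timestamp``
    of the reference record.  Empty inputs yield an empty pairing.
    """
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame()
    a_s = a.sort_values("timestamp").reset_index(drop=True)
    b_s = b.sort_values("timestamp").reset_index(drop=True)
    a_ns = pd.to_datetime(a_s["timestamp"], utc=True).astype("int64").to_numpy()
    b_ns = pd.to_datetime(b_s["timestamp"], utc=True).astype("int64").to_numpy()
    tol_ns = int(tolerance.value)
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for j, t in enumerate(b_ns):
        i = int(np.searchsorted(a_ns, t))
        best, best_dt = None, tol_ns
        for cand in (i - 1, i):
            if 0 <= cand < len(a_ns) and cand not in used:
                dt = abs(int(a_ns[cand]) - int(t))
                if dt <= best_dt:
                    best, best_dt = cand, dt
        if best is not None:
            used.add(best)
            pairs.append((best, j))
    if not pairs:
        return pd.DataFrame()
    ia, ib = zip(*pairs)
    left = a_s.iloc[list(ia)].reset_index(drop=True).add_suffix("_a")
    right = b_s.iloc[list(ib)].reset_index(drop=True).add_suffix("_b")
    merged = pd.concat([left, right], axis=1)
    merged.insert(0, "timestamp", right["timestamp_b"].to_numpy())
    return merged


def records_to_frame(records: Iterable[SensorRecord]) -> pd.DataFrame:
    """Build a canonical frame from :class:`SensorRecord` objects."""
    rows = [
        {
            "timestamp": r.timestamp,
            "device_id": r.device_id,
            "ta_c": r.ta,
            "rh_pct": r.rh,
            "tg_c": r.tg,
            "lw_wm2": r.lw,
            "tirt_c": r.tirt,
            "light_lx": r.light,
            "wind_ms": r.v,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
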