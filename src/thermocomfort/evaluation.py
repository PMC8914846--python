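"""Per-sensor linear calibration and evaluation statistics.

Covers the comparison workflow against a co-located reference instrument:
ordinary-least-squares channel calibration, RMSE/MBE/MAE/MSE error metrics
(sign convention: test device minus reference, so a negative mean bias
means the device underestimates), light-level-binned difference summaries,
and stress-level frequency distributions over full days or working hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comfort import STRESS_LEVELS

__all__ = [
    "LinearCalibration",
    "EvaluationReport",
    "StressFrequency",
    "fit_linear_calibration",
    "apply_calibration",
    "error_metrics",
    "binned_differences",
    "stress_frequency",
    "LIGHT_BINS",
    "WORKING_HOURS_UTC",
]

#: light bins keyed to the test device's own lux channel: dark, dim, lit
LIGHT_BINS = ("0 lx", "1-500 lx", ">500 lx")

#: working-hours window, half-open [08:00, 18:00) UTC
WORKING_HOURS_UTC = (8, 18)


@dataclass(frozen=True)
class LinearCalibration:
    """Per-channel, per-device linear correction ``slope * raw + intercept``."""

    slope: float
    intercept: float
    valid_range: tuple[float, float]
    fitted_on: int

    def __post_init__(self) -> None:
        if self.valid_range[0] >= self.valid_range[1]:
            raise ValueError("valid_range lo must be < hi")
        if self.fitted_on < 2:
            raise ValueError("calibration needs >= 2 pairs")


@dataclass(frozen=True)
class EvaluationReport:
    rmse: float
    mbe: float
    mae: float
    mse: float
    n: int
    by_light_bin: dict | None = None


@dataclass(frozen=True)
class StressFrequency:
    """Percent of records per stress level; fractions sum to 100."""

    fractions_pct: dict
    window: str
    n: int


def fit_linear_calibration(raw, reference, saturation_cutoff: float | None = None) -> LinearCalibration:
    """OLS fit of reference on raw channel values.

    Pairs whose reference exceeds ``saturation_cutoff`` are excluded (the
    raw sensor saturates there and would bias the slope).  The valid range
    is the extent of the raw data used.
    """
    raw = np.asarray(raw, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if raw.shape != reference.shape:
        raise ValueError("raw and reference must have equal length")
    keep = np.isfinite(raw) & np.isfinite(reference)
    if saturation_cutoff is not None:
        keep &= reference < saturation_cutoff
    raw, reference = raw[keep], reference[keep]
    if raw.size < 2 or np.ptp(raw) == 0:
        raise ValueError("need >= 2 usable pairs with distinct raw values")
    slope, intercept = np.polyfit(raw, reference, 1)
    return LinearCalibration(
        slope=float(slope),
        intercept=float(intercept),
        valid_range=(float(raw.min()), float(raw.max())),
        fitted_on=int(raw.size),
    )


def apply_calibration(value, cal: LinearCalibration):
    """Apply a linear calibration; out-of-range inputs are flagged, not rejected.

    Returns ``(calibrated, extrapolated)`` where ``extrapolated`` marks
    values outside the calibration's fitted range.
    """
    arr = np.asarray(value, dtype=float)
    out = cal.slope * arr + cal.intercept
    lo, hi = cal.valid_range
    flag = (arr < lo) | (arr > hi)
    if arr.ndim == 0:
        return float(out), bool(flag)
    return out, flag


def error_metrics(test, reference) -> EvaluationReport:
    """RMSE, MBE, MAE and MSE of test-minus-reference differences."""
    d = np.asarray(test, dtype=float) - np.asarray(reference, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no finite pairs to evaluate")
    mse = float(np.mean(d**2))
    return EvaluationReport(
        rmse=float(np.sqrt(mse)),
        mbe=float(np.mean(d)),
        mae=float(np.mean(np.abs(d))),
        mse=mse,
        n=int(d.size),
    )


def _light_bin(light_lx: np.ndarray) -> np.ndarray:
    """Bin membership by integer lux: exactly 0; (0, 500]; (500, inf)."""
    bins = np.where(light_lx <= 0, 0, np.where(light_lx <= 500, 1, 2))
    return bins


def binned_differences(test, reference, light_lx) -> dict:
    """Five-number difference summaries per light bin.

    Differences are test minus reference (same sign convention as
    :func:`error_metrics`); whiskers follow the Tukey 1.5*IQR convention.
    Returns ``{bin label: {q1, median, q3, lo_whisker, hi_whisker, n}}``
    with only populated bins present.
    """
    d = np.asarray(test, dtype=float) - np.asarray(reference, dtype=float)
    light = np.asarray(light_lx, dtype=float)
    keep = np.isfinite(d) & np.isfinite(light)
    d, light = d[keep], light[keep]
    membership = _light_bin(light)
    out = {}
    for i, label in enumerate(LIGHT_BINS):
        vals = d[membership == i]
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        in_lo = vals[vals >= q1 - 1.5 * iqr]
        in_hi = vals[vals <= q3 + 1.5 * iqr]
        out[label] = {
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "lo_whisker": float(in_lo.min()),
            "hi_whisker": float(in_hi.max()),
            "n": int(vals.size),
        }
    return out


def stress_frequency(
    timestamps,
    stress_levels,
    window: str = "full-day",
) -> StressFrequency:
    """Percent of records per stress level over a time window.

    ``window`` is ``"full-day"`` or ``"working-hours"`` (the half-open
    [08:00, 18:00) UTC subset).  Every one of the nine levels appears in
    the output, zero-valued if unobserved; fractions sum to 100.
    """
    ts = pd.to_datetime(pd.Series(list(timestamps)), utc=True)
    levels = pd.Series(list(stress_levels))
    if len(ts) != len(levels):
        raise ValueError("timestamps and stress_levels must have equal length")
    if window == "working-hours":
        lo, hi = WORKING_HOURS_UTC
        mask = (ts.dt.hour >= lo) & (ts.dt.hour < hi)
        levels = levels[mask.to_numpy()]
    elif window != "full-day":
        raise ValueError(f"unknown window {window!r}")
    if len(levels) == 0:
        raise ValueError(f"no records in window {window!r}")
    counts = levels.value_counts()
    fractions = {lbl: float(100.0 * counts.get(lbl, 0) / len(levels)) for lbl in STRESS_LEVELS}
    unknown = set(counts.index) - set(STRESS_LEVELS)
    if unknown:
        raise ValueError(f"unknown stress labels {sorted(unknown)}")
    return StressFrequency(fractions_pct=fractions, window=window, n=int(len(levels)))
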