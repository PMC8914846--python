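"""Synthetic diurnal workplace scenarios with known radiant ground truth.

Generates device-like sensor streams (5-min cadence by default) for
office / industrial / semi-outdoor settings: sinusoidal air temperature,
a half-sine solar pulse through a window during a configurable sun window,
longwave irradiance from a wall-temperature model, optional waste-heat
offsets, and per-channel Gaussian noise at low-cost-sensor scale.

The ground-truth mean radiant temperature is constructed from the SW/LW
fields through the sphere-weighted radiant flux, and the globe channel is
derived by numerically inverting the globe equation — so with noise off,
both the IR+light (sphere) route and the globe route recover the truth
exactly, and every stage of the pipeline is testable without field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .radiation import SIGMA, RadiationConstants, sw_to_lux
from .mrt import GlobeSpec, globe_from_mrt
from .records import CANONICAL_COLUMNS

__all__ = [
    "ScenarioConfig",
    "PRESETS",
    "generate_scenario",
    "generate_reference_pair",
]

#: default per-channel Gaussian noise, at low-cost-sensor datasheet scale
DEFAULT_NOISE = {
    "ta_c": 0.3,        # K
    "rh_pct": 2.0,      # %
    "tg_c": 0.3,        # K
    "lw_wm2": 5.0,      # W/m2
    "light_rel": 0.05,  # multiplicative (5 %)
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated deployment.

    The sun window (start/end hour, UTC) shapes a half-sine shortwave pulse
    with peak ``sw_peak_wm2`` (kept below the lux-saturation branch so the
    light channel stays invertible); ``waste_heat_k`` adds a constant
    industrial offset to air and wall temperature.  ``site`` controls the
    wind stream: indoor sites carry no anemometer.
    """

    seed: int = 0
    duration_days: float = 2.0
    step_min: int = 5
    device_id: str = "synthetic-01"
    ta_mean_c: float = 24.0
    ta_amplitude_k: float = 3.0
    ta_peak_hour_utc: float = 15.0
    sun_window_utc: tuple[float, float] | None = (6.0, 10.0)
    sw_peak_wm2: float = 400.0
    waste_heat_k: float = 0.0
    wall_offset_k: float = -1.0
    site: str = "indoor"
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    wind_median_ms: float = 0.8
    wind_sigma_log: float = 0.6

    def __post_init__(self) -> None:
        if (24 * 60) % self.step_min != 0:
            raise ValueError("step must divide 24 h")
        if any(s < 0 for s in self.noise.values()):
            raise ValueError("noise sigmas must be >= 0")
        if self.sun_window_utc is not None:
            lo, hi = self.sun_window_utc
            if not (0 <= lo < hi <= 24):
                raise ValueError("sun window must lie within [00:00, 24:00)")
        if self.site not in ("indoor", "semi-outdoor"):
            raise ValueError("site must be 'indoor' or 'semi-outdoor'")


#: scenario presets mirroring typical deployments
PRESETS = {
    "office_east": ScenarioConfig(sun_window_utc=(6.0, 10.0), sw_peak_wm2=400.0),
    "office_hallway": ScenarioConfig(sun_window_utc=None, ta_amplitude_k=1.5),
    "industrial_waste_heat": ScenarioConfig(
        sun_window_utc=None, ta_mean_c=30.0, waste_heat_k=8.0, wall_offset_k=4.0
    ),
    "semi_outdoor_barn": ScenarioConfig(
        site="semi-outdoor", ta_mean_c=20.0, ta_amplitude_k=6.0,
        sun_window_utc=(8.0, 16.0), sw_peak_wm2=250.0, wall_offset_k=-3.0,
    ),
}

#: cup-anemometer starting speed: below this the cups do not turn
ANEMOMETER_DEADBAND_MS = 0.5


def _truth_fields(config: ScenarioConfig) -> pd.DataFrame:
    """Noise-free physical fields on the scenario time grid."""
    n = int(round(config.duration_days * 24 * 60 / config.step_min))
    start = pd.Timestamp("2021-09-02T00:00:00Z")
    ts = start + pd.to_timedelta(np.arange(n) * config.step_min, unit="m")
    hour = (ts - ts.normalize()).total_seconds().to_numpy() / 3600.0

    ta = (
        config.ta_mean_c
        + config.waste_heat_k
        + config.ta_amplitude_k * np.cos(2 * np.pi * (hour - config.ta_peak_hour_utc) / 24.0)
    )
    rh = np.clip(55.0 - 1.5 * (ta - config.ta_mean_c), 20.0, 95.0)

    sw = np.zeros(n)
    if config.sun_window_utc is not None:
        lo, hi = config.sun_window_utc
        inside = (hour >= lo) & (hour < hi)
        sw[inside] = config.sw_peak_wm2 * np.sin(np.pi * (hour[inside] - lo) / (hi - lo))

    t_wall = ta + config.wall_offset_k
    lw = SIGMA * (t_wall + 273.15) ** 4

    constants = RadiationConstants()
    s_str = constants.F * constants.alpha_k * sw + constants.eps_p * lw
    tmrt = (s_str / (constants.eps_p * constants.sigma)) ** 0.25 - 273.15

    return pd.DataFrame(
        {
            "timestamp": ts,
            "ta_c": ta,
            "rh_pct": rh,
            "sw_wm2": sw,
            "lw_wm2": lw,
            "tmrt_c": tmrt,
        }
    )


def _wind_stream(config: ScenarioConfig, n: int, rng: np.random.Generator) -> np.ndarray | None:
    """Recorded cup-anemometer wind [m/s], or None for indoor sites.

    Log-normal draws; speeds under the 0.5 m/s starting speed are recorded
    as 0 (the cups do not turn).  The 0.1 m/s floor is applied downstream,
    not here — the channel carries what the instrument would log.
    """
    if config.site != "semi-outdoor":
        return None
    w = rng.lognormal(mean=np.log(config.wind_median_ms), sigma=config.wind_sigma_log, size=n)
    w = np.where(w < ANEMOMETER_DEADBAND_MS, 0.0, w)
    return w


def generate_scenario(
    config: ScenarioConfig,
    globe: GlobeSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(truth, device)`` streams for one scenario.

    ``truth`` carries the exact physical fields including ``tmrt_c``;
    ``device`` is a canonical sensor frame with per-channel noise applied.
    Reproducible for a fixed ``config.seed``.
    """
    if globe is None:
        globe = GlobeSpec()
    rng = np.random.default_rng(config.seed)
    truth = _truth_fields(config)
    n = len(truth)

    wind_truth = _wind_stream(config, n, rng)
    v_eff = np.full(n, 0.1) if wind_truth is None else np.maximum(wind_truth, 0.1)
    tg = np.array(
        [
            globe_from_mrt(tm, ta, v, globe)
            for tm, ta, v in zip(truth["tmrt_c"], truth["ta_c"], v_eff)
        ]
    )
    truth = truth.assign(tg_c=tg, v_eff_ms=v_eff)

    noise = config.noise
    light_true = sw_to_lux(truth["sw_wm2"].to_numpy())
    device = pd.DataFrame(
        {
            "timestamp": truth["timestamp"],
            "device_id": config.device_id,
            "ta_c": truth["ta_c"] + rng.normal(0, noise.get("ta_c", 0.0), n),
            "rh_pct": np.clip(truth["rh_pct"] + rng.normal(0, noise.get("rh_pct", 0.0), n), 0, 100),
            "tg_c": tg + rng.normal(0, noise.get("tg_c", 0.0), n),
            "lw_wm2": np.clip(truth["lw_wm2"] + rng.normal(0, noise.get("lw_wm2", 0.0), n), 0, None),
            "tirt_c": np.nan,
            "light_lx": np.clip(light_true * (1 + rng.normal(0, noise.get("light_rel", 0.0), n)), 0, None),
            "wind_ms": np.nan if wind_truth is None else wind_truth,
        },
        columns=CANONICAL_COLUMNS,
    )
    if wind_truth is None:
        device = device.drop(columns=["wind_ms"])
    device = device.drop(columns=["tirt_c"])
    return truth, device


def generate_reference_pair(
    config: ScenarioConfig,
    reference_bias: dict | None = None,
    reference_step_min: int = 10,
    reference_noise: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(device, reference)`` streams for instrument comparison.

    The reference instrument samples the same truth on a coarser grid with
    configurable constant bias and noise per channel (``ta_c``, ``rh_pct``,
    ``tmrt_c``); with zero bias and zero noise all error metrics against
    the noise-free device channels vanish.  Feeds ``align_series`` /
    ``error_metrics`` like a co-located field comparison.
    """
    reference_bias = reference_bias or {}
    reference_noise = reference_noise or {}
    rng = np.random.default_rng(config.seed + 1)
    truth, device = generate_scenario(config)
    stride = reference_step_min // config.step_min
    if stride * config.step_min != reference_step_min:
        raise ValueError("reference step must be a multiple of the device step")
    ref = truth.iloc[::stride].reset_index(drop=True)
    n = len(ref)
    reference = pd.DataFrame(
        {
            "timestamp": ref["timestamp"],
            "device_id": "reference",
            "ta_c": ref["ta_c"] + reference_bias.get("ta_c", 0.0) + rng.normal(0, reference_noise.get("ta_c", 0.0), n),
            "rh_pct": np.clip(
                ref["rh_pct"] + reference_bias.get("rh_pct", 0.0) + rng.normal(0, reference_noise.get("rh_pct", 0.0), n),
                0, 100,
            ),
            "tmrt_c": ref["tmrt_c"] + reference_bias.get("tmrt_c", 0.0) + rng.normal(0, reference_noise.get("tmrt_c", 0.0), n),
        }
    )
    return device, reference


def noise_free(config: ScenarioConfig) -> ScenarioConfig:
    """Copy of ``config`` with every noise channel silenced."""
    return replace(config, noise={k: 0.0 for k in config.noise})
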