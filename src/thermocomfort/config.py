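"""YAML configuration loading.

A single document with optional sections ``radiation``, ``globe``,
``person``, ``calibration`` and ``scenario``; each section's keys map 1:1
onto the corresponding dataclass fields, and omitted keys keep the
defaults.  Calibrations are per device and channel::

    calibration:
      mobimet-03:
        ta_c: {slope: 1.01, intercept: -0.2, valid_range: [-10, 50], fitted_on: 120}
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .comfort import PersonConfig
from .evaluation import LinearCalibration
from .mrt import GlobeSpec
from .radiation import RadiationConstants
from .synthetic import ScenarioConfig

__all__ = ["load_config", "RunConfig"]


class RunConfig:
    """Resolved configuration objects for one pipeline run."""

    def __init__(self, raw: dict | None = None):
        raw = raw or {}
        self.radiation = RadiationConstants(**raw.get("radiation", {}))
        self.globe = GlobeSpec(**raw.get("globe", {}))
        self.person = PersonConfig(**raw.get("person", {}))
        self.scenario = ScenarioConfig(**raw.get("scenario", {}))
        self.calibration: dict[str, dict[str, LinearCalibration]] = {}
        for device, channels in raw.get("calibration", {}).items():
            self.calibration[device] = {
                ch: LinearCalibration(
                    slope=spec["slope"],
                    intercept=spec["intercept"],
                    valid_range=tuple(spec.get("valid_range", (-1e9, 1e9))),
                    fitted_on=spec.get("fitted_on", 2),
                )
                for ch, spec in channels.items()
            }

    def with_scenario(self, **overrides) -> "RunConfig":
        out = RunConfig.__new__(RunConfig)
        out.radiation, out.globe, out.person = self.radiation, self.globe, self.person
        out.calibration = self.calibration
        out.scenario = replace(self.scenario, **overrides)
        return out


def load_config(path=None) -> RunConfig:
    """Load a YAML config file, or the all-defaults configuration."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(raw)
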