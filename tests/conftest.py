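from dataclasses import replace

import pandas as pd
import pytest

from thermocomfort import mrt, records, synthetic


@pytest.fixture(scope="session")
def office_noise_free():
    """One noise-free day of the east-window office scenario."""
    cfg = replace(synthetic.noise_free(synthetic.PRESETS["office_east"]), duration_days=1.0)
    truth, device = synthetic.generate_scenario(cfg)
    return truth, device


@pytest.fixture(scope="session")
def derived_office(office_noise_free):
    """Derived + mrt-enriched frame of the noise-free office day."""
    _, device = office_noise_free
    return mrt.add_mrt_columns(records.derive_records(device))


@pytest.fixture
def small_csv(tmp_path):
    """Three-row canonical sensor CSV with all channels populated."""
    path = tmp_path / "small.csv"
    path.write_text(
        "timestamp,device_id,ta_c,rh_pct,tg_c,lw_wm2,tirt_c,light_lx,wind_ms\n"
        "2021-08-08T10:00:00Z,dev-1,24.5,48.0,26.1,430.0,,1200.0,0.0\n"
        "2021-08-08T10:05:00Z,dev-1,24.6,47.5,26.3,431.5,,1250.0,0.7\n"
        "2021-08-08T10:10:00Z,dev-1,24.8,47.0,26.6,433.0,,1300.0,0.2\n"
    )
    return path


def make_grid(start, periods, freq_min, **channels):
    """Canonical frame on a regular time grid with constant channel values."""
    ts = pd.date_range(start, periods=periods, freq=f"{freq_min}min", tz="UTC")
    base = {"timestamp": ts, "device_id": "grid", "ta_c": 24.0, "rh_pct": 50.0, "light_lx": 0.0}
    base.update(channels)
    return pd.DataFrame(base)
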