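import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermocomfort import records
from thermocomfort.records import (
    RecordValidationError,
    align_series,
    effective_wind,
    read_records,
    saturation_vapor_pressure,
    vapor_pressure_from_rh,
    write_records,
)

from conftest import make_grid


class TestReadRecords:
    def test_reads_three_rows_in_time_order(self, small_csv):
        df = read_records(small_csv)
        assert len(df) == 3
        assert df["timestamp"].is_monotonic_increasing
        assert df["ta_c"].tolist() == [24.5, 24.6, 24.8]

    def test_missing_wind_column_means_absent_channel(self, tmp_path):
        path = tmp_path / "indoor.csv"
        path.write_text(
            "timestamp,device_id,ta_c,rh_pct,light_lx\n"
            "2021-08-08T10:00:00Z,dev-1,24.5,48.0,1200.0\n"
        )
        df = read_records(path)
        assert "wind_ms" not in df.columns  # absent, not zero

    def test_rh_out_of_bounds_names_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "timestamp,device_id,ta_c,rh_pct,light_lx\n"
            "2021-08-08T10:00:00Z,dev-1,24.5,48.0,1200.0\n"
            "2021-08-08T10:05:00Z,dev-1,24.5,120.0,1200.0\n"
        )
        with pytest.raises(RecordValidationError, match="row 1"):
            read_records(path)

    def test_malformed_timestamp_is_a_parse_error(self, tmp_path):
        path = tmp_path / "ts.csv"
        path.write_text(
            "timestamp,device_id,ta_c,rh_pct,light_lx\n"
            "yesterday-ish,dev-1,24.5,48.0,1200.0\n"
        )
        with pytest.raises(RecordValidationError, match="timestamp"):
            read_records(path)

    def test_round_trip_is_lossless_at_declared_precision(self, small_csv, tmp_path):
        df = read_records(small_csv)
        out = tmp_path / "out.csv"
        write_records(df, out)
        df2 = read_records(out)
        for col in ("ta_c", "rh_pct", "tg_c", "lw_wm2", "light_lx", "wind_ms"):
            np.testing.assert_allclose(df[col], df2[col], atol=5e-4)
        assert (df["timestamp"] == df2["timestamp"]).all()

    def test_empty_frame_writes_header_only(self, tmp_path):
        out = tmp_path / "empty.csv"
        write_records(pd.DataFrame(columns=records.CANONICAL_COLUMNS), out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("timestamp,")


class TestVaporPressure:
    @pytest.mark.parametrize(
        "ta, rh, expected",
        [
            (20.0, 0.0, 0.0),          # dry air
            (20.0, 100.0, 23.33),      # saturation at 20 degC (Magnus)
            (25.0, 50.0, 15.80),       # half of e_s(25)
        ],
    )
    def test_magnus_values(self, ta, rh, expected):
        assert vapor_pressure_from_rh(ta, rh) == pytest.approx(expected, abs=0.05)

    def test_saturated_air_lies_on_saturation_curve(self):
        t = np.linspace(-10, 50, 25)
        np.testing.assert_allclose(
            vapor_pressure_from_rh(t, 100.0), saturation_vapor_pressure(t), rtol=1e-12
        )

    @given(
        ta=st.floats(-20, 50),
        rh=st.floats(0, 100),
        d_ta=st.floats(0.01, 5),
        d_rh=st.floats(0.01, 5),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotonic_in_both_arguments(self, ta, rh, d_ta, d_rh):
        base = vapor_pressure_from_rh(ta, rh)
        assert vapor_pressure_from_rh(ta + d_ta, rh) >= base
        assert vapor_pressure_from_rh(ta, min(rh + d_rh, 100.0)) >= base

    def test_rejects_rh_outside_range(self):
        with pytest.raises(RecordValidationError):
            vapor_pressure_from_rh(20.0, 120.0)


class TestEffectiveWind:
    @pytest.mark.parametrize(
        "v, expected",
        [(None, 0.1), (0.0, 0.1), (0.05, 0.1), (1.7, 1.7)],
    )
    def test_floor_rule(self, v, expected):
        assert effective_wind(v, site="indoor" if v is None else "semi-outdoor") == expected

    def test_negative_wind_rejected(self):
        with pytest.raises(RecordValidationError):
            effective_wind(-0.3, site="semi-outdoor")

    @given(v=st.floats(0, 20))
    @settings(deadline=None, max_examples=50)
    def test_always_at_least_the_floor(self, v):
        assert effective_wind(v, site="semi-outdoor") >= 0.1


class TestAlignSeries:
    def test_identical_grids_all_matched(self):
        a = make_grid("2021-08-08T00:00Z", 12, 5)
        b = make_grid("2021-08-08T00:00Z", 12, 5)
        pairs = align_series(a, b)
        assert len(pairs) == 12

    def test_five_vs_ten_minute_grid_pairs_every_reference(self):
        a = make_grid("2021-08-08T00:00Z", 24, 5)
        b = make_grid("2021-08-08T00:00Z", 12, 10)
        pairs = align_series(a, b, pd.Timedelta(minutes=2.5))
        assert len(pairs) == 12  # every 10-min record paired
        # exactly the even 5-min samples are used, each once
        used = pd.to_datetime(pairs["timestamp_a"]).dt.minute % 10
        assert (used == 0).all()

    def test_disjoint_ranges_empty(self):
        a = make_grid("2021-08-08T00:00Z", 5, 5)
        b = make_grid("2021-09-08T00:00Z", 5, 5)
        assert len(align_series(a, b)) == 0

    def test_empty_input_is_empty_not_error(self):
        a = make_grid("2021-08-08T00:00Z", 5, 5)
        assert len(align_series(a, a.iloc[0:0])) == 0


class TestSensorRecord:
    def test_invariants_enforced(self):
        ts = pd.Timestamp("2021-08-08T10:00Z")
        with pytest.raises(RecordValidationError):
            records.SensorRecord(ts, "d", ta=24.0, rh=101.0, light=0.0)
        with pytest.raises(RecordValidationError):
            records.SensorRecord(ts, "d", ta=24.0, rh=50.0, light=-1.0)
        r = records.SensorRecord(ts, "d", ta=24.0, rh=50.0, light=0.0)
        assert r.v is None and r.tg is None
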