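import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermocomfort.comfort import (
    STRESS_LEVELS,
    EnergyBalanceError,
    PersonConfig,
    classify_pet,
    comfort_pipeline,
    compute_frame,
    pet,
    solve_energy_balance,
)

sys.path.insert(0, str(Path(__file__).parent))
from _synthetic_pet_oracle import pet_oracle  # noqa: E402


class TestEnergyBalance:
    def test_neutral_conditions_give_physiological_state(self):
        st_ = solve_energy_balance(22.0, 12.0, 22.0, 0.1)
        assert st_.t_core == pytest.approx(37.0, abs=0.7)
        assert 26.0 < st_.t_skin < 35.0
        assert st_.t_skin < st_.t_core
        assert max(abs(r) for r in st_.residuals) < 1e-3

    def test_hotter_radiant_field_warms_the_skin(self):
        lo = solve_energy_balance(25.0, 12.0, 25.0, 0.1)
        hi = solve_energy_balance(25.0, 12.0, 45.0, 0.1)
        assert hi.t_skin > lo.t_skin

    def test_deterministic_bitwise(self):
        a = solve_energy_balance(28.0, 15.0, 35.0, 0.3)
        b = solve_energy_balance(28.0, 15.0, 35.0, 0.3)
        assert (a.t_core, a.t_skin, a.t_clothing) == (b.t_core, b.t_skin, b.t_clothing)

    def test_wind_floor_is_enforced(self):
        with pytest.raises(ValueError):
            solve_energy_balance(22.0, 12.0, 22.0, 0.0)

    def test_person_config_validation(self):
        with pytest.raises(ValueError):
            PersonConfig(height_m=3.0)
        with pytest.raises(ValueError):
            PersonConfig(sex="other")
        assert PersonConfig().body_surface_m2 == pytest.approx(1.91, abs=0.02)


class TestPet:
    @pytest.mark.parametrize("t", [10.0, 15.0, 20.0, 25.0, 30.0, 35.0])
    def test_reference_environment_identity(self, t):
        # in the reference environment itself, PET is the air temperature
        assert pet(t, 12.0, t, 0.1) == pytest.approx(t, abs=0.5)

    def test_radiant_load_raises_pet_above_air_temperature(self):
        assert pet(25.0, 15.0, 45.0, 0.1) > 25.0

    def test_strictly_increasing_in_tmrt_and_ta(self):
        pets_tmrt = [pet(25.0, 12.0, tm, 0.1) for tm in np.linspace(20, 55, 8)]
        assert all(a < b for a, b in zip(pets_tmrt, pets_tmrt[1:]))
        pets_ta = [pet(ta, 12.0, 30.0, 0.1) for ta in np.linspace(16, 38, 8)]
        assert all(a < b for a, b in zip(pets_ta, pets_ta[1:]))

    def test_wind_changes_pet_monotonically_in_warm_regime(self):
        vals = [pet(30.0, 12.0, 30.0, v) for v in (0.1, 0.3, 0.6, 1.0)]
        diffs = np.diff(vals)
        assert (diffs < 0).all() or (diffs > 0).all()

    def test_agreement_with_standin_oracle_on_grid(self):
        worst = 0.0
        for ta in (15.0, 21.0, 27.0, 33.0, 40.0):
            for tmrt in (15.0, 26.0, 37.0, 48.0, 60.0):
                for vp, v in ((5.0, 0.1), (25.0, 2.0)):
                    expected, _ = pet_oracle(ta, vp, tmrt, v)
                    worst = max(worst, abs(pet(ta, vp, tmrt, v) - expected))
        assert worst <= 0.1

    def test_oracle_confirms_neutral_body_state(self):
        _, (tc, tsk, _) = pet_oracle(22.0, 12.0, 22.0, 0.1)
        got = solve_energy_balance(22.0, 12.0, 22.0, 0.1)
        assert got.t_core == pytest.approx(tc, abs=1e-4)
        assert got.t_skin == pytest.approx(tsk, abs=1e-4)


class TestClassification:
    @pytest.mark.parametrize(
        "value, label",
        [
            (-5.0, "extreme cold stress"),
            (3.99, "extreme cold stress"),
            (4.0, "strong cold stress"),       # boundaries belong to the upper class
            (13.0, "slight cold stress"),
            (17.99, "slight cold stress"),
            (18.0, "no thermal stress"),
            (20.0, "no thermal stress"),
            (23.0, "slight heat stress"),
            (29.0, "moderate heat stress"),
            (30.0, "moderate heat stress"),
            (35.0, "strong heat stress"),
            (41.0, "extreme heat stress"),
            (50.0, "extreme heat stress"),
        ],
    )
    def test_boundary_convention(self, value, label):
        assert classify_pet(value) == label

    @given(value=st.floats(-80, 80))
    @settings(deadline=None, max_examples=200)
    def test_total_and_monotone(self, value):
        label = classify_pet(value)
        assert label in STRESS_LEVELS
        # monotone step function: a warmer PET never maps to a colder class
        assert STRESS_LEVELS.index(classify_pet(value + 1.0)) >= STRESS_LEVELS.index(label)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            classify_pet(float("nan"))


class TestPipeline:
    def test_full_record_populates_every_field(self):
        rec = {"ta_c": 24.0, "vp_hpa": 14.0, "v_eff_ms": 0.1, "tg_c": 26.0}
        res = comfort_pipeline(rec, method="globe")
        assert res.tmrt.method == "globe"
        assert res.stress_level in STRESS_LEVELS
        assert res.pet_c == pytest.approx(pet(24.0, 14.0, res.tmrt.tmrt_c, 0.1))

    def test_missing_globe_channel_errors(self):
        from thermocomfort.mrt import ChannelMissingError

        with pytest.raises(ChannelMissingError):
            comfort_pipeline({"ta_c": 24.0, "vp_hpa": 14.0, "v_eff_ms": 0.1}, method="globe")

    def test_batch_preserves_order(self, derived_office):
        sub = derived_office.iloc[60:75]
        out = compute_frame(sub, method="globe")
        assert (out.index == sub.index).all()
        assert len(out) == len(sub)
        assert out["pet_c"].notna().all()
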