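"""Tumor growth model and efficacy statistics (TGI, %TV change, Welch)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import serdstudy as sd
from serdstudy.tumor_growth import (
    VOLUME_FLOOR_MM3,
    align_arms_to_common_end,
    log_fold_changes,
)


def make_series(volumes, days=None, animal="a1", arm="arm"):
    v = np.asarray(volumes, dtype=float)
    d = np.arange(len(v), dtype=float) if days is None else np.asarray(days, float)
    return sd.TumorVolumeSeries(animal=animal, arm=arm, days=d, volume=v)


def flat_er(level=1.0):
    return sd.ERTimeCourse(times=np.array([0.0, 1e4]), level=np.array([level, level]))


class TestSimulateTumor:
    def test_vehicle_reduces_to_exponential_model(self):
        p = sd.TumorGrowthParams(b0=0.02, bkill=0.5)
        days = np.array([0.0, 7.0, 14.0])
        s = sd.simulate_tumor(p, flat_er(1.0), days, v0=200.0)
        np.testing.assert_allclose(s.volume, 200.0 * 10 ** (0.02 * days), rtol=1e-9)
        assert s.volume[-1] == pytest.approx(381.1, abs=0.1)

    def test_full_suppression_regresses_at_net_slope(self):
        b0 = 0.02
        p = sd.TumorGrowthParams(b0=b0, bkill=2 * b0, gamma=1.0)
        days = np.array([0.0, 10.0])
        s = sd.simulate_tumor(p, flat_er(0.0), days, v0=200.0)
        assert np.log10(s.volume[-1] / s.volume[0]) / 10.0 == pytest.approx(
            -b0, rel=1e-9
        )

    def test_zero_kill_rate_ignores_er(self):
        p = sd.TumorGrowthParams(b0=0.02, bkill=0.0)
        days = np.array([0.0, 7.0, 14.0])
        a = sd.simulate_tumor(p, flat_er(1.0), days, v0=150.0)
        b = sd.simulate_tumor(p, flat_er(0.1), days, v0=150.0)
        np.testing.assert_allclose(a.volume, b.volume, rtol=1e-12)


class TestFitGrowthRate:
    def test_exact_on_noiseless_exponential(self):
        days = np.array([0.0, 3, 7, 10, 14])
        s = make_series(100.0 * 10 ** (0.02 * days), days=days)
        fit = sd.fit_growth_rate(s)
        assert fit.b == pytest.approx(0.02, abs=1e-12)
        assert fit.a == pytest.approx(2.0, abs=1e-12)

    def test_floor_applied_before_log(self):
        """A 10 mm^3 measurement participates as 15 mm^3."""
        days = np.array([0.0, 7.0, 14.0])
        s = make_series([100.0, 40.0, 10.0], days=days)
        fit = sd.fit_growth_rate(s)
        y = np.log10(np.array([100.0, 40.0, VOLUME_FLOOR_MM3]))
        expected = stats.linregress(days, y)
        assert fit.b == pytest.approx(expected.slope, abs=1e-12)

    def test_requires_three_days(self):
        with pytest.raises(ValueError, match=">= 3"):
            sd.fit_growth_rate(make_series([100.0, 120.0]))

    def test_recovers_vehicle_rate_from_simulation(self, truth, small_design, noiseless):
        bundle = sd.simulate_study(small_design, truth, noiseless)
        vehicle = bundle.volumes_by_arm()["vehicle"]
        for s in vehicle:
            assert sd.fit_growth_rate(s).b == pytest.approx(
                truth.growth.b0, rel=1e-9
            )


class TestPercentTVChange:
    @pytest.mark.parametrize(
        "v_end,expected", [(200.0, 0.0), (300.0, 50.0), (100.0, -50.0)]
    )
    def test_direct_formula(self, v_end, expected):
        s = make_series([200.0, 250.0, v_end])
        assert sd.percent_tv_change(s) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.1, 100.0))
    def test_scale_invariance(self, scale):
        base = make_series([200.0, 260.0, 310.0])
        scaled = make_series(scale * base.volume)
        assert sd.percent_tv_change(scaled) == pytest.approx(
            sd.percent_tv_change(base), rel=1e-9
        )


class TestTGI:
    def control(self):
        # every control animal doubles: GM fold change = 2
        return [make_series([200.0, 300.0, 400.0], animal=f"c{i}") for i in range(3)]

    def test_control_vs_itself_is_zero(self):
        res = sd.tgi(self.control(), self.control())
        assert res.tgi_pct == pytest.approx(0.0, abs=1e-9)

    def test_static_treated_arm_is_100(self):
        treated = [make_series([250.0, 240.0, 250.0], animal=f"t{i}") for i in range(3)]
        res = sd.tgi(treated, self.control())
        assert res.tgi_pct == pytest.approx(100.0, abs=1e-9)

    def test_half_growth_is_50(self):
        treated = [make_series([200.0, 250.0, 300.0], animal=f"t{i}") for i in range(3)]
        res = sd.tgi(treated, self.control())
        assert res.gm_control == pytest.approx(2.0)
        assert res.gm_treated == pytest.approx(1.5)
        assert res.tgi_pct == pytest.approx(50.0, abs=1e-9)

    def test_regression_exceeds_100_unclipped(self):
        treated = [make_series([200.0, 150.0, 100.0], animal=f"t{i}") for i in range(3)]
        res = sd.tgi(treated, self.control())
        assert res.tgi_pct > 100.0

    def test_non_growing_control_flagged_undefined(self):
        shrinking = [make_series([200.0, 180.0, 160.0], animal=f"c{i}") for i in range(3)]
        res = sd.tgi(self.control(), shrinking)
        assert not res.defined and res.tgi_pct is None
        assert "TGI undefined" in res.note

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.1, 100.0))
    def test_scale_invariance(self, scale):
        treated = [make_series([200.0, 250.0, 300.0], animal=f"t{i}") for i in range(2)]
        control = self.control()
        base = sd.tgi(treated, control, with_p=False).tgi_pct
        scaled = sd.tgi(
            [make_series(scale * s.volume, animal=s.animal) for s in treated],
            [make_series(scale * s.volume, animal=s.animal) for s in control],
            with_p=False,
        ).tgi_pct
        assert scaled == pytest.approx(base, rel=1e-9)


class TestDoseResponseMonotonicity:
    def test_noiseless_tgi_nondecreasing_in_dose(self, truth, noiseless):
        design = sd.default_design(
            doses=(0.03, 0.1, 0.3, 1.0), n_per_arm=1, duration_days=14.0
        )
        bundle = sd.simulate_study(design, truth, noiseless)
        by_arm = bundle.volumes_by_arm()
        values = [
            sd.tgi(by_arm[a], by_arm["vehicle"], with_p=False).tgi_pct
            for a, reg in design.arms
            if reg is not None
        ]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))


def welch_one_tailed_oracle(x, y):
    """Independently coded one-tailed Welch p (alternative: mean x < mean y)."""
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    t = (np.mean(x) - np.mean(y)) / np.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return float(stats.t.cdf(t, df))


class TestCompareToVehicle:
    def test_identical_groups_give_half(self):
        # within-arm variation, identical arms: t = 0 exactly, so p = 0.5
        arm = [
            make_series([200.0 + 10 * i, 260.0 + 25 * i, 330.0 + 15 * i], animal=f"x{i}")
            for i in range(4)
        ]
        assert sd.compare_to_vehicle(arm, arm) == pytest.approx(0.5, abs=1e-12)

    def test_matches_independent_welch_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            nt, nc = rng.integers(3, 9, size=2)
            treated = [
                make_series([200.0, 200.0 * np.exp(lc)], days=[0.0, 14.0], animal=f"t{i}")
                for i, lc in enumerate(rng.normal(0.3, 0.4, nt))
            ]
            control = [
                make_series([200.0, 200.0 * np.exp(lc)], days=[0.0, 14.0], animal=f"c{i}")
                for i, lc in enumerate(rng.normal(0.7, 0.3, nc))
            ]
            p = sd.compare_to_vehicle(treated, control)
            expected = welch_one_tailed_oracle(
                log_fold_changes(treated), log_fold_changes(control)
            )
            assert p == pytest.approx(expected, abs=1e-9)

    def test_single_animal_rejected(self):
        one = [make_series([200.0, 220.0])]
        two = [make_series([200.0, 220.0], animal="b"), make_series([210.0, 230.0], animal="c")]
        with pytest.raises(ValueError, match=">= 2 animals"):
            sd.compare_to_vehicle(one, two)


class TestAlignArms:
    def test_locf_within_window_and_exclusion_beyond(self):
        treated = [
            make_series([200.0, 250.0, 300.0], days=[0, 7, 14], animal="t_full"),
            make_series([200.0, 250.0], days=[0, 10], animal="t_locf"),
            make_series([200.0, 250.0], days=[0, 3], animal="t_drop"),
        ]
        control = [make_series([200.0, 280.0, 390.0], days=[0, 7, 14], animal="c1")]
        a_t, a_c, log = align_arms_to_common_end(treated, control)
        assert {s.animal for s in a_t} == {"t_full", "t_locf"}
        locf = next(s for s in a_t if s.animal == "t_locf")
        assert locf.days[-1] == 14.0 and locf.volume[-1] == 250.0
        assert any("excluded" in line for line in log)
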