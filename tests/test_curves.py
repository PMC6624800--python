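"""Kaplan-Meier estimation, step queries, RMST and plateau detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

from tailcredit import (NOT_REACHED, NOT_REPORTED, PlateauVerdict, StepCurve,
                        detect_plateau, km_estimate, median_survival,
                        read_curve_tsv, read_raw_times_tsv, rmst, survival_at,
                        write_curve_tsv)

import oracles
from conftest import make_curve, random_step_curve


class TestKmEstimate:
    @pytest.mark.parametrize("times,flags,exp_times,exp_surv", [
        ([1, 2], [1, 1], [1, 2], [0.5, 0.0]),
        # censored subject contributes a flat step, then (2/3)*(0/1) = 0
        ([1, 2, 3], [1, 0, 1], [1, 2, 3], [2 / 3, 2 / 3, 0.0]),
        ([5, 7], [0, 0], [5, 7], [1.0, 1.0]),
    ])
    def test_hand_product_limit(self, times, flags, exp_times, exp_surv):
        curve = km_estimate(times, flags)
        assert curve.times.tolist() == exp_times
        assert curve.surv == pytest.approx(exp_surv)
        assert curve.max_followup == max(times)
        assert curve.n_enrolled == len(times)

    def test_censored_only_curve_is_flat(self):
        curve = km_estimate([5, 7], [0, 0])
        assert curve.tail_height == 1.0
        assert median_survival(curve) is NOT_REACHED

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            km_estimate([1.0, 2.0], [1])

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_empirical_survival_without_censoring(self, data):
        """With no censoring the product-limit curve is the empirical
        survival function (direct-counting oracle, n <= 8)."""
        n = data.draw(st.integers(1, 8))
        times = data.draw(st.lists(
            st.floats(0.1, 50, allow_nan=False), min_size=n, max_size=n))
        curve = km_estimate(times, [1] * n)
        for t in list(times) + [0.0, min(times) / 2, max(times)]:
            assert survival_at(curve, t) == pytest.approx(
                oracles.empirical_survival(times, t))

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_naive_product_limit_with_censoring(self, data):
        n = data.draw(st.integers(1, 8))
        times = data.draw(st.lists(
            st.floats(0.1, 50, allow_nan=False), min_size=n, max_size=n))
        flags = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        curve = km_estimate(times, flags)
        grid, surv, at_risk = oracles.naive_km(times, flags)
        assert curve.times == pytest.approx(grid)
        assert curve.surv == pytest.approx(surv)
        assert curve.at_risk.tolist() == at_risk


class TestStepCurveValidation:
    def test_rejects_increasing_survival(self):
        with pytest.raises(ValueError, match="non-increasing"):
            make_curve([1.0, 2.0], [0.5, 0.6])

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_curve([2.0, 1.0], [0.8, 0.5])

    def test_rejects_short_max_followup(self):
        with pytest.raises(ValueError, match="max_followup"):
            make_curve([1.0, 5.0], [0.8, 0.5], max_followup=3.0)


class TestSurvivalAt:
    def test_before_first_step(self, single_step_curve):
        assert survival_at(single_step_curve, 0.5) == 1.0

    def test_right_continuous_at_step(self, single_step_curve):
        assert survival_at(single_step_curve, 1.0) == 0.5

    def test_beyond_followup_is_not_reported(self, single_step_curve):
        assert survival_at(single_step_curve, 11.0) is NOT_REPORTED

    def test_negative_time_rejected(self, single_step_curve):
        with pytest.raises(ValueError):
            survival_at(single_step_curve, -1.0)

    def test_non_increasing_wherever_defined(self, rng):
        for _ in range(20):
            curve = random_step_curve(rng)
            grid = np.linspace(0, curve.max_followup, 40)
            values = [survival_at(curve, t) for t in grid]
            assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestMedian:
    def test_first_crossing(self):
        curve = make_curve([4.0, 9.0], [0.6, 0.4])
        assert median_survival(curve) == 9.0

    def test_inclusive_at_exactly_half(self):
        curve = make_curve([6.0], [0.5])
        assert median_survival(curve) == 6.0

    def test_not_reached_on_flat_curve(self, flat_curve):
        assert median_survival(flat_curve) is NOT_REACHED


class TestRmst:
    def test_flat_curve_area_is_tau(self, flat_curve):
        assert rmst(flat_curve, 10.0) == pytest.approx(10.0)

    def test_single_step_rectangle_sum(self, single_step_curve):
        # 4 months of the step at t=4 have S=1... here step at 1: 1*1 + 9*0.5
        curve = make_curve([4.0], [0.5], max_followup=10.0)
        assert rmst(curve, 10.0) == pytest.approx(4 * 1.0 + 6 * 0.5)

    def test_tau_beyond_followup_rejected(self, single_step_curve):
        with pytest.raises(ValueError):
            rmst(single_step_curve, 11.0)

    def test_matches_naive_integration_and_lifelines(self, rng):
        for _ in range(10):
            curve = random_step_curve(rng)
            tau = float(rng.uniform(0.1, curve.max_followup))
            expected = oracles.naive_rmst(
                list(curve.times), list(curve.surv), tau)
            assert rmst(curve, tau) == pytest.approx(expected)

    def test_agrees_with_lifelines_on_fitted_curve(self, rng):
        durations = rng.exponential(10, 300)
        events = rng.random(300) < 0.8
        durations = np.minimum(durations, 30.0)
        events = events & (durations < 30.0)
        kmf = KaplanMeierFitter().fit(durations, events)
        curve = km_estimate(durations, events)
        for tau in (5.0, 15.0, 29.0):
            assert rmst(curve, tau) == pytest.approx(
                restricted_mean_survival_time(kmf, t=tau), rel=1e-9)

    def test_monotone_and_bounded_in_tau(self, rng):
        curve = random_step_curve(rng)
        taus = np.linspace(0.1, curve.max_followup, 25)
        values = [rmst(curve, t) for t in taus]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert all(v <= t + 1e-12 for v, t in zip(values, taus))


class TestPlateauDetector:
    def test_flat_tail_with_support_is_plateau(self):
        curve = make_curve([2.0, 5.0, 30.0], [0.7, 0.4, 0.4],
                           at_risk=[100, 80, 50], max_followup=30.0)
        verdict = detect_plateau(curve)
        assert verdict.is_plateau
        assert verdict.drop_in_window == pytest.approx(0.0)
        assert verdict.source == "detector"

    def test_large_drop_in_window_is_not_plateau(self):
        # trailing 20% window opens at t=24; S drops 0.5 -> 0.3 inside it
        curve = make_curve([2.0, 20.0, 27.0], [0.7, 0.5, 0.3],
                           at_risk=[100, 60, 50], max_followup=30.0)
        verdict = detect_plateau(curve)
        assert verdict.drop_in_window == pytest.approx(0.20)
        assert not verdict.is_plateau

    def test_thin_at_risk_guard(self):
        curve = make_curve([2.0, 30.0], [0.4, 0.4], at_risk=[100, 3],
                           max_followup=30.0)
        assert not detect_plateau(curve).is_plateau

    def test_degenerate_followup_rejected(self):
        curve = StepCurve(times=np.array([]), surv=np.array([]),
                          at_risk=np.array([], dtype=int), max_followup=0.0,
                          n_enrolled=5)
        with pytest.raises(ValueError):
            detect_plateau(curve)

    def test_monotone_in_drop_tolerance(self, rng):
        """Raising drop_tol never flips a plateau verdict true -> false."""
        for _ in range(30):
            curve = random_step_curve(rng)
            verdicts = [detect_plateau(curve, drop_tol=tol).is_plateau
                        for tol in (0.0, 0.02, 0.05, 0.1, 0.3, 1.0)]
            assert verdicts == sorted(verdicts)

    def test_manual_override_constructor(self):
        verdict = PlateauVerdict.manual(True)
        assert verdict.is_plateau and verdict.source == "manual_override"


class TestTsvRoundTrip:
    def test_curve_roundtrip_is_exact(self, tmp_path, rng):
        curve = km_estimate(rng.exponential(10, 50),
                            rng.random(50) < 0.7)
        path = tmp_path / "curve.tsv"
        write_curve_tsv(curve, path)
        loaded = read_curve_tsv(path)
        assert loaded.times.tolist() == curve.times.tolist()
        assert loaded.surv.tolist() == curve.surv.tolist()
        assert loaded.at_risk.tolist() == curve.at_risk.tolist()
        assert loaded.max_followup == curve.max_followup

    def test_invalid_file_is_an_error_not_a_fix(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time_months\tsurvival\tat_risk\n1.0\t0.5\t10\n2.0\t0.8\t5\n")
        with pytest.raises(ValueError, match="non-increasing"):
            read_curve_tsv(path)

    def test_raw_times_reader(self, tmp_path):
        path = tmp_path / "raw.tsv"
        path.write_text("time_months\tevent\n1.0\t1\n2.5\t0\n")
        times, events = read_raw_times_tsv(path)
        assert times.tolist() == [1.0, 2.5]
        assert events.tolist() == [True, False]
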