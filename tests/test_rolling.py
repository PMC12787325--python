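"""Tests for the per-minute rolling estimation protocol."""

import dataclasses

import numpy as np
import pytest
import scipy.stats

import hrtwin as ht
from hrtwin.exceptions import SeriesTooShortError
from hrtwin.rolling import RollingFitResult


def rolling_result(predictions, actual_values, m=1):
    """Hand-built result whose predictions target actual_values, in order."""
    n = len(predictions)
    fit_indices = np.arange(1, n + 1)
    values = np.concatenate(([99.0], actual_values))  # minute 1 unused
    series = ht.HeartRateSeries("hand", values)
    return (
        RollingFitResult(
            participant_id="hand",
            order=m,
            fit_indices=fit_indices,
            trajectory=np.zeros((n, m + 1)),
            predictions=np.asarray(predictions, dtype=float),
        ),
        series,
    )


class TestRollingFit:
    @pytest.mark.parametrize(
        "n, m, expected",
        [(1440, 5, 1429), (1440, 1, 1437), (100, 5, 89), (14, 5, 3), (4, 1, 1)],
    )
    def test_prediction_count_law(self, n, m, expected):
        rng = np.random.default_rng(n + m)
        s = ht.HeartRateSeries("t", rng.uniform(60, 100, size=n))
        fit = ht.rolling_fit(s, m)
        assert fit.n_fits == expected == n - 1 - 2 * m
        assert fit.predictions.shape == (expected,)
        assert fit.trajectory.shape == (expected, m + 1)
        np.testing.assert_array_equal(fit.fit_indices, np.arange(2 * m + 1, n))

    def test_series_too_short(self):
        s = ht.HeartRateSeries("t", np.full(11, 70.0))
        with pytest.raises(SeriesTooShortError):
            ht.rolling_fit(s, 5)  # needs N >= 12

    def test_constant_series_predicts_the_constant(self, constant_series):
        for m in (1, 3, 5):
            fit = ht.rolling_fit(constant_series, m)
            np.testing.assert_allclose(fit.predictions, 70.0, atol=1e-8)

    @pytest.mark.parametrize("m", [1, 3, 5])
    def test_fast_path_matches_min_norm_solver(self, m):
        spec = dataclasses.replace(
            ht.PRESETS["participant6"], seed=7, n_minutes=150
        )
        s = ht.generate_ar_series(spec, "q")
        fit = ht.rolling_fit(s, m)
        for j, k in enumerate(fit.fit_indices):
            direct = ht.solve_min_norm(ht.build_lag_design(s, m, int(k)))
            np.testing.assert_allclose(
                fit.trajectory[j], direct.as_array(), rtol=1e-8, atol=1e-10
            )

    def test_sliding_window_uses_only_recent_history(self):
        rng = np.random.default_rng(5)
        s = ht.HeartRateSeries("t", rng.uniform(60, 100, size=200))
        window = 64
        fit = ht.rolling_fit(s, 2, window=window)
        # pick a window end well past the first day-equivalent
        j = int(np.flatnonzero(fit.fit_indices == 150)[0])
        sub = ht.HeartRateSeries("t", s.values[150 - window : 150])
        direct = ht.solve_min_norm(ht.build_lag_design(sub, 2, window))
        np.testing.assert_allclose(fit.trajectory[j], direct.as_array(), rtol=1e-8)
        # and the growing phase matches the from-the-start fit
        j0 = 0
        k0 = int(fit.fit_indices[j0])
        direct0 = ht.solve_min_norm(ht.build_lag_design(s, 2, k0))
        np.testing.assert_allclose(fit.trajectory[j0], direct0.as_array(), rtol=1e-8)

    def test_bit_identical_reruns(self, participant2_series):
        a = ht.rolling_fit(participant2_series, 3)
        b = ht.rolling_fit(participant2_series, 3)
        np.testing.assert_array_equal(a.trajectory, b.trajectory)
        np.testing.assert_array_equal(a.predictions, b.predictions)


class TestComputeErr:
    def test_hand_worked_example(self):
        result, series = rolling_result([71, 70, 74, 69], [70, 70, 72, 71])
        ev = ht.compute_err(result, series, eval_fraction=0.5)
        assert ev.err == 2.0
        assert ev.eval_count == 2

    def test_perfect_predictions_give_zero(self):
        result, series = rolling_result([70, 71, 72, 73], [70, 71, 72, 73])
        assert ht.compute_err(result, series).err == 0.0

    def test_tail_count_is_ceiling(self):
        rng = np.random.default_rng(0)
        s = ht.HeartRateSeries("t", rng.uniform(60, 100, size=1440))
        fit = ht.rolling_fit(s, 5)
        ev = ht.compute_err(fit, s, eval_fraction=0.2)
        assert fit.n_fits == 1429
        assert ev.eval_count == 286  # ceil(0.2 * 1429)

    def test_bad_fraction_rejected(self):
        result, series = rolling_result([70.0], [70.0])
        with pytest.raises(ValueError):
            ht.compute_err(result, series, eval_fraction=0.0)
        with pytest.raises(ValueError):
            ht.compute_err(result, series, eval_fraction=1.5)


class TestParameterStability:
    def test_constant_trajectory_has_zero_sd(self, constant_series):
        fit = ht.rolling_fit(constant_series, 1)
        stab = ht.parameter_stability(fit)
        assert np.all(stab.sds >= 0)
        np.testing.assert_allclose(stab.sds, 0.0, atol=1e-10)

    def test_textbook_sample_sd(self):
        result = RollingFitResult(
            participant_id="x",
            order=0 + 1,
            fit_indices=np.arange(1, 4),
            trajectory=np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]]),
            predictions=np.zeros(3),
        )
        stab = ht.parameter_stability(result, slice_fraction=1.0)
        assert stab.means[0] == 2.0
        assert stab.sds[0] == 1.0  # ddof=1

    def test_length_one_slice_reports_zero_sd(self):
        result = RollingFitResult(
            participant_id="x",
            order=1,
            fit_indices=np.arange(1, 4),
            trajectory=np.array([[1.0, 0.5], [2.0, 0.6], [3.0, 0.7]]),
            predictions=np.zeros(3),
        )
        stab = ht.parameter_stability(result, slice_fraction=0.2)
        assert stab.n_used == 1
        np.testing.assert_array_equal(stab.sds, [0.0, 0.0])

    def test_persistent_ar1_tail_sd_is_small(self):
        # with 24 h of data the lag-1 coefficient trajectory has settled:
        # its tail SD stays below 0.05 in nearly every realization
        hits = 0
        for seed in range(50):
            spec = dataclasses.replace(ht.PRESETS["participant2"], seed=seed)
            s = ht.generate_ar_series(spec)
            fit = ht.rolling_fit(s, 1)
            stab = ht.parameter_stability(fit)
            hits += stab.sds[1] < 0.05
        assert hits >= 45

    def test_tail_sd_shrinks_with_series_length(self):
        # convergence: longer series -> flatter trajectory tail
        sds = []
        for n in (360, 720, 1440):
            vals = []
            for seed in range(20):
                spec = dataclasses.replace(
                    ht.PRESETS["participant2"], seed=seed, n_minutes=n
                )
                fit = ht.rolling_fit(ht.generate_ar_series(spec), 1)
                vals.append(ht.parameter_stability(fit).sds[1])
            sds.append(np.mean(vals))
        assert sds[0] > sds[1] > sds[2]


class TestParameterPvalues:
    def test_exact_fit_flagged_undefined(self):
        s = ht.HeartRateSeries("g", np.array([2.0, 4, 8, 16, 32, 64, 128]))
        pv = ht.parameter_pvalues(s, 1)
        assert np.all(np.isnan(pv))

    def test_rank_deficient_flagged_undefined(self, constant_series):
        pv = ht.parameter_pvalues(constant_series, 1)
        assert np.all(np.isnan(pv))

    def test_strong_ar1_is_near_zero(self):
        spec = ht.SyntheticSpec(
            order=1, intercept=7.8, coefficients=(0.9,), innovation_sd=3.0, seed=3
        )
        pv = ht.parameter_pvalues(ht.generate_ar_series(spec), 1)
        assert pv[1] < 1e-6

    def test_white_noise_pvalues_uniform(self):
        # type-I calibration: under a1 = 0 the lag-coefficient p-value is
        # Uniform(0,1); checked across 200 seeds with a KS test
        spec = ht.SyntheticSpec(
            order=1,
            intercept=78.0,
            coefficients=(0.0,),
            innovation_sd=3.0,
            round_to_int=False,
        )
        pvals = []
        for seed in range(200):
            s = ht.generate_ar_series(dataclasses.replace(spec, seed=seed))
            pvals.append(ht.parameter_pvalues(s, 1)[1])
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestSelectBestOrder:
    def test_constant_series_ties_break_to_smallest_order(self, constant_series):
        summary = ht.select_best_order(constant_series)
        assert summary.order == 1
        assert summary.err == pytest.approx(0.0, abs=1e-8)

    def test_dominant_lag3_structure_prefers_order_three_or_more(self):
        spec = ht.SyntheticSpec(
            order=3,
            intercept=7.8,
            coefficients=(0.05, 0.05, 0.8),
            innovation_sd=3.0,
            seed=12,
        )
        summary = ht.select_best_order(ht.generate_ar_series(spec))
        assert summary.order >= 3

    def test_too_short_for_all_candidates(self):
        s = ht.HeartRateSeries("t", np.full(11, 70.0))
        with pytest.raises(SeriesTooShortError):
            ht.select_best_order(s, m_max=5)

    def test_summary_carries_winning_fit(self, participant2_series):
        summary = ht.select_best_order(participant2_series)
        assert summary.best_fit is not None
        assert summary.best_fit.order == summary.order
        assert summary.pvalues.shape == (summary.order + 1,)
        assert summary.err >= 0
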