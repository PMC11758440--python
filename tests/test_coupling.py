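"""Coupling analysis: response sizes, standardization, OLS fits, residuals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ztefmri.coupling as cp
from ztefmri.errors import (DegenerateFitError, DegenerateStandardizationError,
                            InvalidArgumentError)
from ztefmri.timeseries import TimeSeries


def _records(sizes, experiment="E1", subject="S1", freq=7.0, modality="electrical"):
    return [cp.ResponseRecord(subject=subject, experiment=experiment,
                              modality=modality, frequency_hz=freq, trial=i,
                              fmri_size=f, neural_size=n)
            for i, (f, n) in enumerate(sizes)]


class TestResponseSize:
    def test_all_ones_window_sum(self):
        # 22-s window at 2-s volumes: 11 samples
        assert cp.response_size(np.ones(35), 0.5, (0.0, 22.0), rel_t0=-28.0) == 11.0

    def test_zero_epoch(self):
        assert cp.response_size(np.zeros(35), 0.5, (0.0, 22.0), rel_t0=-28.0) == 0.0

    def test_ramp_partial_sum(self):
        epoch = np.arange(20.0)
        # rel times 0..19 at fs=1; [0, 4) sums indices 0..3
        assert cp.response_size(epoch, 1.0, (0.0, 4.0)) == 0 + 1 + 2 + 3

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cp.response_size(np.ones(5), 1.0, (0.0, 22.0))


class TestStandardize:
    def test_two_point_zscore(self):
        recs = _records([(1.0, 1.0), (3.0, 3.0)])
        out = cp.standardize_within_experiment(recs)
        got = sorted(r.fmri_size for r in out)
        np.testing.assert_allclose(got, [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 8)
        vals = (vals - vals.mean()) / vals.std(ddof=1)
        recs = _records([(v, v) for v in vals])
        out = cp.standardize_within_experiment(recs)
        np.testing.assert_allclose([r.fmri_size for r in out], vals, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 10)
        a = cp.standardize_within_experiment(_records([(v, v) for v in base]))
        b = cp.standardize_within_experiment(
            _records([(5.0 + 3.0 * v, 5.0 + 3.0 * v) for v in base]))
        np.testing.assert_allclose([r.fmri_size for r in a],
                                   [r.fmri_size for r in b], atol=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2 ** 16), n=st.integers(3, 20))
    def test_zscores_have_unit_moments(self, seed, n):
        rng = np.random.default_rng(seed)
        recs = _records(list(zip(rng.normal(2, 3, n), rng.normal(-1, 0.5, n))))
        out = cp.standardize_within_experiment(recs)
        f = np.array([r.fmri_size for r in out])
        g = np.array([r.neural_size for r in out])
        for v in (f, g):
            assert abs(v.mean()) < 1e-12
            assert v.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateStandardizationError):
            cp.standardize_within_experiment(_records([(2.0, 1.0), (2.0, 5.0)]))


class TestAggregate:
    def test_identical_trials_average_to_value(self):
        recs = _records([(1.5, 0.5)] * 4)
        agg = cp.aggregate_subject_frequency(recs)
        assert len(agg) == 1
        assert agg.iloc[0]["fmri_size"] == pytest.approx(1.5)
        assert agg.iloc[0]["n_trials"] == 4

    def test_complete_design_cardinality(self):
        freqs = (1.0, 3.0, 5.0, 7.0, 9.0, 13.0, 17.0)
        recs = []
        for s in range(13):
            for f in freqs:
                recs += _records([(0.1, 0.2)] * 4, experiment=f"S{s}E1",
                                 subject=f"S{s}", freq=f)
        agg = cp.aggregate_subject_frequency(recs)
        assert len(agg) == 13 * 7  # 91 subject-frequency means per modality

    def test_planted_cell_means_recovered(self):
        rng = np.random.default_rng(3)
        means = {1.0: 0.5, 7.0: 2.0}
        recs = []
        for f, mu in means.items():
            noise = rng.normal(0, 1, 6)
            noise -= noise.mean()
            recs += _records([(mu + e, mu + e) for e in noise], freq=f)
        agg = cp.aggregate_subject_frequency(recs)
        for f, mu in means.items():
            row = agg[agg["frequency_hz"] == f].iloc[0]
            assert row["fmri_size"] == pytest.approx(mu, abs=1e-12)


class TestLinearFit:
    def test_exact_proportionality_no_intercept(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = cp.linear_fit(x, 2.0 * x, with_intercept=False)
        assert fit.beta1 == pytest.approx(2.0)
        assert fit.beta0 is None
        assert fit.r2 == pytest.approx(1.0)
        assert fit.mse == pytest.approx(0.0, abs=1e-20)

    def test_exact_line_with_intercept(self):
        fit = cp.linear_fit(np.array([0.0, 1.0, 2.0]), np.array([1.0, 3.0, 5.0]))
        assert fit.beta1 == pytest.approx(2.0)
        assert fit.beta0 == pytest.approx(1.0)

    @pytest.mark.parametrize("with_intercept", [True, False])
    def test_matches_statsmodels_ols(self, with_intercept):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        x = rng.normal(0, 2, 50)
        y = 1.4 * x + 0.7 + rng.normal(0, 1, 50)
        fit = cp.linear_fit(x, y, with_intercept=with_intercept)
        X = sm.add_constant(x) if with_intercept else x[:, None]
        ref = sm.OLS(y, X).fit()
        slope_ref = ref.params[-1] if with_intercept else ref.params[0]
        assert fit.beta1 == pytest.approx(slope_ref, abs=1e-10)
        if with_intercept:
            assert fit.beta0 == pytest.approx(ref.params[0], abs=1e-10)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-10)
        assert fit.mse == pytest.approx(ref.ssr / len(x), abs=1e-10)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2 ** 16),
           ax=st.floats(0.1, 5.0), bx=st.floats(-3.0, 3.0),
           ay=st.floats(0.1, 5.0), by=st.floats(-3.0, 3.0))
    def test_r2_invariant_under_affine_transforms(self, seed, ax, bx, ay, by):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 30)
        y = 0.8 * x + rng.normal(0, 0.5, 30)
        r2 = cp.linear_fit(x, y).r2
        r2t = cp.linear_fit(ax * x + bx, ay * y + by).r2
        assert r2t == pytest.approx(r2, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateFitError):
            cp.linear_fit(np.ones(5), np.arange(5.0), with_intercept=True)
        with pytest.raises(DegenerateFitError):
            cp.linear_fit(np.zeros(5), np.arange(5.0), with_intercept=False)
        with pytest.raises(InvalidArgumentError):
            cp.linear_fit(np.ones(1), np.ones(1))


def _epoch_pair(gains, n=35, fs=0.5, rel_t0=-28.0, seed=0):
    rng = np.random.default_rng(seed)
    base = np.abs(rng.normal(1, 0.3, n))
    fmri, conv = {}, {}
    for f, g in gains.items():
        conv[f] = TimeSeries(rel_t0, fs, base.copy())
        fmri[f] = TimeSeries(rel_t0, fs, g * base)
    return fmri, conv


class TestFrequencyWiseFit:
    def test_common_gain_recovered_at_all_frequencies(self):
        fmri, conv = _epoch_pair({f: 1.5 for f in (1.0, 7.0, 17.0)})
        fits = cp.frequency_wise_timecourse_fit(fmri, conv)
        for f in fits:
            assert fits[f].beta1 == pytest.approx(1.5)

    def test_planted_increasing_gains_recovered_in_order(self):
        gains = {1.0: 0.5, 5.0: 1.0, 9.0: 1.8, 17.0: 3.0}
        fmri, conv = _epoch_pair(gains)
        fits = cp.frequency_wise_timecourse_fit(fmri, conv)
        betas = [fits[f].beta1 for f in sorted(fits)]
        assert betas == sorted(betas)
        assert all(b2 > b1 for b1, b2 in zip(betas, betas[1:]))

    def test_zero_fmri_gives_zero_slope(self):
        fmri, conv = _epoch_pair({7.0: 1.0})
        fmri[7.0] = fmri[7.0].copy_with(np.zeros(fmri[7.0].n))
        fits = cp.frequency_wise_timecourse_fit(fmri, conv)
        assert fits[7.0].beta1 == 0.0
        assert fits[7.0].mse == 0.0

    def test_mismatched_grids_rejected(self):
        fmri, conv = _epoch_pair({7.0: 1.0})
        conv[7.0] = TimeSeries(0.0, 1.0, np.ones(10))
        with pytest.raises(InvalidArgumentError):
            cp.frequency_wise_timecourse_fit(fmri, conv)


class TestFixedScalingResiduals:
    def test_global_gain_leaves_no_residuals(self):
        fmri, conv = _epoch_pair({f: 2.0 for f in (1.0, 7.0, 13.0)})
        res = cp.fixed_scaling_residuals(fmri, conv, ref_frequency=7.0)
        for f in res:
            np.testing.assert_allclose(res[f].values, 0.0, atol=1e-10)

    def test_frequency_dependent_gains_leave_structured_residuals(self):
        fmri, conv = _epoch_pair({1.0: 1.0, 7.0: 2.0, 17.0: 4.0})
        res = cp.fixed_scaling_residuals(fmri, conv, ref_frequency=7.0)
        rel = res[7.0].times
        ref_win = (rel >= 0.0) & (rel < 4.0)
        np.testing.assert_allclose(res[7.0].values[ref_win], 0.0, atol=1e-10)
        assert np.max(np.abs(res[1.0].values)) > 0.1
        assert np.max(np.abs(res[17.0].values)) > 0.1

    def test_reference_residual_orthogonal_to_predictor(self):
        rng = np.random.default_rng(5)
        n = 35
        conv7 = TimeSeries(-28.0, 0.5, np.abs(rng.normal(1, 0.3, n)))
        fmri7 = TimeSeries(-28.0, 0.5, 1.7 * conv7.values + rng.normal(0, 0.2, n))
        res = cp.fixed_scaling_residuals({7.0: fmri7}, {7.0: conv7},
                                         ref_frequency=7.0)
        rel = conv7.times
        m = (rel >= 0.0) & (rel < 4.0)
        assert res[7.0].values[m] @ conv7.values[m] == pytest.approx(0.0, abs=1e-10)

    def test_missing_reference_frequency_rejected(self):
        fmri, conv = _epoch_pair({1.0: 1.0})
        with pytest.raises(InvalidArgumentError):
            cp.fixed_scaling_residuals(fmri, conv, ref_frequency=7.0)


class TestMeanOfMeans:
    def test_single_subject_returns_trial_mean(self):
        eps = {"S1": np.array([[1.0, 2.0], [3.0, 4.0]])}
        np.testing.assert_allclose(cp.mean_of_means(eps), [2.0, 3.0])

    def test_subjects_weigh_equally_regardless_of_trial_count(self):
        eps = {"A": np.array([[0.0], [0.0]]), "B": np.array([[2.0]])}
        np.testing.assert_allclose(cp.mean_of_means(eps), [1.0])  # not 2/3

    def test_balanced_design_equals_pooled_mean(self):
        rng = np.random.default_rng(6)
        eps = {f"S{i}": rng.normal(0, 1, size=(3, 7)) for i in range(4)}
        pooled = np.concatenate(list(eps.values())).mean(axis=0)
        np.testing.assert_allclose(cp.mean_of_means(eps), pooled, atol=1e-12)
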