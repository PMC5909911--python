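"""Likelihood construction, optimiser behaviour and lag estimation."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

import tatscore as ts
from tatscore.fitting import (
    SearchSpace,
    _CohortEngine,
    bernoulli_logistic_mle,
    gaussian_panel_mle,
)

LN2 = math.log(2.0)

TRUTH = ts.ModelParams(LN2 / 12, 73.0, 0.6)

QUICK_SPACE = SearchSpace(
    alphas=tuple(LN2 / h for h in (8.0, 12.0, 16.0, 20.0)),
    betas=(50.0, 73.0, 100.0),
    thetas=tuple(np.round(np.arange(0.2, 1.01, 0.1), 4)),
)


class TestBernoulliLogisticMLE:
    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.5 - 2.0 * x)))).astype(float)
        g0, g1, ll = bernoulli_logistic_mle(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert g0 == pytest.approx(ref.params[0], abs=1e-6)
        assert g1 == pytest.approx(ref.params[1], abs=1e-6)
        assert ll == pytest.approx(ref.llf, abs=1e-8)

    def test_hand_computed_bernoulli_sum(self):
        # ten windows with hand-set scores/outcomes: the returned maximum
        # must equal the direct Bernoulli sum at the fitted coefficients
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        y = np.array([1, 1, 0, 1, 0, 0, 1, 0, 0, 0], dtype=float)
        g0, g1, ll = bernoulli_logistic_mle(x, y)
        p = 1 / (1 + np.exp(-(g0 + g1 * x)))
        direct = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_no_outcome_variation_rejected(self):
        with pytest.raises(ValueError, match="no variation"):
            bernoulli_logistic_mle(np.arange(5.0), np.ones(5))


class TestExacerbationLikelihood:
    def test_null_cohort_slope_near_zero(self, small_cohort):
        """With outcomes shuffled across windows, the profiled slope is
        near zero and the likelihood is close to intercept-only."""
        rng = np.random.default_rng(0)
        cohort = []
        all_y = np.concatenate([r.exacerbations for r in small_cohort])
        rng.shuffle(all_y)
        k = 0
        for rec in small_cohort:
            clone = ts.PatientRecord(
                rec.patient_id, rec.events, rec.monitoring_span, rec.age, rec.sex
            )
            clone.exacerbations = list(all_y[k : k + 3])
            k += 3
            cohort.append(clone)
        engine = _CohortEngine(cohort)
        scores, y, _ = engine.window_scores(TRUTH.alpha, TRUTH.beta, TRUTH.theta)
        g0, g1, ll = bernoulli_logistic_mle(scores, y)
        pbar = y.mean()
        ll0 = len(y) * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))
        assert abs(ll - ll0) < 3.0       # within chi-square(1) noise
        assert abs(g1 * scores.std()) < 1.0

    def test_truth_beats_extreme_thresholds_on_average(self):
        """Averaged over replicate cohorts, the likelihood at the generating
        threshold exceeds the likelihood at far-off thresholds."""
        deltas_low, deltas_high = [], []
        for seed in range(5):
            cohort = ts.generate_cohort(
                200, months=3,
                outcome_model=ts.OutcomeModel(true_params=TRUTH), seed=seed,
            )
            engine = _CohortEngine(cohort)
            lls = {}
            for theta in (0.2, 0.6, 1.1):
                s, y, _ = engine.window_scores(TRUTH.alpha, TRUTH.beta, theta)
                lls[theta] = bernoulli_logistic_mle(s, y)[2]
            deltas_low.append(lls[0.6] - lls[0.2])
            deltas_high.append(lls[0.6] - lls[1.1])
        assert np.mean(deltas_low) > 0
        assert np.mean(deltas_high) > 0

    def test_degenerate_outcomes_raise(self, small_cohort):
        cohort = []
        for rec in small_cohort[:10]:
            clone = ts.PatientRecord(
                rec.patient_id, rec.events, rec.monitoring_span, rec.age, rec.sex
            )
            clone.exacerbations = [1, 1, 1]
            cohort.append(clone)
        with pytest.raises(ValueError):
            ts.exacerbation_log_likelihood(cohort, TRUTH)


class TestFitExacerbationModel:
    def test_refinement_never_below_grid(self, small_cohort):
        result = ts.fit_exacerbation_model(small_cohort, search_space=QUICK_SPACE)
        engine = _CohortEngine(small_cohort)
        for alpha in QUICK_SPACE.alphas[::2]:
            for theta in QUICK_SPACE.thetas[::3]:
                s, y, _ = engine.window_scores(alpha, 73.0, theta)
                assert result.log_likelihood >= bernoulli_logistic_mle(s, y)[2] - 1e-6
        assert result.confidence_intervals["theta"][0] <= result.params.theta
        assert result.confidence_intervals["theta"][1] >= result.params.theta
        assert result.n_patients == 60
        assert result.n_windows == 180

    def test_flat_beta_plateau(self, small_cohort):
        """The likelihood depends only weakly on the sharpness parameter
        across a broad range, echoing the fitted plateau."""
        engine = _CohortEngine(small_cohort)
        lls = []
        for beta in (50.0, 73.0, 100.0):
            s, y, _ = engine.window_scores(TRUTH.alpha, beta, 0.6)
            lls.append(bernoulli_logistic_mle(s, y)[2])
        assert max(lls) - min(lls) < 2.0

    def test_profile_is_returned_over_theta_grid(self, small_cohort):
        result = ts.fit_exacerbation_model(
            small_cohort, search_space=QUICK_SPACE, refine=False
        )
        assert result.profile.shape == (len(QUICK_SPACE.thetas), 2)
        np.testing.assert_array_equal(result.profile[:, 0], QUICK_SPACE.thetas)
        assert np.isfinite(result.profile[:, 1]).all()


class TestReverseCorrelationLag:
    def _daily_scores(self, seed=0):
        rng = np.random.default_rng(seed)
        return np.clip(rng.uniform(0.1, 1.0, 90), 0, 1)

    def test_recovers_constructed_lag(self):
        raw = self._daily_scores()
        target = ts.exponential_moving_average(raw, 18.0)
        pefr = 300.0 + 100.0 * target  # noiseless linear response
        result = ts.reverse_correlation_lag(raw, pefr, lag_grid=np.arange(0, 48.1, 6))
        assert abs(result.tau - 18.0) <= 6.0
        assert not result.low_confidence

    def test_noise_flags_low_confidence(self):
        rng = np.random.default_rng(1)
        raw = self._daily_scores(1)
        result = ts.reverse_correlation_lag(raw, rng.normal(size=90))
        assert result.low_confidence

    def test_zero_lag_tie_breaks_to_smallest(self):
        raw = self._daily_scores(2)
        pefr = 250.0 + 50.0 * raw  # instantaneous response
        result = ts.reverse_correlation_lag(raw, pefr, lag_grid=[0.0, 6.0, 12.0])
        assert result.tau == 0.0

    def test_insufficient_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ts.reverse_correlation_lag(np.ones(5), np.ones(5))


class TestFitPefrModel:
    PEFR_SPACE = SearchSpace(
        alphas=tuple(LN2 / h for h in (8.0, 12.0, 16.0)),
        betas=(50.0, 73.0, 100.0),
        thetas=tuple(np.round(np.arange(0.3, 0.901, 0.05), 4)),
        taus=(6.0, 12.0, 18.0, 24.0, 30.0),
    )

    @pytest.fixture(scope="class")
    def pefr_cohort(self):
        truth = ts.ModelParams(LN2 / 12, 73.0, 0.56, 18.0)
        return ts.generate_cohort(
            200, months=3,
            outcome_model=ts.OutcomeModel(true_params=truth, include_pefr=True),
            seed=21,
        )

    def test_parameter_recovery(self, pefr_cohort):
        result = ts.fit_pefr_model(pefr_cohort, search_space=self.PEFR_SPACE)
        assert abs(result.params.theta - 0.56) <= 0.1
        assert abs(result.params.tau - 18.0) <= 6.0
        assert result.gamma1 > 0  # flow improves with adherence

    def test_zero_slope_flags_theta_unidentifiable(self, pefr_cohort):
        rng = np.random.default_rng(3)
        flat = []
        for rec in pefr_cohort[:60]:
            clone = ts.PatientRecord(
                rec.patient_id, rec.events, rec.monitoring_span, rec.age, rec.sex
            )
            clone.exacerbations = rec.exacerbations
            clone.pefr = rng.normal(376.0, 25.0, size=rec.pefr.size)
            flat.append(clone)
        result = ts.fit_pefr_model(flat, search_space=self.PEFR_SPACE, refine=False)
        assert "theta_weakly_identified" in result.flags

    def test_gaussian_panel_mle_matches_ols_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, (20, 30))
        intercepts = rng.normal(300, 40, size=(20, 1))
        y = intercepts + 55.0 * x + rng.normal(0, 10, size=x.shape)
        _, slope, _ = gaussian_panel_mle(x, y)
        # within-patient demeaned OLS is the textbook fixed-effects slope
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        ref = float((xc * yc).sum() / (xc * xc).sum())
        assert slope == pytest.approx(ref, rel=1e-12)


def test_exacerbation_and_pefr_estimates_agree():
    """Both outcome channels fitted on one cohort with a single true
    threshold give estimates whose profile intervals overlap."""
    truth = ts.ModelParams(LN2 / 12, 73.0, 0.6, 18.0)
    cohort = ts.generate_cohort(
        120, months=3,
        outcome_model=ts.OutcomeModel(true_params=truth, include_pefr=True),
        seed=33,
    )
    fit_e = ts.fit_exacerbation_model(cohort, search_space=QUICK_SPACE)
    fit_p = ts.fit_pefr_model(
        cohort, search_space=TestFitPefrModel.PEFR_SPACE
    )
    lo_e, hi_e = fit_e.confidence_intervals["theta"]
    lo_p, hi_p = fit_p.confidence_intervals["theta"]
    assert max(lo_e, lo_p) <= min(hi_e, hi_p)  # intervals overlap
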