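import math

import numpy as np
import pytest

from amikpk import (
    AssayErrorModel,
    CovariateModel,
    DiscretePopulation,
    DoseEvent,
    FitOptions,
    Subject,
    TDMDesign,
    covariate_scan,
    fit_summary,
    npag_fit,
    predictions,
    simulate_tdm_cohort,
    subject_loglik,
)
from amikpk.cohort_sim import _draw_covariates
from amikpk.pk_model import one_compartment_grid
from amikpk.pop_fit import _em_weights, _loglik_matrix, _posterior_weights


def _noise_free_subject(cl_true, v_true, ccr=52.9, sid="x", seed=0):
    """Subject whose observations equal the model predictions exactly."""
    rng = np.random.default_rng(seed)
    cov = _draw_covariates(TDMDesign(ccr_range=(ccr, ccr)), rng)
    doses = [DoseEvent(0.0, 600.0, 0.5), DoseEvent(24.0, 600.0, 0.5)]
    times = np.array([0.75, 1.0, 2.0, 4.0, 8.0, 12.0, 23.5, 25.0])
    cl_i = cl_true * cov.ccr / 52.9
    pred = one_compartment_grid(
        np.array([cl_i]), np.array([v_true]), doses, times
    )[0]
    return Subject(sid, cov, doses, times, pred, np.zeros(times.size, bool))


class TestSubjectLoglik:
    def test_zero_residual_closed_form(self, error_model):
        s = _noise_free_subject(2.25, 18.0)
        ll = subject_loglik(2.25, 18.0, s, CovariateModel(), error_model)
        sd = error_model.sd(s.concentrations)
        expected = -np.sum(np.log(sd * math.sqrt(2 * math.pi)))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_term_by_term_hand_sum(self, error_model):
        s = _noise_free_subject(2.0, 20.0, seed=3)
        # perturb observations so residuals are non-zero
        obs = s.concentrations + np.linspace(-1.0, 1.0, s.n_obs)
        s2 = Subject(s.id, s.covariates, s.doses, s.times, obs, s.blq)
        cls_v = (2.7, 16.0)
        ll = subject_loglik(*cls_v, s2, CovariateModel(), error_model)
        # brute-force summation, one observation at a time
        cl_i = cls_v[0] * s.covariates.ccr / 52.9
        hand = 0.0
        for t, y in zip(s2.times, obs):
            pred = float(
                one_compartment_grid(
                    np.array([cl_i]), np.array([cls_v[1]]), s.doses,
                    np.array([t]),
                )[0, 0]
            )
            sd = error_model.sd(pred)
            hand += (
                -0.5 * ((y - pred) / sd) ** 2
                - math.log(sd)
                - 0.5 * math.log(2 * math.pi)
            )
        assert ll == pytest.approx(hand, abs=1e-12)

    def test_decreases_with_growing_residual(self, error_model):
        s = _noise_free_subject(2.25, 18.0)
        lls = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            obs = s.concentrations + shift
            s2 = Subject(s.id, s.covariates, s.doses, s.times, obs, s.blq)
            lls.append(
                subject_loglik(2.25, 18.0, s2, CovariateModel(), error_model)
            )
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_impossible_input_gives_minus_inf(self, error_model):
        s = _noise_free_subject(2.25, 18.0)
        assert subject_loglik(-1.0, 18.0, s, None, error_model) == -np.inf


class TestMixtureLikelihood:
    def test_fixed_grid_loglik_matches_brute_force(self, error_model):
        """EM mixture log-likelihood equals direct enumeration on a
        5x5 fixed grid with three subjects (no adaptation)."""
        cohort = [
            _noise_free_subject(1.8, 15.0, sid="a", seed=1),
            _noise_free_subject(2.4, 19.0, sid="b", seed=2),
            _noise_free_subject(3.0, 22.0, sid="c", seed=3),
        ]
        grid = np.array(
            [(c, v) for c in np.linspace(1.5, 3.5, 5)
             for v in np.linspace(14.0, 24.0, 5)]
        )
        factors = np.array([s.covariates.ccr / 52.9 for s in cohort])
        logL = _loglik_matrix(cohort, grid, factors, error_model, False)
        w = np.full(25, 1 / 25)
        w_opt, ll_opt = _em_weights(logL, w)
        # brute force: plain python double loop, no shared code path
        brute = 0.0
        for i, s in enumerate(cohort):
            mix = 0.0
            for j, (cls_j, v_j) in enumerate(grid):
                lik = math.exp(
                    subject_loglik(
                        cls_j, v_j, s, CovariateModel(), error_model
                    )
                )
                mix += w_opt[j] * lik
            brute += math.log(mix)
        assert ll_opt == pytest.approx(brute, rel=1e-9)
        assert w_opt.sum() == pytest.approx(1.0, abs=1e-9)

    def test_em_never_decreases_likelihood(self, small_cohort, error_model):
        fit = npag_fit(
            small_cohort, FitOptions(seed=2, n_initial=64), error_model,
            CovariateModel(),
        )
        hist = np.array(fit.ll_history)
        assert np.all(np.diff(hist) > -1e-6)

    def test_posterior_matches_hand_computed_bayes_ratio(self, error_model):
        s = _noise_free_subject(2.25, 18.0)
        support = np.array([[2.25, 18.0], [3.0, 25.0]])
        prior = np.array([0.3, 0.7])
        factor = s.covariates.ccr / 52.9
        logL = _loglik_matrix([s], support, np.array([factor]), error_model,
                              False)
        post = _posterior_weights(logL, prior)[0]
        l1, l2 = np.exp(logL[0] - logL[0].max())
        expected = prior * [l1, l2] / (prior[0] * l1 + prior[1] * l2)
        np.testing.assert_allclose(post, expected, atol=1e-12)
        assert post.sum() == pytest.approx(1.0, abs=1e-12)


class TestNPAGFit:
    def test_single_subject_noise_free_recovery(self, error_model):
        s = _noise_free_subject(2.6, 20.0, seed=7)
        fit = npag_fit([s], FitOptions(seed=3), error_model, CovariateModel())
        dominant = fit.support[np.argmax(fit.probabilities)]
        assert dominant[0] == pytest.approx(2.6, rel=0.01)
        assert dominant[1] == pytest.approx(20.0, rel=0.01)
        assert fit.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_cohort_rejected(self, error_model):
        with pytest.raises(ValueError):
            npag_fit([], FitOptions(), error_model)

    def test_subject_order_invariance(self, small_cohort, error_model):
        opts = FitOptions(seed=5, n_initial=64, max_cycles=20)
        f1 = npag_fit(small_cohort, opts, error_model, CovariateModel())
        f2 = npag_fit(small_cohort[::-1], opts, error_model, CovariateModel())
        assert f1.mean()["CLs"] == pytest.approx(f2.mean()["CLs"], rel=1e-6)
        assert f1.mean()["V"] == pytest.approx(f2.mean()["V"], rel=1e-6)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-6)

    def test_one_compartment_wins_aic_on_one_compartment_data(
        self, population, error_model
    ):
        design = TDMDesign(n_doses=2, sample_offsets_h=(1.0, 4.0, 12.0, 23.5))
        cohort = simulate_tdm_cohort(population, 8, design, error_model, seed=5)
        f1 = npag_fit(
            cohort, FitOptions(seed=1, n_initial=128), error_model,
            CovariateModel(),
        )
        f2 = npag_fit(
            cohort,
            FitOptions(
                seed=1, n_initial=128, structural="two_compartment",
                max_cycles=20,
            ),
            error_model,
            CovariateModel(),
        )
        assert f1.aic < f2.aic


class TestCovariateScan:
    def test_recovers_renal_effect(self, population, error_model):
        design = TDMDesign(n_doses=3, third_sample_prob=1.0)
        cohort = simulate_tdm_cohort(
            population, 20, design, error_model, seed=17
        )
        opts = FitOptions(seed=1, n_initial=128, max_cycles=40)
        base = npag_fit(cohort, opts, error_model)
        report = covariate_scan(cohort, base, ["ccr", "weight"], opts,
                                error_model)
        assert report.loc["ccr", "included"]
        assert report.loc["ccr", "delta_m2ll"] > 3.84
        assert report.loc["ccr", "selected"]

    def test_constant_covariate_skipped(self, error_model):
        cohort = [
            _noise_free_subject(2.0, 18.0, sid=f"s{i}", seed=i)
            for i in range(3)
        ]
        opts = FitOptions(seed=1, n_initial=64, max_cycles=10)
        base = npag_fit(cohort, opts, error_model)
        report = covariate_scan(cohort, base, ["ccr"], opts, error_model)
        # all subjects share CCr 52.9 -> constant, flagged and skipped
        assert report.loc["ccr", "skipped"]
        assert not report.loc["ccr", "included"]


class TestSummaryAndPredictions:
    def test_two_point_summary_moments(self):
        model = DiscretePopulation(
            support=np.array([[1.0, 16.0], [3.0, 20.0]]),
            probabilities=np.array([0.5, 0.5]),
        )
        table = fit_summary(model)
        assert table.loc["CLs", "mean"] == pytest.approx(2.0)
        assert table.loc["CLs", "median"] == pytest.approx(2.0)
        assert table.loc["CLs", "sd"] == pytest.approx(1.0)
        assert table.loc["CLs", "var"] == pytest.approx(
            table.loc["CLs", "sd"] ** 2
        )

    def test_cv_percent_from_printed_moments(self):
        model = DiscretePopulation(
            support=np.array([[2.25 - 0.78, 18.0], [2.25 + 0.78, 18.0]]),
            probabilities=np.array([0.5, 0.5]),
        )
        # mean 2.25, SD 0.78 -> CV% 34.67
        assert fit_summary(model).loc["CLs", "cv_pct"] == pytest.approx(
            34.67, abs=0.01
        )

    def test_noise_free_one_point_model_has_zero_bias(self, error_model):
        s = _noise_free_subject(2.25, 18.0)
        model = npag_fit(
            [s], FitOptions(seed=1, n_initial=64, max_cycles=10),
            error_model, CovariateModel(),
        )
        # collapse to the best point: residuals should be ~0
        table, stats = predictions(model, [s], error_model)
        assert stats["bias_ind"] == pytest.approx(0.0, abs=0.05)
        assert stats["imprecision_ind"] == pytest.approx(0.0, abs=0.05)

    def test_shrinkage_in_range_for_fitted_model(
        self, small_cohort, error_model
    ):
        fit = npag_fit(
            small_cohort, FitOptions(seed=4, n_initial=64, max_cycles=20),
            error_model, CovariateModel(),
        )
        table = fit_summary(fit)
        for name in ("CLs", "V"):
            assert 0.0 <= table.loc[name, "shrink_pct"] <= 100.0
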