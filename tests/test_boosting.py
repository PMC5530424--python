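"""Offset model, gradients, df calibration, boosting loop, tuning, prediction."""

import numpy as np
import pytest
from scipy.special import expit

from kernboost.boosting import (
    KernelBaseLearner,
    boost,
    fit_base_learner,
    fit_offset_logistic,
    negative_gradient,
    pathway_effects,
    predict_proba,
    select_mstop,
    selected_pathways,
    tune_mstop,
)
from kernboost.evaluate import selection_frequency
from kernboost.kernel import GenotypeMatrix


def psd_kernel(rng, n, rank=None):
    rank = rank or n
    B = rng.standard_normal((n, rank))
    return B @ B.T


# ---------------------------------------------------------------------------
# offset
# ---------------------------------------------------------------------------

class TestOffset:
    def test_intercept_only_closed_forms(self):
        y = np.array([0, 1, 0, 1])
        assert fit_offset_logistic(y).beta[0] == pytest.approx(0.0)
        y = np.array([1, 0, 0, 0])
        assert fit_offset_logistic(y).beta[0] == pytest.approx(np.log(1 / 3))

    def test_binary_covariate_matches_contingency_log_odds(self):
        # x=0: 10 cases / 30 controls;  x=1: 40 cases / 20 controls
        y = np.r_[np.ones(10), np.zeros(30), np.ones(40), np.zeros(20)]
        x = np.r_[np.zeros(40), np.ones(60)][:, None]
        m = fit_offset_logistic(y, x)
        assert m.beta[0] == pytest.approx(np.log(10 / 30), abs=1e-6)
        assert m.beta[1] == pytest.approx(np.log((40 / 20) / (10 / 30)), abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_offset_logistic(np.ones(10))

    def test_perfect_separation_raises_with_advice(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        x = y[:, None] * 2 - 1
        with pytest.raises(ValueError, match="separation"):
            fit_offset_logistic(y, x)

    def test_missing_covariates_at_prediction_rejected(self):
        y = np.array([0, 1] * 20)
        x = np.random.default_rng(0).standard_normal((40, 1))
        m = fit_offset_logistic(y, x)
        with pytest.raises(ValueError, match="covariates"):
            m.linear_predictor(40, None)


# ---------------------------------------------------------------------------
# gradient
# ---------------------------------------------------------------------------

class TestNegativeGradient:
    def test_known_values_and_saturation(self):
        assert negative_gradient(np.array([1]), np.array([0.0]))[0] == pytest.approx(0.5)
        assert negative_gradient(np.array([0]), np.array([0.0]))[0] == pytest.approx(-0.5)
        assert negative_gradient(np.array([1]), np.array([20.0]))[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_finite_differences_of_loss(self, rng):
        def loss(y, eta):
            return np.logaddexp(0.0, eta) - y * eta

        for _ in range(10):
            y = float(rng.integers(0, 2))
            eta = float(rng.normal(scale=2))
            h = 1e-6
            numeric = -(loss(y, eta + h) - loss(y, eta - h)) / (2 * h)
            analytic = negative_gradient(np.array([y]), np.array([eta]))[0]
            assert analytic == pytest.approx(numeric, abs=1e-6)


# ---------------------------------------------------------------------------
# base-learner calibration and fitting
# ---------------------------------------------------------------------------

class TestCalibrateLambda:
    def test_closed_form_two_eigenvalues(self):
        bl = KernelBaseLearner("p", np.diag([4.0, 1.0]), df_target=1.0)
        assert bl.lam == pytest.approx(2.0, abs=1e-6)
        assert bl.degrees_of_freedom(bl.lam) == pytest.approx(1.0, abs=1e-6)

    def test_df_limits(self, rng):
        K = psd_kernel(rng, 10, rank=6)
        bl = KernelBaseLearner("p", K, df_target=3.0)
        assert bl.degrees_of_freedom(1e-14) == pytest.approx(6.0, abs=1e-6)
        assert bl.degrees_of_freedom(1e14) == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_df_rejected(self, rng):
        K = psd_kernel(rng, 8, rank=3)
        with pytest.raises(ValueError, match="infeasible"):
            KernelBaseLearner("p", K, df_target=5.0)


class TestFitBaseLearner:
    def test_zero_gradient_gives_zero_fit(self, rng):
        bl = KernelBaseLearner("p", psd_kernel(rng, 8), df_target=3.0)
        gamma, rss = fit_base_learner(bl, np.zeros(8))
        np.testing.assert_array_equal(gamma, 0)
        assert rss == 0.0

    def test_interpolation_limit_at_vanishing_penalty(self, rng):
        bl = KernelBaseLearner("p", psd_kernel(rng, 8), df_target=3.0)
        bl.lam = 1e-12
        u = rng.standard_normal(8)
        _, rss = fit_base_learner(bl, u)
        assert rss < 1e-15 * float(u @ u) + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_dual_form_equivalence_on_full_rank_kernels(self, seed):
        # transformed-design ridge vs direct kernel-penalized least squares
        rng = np.random.default_rng(seed)
        n = 8
        K = psd_kernel(rng, n) + 0.5 * np.eye(n)
        bl = KernelBaseLearner("p", K, df_target=3.0)
        u = rng.standard_normal(n)
        fitted = bl.V @ (bl.d / (bl.d + bl.lam) * (bl.V.T @ u))
        gamma12 = np.linalg.solve(K.T @ K + bl.lam * K, K.T @ u)
        fitted12 = K @ gamma12
        np.testing.assert_allclose(fitted, fitted12, atol=1e-8)

    def test_weak_learner_strictly_reduces_rss(self, rng):
        bl = KernelBaseLearner("p", psd_kernel(rng, 10, rank=5), df_target=3.0)
        u = rng.standard_normal(10)
        _, rss = fit_base_learner(bl, u)
        assert rss < float(u @ u)


# ---------------------------------------------------------------------------
# boosting loop
# ---------------------------------------------------------------------------

def make_learners(rng, n, P, rank=6, df=3.0):
    return [
        KernelBaseLearner(f"pw{j}", psd_kernel(rng, n, rank), df_target=df)
        for j in range(P)
    ]


class TestBoost:
    def test_zero_iterations_is_offset_only(self, rng):
        y = (rng.random(30) < 0.5).astype(int)
        learners = make_learners(rng, 30, 3)
        offset = fit_offset_logistic(y)
        fit = boost(y, learners, offset, m_stop=0)
        np.testing.assert_allclose(fit.eta_train, offset.linear_predictor(30))
        assert np.all(fit.f_hat == 0)
        assert selected_pathways(fit) == set()

    def test_single_learner_full_step_interpolates_gradient(self, rng):
        y = (rng.random(20) < 0.5).astype(int)
        bl = KernelBaseLearner("p", psd_kernel(rng, 20), df_target=5.0)
        bl.lam = 1e-12  # interpolation limit
        offset = fit_offset_logistic(y)
        fit = boost(y, [bl], offset, nu=1.0, m_stop=1)
        u1 = y - expit(offset.linear_predictor(20))
        np.testing.assert_allclose(
            fit.eta_train, offset.linear_predictor(20) + u1, atol=1e-8
        )

    def test_accounting_identity_after_every_iteration(self, rng):
        y = (rng.random(40) < 0.5).astype(int)
        learners = make_learners(rng, 40, 4)
        offset = fit_offset_logistic(y)
        for m in range(0, 12, 3):
            fit = boost(y, learners, offset, m_stop=m)
            np.testing.assert_allclose(
                fit.eta_train, fit.eta_offset + fit.f_hat.sum(axis=0), atol=1e-10
            )

    def test_training_risk_non_increasing(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        learners = make_learners(rng, 50, 3)
        fit = boost(y, learners, fit_offset_logistic(y), nu=0.1, m_stop=30)
        risks = np.array(fit.risk_path)
        assert np.all(np.diff(risks) <= 1e-12)

    def test_selection_path_to_set(self, rng):
        y = (rng.random(20) < 0.5).astype(int)
        learners = make_learners(rng, 20, 6)
        fit = boost(y, learners, fit_offset_logistic(y), m_stop=5)
        fit.selection_path = [2, 2, 5]
        assert selected_pathways(fit) == {"pw2", "pw5"}

    def test_distinct_selections_bounded_by_mstop(self, rng):
        y = (rng.random(30) < 0.5).astype(int)
        learners = make_learners(rng, 30, 8)
        for m in (0, 1, 3):
            fit = boost(y, learners, fit_offset_logistic(y), m_stop=m)
            assert len(selected_pathways(fit)) <= m

    def test_invalid_step_length_rejected(self, rng):
        y = (rng.random(20) < 0.5).astype(int)
        with pytest.raises(ValueError, match="nu"):
            boost(y, make_learners(rng, 20, 2), fit_offset_logistic(y), nu=0.0, m_stop=1)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

class TestTuneMstop:
    def test_select_mstop_unique_minimum(self):
        curve = np.ones(20)
        curve[7] = 0.3
        assert select_mstop(curve) == 7

    def test_select_mstop_prefers_smallest_on_ties(self):
        curve = np.ones(12)
        curve[3] = curve[9] = 0.5
        assert select_mstop(curve) == 3

    def test_fold_grid_includes_zero_and_shapes(self, rng):
        y = (rng.random(60) < 0.5).astype(int)
        learners = make_learners(rng, 60, 3)
        cv = tune_mstop(y, learners, m_max=8, n_folds=4, seed=2)
        assert cv.fold_risks.shape == (4, 9)
        assert 0 <= cv.m_stop_opt <= 8
        for sub in cv.folds:
            assert len(np.unique(y[sub])) == 2  # stratification keeps both classes

    def test_single_class_subsample_impossible(self):
        y = np.r_[np.ones(30), np.zeros(1)].astype(int)
        with pytest.raises(ValueError):
            tune_mstop(y, [], m_max=2, n_folds=2, subsample_fraction=0.5, seed=0)

    def test_null_phenotype_tunes_to_small_models(self, null_study):
        m_stops = np.array(null_study.m_stops)
        assert np.median(m_stops) <= 10
        assert np.mean(m_stops == 0) >= 0.3  # frequently the empty model


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

class TestPredict:
    def test_training_predictions_reproduced_through_kernels(self, small_fit, small_effect_data):
        p_in = small_fit.fitted_proba()
        p_kernel = predict_proba(small_fit, small_effect_data.genotypes)
        np.testing.assert_allclose(p_kernel, p_in, atol=1e-10)

    def test_empty_model_predicts_offset_probability(self, rng):
        y = (rng.random(30) < 0.5).astype(int)
        learners = make_learners(rng, 30, 2)
        fit = boost(y, learners, fit_offset_logistic(y), m_stop=0)
        assert np.allclose(fit.fitted_proba(), y.mean())

    def test_identical_new_individual_gets_identical_effects(self, small_fit, small_effect_data):
        geno = small_effect_data.genotypes
        i = 7
        Z_new = GenotypeMatrix(
            geno.Z[[i]].astype(int), ["clone"], list(geno.snp_ids)
        )
        effects = pathway_effects(small_fit, Z_new)
        np.testing.assert_allclose(effects[:, 0], small_fit.f_hat[:, i], atol=1e-9)


# ---------------------------------------------------------------------------
# parameter recovery on simulated effects
# ---------------------------------------------------------------------------

class TestParameterRecovery:
    def test_causal_pathways_selected_more_often_than_any_noise_pathway(self, effect_study):
        freq = selection_frequency(effect_study)
        causal = effect_study.causal_pathways
        noise_max = freq.drop(causal).max()
        for p in causal:
            assert freq[p] > noise_max
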