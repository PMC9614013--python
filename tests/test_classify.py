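"""Classifiers, leave-one-out evaluation, nested tuning, metrics."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from infantmotion.classify import (ClassifierSpec, fit_predict, loo_evaluate,
                                   llgmn_posterior, metrics, nested_tune,
                                   quadratic_expansion)

KINDS = ("lda", "lr", "mlp", "llgmn")


class TestQuadraticExpansion:
    def test_dimension(self):
        X = np.ones((3, 4))
        assert quadratic_expansion(X).shape == (3, 1 + 4 + 10)

    def test_monomial_order(self):
        x = np.array([[2.0, 3.0]])
        # [1, x1, x2, x1*x1, x1*x2, x2*x2]
        assert np.allclose(quadratic_expansion(x),
                           [[1, 2, 3, 4, 6, 9]])


def gmm_weights(pis, mus, covs, d):
    """Analytic LLGMN weights reproducing a Gaussian-mixture posterior."""
    iu, ju = np.triu_indices(d)
    ws = []
    for pi, mu, cov in zip(pis, mus, covs):
        P = np.linalg.inv(cov)
        bias = (np.log(pi) - 0.5 * np.log(np.linalg.det(cov))
                - 0.5 * mu @ P @ mu - d / 2 * np.log(2 * np.pi))
        quad = np.array([-0.5 * P[i, i] if i == j else -P[i, j]
                         for i, j in zip(iu, ju)])
        ws.append(np.concatenate([[bias], P @ mu, quad]))
    return np.stack(ws, axis=1)


class TestLLGMNPosterior:
    def test_zero_weights_are_uninformative(self):
        D = 1 + 2 + 3
        W = np.zeros((D, 2, 1))
        post = llgmn_posterior(W, np.array([[0.3, -1.2]]))
        assert np.allclose(post, 0.5)

    def test_posteriors_sum_to_one(self, rng):
        D = 1 + 3 + 6
        W = rng.normal(0, 1, (D, 2, 3))
        post = llgmn_posterior(W, rng.normal(0, 2, (20, 3)))
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_matches_gmm_bayes_posterior(self, rng):
        d = 2
        pis = [[0.5], [0.25, 0.25]]
        mus = [[np.zeros(2)], [np.array([2.0, 1.0]), np.array([-1.0, 2.0])]]
        covs = [[np.eye(2)],
                [np.array([[1.0, 0.3], [0.3, 2.0]]), 0.5 * np.eye(2)]]
        D = 1 + d + d * (d + 1) // 2
        W = np.zeros((D, 2, 2))
        W[:, 0, 0] = gmm_weights(pis[0], mus[0], covs[0], d)[:, 0]
        W[0, 0, 1] = -1e3   # inert padding unit for class 0
        W[:, 1, :] = gmm_weights(pis[1], mus[1], covs[1], d)
        X = rng.normal(0, 2, (100, 2))
        got = llgmn_posterior(W, X)[:, 1]
        p0 = sum(pi * multivariate_normal.pdf(X, mu, cov)
                 for pi, mu, cov in zip(pis[0], mus[0], covs[0]))
        p1 = sum(pi * multivariate_normal.pdf(X, mu, cov)
                 for pi, mu, cov in zip(pis[1], mus[1], covs[1]))
        assert np.allclose(got, p1 / (p0 + p1), atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            llgmn_posterior(np.zeros((9, 2, 1)), np.ones((1, 3)))


class TestFitPredict:
    @pytest.mark.parametrize("kind", KINDS)
    def test_memorised_point_predicted(self, kind, rng):
        X = np.vstack([rng.normal(0, 1, (10, 3)),
                       rng.normal(4, 1, (10, 3))])
        y = np.r_[np.zeros(10), np.ones(10)]
        spec = ClassifierSpec(kind, hyper=3, seed=0)
        post, label = fit_predict(spec, X, y, X[[0, 15]])
        assert label[0] == False and label[1] == True  # noqa: E712

    @pytest.mark.parametrize("kind", KINDS)
    def test_separable_classes_high_accuracy(self, kind, rng):
        n, d = 200, 7
        X = np.vstack([rng.normal(0, 1, (n // 2, d)),
                       rng.normal(3, 1, (n // 2, d))])
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        Xte = np.vstack([rng.normal(0, 1, (50, d)),
                         rng.normal(3, 1, (50, d))])
        yte = np.r_[np.zeros(50), np.ones(50)].astype(bool)
        spec = ClassifierSpec(kind, hyper=5, seed=1)
        _, labels = fit_predict(spec, X, y, Xte)
        assert np.mean(labels == yte) >= 0.95

    def test_lda_symmetric_midpoint(self):
        jitter = 0.01 * np.arange(8)
        X = np.vstack([np.column_stack([np.full(8, -1.0), jitter]),
                       np.column_stack([np.full(8, 1.0), jitter])])
        y = np.r_[np.zeros(8), np.ones(8)]
        post, _ = fit_predict(ClassifierSpec("lda"), X, y,
                              np.array([[0.0, jitter.mean()]]))
        assert post[0] == pytest.approx(0.5, abs=1e-6)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_predict(ClassifierSpec("lda"), np.ones((5, 2)),
                        np.zeros(5), np.ones((1, 2)))

    def test_llgmn_nests_lda_on_separable_data(self, rng):
        """With one component per class the LLGMN family contains the
        linear boundary, so training accuracy is at least LDA's."""
        X = np.vstack([rng.normal(0, 1, (25, 3)),
                       rng.normal(2.2, 1, (25, 3))])
        y = np.r_[np.zeros(25), np.ones(25)]
        _, lda_lab = fit_predict(ClassifierSpec("lda"), X, y, X)
        _, llg_lab = fit_predict(ClassifierSpec("llgmn", hyper=1, seed=0),
                                 X, y, X, epochs=2000)
        assert np.mean(llg_lab == y.astype(bool)) \
            >= np.mean(lda_lab == y.astype(bool))


class TestLooEvaluate:
    def _cohort(self, rng, n_low=34, n_high=7, gap=3.0):
        X = np.vstack([rng.normal(0, 1, (n_low, 4)),
                       rng.normal(gap, 1, (n_high, 4))])
        y = np.r_[np.zeros(n_low), np.ones(n_high)].astype(int)
        return X, y

    def test_fold_count_equals_cohort_size(self, rng):
        X, y = self._cohort(rng)
        res = loo_evaluate(ClassifierSpec("lda"), X, y)
        assert len(res.scores) == 41
        assert res.confusion["tp"] + res.confusion["fn"] == 7

    def test_separable_cohort_perfect_screening(self, rng):
        X, y = self._cohort(rng, gap=6.0)
        res = loo_evaluate(ClassifierSpec("mlp", hyper=6, seed=0), X, y)
        assert res.metrics["sensitivity"] == 1.0
        assert res.metrics["specificity"] == 1.0

    def test_sample_order_invariance(self, rng):
        X, y = self._cohort(rng, n_low=12, n_high=6, gap=1.0)
        ids = np.arange(len(y))
        res = loo_evaluate(ClassifierSpec("mlp", hyper=4, seed=3), X, y,
                           sample_ids=ids)
        perm = rng.permutation(len(y))
        res_p = loo_evaluate(ClassifierSpec("mlp", hyper=4, seed=3),
                             X[perm], y[perm], sample_ids=ids[perm])
        assert np.allclose(res_p.scores, res.scores[perm], atol=1e-10)

    def test_single_class_fold_rejected(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((1, 2))])
        y = np.r_[np.zeros(5), np.ones(1)].astype(int)
        with pytest.raises(ValueError, match="fold"):
            loo_evaluate(ClassifierSpec("lda"), X, y)


class TestNestedTune:
    def test_singleton_grid_always_selected(self, rng):
        X = np.vstack([rng.normal(0, 1, (12, 3)),
                       rng.normal(2, 1, (6, 3))])
        y = np.r_[np.zeros(12), np.ones(6)].astype(int)
        res = nested_tune("mlp", [7], X, y, seed=0, epochs=60)
        assert res.fold_hyper == [7] * 18
        assert res.tuned_mean == 7.0 and res.tuned_sd == 0.0

    def test_tuned_summary_matches_fold_log(self, rng):
        X = np.vstack([rng.normal(0, 1, (12, 3)),
                       rng.normal(2.5, 1, (6, 3))])
        y = np.r_[np.zeros(12), np.ones(6)].astype(int)
        res = nested_tune("llgmn", [1, 2], X, y, seed=1, repetitions=1,
                          epochs=60)
        assert res.tuned_mean == pytest.approx(np.mean(res.fold_hyper))
        assert res.tuned_sd == pytest.approx(np.std(res.fold_hyper, ddof=1))

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            nested_tune("mlp", [], np.ones((6, 2)),
                        np.array([0, 0, 0, 1, 1, 1]))


class TestMetrics:
    def test_reconstructed_confusion_matrix_row(self):
        """Sensitivity/specificity/F1 arithmetic on TP=5 FN=2 FP=1 TN=33."""
        y = np.r_[np.ones(7), np.zeros(34)].astype(bool)
        pred = np.r_[np.ones(5), np.zeros(2), np.ones(1), np.zeros(33)]
        scores = np.where(pred > 0, 0.9, 0.1)
        conf, m = metrics(y, scores, pred.astype(bool))
        assert conf == {"tp": 5, "fn": 2, "fp": 1, "tn": 33}
        assert m["sensitivity"] == pytest.approx(0.714, abs=5e-4)
        assert m["specificity"] == pytest.approx(0.971, abs=5e-4)
        assert m["f1"] == pytest.approx(0.769, abs=5e-4)

    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1], dtype=bool)
        _, m = metrics(y, np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert m["roc_auc"] == 1.0 and m["pr_auc"] == 1.0

    def test_degenerate_scores_fall_back(self):
        y = np.array([0, 1, 0, 1], dtype=bool)
        with pytest.warns(UserWarning, match="degenerate"):
            _, m = metrics(y, np.full(4, 0.5), y)
        assert m["roc_auc"] == 0.5 and m["pr_auc"] == 0.5

    def test_needs_both_classes(self):
        with pytest.raises(ValueError):
            metrics(np.ones(4, bool), np.ones(4) * 0.7, np.ones(4, bool))

    def test_random_scores_are_chance_level(self, rng):
        aucs = []
        for _ in range(300):
            y = np.r_[np.zeros(20), np.ones(20)].astype(bool)
            s = rng.random(40)
            _, m = metrics(y, s, s > 0.5)
            aucs.append(m["roc_auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)
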