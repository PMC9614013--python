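"""Brunner-Munzel test, selection/lumping, exact tests, Yule's Q."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from scipy.special import gammaln

from infantmotion.stats import (brunner_munzel, fisher_exact,
                                lump_correlated, run_selection,
                                select_features, yules_q)


class TestBrunnerMunzel:
    def test_identical_multisets_are_exchangeable(self):
        x = np.array([1.0, 2, 2, 3, 5, 5, 8])
        r = brunner_munzel(x, x.copy())
        assert r.p_hat == pytest.approx(0.5)
        assert abs(r.W) < 1e-12

    def test_complete_separation(self):
        x = np.arange(7.0)
        y = np.arange(10.0, 44.0)
        r = brunner_munzel(x, y)
        assert r.p_hat == 1.0
        assert r.p < 0.01

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 7)
            y = rng.normal(rng.normal(), rng.uniform(0.5, 2), 34)
            ours = brunner_munzel(x, y)
            ref = sps.brunnermunzel(x, y)
            assert ours.W == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_are_handled_like_scipy(self, rng):
        x = rng.integers(0, 4, 10).astype(float)
        y = rng.integers(0, 4, 15).astype(float)
        ours = brunner_munzel(x, y)
        ref = sps.brunnermunzel(x, y)
        assert ours.W == pytest.approx(ref.statistic, rel=1e-12)

    def test_degenerate_variance_warns(self):
        with pytest.warns(UserWarning, match="zero rank variance"):
            r = brunner_munzel(np.ones(5), np.ones(6))
        assert r.W == 0.0 and r.p == 1.0

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            brunner_munzel([1.0], [1.0, 2.0])

    def test_permutation_p_matches_independent_oracle(self, rng):
        """Our batched permutation p against a per-permutation scipy loop."""
        for trial in range(4):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.7, 1.5, 12)
            ours = brunner_munzel(x, y, method="permutation",
                                  n_perm=20_000, seed=trial)
            pool = np.concatenate([x, y])
            w_obs = sps.brunnermunzel(x, y).statistic
            oracle_rng = np.random.default_rng(1000 + trial)
            B, hits = 3000, 0
            for _ in range(B):
                perm = oracle_rng.permutation(len(pool))
                wb = sps.brunnermunzel(pool[perm[:6]], pool[perm[6:]]).statistic
                if abs(wb) >= abs(w_obs) - 1e-12:
                    hits += 1
            oracle_p = (1 + hits) / (B + 1)
            se = np.sqrt(oracle_p * (1 - oracle_p) / B)
            assert ours.p == pytest.approx(oracle_p, abs=4 * se + 0.01)

    def test_t_approximation_tracks_permutation_p(self, rng):
        for trial in range(5):
            x = rng.normal(0, 1, 7)
            y = rng.normal(0.5, 1, 34)
            p_t = brunner_munzel(x, y).p
            p_perm = brunner_munzel(x, y, method="permutation",
                                    n_perm=10_000, seed=trial).p
            assert abs(p_t - p_perm) < 0.04


class TestSelectFeatures:
    def _cohort(self, rng, shift=0.0):
        X = pd.DataFrame(rng.normal(0, 1, (41, 5)),
                         columns=[f"f{i}" for i in range(5)])
        X.loc[34:, "f2"] += shift
        labels = np.r_[np.zeros(34), np.ones(7)]
        return X, labels

    def test_alpha_zero_retains_nothing(self, rng):
        X, labels = self._cohort(rng)
        _, retained = select_features(X, labels, alpha=0.0)
        assert retained == []

    def test_planted_shift_retained(self, rng):
        X, labels = self._cohort(rng, shift=3.0)
        _, retained = select_features(X, labels, alpha=0.10)
        assert "f2" in retained

    def test_empty_group_rejected(self, rng):
        X, _ = self._cohort(rng)
        with pytest.raises(ValueError):
            select_features(X, np.zeros(41))

    def test_reports_all_features(self, rng):
        X, labels = self._cohort(rng)
        bm, _ = select_features(X, labels, alpha=0.10)
        assert set(bm) == set(X.columns)

    def test_null_retention_matches_binomial_expectation(self, rng):
        """On null cohorts of 26 features, about 26 * 0.10 features are
        retained per seed on average (slightly above, reflecting the
        t-approximation's mild small-sample liberality)."""
        counts = []
        labels = np.r_[np.zeros(34), np.ones(7)]
        for _ in range(400):
            X = pd.DataFrame(rng.normal(0, 1, (41, 26)))
            _, retained = select_features(X, labels, alpha=0.10)
            counts.append(len(retained))
        assert np.mean(counts) == pytest.approx(2.6, abs=0.5)


class TestLumpCorrelated:
    def test_duplicated_feature_collapses(self, rng):
        a = rng.normal(0, 1, 50)
        X = pd.DataFrame({"a": a, "b": 2 * a + 1})
        groups, pred, _ = lump_correlated(X, 0.7)
        assert len(pred.columns) == 1
        za = (a - a.mean()) / a.std()
        assert np.allclose(pred.iloc[:, 0], za, atol=1e-9)

    def test_study_grouping_yields_seven_predictors(self, rng):
        """14 retained features with correlated clusters of 4 and 5
        collapse to 7 predictors."""
        n = 41
        base1 = rng.normal(0, 1, n)
        base2 = rng.normal(0, 1, n)
        cols = {}
        for i in range(4):
            cols[f"g1_{i}"] = base1 + rng.normal(0, 0.1, n)
        for i in range(5):
            cols[f"g2_{i}"] = base2 + rng.normal(0, 0.1, n)
        for i in range(5):
            cols[f"solo_{i}"] = rng.normal(0, 1, n)
        X = pd.DataFrame(cols)
        groups, pred, _ = lump_correlated(X, 0.7)
        assert X.shape[1] == 14
        assert pred.shape[1] == 7
        sizes = sorted(len(g) for g in groups)
        assert sizes == [1, 1, 1, 1, 1, 4, 5]

    def test_uncorrelated_features_pass_through(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (100, 6)),
                         columns=list("abcdef"))
        _, pred, _ = lump_correlated(X, 0.7)
        assert pred.shape[1] == 6

    def test_no_residual_correlation(self, rng):
        n = 60
        base = rng.normal(0, 1, n)
        X = pd.DataFrame({
            "a": base + rng.normal(0, 0.2, n),
            "b": base + rng.normal(0, 0.2, n),
            "c": rng.normal(0, 1, n),
        })
        _, pred, _ = lump_correlated(X, 0.7)
        r = np.corrcoef(pred.to_numpy(float), rowvar=False)
        off = np.abs(r[~np.eye(r.shape[0], dtype=bool)])
        assert (off < 0.7).all()

    def test_constant_feature_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 30),
                          "const": np.ones(30)})
        with pytest.warns(UserWarning, match="constant"):
            _, pred, dropped = lump_correlated(X, 0.7)
        assert dropped == ["const"]
        assert list(pred.columns) == ["a"]

    def test_run_selection_bundles_stages(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (41, 4)),
                         columns=list("wxyz"))
        X.loc[34:, "x"] += 3
        X["y"] = X["x"] * 1.5 + rng.normal(0, 0.05, 41)
        labels = np.r_[np.zeros(34), np.ones(7)]
        out = run_selection(X, labels, alpha=0.10, lump_r=0.7)
        assert {"x", "y"} <= set(out.retained)
        assert out.predictors.shape[0] == 41


class TestFisherExact:
    def test_two_table_enumeration(self):
        # margins (1,1)x(1,1): two tables, each probability 0.5
        assert fisher_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_zero_row_gives_unity(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_matches_scipy_on_2x2(self, rng):
        for _ in range(20):
            t = rng.integers(0, 12, (2, 2))
            if t.sum() == 0:
                continue
            ours = fisher_exact(t)
            ref = sps.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_hypergeometric_closed_form(self):
        t = np.array([[3, 7], [5, 2]])
        ours = fisher_exact(t)
        # enumerate over the single free cell using the hypergeometric pmf
        n1, n2 = t.sum(axis=1)
        c1 = t[:, 0].sum()
        obs = sps.hypergeom.pmf(t[0, 0], n1 + n2, n1, c1)
        p = sum(sps.hypergeom.pmf(a, n1 + n2, n1, c1)
                for a in range(max(0, c1 - n2), min(n1, c1) + 1)
                if sps.hypergeom.pmf(a, n1 + n2, n1, c1) <= obs + 1e-9)
        assert ours == pytest.approx(p, abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self):
        t = [[5, 1, 3, 0, 2], [1, 4, 0, 3, 1]]   # 5 columns: MC path
        p_mc = fisher_exact(t, mc_draws=200_000, seed=3)
        # enumerate the 5-column table directly as the oracle
        from infantmotion.stats import _enumerate_tables, _table_logprob
        tt = np.asarray(t)
        rows, cols = tt.sum(1), tt.sum(0)
        lf = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
              - gammaln(tt.sum() + 1))
        obs = _table_logprob(tt, lf)
        p_exact = sum(np.exp(_table_logprob(np.asarray(tab), lf))
                      for tab in _enumerate_tables(list(rows), list(cols))
                      if _table_logprob(np.asarray(tab), lf) <= obs + 1e-9)
        assert p_mc == pytest.approx(p_exact, abs=0.01)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[-1, 2], [3, 4]])


class TestYulesQ:
    def test_perfect_association(self):
        assert yules_q([[5, 0], [0, 9]]) == 1.0

    def test_independence(self):
        assert yules_q([[1, 1], [1, 1]]) == 0.0

    def test_arithmetic(self):
        assert yules_q([[5, 2], [1, 33]]) == pytest.approx(163 / 167)

    def test_undefined_raises(self):
        with pytest.raises(ValueError):
            yules_q([[0, 3], [0, 5]])
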