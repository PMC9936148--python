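"""Mutual information, the penalized-lasso solver, relief-f, and the
two-stage selection chain."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from mibrainnet import (
    FeatureMatrix,
    build_penalty_matrix,
    mutcorlasso_fit,
    mutcorlasso_select,
    mutual_information,
    relief_f,
    select_pipeline,
)


class TestMutualInformation:
    def test_independent_vectors_score_near_zero(self):
        # histogram-MI bias for independent data is ~(bins-1)^2/(2n) ~ 0.04
        rng = np.random.default_rng(0)
        x, z = rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000)
        assert mutual_information(x, z) < 0.05

    def test_identity_equals_marginal_entropy(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 500)
        mi = mutual_information(x, x)
        counts, _ = np.histogram(x, bins=10)
        p = counts / counts.sum()
        ent = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert np.isclose(mi, ent, atol=1e-12)
        assert mi > 0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, z = rng.standard_normal(300), rng.standard_normal(300)
        assert mutual_information(x, z) == mutual_information(z, x)

    def test_constant_vector_gives_zero(self):
        z = np.random.default_rng(3).uniform(0, 1, 100)
        assert mutual_information(np.full(100, 2.0), z) == 0.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            mutual_information(np.ones(5), np.ones(5))


class TestPenaltyMatrix:
    def test_diagonal_is_one_plus_marginal_entropy(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (3, 200))
        R, C = build_penalty_matrix(X)
        for k in range(3):
            ent = mutual_information(X[k], X[k])
            assert np.isclose(R[k, k], 1.0 + ent, atol=1e-12)
        np.testing.assert_allclose(C, R * R)

    def test_symmetric_and_independent_rows_small(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 1000))
        R, C = build_penalty_matrix(X)
        np.testing.assert_allclose(R, R.T)
        off = ~np.eye(4, dtype=bool)
        assert np.all(C[off] < 0.01)

    def test_zero_norm_row_contributes_no_cosine(self):
        X = np.vstack([np.zeros(100), np.linspace(0, 1, 100)])
        R, _ = build_penalty_matrix(X)
        # cosine part is zeroed; what remains on the off-diagonal is |MI| = 0
        assert R[0, 1] == 0.0


class TestMutcorLasso:
    def test_zero_target_collapses_weights(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((6, 100))
        model = mutcorlasso_fit(X, np.zeros(100), alpha=0.5, beta=0.0, rng=0)
        assert np.max(np.abs(model.w)) < 1e-6

    def test_matches_coordinate_descent_oracle_at_beta_zero(self):
        # small-alpha regime: the fixed point and the lasso optimum agree on
        # the Eq-8 objective to <1% and on the planted support
        rng = np.random.default_rng(7)
        for _ in range(10):
            p, n = 10, 200
            X = rng.standard_normal((p, n))
            w_true = np.zeros(p)
            idx = rng.choice(p, 3, replace=False)
            w_true[idx] = rng.uniform(1, 2, 3) * rng.choice([-1, 1], 3)
            y = w_true @ X + 0.5 * rng.standard_normal(n)
            alpha = 0.01
            model = mutcorlasso_fit(X, y, alpha=alpha, beta=0.0, rng=rng)
            oracle = Lasso(alpha=alpha / (2 * n), fit_intercept=False, max_iter=100000).fit(X.T, y)

            def objective(w):
                r = y - X.T @ w
                return r @ r + alpha * np.abs(w).sum()

            rel = abs(objective(model.w) - objective(oracle.coef_)) / objective(oracle.coef_)
            assert rel < 0.01
            assert set(np.argsort(-np.abs(model.w))[:3]) == set(idx)

    def test_lyapunov_descent_is_monotone(self):
        # the printed update is majorize-minimize for the log-penalized
        # objective; that quantity must never increase
        rng = np.random.default_rng(11)
        for _ in range(10):
            p, n = 8, 100
            X = rng.standard_normal((p, n))
            y = rng.standard_normal(n)
            alpha, beta = 0.5, 0.1
            _, C = build_penalty_matrix(X)
            B = X @ X.T + beta * C
            Xy = X @ y
            w = rng.uniform(0, 1, p)

            def f_log(w):
                r = y - X.T @ w
                return r @ r + beta * w @ C @ w + 2 * alpha * np.sum(np.log(np.abs(w) + 1e-300))

            prev = f_log(w)
            for _ in range(100):
                inner = (w[:, None] * B * w[None, :]) + alpha * np.eye(p)
                w = w * np.linalg.solve(inner, w * Xy)
                cur = f_log(w)
                assert cur <= prev + 1e-9 * abs(prev)
                prev = cur

    def test_eq8_objective_transients_stay_bounded(self):
        # the l1 objective itself may wiggle (it is not the Lyapunov
        # function); increases stay below 2% relative per step
        rng = np.random.default_rng(5)
        for _ in range(10):
            X = rng.standard_normal((8, 100))
            y = rng.standard_normal(100)
            model = mutcorlasso_fit(X, y, alpha=0.5, beta=0.1, rng=rng)
            tr = model.objective_trace[5:]
            if tr.size > 1:
                rel = np.diff(tr) / np.abs(tr[:-1])
                assert rel.max() < 0.02

    def test_default_learning_rates_accepted(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (5, 60))
        y = rng.integers(0, 2, 60).astype(float)
        model = mutcorlasso_fit(X, y, alpha=0.5, beta=0.1, rng=1)
        assert model.alpha == 0.5 and model.beta == 0.1
        assert model.iterations_run <= 1000

    def test_invalid_inputs(self):
        X = np.random.default_rng(0).standard_normal((4, 50))
        with pytest.raises(ValueError, match="alpha"):
            mutcorlasso_fit(X, np.zeros(50), alpha=0.0)
        with pytest.raises(ValueError, match="length"):
            mutcorlasso_fit(X, np.zeros(10))


class TestMutcorLassoSelect:
    def _feature_matrix(self, rng, n_features=40, n_trials=120, n_informative=5):
        labels = 1 + (np.arange(n_trials) % 2)
        X = rng.uniform(0, 1, (n_trials, n_features))
        informative = rng.choice(n_features, n_informative, replace=False)
        for f in informative:
            X[:, f] += 0.8 * (labels == 2)
        X = (X - X.min(axis=0)) / (X.max(axis=0) - X.min(axis=0))
        names = [f"f{i}" for i in range(n_features)]
        return FeatureMatrix(X, names), labels, set(informative)

    def test_identity_selection(self):
        rng = np.random.default_rng(0)
        fm, labels, _ = self._feature_matrix(rng)
        res = mutcorlasso_select(fm, labels, n_keep=fm.n_features, rng=0)
        assert res.lasso_selected == list(range(fm.n_features))

    def test_planted_features_survive(self):
        # alpha at the low end of the tuning grid: the log-penalty fixed
        # point at large alpha keeps only one representative of a group of
        # mutually correlated features, while small alpha retains them all
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fm, labels, informative = self._feature_matrix(rng)
            res = mutcorlasso_select(fm, labels, n_keep=10, alpha=0.1, rng=seed)
            hits.append(len(informative & set(res.lasso_selected)))
        assert np.median(hits) >= 4  # 5 planted; most must be kept

    def test_n_keep_too_large_rejected(self):
        rng = np.random.default_rng(0)
        fm, labels, _ = self._feature_matrix(rng, n_features=8)
        with pytest.raises(ValueError, match="exceeds"):
            mutcorlasso_select(fm, labels, n_keep=9)


class TestReliefF:
    def test_constant_feature_weight_exactly_zero(self):
        rng = np.random.default_rng(0)
        n = 60
        labels = 1 + (np.arange(n) % 2)
        X = np.c_[np.full(n, 0.5), rng.uniform(0, 1, n)]
        model = relief_f(X, labels, rng=0)
        assert model.w[0] == 0.0

    def test_separating_feature_outranks_noise(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 100
            labels = 1 + (np.arange(n) % 2)
            X = np.c_[(labels == 2).astype(float), rng.uniform(0, 1, n)]
            model = relief_f(X, labels, rng=rng)
            wins += model.w[0] > model.w[1]
        assert wins >= 19

    def test_same_seed_reproduces_weights(self):
        rng = np.random.default_rng(0)
        n = 80
        labels = 1 + (np.arange(n) % 4)
        X = rng.uniform(0, 1, (n, 6))
        a = relief_f(X, labels, rng=123)
        b = relief_f(X, labels, rng=123)
        np.testing.assert_array_equal(a.w, b.w)

    def test_invariant_under_sample_permutation_given_rounds(self):
        # reordering trials while remapping the sampled-round indices must
        # leave the weights untouched
        rng = np.random.default_rng(1)
        n = 60
        labels = 1 + (np.arange(n) % 2)
        X = rng.uniform(0, 1, (n, 5))
        rounds = rng.integers(0, n, 60)
        perm = rng.permutation(n)
        inv = np.empty(n, dtype=int)
        inv[perm] = np.arange(n)
        a = relief_f(X, labels, rounds=rounds)
        b = relief_f(X[perm], labels[perm], rounds=inv[rounds])
        np.testing.assert_allclose(a.w, b.w, atol=1e-12)

    def test_small_class_rejected(self):
        labels = np.r_[np.ones(4, int), 2 * np.ones(20, int)]
        X = np.random.default_rng(0).uniform(0, 1, (24, 3))
        with pytest.raises(ValueError, match="<= k"):
            relief_f(X, labels, k=6)


class TestSelectPipeline:
    def test_dimension_bookkeeping_120_20_10(self):
        # the stated reduction chain: 120 fused features -> 20 -> 10
        rng = np.random.default_rng(0)
        n = 80
        labels = 1 + (np.arange(n) % 4)
        fm = FeatureMatrix(rng.uniform(0, 1, (n, 120)), [f"f{i}" for i in range(120)])
        res = select_pipeline(fm, labels, rng=0)
        assert len(res.lasso_selected) == 20
        assert len(res.selected) == 10
        assert set(res.selected) <= set(res.lasso_selected)

    def test_identity_when_keep_equals_total(self):
        rng = np.random.default_rng(1)
        n = 60
        labels = 1 + (np.arange(n) % 2)
        fm = FeatureMatrix(rng.uniform(0, 1, (n, 8)), [f"f{i}" for i in range(8)])
        res = select_pipeline(fm, labels, n_keep_lasso=8, n_keep_relief=8, rng=0)
        assert res.selected == list(range(8))

    def test_planted_signal_reaches_final_ten(self):
        # 5 informative of 60 features; most survive both stages
        survivors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 100
            labels = 1 + (np.arange(n) % 2)
            X = rng.uniform(0, 1, (n, 60))
            informative = rng.choice(60, 5, replace=False)
            for f in informative:
                X[:, f] += 0.8 * (labels == 2)
            X = (X - X.min(axis=0)) / (X.max(axis=0) - X.min(axis=0))
            fm = FeatureMatrix(X, [f"f{i}" for i in range(60)])
            res = select_pipeline(fm, labels, alpha=0.1, rng=seed)
            survivors.append(len(set(informative) & set(res.selected)))
        assert np.median(survivors) >= 4

    def test_keep_order_validated(self):
        fm = FeatureMatrix(np.zeros((20, 5)), [f"f{i}" for i in range(5)])
        with pytest.raises(ValueError, match="exceed"):
            select_pipeline(fm, 1 + np.arange(20) % 2, n_keep_lasso=3, n_keep_relief=5)
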