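import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

import tdfe
from tdfe import (
    DesignLabels,
    OmicsTensor,
    categorical_regression,
    loo_lda_eval,
    mnmf,
    nonnegative_shift,
    rf_importance,
)
from tdfe.comparators import CategoricalRegressionFE, MultiNMF, RandomForestFE
from tdfe.hosvd import unfold
from tdfe.synthetic import design_labels_for


class TestCategoricalRegression:
    @pytest.fixture()
    def toy(self, rng):
        # 2x2 design, 3 replicates per cell, printed effects
        J = np.repeat([1, 1, 2, 2], 3)
        K = np.tile(np.repeat([1, 2], 3), 2)
        effects = {1: 1.0, 2: 3.0}
        x = np.array([effects[j] + 0.5 * k for j, k in zip(J, K)])
        x = x + rng.normal(0, 0.4, size=12)
        return x, DesignLabels(factors=(J, K))

    def test_matches_ols_oracle(self, toy):
        """The vectorised fit reproduces a per-feature least-squares F-test
        (no-intercept model, uncentered total SS) from statsmodels."""
        x, labels = toy
        p = categorical_regression(x[None, :], labels)
        D = labels.design_matrix()
        fit = sm.OLS(x, D, hasconst=False).fit()
        assert p[0] == pytest.approx(fit.f_pvalue, rel=1e-10)

    def test_matches_hand_sum_of_squares(self, toy):
        x, labels = toy
        D = labels.design_matrix()
        beta, *_ = np.linalg.lstsq(D, x, rcond=None)
        sse = np.sum((x - D @ beta) ** 2)
        sst = np.sum(x**2)
        rank = np.linalg.matrix_rank(D)
        F = ((sst - sse) / rank) / (sse / (len(x) - rank))
        p_hand = sps.f.sf(F, rank, len(x) - rank)
        assert categorical_regression(x[None, :], labels)[0] == pytest.approx(p_hand)

    def test_intercept_variant_matches_centered_ols(self, toy):
        x, labels = toy
        p = categorical_regression(x[None, :], labels, intercept=True)
        fit = sm.OLS(x, labels.design_matrix(intercept=True)).fit()
        assert p[0] == pytest.approx(fit.f_pvalue, rel=1e-10)

    def test_degenerate_features(self):
        labels = DesignLabels(
            factors=(np.repeat([1, 2], 6), np.tile(np.repeat([1, 2], 3), 2))
        )
        X = np.vstack([np.zeros(12), np.full(12, 4.0)])
        p = categorical_regression(X, labels)
        assert p[0] == 1.0  # all-zero feature: nothing to explain
        assert p[1] < 1e-100  # constant nonzero: near-perfect zero-model rejection

    def test_null_pvalues_uniform(self, rng):
        """On pure-noise features the per-feature p-values are uniform."""
        cfg = tdfe.SyntheticConfig(n_features=10_000, n_signal=0, seed=7)
        t = tdfe.generate_synthetic(cfg)
        p = categorical_regression(unfold(t.values, 0), design_labels_for(cfg))
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_estimator_selects_planted_signal(self, small_tensor, small_config):
        est = CategoricalRegressionFE(design_labels_for(small_config), alpha=0.01)
        est.fit(small_tensor)
        truth = small_tensor.metadata["truth_mask"]
        assert np.sum(est.support_ & truth) == truth.sum()

    def test_validation(self):
        with pytest.raises(ValueError):
            DesignLabels(factors=())
        with pytest.raises(ValueError):
            DesignLabels(factors=(np.array([1, 1, 1]),))
        labels = DesignLabels(factors=(np.array([1, 2, 1, 2]),))
        with pytest.raises(ValueError):
            categorical_regression(np.zeros((3, 5)), labels)


class TestMNMF:
    def test_exact_factorization_reaches_zero_objective(self, rng):
        Q = rng.uniform(size=(30, 3))
        H = rng.uniform(size=(3, 8))
        X = Q @ H
        # multiplicative updates converge geometrically but slowly near an
        # exact factorization; a tiny instance affords the iterations
        res = mnmf(X, n=3, seed=0, max_iter=30_000, tol=0.0)
        assert res.objective < 1e-6 * np.linalg.norm(X)

    def test_objective_trace_monotone(self, rng):
        X = np.abs(rng.normal(size=(50, 12)))
        res = mnmf(X, n=3, seed=1, max_iter=300, tol=0.0)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)
        assert np.all(res.Q >= 0) and np.all(res.H >= 0)

    def test_block_objective_identity(self, rng):
        """The summed per-block squared Frobenius objectives equal the
        concatenated-matrix objective for a shared Q."""
        blocks = [rng.uniform(size=(20, m)) for m in (3, 5, 4)]
        X = np.hstack(blocks)
        Q = rng.uniform(size=(20, 2))
        H = rng.uniform(size=(2, 12))
        Hs = np.split(H, np.cumsum([3, 5])[:2], axis=1)
        block_sum = sum(
            np.linalg.norm(Xk - Q @ Hk) ** 2 for Xk, Hk in zip(blocks, Hs)
        )
        concat = np.linalg.norm(X - Q @ H) ** 2
        assert block_sum == pytest.approx(concat, rel=1e-12)

    def test_final_objective_comparable_to_sklearn(self, rng):
        """Independent route: sklearn's multiplicative-update NMF reaches a
        similar Frobenius objective on the same matrix."""
        from sklearn.decomposition import NMF

        X = np.abs(rng.normal(size=(60, 10))) + 0.1
        ours = mnmf(X, n=3, seed=0, max_iter=500, tol=0.0).objective
        sk = NMF(
            n_components=3, solver="mu", init="random", random_state=0,
            max_iter=500, tol=1e-12,
        )
        W = sk.fit_transform(X)
        theirs = np.linalg.norm(X - W @ sk.components_)
        assert ours <= theirs * 1.1

    def test_preprocessing_modes(self, rng):
        X = rng.normal(size=(5, 4))
        shifted = nonnegative_shift(X, "min")
        assert shifted.min() == 0.0
        Y = np.abs(X)
        Y[0, 0] = 0.0
        eps = nonnegative_shift(Y, "epsilon")
        assert eps[0, 0] == 1e-10
        with pytest.raises(ValueError):
            nonnegative_shift(X, "epsilon")
        with pytest.raises(ValueError):
            nonnegative_shift(X, "bogus")

    def test_rejects_negative_input(self, rng):
        with pytest.raises(ValueError):
            mnmf(rng.normal(size=(5, 4)), n=2)

    def test_estimator_wrapper(self, rng):
        X = rng.normal(size=(30, 9))
        est = MultiNMF(n_components=2, seed=3, shift="min").fit(X)
        assert est.Q_.shape == (30, 2)
        assert est.H_.shape == (2, 9)
        assert np.all(np.diff(est.objective_trace_) <= 1e-9)


class TestRandomForest:
    def test_separating_feature_ranks_first(self, rng):
        n = 60
        X = rng.normal(size=(30, n))
        y = np.repeat([0, 1], n // 2)
        X[4] = y * 3 + rng.normal(0, 0.2, size=n)
        imp, oob = rf_importance(X, y, n_estimators=200, seed=0)
        assert imp.argmax() == 4
        assert np.mean(oob == y) > 0.9

    def test_permuted_labels_behave_as_null(self, rng):
        n = 60
        X = rng.normal(size=(30, n))
        y = np.repeat([0, 1], n // 2)
        X[4] = y * 3 + rng.normal(0, 0.2, size=n)
        imp, _ = rf_importance(X, rng.permutation(y), n_estimators=200, seed=0)
        # with labels destroyed, the oracle feature is no longer singled out
        assert imp[4] < 5 * np.median(imp[imp > 0])

    def test_duplicated_feature_importance_splits(self, rng):
        """With every split scanning all candidates, duplicating a feature
        splits its importance so the duplicates sum to the singleton's."""
        n = 40
        X = rng.normal(size=(20, n))
        y = np.repeat([0, 1], n // 2)
        X[0] = y * 2 + rng.normal(0, 0.3, size=n)
        imp1, _ = rf_importance(X, y, n_estimators=500, seed=0, max_features=None)
        Xd = np.vstack([X[0:1], X])
        imp2, _ = rf_importance(Xd, y, n_estimators=500, seed=1, max_features=None)
        assert imp2[0] + imp2[1] == pytest.approx(imp1[0], rel=0.15)

    def test_top_k_estimator(self, rng):
        n = 60
        X = rng.normal(size=(30, n))
        y = np.repeat([0, 1], n // 2)
        X[4] = y * 3
        est = RandomForestFE(y, n_estimators=100, seed=0, top_k=5).fit(X)
        assert est.support_.sum() == 5
        assert est.support_[4]


class TestLOOLDA:
    @staticmethod
    def _class_labels(groups, tissues, reps):
        return np.array(
            [f"g{j}_t{k}" for j in range(groups) for k in range(tissues) for _ in range(reps)]
        )

    def test_separable_construction_has_zero_error(self, rng):
        """Class-specific mean patterns with no replicate dependence give a
        perfectly separable product representation."""
        y = self._class_labels(4, 2, 3)
        x = rng.normal(size=(200, 4, 2, 3)) * 0.05
        for j in range(4):
            for k in range(2):
                x[:30, j, k, :] += (rng.normal(size=30) * 4)[:, None]
        sel = np.zeros(200, dtype=bool)
        sel[:30] = True
        res = loo_lda_eval(OmicsTensor(x), sel, y)
        assert res.error_rate == 0.0
        assert res.confusion.to_numpy().sum() == 24

    def test_confusion_is_consistent_with_error_rate(self, rng):
        """Confusion row sums match the class sizes and the diagonal agrees
        with the reported error rate.  (Note: on unstructured data the
        product representation still encodes each sample's grid position,
        so its leave-one-out error is geometry-dependent, not pinned at the
        1 - 1/K chance level.)"""
        y = self._class_labels(4, 2, 3)
        x = rng.normal(size=(60, 4, 2, 3))
        res = loo_lda_eval(OmicsTensor(x), np.ones(60, dtype=bool), y)
        cm = res.confusion.to_numpy()
        np.testing.assert_array_equal(cm.sum(axis=1), np.full(8, 3))
        assert res.error_rate == pytest.approx(1 - np.trace(cm) / cm.sum())

    def test_validation(self, rng):
        x = rng.normal(size=(10, 4, 2, 3))
        y = self._class_labels(4, 2, 3)
        with pytest.raises(ValueError, match="selected"):
            loo_lda_eval(OmicsTensor(x), np.zeros(10, dtype=bool), y)
        singleton = y.copy()
        singleton[0] = "lonely"
        with pytest.raises(ValueError, match="class"):
            loo_lda_eval(OmicsTensor(x), np.ones(10, dtype=bool), singleton)

    def test_index_ranges_restrict_features(self, rng):
        x = rng.normal(size=(30, 4, 2, 3))
        y = self._class_labels(4, 2, 3)
        res = loo_lda_eval(
            OmicsTensor(x), np.ones(30, dtype=bool), y, index_ranges=(2, 1, 1)
        )
        assert 0.0 <= res.error_rate <= 1.0
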