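"""Base selectors: t test, PLS-DA VIP, and the lasso/elastic-net paths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabmark import SimulationConfig, simulate_dataset
from stabmark.selectors import (
    enet_select,
    lasso_select,
    plsda_vip,
    ttest_scores,
)

from conftest import make_labeled


class TestTtest:
    def test_pooled_t_matches_hand_formula(self):
        data = make_labeled([[1], [2], [3], [4], [5], [6]], [0, 0, 0, 1, 1, 1])
        res = ttest_scores(data)
        # pooled two-sample t for (1,2,3) vs (4,5,6): |t| = 3 / sqrt(1 * 2/3)
        assert res.scores[0] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0))
        assert res.meta["t"][0] > 0  # treatment minus control

    def test_identical_groups_give_zero(self):
        data = make_labeled([[1.0], [2.0], [1.0], [2.0]], [0, 0, 1, 1])
        res = ttest_scores(data)
        assert res.scores[0] == 0.0
        assert res.pvalues[0] == 1.0

    def test_scale_invariance(self, noise_data):
        base = ttest_scores(noise_data)
        scaled = noise_data.subset()
        scaled.X[:, 3] *= 17.5
        res = ttest_scores(scaled)
        assert res.scores[3] == pytest.approx(base.scores[3])
        assert res.pvalues[3] == pytest.approx(base.pvalues[3])

    def test_zero_variance_handling(self):
        X = np.array([[1.0, 0.0], [1.0, 0.1], [1.0, -0.1], [2.0, 0.2], [2.0, 0.0], [2.0, -0.2]])
        res = ttest_scores(make_labeled(X, [0, 0, 0, 1, 1, 1]))
        # constant within groups but different means: finite surrogate, p = 0
        assert np.isfinite(res.scores[0])
        assert res.scores[0] > res.scores[1]
        assert res.pvalues[0] == 0.0

    def test_welch_differs_under_unequal_variance(self, rng):
        X = np.concatenate([rng.normal(0, 1, (10, 1)), rng.normal(1, 5, (30, 1))])
        data = make_labeled(X, [0] * 10 + [1] * 30)
        pooled = ttest_scores(data, equal_var=True)
        welch = ttest_scores(data, equal_var=False)
        assert pooled.pvalues[0] != pytest.approx(welch.pvalues[0])


class TestVIP:
    def test_mean_squared_vip_is_one(self, noise_data):
        res = plsda_vip(noise_data)
        assert np.sum(res.scores**2) == pytest.approx(noise_data.p)

    def test_single_variable_vip_is_one(self):
        data = make_labeled([[0.1], [0.4], [-0.2], [0.9], [1.4], [1.1]], [0, 0, 0, 1, 1, 1])
        assert plsda_vip(data, ncomp=1).scores[0] == pytest.approx(1.0)

    def test_matches_sklearn_pls_weights(self, rng):
        # independent oracle: VIP recomputed from sklearn's NIPALS fit
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((30, 8))
        y = np.repeat([0, 1], 15)
        data = make_labeled(X, y)
        res = plsda_vip(data, ncomp=2)

        yc = (y - y.mean()) / y.std()
        pls = PLSRegression(n_components=2, scale=False).fit(X - X.mean(0), yc)
        W = pls.x_weights_
        ss = (pls.y_loadings_.ravel() ** 2) * np.sum(pls.x_scores_**2, axis=0)
        vip_ref = np.sqrt(X.shape[1] * (W**2 @ ss) / ss.sum())
        assert np.allclose(res.scores, vip_ref, atol=1e-8)

    def test_strong_variable_attains_max_vip(self):
        # one variable with a 3-sigma shift among 49 noise variables
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            d = simulate_dataset(
                SimulationConfig(n_total=100, p=50, q=0.02, delta=3.0, seed=rep)
            )
            res = plsda_vip(d)
            hits += d.truth[res.ranking[0]]
        assert hits >= n_rep - 1

    def test_component_reduction_warns(self):
        data = make_labeled(np.random.default_rng(0).standard_normal((4, 2)), [0, 0, 1, 1])
        with pytest.warns(UserWarning, match="reducing PLS components"):
            plsda_vip(data, ncomp=5)


class TestPathSelectors:
    def test_lambda_max_has_empty_active_set(self, noise_data):
        res = lasso_select(noise_data, k_target=5)
        sizes = res.meta["path_sizes"]
        assert sizes[0] == 0  # largest lambda: nothing active

    def test_entry_order_on_orthonormal_design(self, rng):
        # closed form: on an orthonormal design the lasso activates variables
        # in descending order of |x_j . y|
        n, p = 60, 10
        raw = rng.standard_normal((n, p))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        y = np.repeat([0, 1], n // 2)
        rng.shuffle(y)
        data = make_labeled(Q, y)
        res = lasso_select(data, k_target=p)
        yc = y - y.mean()
        expected = np.argsort(-np.abs(Q.T @ yc))
        assert np.array_equal(res.ranking, expected)

    def test_k_target_beyond_path_returns_maximal_set(self, rng):
        # n = 12 samples: the path cannot hold 30 active variables
        X = rng.standard_normal((12, 40))
        data = make_labeled(X, [0] * 6 + [1] * 6)
        res = lasso_select(data, k_target=30)
        assert res.meta["active_size"] == res.meta["path_sizes"].max()

    def test_enet_alpha_one_is_lasso(self, small_signal_data):
        a = lasso_select(small_signal_data, k_target=4)
        b = enet_select(small_signal_data, k_target=4, alpha=1.0)
        assert np.array_equal(a.ranking, b.ranking)
        assert np.allclose(a.scores, b.scores)

    def test_enet_grouping_of_correlated_pair(self, rng):
        # two nearly identical informative variables: the elastic net keeps
        # both in its active set far more often than the lasso does
        both_enet, both_lasso, n_rep = 0, 0, 30
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            n = 60
            y = np.repeat([0, 1], n // 2)
            x1 = r.standard_normal(n) + 1.5 * y
            x2 = x1 + 0.02 * r.standard_normal(n)
            X = np.column_stack([x1, x2, r.standard_normal((n, 18))])
            data = make_labeled(X, y)
            for fn, counter in ((lasso_select, "lasso"), (enet_select, "enet")):
                res = fn(data, 2)
                both = bool(np.all(res.meta["coef"][:2] != 0))
                if counter == "enet":
                    both_enet += both
                else:
                    both_lasso += both
        assert both_enet >= 27  # ~>= 90% of replicates
        assert both_enet > both_lasso

    def test_noise_keeps_true_target_rule(self, small_signal_data):
        res = enet_select(small_signal_data, k_target=2)
        assert res.meta["active_size"] >= 2
        assert res.meta["lambda"] > 0


class TestInvariants:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance_ttest_vip(self, seed):
        rng = np.random.default_rng(seed)
        d = simulate_dataset(SimulationConfig(n_total=20, p=12, q=0.25, delta=1.0, seed=seed))
        perm = rng.permutation(d.p)
        d_perm = d.subset(cols=perm)
        for fn in (lambda x: ttest_scores(x), lambda x: plsda_vip(x)):
            a, b = fn(d), fn(d_perm)
            assert np.allclose(b.scores, a.scores[perm])

    def test_permutation_equivariance_lasso(self, small_signal_data):
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_signal_data.p)
        a = lasso_select(small_signal_data, 4)
        b = lasso_select(small_signal_data.subset(cols=perm), 4)
        assert np.allclose(b.scores, a.scores[perm])

    def test_label_swap_leaves_abs_scores(self, noise_data):
        swapped = make_labeled(noise_data.X, 1 - noise_data.y)
        assert np.allclose(ttest_scores(swapped).scores, ttest_scores(noise_data).scores)
        assert np.allclose(plsda_vip(swapped).scores, plsda_vip(noise_data).scores)

    def test_active_set_grows_down_the_path(self, small_signal_data):
        # screening check: the active set starts empty at lambda_max and is
        # near-monotone down the path (a coefficient may momentarily cross
        # zero, so allow unit-sized local dips)
        for fn in (lasso_select, enet_select):
            sizes = fn(small_signal_data, 4).meta["path_sizes"].astype(int)
            assert sizes[0] == 0
            assert np.all(sizes >= np.maximum.accumulate(sizes) - 1)
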