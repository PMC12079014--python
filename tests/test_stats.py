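"""Gradient statistics: Mantel, paired t, linear models, IPCA/SIPCA, MANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

import commphylo as cp
from commphylo.containers import DistanceMatrix


def _dm(values, ids=None):
    ids = ids or list(range(len(values)))
    return DistanceMatrix(ids, values)


def _random_dm(rng, n=10):
    pts = rng.normal(size=(n, 3))
    return _dm(squareform(pdist(pts)))


class TestMantel:
    def test_identity_gives_rho_one_and_min_p(self, rng):
        d = _random_dm(rng)
        res = cp.mantel_spearman(d, d, n_perm=99, rng=rng)
        assert res.rho == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1.0 / 100.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        d = _random_dm(rng)
        d2 = _dm(np.exp(d.values) - 1.0, d.ids)
        res = cp.mantel_spearman(d, d2, n_perm=99, rng=rng)
        assert res.rho == pytest.approx(1.0)

    def test_zero_variance_rejected(self, rng):
        d = _random_dm(rng)
        flat = _dm(np.ones((10, 10)) - np.eye(10), d.ids)
        with pytest.raises(cp.ValidationError):
            cp.mantel_spearman(d, flat, n_perm=99, rng=rng)

    def test_null_p_roughly_uniform_for_independent_matrices(self):
        rng = np.random.default_rng(17)
        ps = [cp.mantel_spearman(_random_dm(rng), _random_dm(rng),
                                 n_perm=99, rng=rng).p_perm
              for _ in range(100)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as skbio_mantel
        d1, d2 = _random_dm(rng), _random_dm(rng)
        ours = cp.mantel_spearman(d1, d2, n_perm=999, rng=rng)
        theirs = skbio_mantel(
            skbio.DistanceMatrix(d1.values, [str(i) for i in d1.ids]),
            skbio.DistanceMatrix(d2.values, [str(i) for i in d2.ids]),
            method="spearman", permutations=999, alternative="greater")
        assert ours.rho == pytest.approx(theirs[0], abs=1e-12)
        assert ours.p_perm == pytest.approx(theirs[1], abs=0.05)


class TestPairedT:
    def test_zero_differences(self):
        t, df, p = cp.paired_t([1.0, 2.0], [1.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_hand_formula(self):
        t, df, p = cp.paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2.0 * np.sqrt(3.0))
        assert df == 2

    def test_df_for_ten_site_pairwise_triangle(self, rng):
        n_pairs = 10 * 9 // 2
        x = rng.normal(size=n_pairs)
        y = rng.normal(size=n_pairs)
        _, df, _ = cp.paired_t(x, y)
        assert df == 44

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        t1, _, p1 = cp.paired_t(x, y)
        t2, _, p2 = cp.paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestGradientLm:
    def _design(self, n_sites=10):
        aridity = np.tile(cp.aridity_gradient(n_sites), 2)
        season = ["wet"] * n_sites + ["dry"] * n_sites
        la = np.log10(aridity)
        la = la - la.mean()
        return aridity, season, la

    def test_noiseless_coefficients_recovered_exactly(self):
        aridity, season, la = self._design()
        dry = np.array([s == "dry" for s in season], dtype=float)
        y = 0.5 - 1.2 * la + 2.0 * la ** 2 + 0.7 * dry - 0.3 * la * dry
        res = cp.fit_gradient_lm(y, aridity, season)
        got = res.params.set_index("term")["estimate"]
        assert got["a"] == pytest.approx(-1.2, abs=1e-10)
        assert got["a2"] == pytest.approx(2.0, abs=1e-10)
        assert got["season[T.dry]"] == pytest.approx(0.7, abs=1e-10)
        assert got["a2:season[T.dry]"] == pytest.approx(0.0, abs=1e-10)

    def test_quadratic_recovery_under_noise(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            aridity, season, la = self._design()
            y = 1.5 * la ** 2 + rng.normal(scale=0.3, size=len(la))
            res = cp.fit_gradient_lm(y, aridity, season)
            row = res.params.set_index("term")
            est, se = row.loc["a2", "estimate"], row.loc["a2", "se"]
            if abs(est - 1.5) <= 2 * se:
                hits += 1
        assert hits >= 16  # ~95% coverage over 20 stochastic replicates

    def test_residuals_orthogonal_to_design(self, rng):
        aridity, season, _ = self._design()
        y = rng.normal(size=len(aridity))
        res = cp.fit_gradient_lm(y, aridity, season)
        exog = res.model.model.exog
        assert np.abs(exog.T @ res.model.resid).max() < 1e-8

    def test_single_season_rejected(self, rng):
        aridity = cp.aridity_gradient(10)
        with pytest.raises(cp.ValidationError):
            cp.fit_gradient_lm(rng.normal(size=10), aridity, ["wet"] * 10)

    def test_bonferroni_threshold_for_four_model_family(self):
        assert cp.bonferroni_threshold(0.05, 4) == pytest.approx(0.0125)


class TestIpca:
    def _mixed_sources(self, seed, n=200, p=40):
        rng = np.random.default_rng(seed)
        S = rng.uniform(-1, 1, (n, 2))
        A = np.zeros((2, p))
        idx = rng.permutation(p)
        A[0, idx[:4]] = rng.uniform(0.8, 1.2, 4) * rng.choice([-1, 1], 4)
        A[1, idx[4:8]] = rng.uniform(0.8, 1.2, 4) * rng.choice([-1, 1], 4)
        X = S @ A + 0.05 * rng.normal(size=(n, p))
        return S, X

    def test_recovers_sub_gaussian_sources(self):
        for seed in range(10):
            S, X = self._mixed_sources(seed)
            model = cp.ipca(X, 2, random_state=seed)
            cors = np.abs(np.corrcoef(np.c_[S, model.scores_].T)[:2, 2:])
            assert cors.max(axis=1).min() > 0.95

    def test_gaussian_data_has_near_zero_kurtosis(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 12))
        model = cp.ipca(X, 2)
        assert np.all(np.abs(model.kurtosis_) < 0.5)

    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.uniform(-1, 1, 100), rng.normal(size=8))
        X += 1e-8 * rng.normal(size=X.shape)
        model = cp.ipca(X, 1)
        assert model.explained_variance_ratio_[0] > 0.99

    def test_scores_centred_and_variance_ratios_bounded(self, rng):
        X = rng.normal(size=(60, 10)) @ rng.normal(size=(10, 10))
        model = cp.ipca(X, 3)
        assert np.abs(model.scores_.mean(axis=0)).max() < 1e-8
        assert model.explained_variance_ratio_.sum() <= 1.0 + 1e-9

    def test_sklearn_get_set_params_round_trip(self):
        model = cp.IPCA(n_components=3, scale=False)
        params = model.get_params()
        clone = cp.IPCA(**params)
        assert clone.get_params() == params


class TestSipca:
    def test_keepx_bounds_nonzero_loadings(self, rng):
        X = rng.normal(size=(30, 12)) + np.outer(rng.uniform(-1, 1, 30),
                                                 rng.normal(size=12))
        model = cp.sipca(X, 2, keep_x=5)
        nnz = (np.abs(model.loadings_) > 0).sum(axis=0)
        assert np.all(nnz <= 5)

    def test_keepx_one_single_driving_trait(self, rng):
        X = rng.normal(size=(30, 6)) + np.outer(rng.uniform(-1, 1, 30),
                                                rng.normal(size=6))
        model = cp.sipca(X, 2, keep_x=1)
        nnz = (np.abs(model.loadings_) > 0).sum(axis=0)
        assert np.all(nnz == 1)

    def test_keepx_equal_trait_count_matches_ipca(self, rng):
        X = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
        dense = cp.ipca(X, 2, random_state=0)
        sparse = cp.sipca(X, 2, keep_x=6, random_state=0)
        np.testing.assert_allclose(np.abs(sparse.loadings_),
                                   np.abs(dense.loadings_), atol=1e-8)

    def test_keepx_beyond_traits_rejected(self, rng):
        with pytest.raises(cp.ValidationError):
            cp.sipca(rng.normal(size=(20, 4)), 2, keep_x=9)


class TestKurtosisSelection:
    @pytest.mark.parametrize("kurt,expected", [
        ((8.0, 6.5, 0.4, 0.3), 2),   # largest drop after the 2nd component
        ((5.0, 0.1), 1),
    ])
    def test_largest_relative_drop(self, kurt, expected):
        assert cp.select_components_by_kurtosis(kurt) == expected

    def test_all_equal_warns_and_keeps_one(self):
        with pytest.warns(UserWarning):
            assert cp.select_components_by_kurtosis((1.0, 1.0, 1.0)) == 1


class TestManova:
    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(23)
        ps = []
        for _ in range(200):
            scores = rng.normal(size=(12, 2))
            ps.append(cp.manova_components(scores, rng.normal(size=12)).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_strong_linear_relation_detected(self, rng):
        a = np.linspace(0, 1, 15)
        scores = np.c_[2 * a, -a] + 1e-4 * rng.normal(size=(15, 2))
        res = cp.manova_components(scores, a)
        assert res.statistic < 1e-4
        assert res.p < 1e-6

    def test_single_component_reduces_to_univariate_f(self, rng):
        a = np.linspace(0, 1, 12)
        y = 0.8 * a + rng.normal(scale=0.2, size=12)
        res = cp.manova_components(y[:, None], a)
        slope = sps.linregress(a, y)
        assert res.f_approx == pytest.approx(slope.rvalue ** 2 /
                                             (1 - slope.rvalue ** 2) * 10)
        assert res.p == pytest.approx(slope.pvalue)
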