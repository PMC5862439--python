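import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from rohselect.association import (
    _reml_loglik,
    analysis1_logistic,
    analysis2_lmm,
    bin_roh_matrix,
    cohort_correlations,
    filter_uninformative_bins,
    group_mean_length_change,
    make_bins,
    reml_fit,
)
from rohselect.io import ChromSizes, load_chrom_sizes


class TestMakeBins:
    def test_truncated_final_bin(self):
        bins = make_bins(ChromSizes({"c": 25_000_000}))
        assert bins[["start", "end"]].values.tolist() == [
            [1, 10_000_000],
            [10_000_001, 20_000_000],
            [20_000_001, 25_000_000],
        ]

    def test_bundled_autosomes_bin_count(self):
        bins = make_bins(load_chrom_sizes("umd3.1_autosomes"))
        assert len(bins) == 269

    def test_exact_fit_single_bin(self):
        bins = make_bins(ChromSizes({"c": 10_000_000}))
        assert len(bins) == 1 and bins.iloc[0]["end"] == 10_000_000

    def test_bins_tile_each_chromosome(self):
        sizes = ChromSizes({"a": 37_000_001, "b": 9_999_999})
        bins = make_bins(sizes)
        for chrom, length in sizes.items():
            sub = bins[bins["chrom"] == chrom]
            assert len(sub) == int(np.ceil(length / 10_000_000))
            assert (sub["end"] - sub["start"] + 1).sum() == length
        assert len(bins) == sum(int(np.ceil(v / 1e7)) for v in sizes.sizes.values())

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            make_bins(ChromSizes({"c": 5}), width=0)


class TestBinMatrix:
    bins = make_bins(ChromSizes({"1": 25_000_000}))

    def test_boundary_spanning_segment_split(self):
        seg = pd.DataFrame(
            {"sample_id": ["a"], "chrom": ["1"], "start": [9_500_001], "end": [10_600_000]}
        )
        mat = bin_roh_matrix(seg, self.bins, ["a"])
        assert mat.iloc[0, 0] == 500_000
        assert mat.iloc[0, 1] == 600_000

    def test_empty_sample_row_zero(self):
        seg = pd.DataFrame(
            {"sample_id": ["a"], "chrom": ["1"], "start": [1], "end": [100]}
        )
        mat = bin_roh_matrix(seg, self.bins, ["a", "b"])
        assert (mat.loc["b"] == 0).all()

    def test_exact_bin_coverage(self):
        seg = pd.DataFrame(
            {"sample_id": ["a"], "chrom": ["1"], "start": [10_000_001], "end": [20_000_000]}
        )
        mat = bin_roh_matrix(seg, self.bins, ["a"])
        assert mat.iloc[0, 1] == 10_000_000

    def test_unknown_chromosome_rejected(self):
        seg = pd.DataFrame({"sample_id": ["a"], "chrom": ["Z"], "start": [1], "end": [2]})
        with pytest.raises(ValueError):
            bin_roh_matrix(seg, self.bins, ["a"])


class TestUninformativeBins:
    def test_filtering_rules(self):
        mat = pd.DataFrame(
            {
                "allzero": [0, 0, 0],
                "mixed": [0, 0, 5_000],
                "allfull": [10_000_000] * 3,
            },
            index=["a", "b", "c"],
        )
        out = filter_uninformative_bins(mat)
        assert list(out.columns) == ["mixed"]

    def test_all_removed_rejected(self):
        mat = pd.DataFrame({"x": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            filter_uninformative_bins(mat)


class TestAnalysis1:
    @staticmethod
    def _mat(status, ids):
        return pd.DataFrame({"bin": np.asarray(status) * 1_000}, index=ids)

    def test_null_design_flat(self):
        ids = [f"s{i}" for i in range(40)]
        kpn = pd.Series(np.arange(40.0), index=ids)
        status = np.tile([0, 1], 20)  # independent of KPN by construction
        res = analysis1_logistic(self._mat(status, ids), kpn)
        assert abs(res["coefficient"].iloc[0]) < 0.05
        assert res["p_value"].iloc[0] > 0.5

    def test_matches_direct_likelihood_maximization(self, rng):
        """Slope/intercept must maximize the exact Bernoulli likelihood:
        compare against Nelder-Mead on the analytic log-likelihood."""
        ids = [f"s{i}" for i in range(12)]
        kpn = pd.Series(np.arange(1.0, 13.0), index=ids)
        status = np.array([0, 0, 1, 0, 1, 0, 1, 1, 0, 1, 1, 1])
        res = analysis1_logistic(self._mat(status, ids), kpn)

        def nll(theta):
            eta = theta[0] + theta[1] * kpn.to_numpy()
            return -np.sum(status * eta - np.log1p(np.exp(eta)))

        opt = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12})
        assert res["coefficient"].iloc[0] == pytest.approx(opt.x[1], abs=1e-4)

    def test_constant_status_flagged(self):
        ids = ["a", "b", "c"]
        res = analysis1_logistic(self._mat([1, 1, 1], ids), pd.Series([1.0, 2.0, 3.0], index=ids))
        assert not res["converged"].iloc[0]

    def test_separation_flagged(self):
        ids = [f"s{i}" for i in range(10)]
        kpn = pd.Series(np.arange(10.0), index=ids)
        status = (np.arange(10) >= 5).astype(int)  # perfectly separated
        res = analysis1_logistic(self._mat(status, ids), kpn)
        assert not res["converged"].iloc[0]

    def test_slope_scales_with_affine_kpn_recoding(self):
        ids = [f"s{i}" for i in range(30)]
        rng = np.random.default_rng(3)
        kpn = pd.Series(np.arange(30.0), index=ids)
        status = (rng.random(30) < 1 / (1 + np.exp(-(kpn - 15) / 5))).astype(int)
        mat = self._mat(status, ids)
        res1 = analysis1_logistic(mat, kpn)
        res2 = analysis1_logistic(mat, 10 * kpn + 7)
        assert res1["coefficient"].iloc[0] == pytest.approx(
            10 * res2["coefficient"].iloc[0], rel=1e-4
        )


def random_grm(rng, n, m=400):
    Z = rng.integers(0, 3, size=(n, m)).astype(float)
    Z -= Z.mean(axis=0)
    G = Z @ Z.T / Z.var(axis=0).sum()
    return (G + G.T) / 2


class TestREML:
    def test_optimum_matches_dense_grid(self, rng):
        for _ in range(3):
            n = 20
            G = random_grm(rng, n, 60)
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
            y = X @ [2.0, 1.0] + L @ rng.normal(size=n) + rng.normal(size=n)
            fit = reml_fit(y, X, G)
            d, U = np.linalg.eigh(G)
            d = np.clip(d, 0.0, None)
            yt, xt = U.T @ y, U.T @ X
            grid = np.linspace(np.log(1e-8), np.log(1e8), 15_000)
            grid_max = max(_reml_loglik(g, d, yt, xt) for g in grid)
            assert fit.loglik >= grid_max - 1e-3

    def test_collapse_to_ols_when_no_genetic_variance(self, rng):
        import statsmodels.api as sm

        n = 60
        G = random_grm(rng, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + rng.normal(size=n)  # iid: sigma_g should hit 0
        fit = reml_fit(y, X, G)
        ols = sm.OLS(y, X).fit()
        if fit.sigma_g2 == 0.0:
            assert np.allclose(fit.beta, ols.params, atol=1e-6)
            wald_ols = stats.chi2.sf((ols.params / ols.bse) ** 2, 1)
            assert np.allclose(fit.wald_p, wald_ols, atol=1e-6)
        else:  # tiny positive estimate; betas still near OLS
            assert np.allclose(fit.beta, ols.params, atol=1e-3)

    def test_variance_components_recovered(self):
        """Equal genetic and residual variances on a family-structured GRM:
        both components recovered within 25% median relative error."""
        from conftest import family_structured_grm

        _, G = family_structured_grm()
        n = G.shape[0]
        L = np.linalg.cholesky(G + 1e-6 * np.eye(n))
        rels = []
        for seed in range(20):
            r = np.random.default_rng(500 + seed)
            y = 5 + L @ r.normal(size=n) + r.normal(size=n)
            fit = reml_fit(y, np.ones((n, 1)), G)
            rels.append(abs(fit.sigma_g2 - 1.0))
        assert np.median(rels) < 0.25

    def test_rank_deficient_design_rejected(self, rng):
        n = 10
        G = random_grm(rng, n)
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            reml_fit(rng.normal(size=n), X, G)

    def test_asymmetric_grm_rejected(self, rng):
        n = 6
        G = rng.normal(size=(n, n))
        with pytest.raises(ValueError, match="symmetric"):
            reml_fit(rng.normal(size=n), np.ones((n, 1)), G)


class TestAnalysis2:
    def test_null_coefficient_near_zero(self, rng):
        n = 80
        ids = [f"s{i}" for i in range(n)]
        G = random_grm(rng, n)
        lengths = pd.DataFrame({"b1": rng.exponential(5e5, n)}, index=ids)
        weights = pd.Series(340 + rng.normal(0, 15, n), index=ids)
        fac = pd.Series(rng.choice(["F1", "F2"], n), index=ids)
        res = analysis2_lmm(lengths, weights, fac, ids, G)
        assert res["p_value"].iloc[0] > 0.01 or abs(res["coefficient"].iloc[0]) < 1e-4

    def test_known_negative_effect_recovered(self, rng):
        n = 100
        ids = [f"s{i}" for i in range(n)]
        G = random_grm(rng, n)
        lengths = pd.DataFrame({"b1": rng.exponential(8e5, n) * (rng.random(n) < 0.6)},
                               index=ids)
        weights = pd.Series(340 - 2e-5 * lengths["b1"] + rng.normal(0, 5, n), index=ids)
        fac = pd.Series(["F1"] * n, index=ids)  # single level: dummies dropped
        res = analysis2_lmm(lengths, weights, fac, ids, G)
        assert res["coefficient"].iloc[0] < 0
        assert res["coefficient"].iloc[0] == pytest.approx(-2e-5, rel=0.5)

    def test_missing_weights_excluded(self, rng):
        n = 30
        ids = [f"s{i}" for i in range(n)]
        G = random_grm(rng, n)
        lengths = pd.DataFrame({"b1": rng.exponential(5e5, n)}, index=ids)
        w = 340 + rng.normal(0, 10, n)
        weights = pd.Series(w, index=ids)
        weights.iloc[:5] = np.nan
        fac = pd.Series(rng.choice(["F1", "F2"], n), index=ids)
        res = analysis2_lmm(lengths, weights, fac, ids, G)
        assert res["converged"].iloc[0]


class TestGroupChangeAndCorrelations:
    def test_group_change_arithmetic(self):
        mat = pd.DataFrame({"b": [1_000_000.0, 1_000_000.0, 1_500_000.0, 1_500_000.0]},
                           index=["a", "b", "c", "d"])
        kpn = pd.Series([1, 2, 3, 4], index=mat.index)
        out = group_mean_length_change(mat, kpn, cutoff=2)
        assert out["mean_change_bp"].iloc[0] == pytest.approx(500_000)

    def test_identical_groups_zero_change(self):
        mat = pd.DataFrame({"b": [5.0, 5.0]}, index=["a", "b"])
        out = group_mean_length_change(mat, pd.Series([1, 3], index=mat.index), cutoff=2)
        assert out["mean_change_bp"].iloc[0] == 0

    def test_empty_group_rejected(self):
        mat = pd.DataFrame({"b": [5.0, 6.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            group_mean_length_change(mat, pd.Series([1, 2], index=mat.index), cutoff=10)

    def test_self_correlation_perfect(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        out = cohort_correlations(v, v, v).set_index(["var_a", "var_b"])
        assert out.loc[("kpn", "f_roh"), "rho"] == pytest.approx(1.0)

    def test_tie_corrected_rank_formula(self):
        froh = pd.Series([0.1, 0.1, 0.3, 0.4], index=list("abcd"))
        kpn = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        w = pd.Series([300.0, 310.0, 320.0, 330.0], index=list("abcd"))
        out = cohort_correlations(froh, kpn, w).set_index(["var_a", "var_b"])
        rho, p = stats.spearmanr(kpn, froh)
        assert out.loc[("kpn", "f_roh"), "rho"] == pytest.approx(rho)

    def test_constant_vector_flagged(self):
        froh = pd.Series([0.1, 0.1, 0.1], index=list("abc"))
        kpn = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        w = pd.Series([300.0, 310.0, 320.0], index=list("abc"))
        out = cohort_correlations(froh, kpn, w)
        assert out.set_index(["var_a", "var_b"]).loc[("kpn", "f_roh"), "degenerate"]
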