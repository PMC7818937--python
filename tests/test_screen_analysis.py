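"""Normalization, guide ranking, α-RRA scoring, permutation p, and BH FDR."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from circscreen import (
    AnalysisConfig,
    ScreenCountMatrix,
    alpha_rra_gene_score,
    analyze_screen,
    bh_adjust,
    call_hits,
    guide_lfc,
    median_ratio_normalize,
    permutation_pvalues,
    sample_correlation,
)


def _df(arr, samples):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=samples)


class TestNormalization:
    def test_proportional_samples(self):
        counts = _df([[10, 20], [30, 60], [5, 10]], ["a", "b"])
        norm, sf = median_ratio_normalize(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        pd.testing.assert_frame_equal(norm["a"].to_frame("x"), norm["b"].to_frame("x"))

    def test_identical_samples_equal_factors(self):
        counts = _df([[10, 10, 10], [3, 3, 3]], ["a", "b", "c"])
        _, sf = median_ratio_normalize(counts)
        assert sf.nunique() == 1

    def test_matches_direct_median_of_ratios(self):
        rng = np.random.default_rng(0)
        counts = _df(rng.integers(1, 1000, size=(200, 4)), list("abcd"))
        _, sf = median_ratio_normalize(counts)
        mat = counts.to_numpy(float)
        geo = np.exp(np.log(mat).mean(axis=1))
        expected = np.median(mat / geo[:, None], axis=0)
        np.testing.assert_allclose(sf.to_numpy(), expected)

    def test_fallback_total_count_scaling(self):
        counts = _df([[0, 5], [5, 0]], ["a", "b"])
        with pytest.warns(UserWarning, match="total-count"):
            _, sf = median_ratio_normalize(counts)
        assert sf["a"] == pytest.approx(1.0) and sf["b"] == pytest.approx(1.0)


class TestGuideLfc:
    def test_equal_groups_zero_lfc(self):
        norm = _df([[4, 4], [8, 8]], ["c", "t"])
        out = guide_lfc(norm, ["c"], ["t"], pseudocount=1)
        assert (out["lfc"] == 0).all()

    def test_fourfold_is_two(self):
        norm = _df([[10, 40]], ["c", "t"])
        out = guide_lfc(norm, ["c"], ["t"], pseudocount=0)
        assert out["lfc"].iloc[0] == pytest.approx(2.0)

    def test_ranks_match_independent_sort(self):
        rng = np.random.default_rng(5)
        norm = _df(rng.integers(0, 500, size=(50, 2)), ["c", "t"])
        out = guide_lfc(norm, ["c"], ["t"])
        order = out.sort_values(["lfc"], kind="mergesort").index
        assert list(out.loc[order, "rank_neg"]) == list(range(1, 51))
        assert sorted(out["rank_neg"]) == list(range(1, 51))
        np.testing.assert_allclose(out["r_neg"], out["rank_neg"] / 50)
        # positive ranks reverse the ordering up to tie-breaks
        assert out.loc[out["lfc"].idxmax(), "rank_pos"] == 1

    def test_group_validation(self):
        norm = _df([[1, 2]], ["c", "t"])
        with pytest.raises(ValueError):
            guide_lfc(norm, [], ["t"])
        with pytest.raises(ValueError):
            guide_lfc(norm, ["c"], ["c"])


class TestAlphaRra:
    def test_single_guide_uniform_order_statistic(self):
        assert alpha_rra_gene_score([0.1], alpha=0.25) == pytest.approx(0.1)

    def test_two_guides_full_alpha(self):
        # rho1 = 1-(1-0.1)^2 = 0.19, rho2 = 0.2^2 = 0.04 -> min = 0.04
        assert alpha_rra_gene_score([0.1, 0.2], alpha=1.0) == pytest.approx(0.04)

    def test_alpha_cutoff_restricts_to_first(self):
        assert alpha_rra_gene_score([0.1, 0.2], alpha=0.15) == pytest.approx(0.19)

    def test_no_guide_in_top_fraction_scores_one(self):
        assert alpha_rra_gene_score([0.5, 0.9], alpha=0.25) == 1.0

    @given(st.integers(1, 10), st.integers(1, 10), st.floats(0.01, 0.99))
    def test_beta_binomial_identity(self, n, k, r):
        if k > n:
            return
        beta_tail = stats.beta.cdf(r, k, n - k + 1)
        binom_tail = stats.binom.sf(k - 1, n, r)
        assert beta_tail == pytest.approx(binom_tail, abs=1e-12)

    @given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=8),
           st.integers(0, 7), st.floats(0.05, 1.0))
    def test_improving_a_rank_never_increases_rho(self, ranks, which, alpha):
        ranks = sorted(ranks)
        rho = alpha_rra_gene_score(ranks, alpha)
        which = min(which, len(ranks) - 1)
        improved = list(ranks)
        improved[which] = improved[which] / 2
        assert alpha_rra_gene_score(improved, alpha) <= rho + 1e-12


class TestPermutationP:
    def test_worst_score_gives_p_one(self):
        p = permutation_pvalues({"g": (1.0, 2)}, n_guides_total=10, alpha=0.25,
                                n_permutations=200, seed=0)
        assert p["g"] == pytest.approx(1.0)

    def test_single_guide_best_rank(self):
        # one guide at rank 1 of 100: null P(rho_null <= rho_obs) = 1/100
        rho = alpha_rra_gene_score([1 / 100], alpha=0.25)
        n_perm = 10_000
        p = permutation_pvalues({"g": (rho, 1)}, 100, 0.25, n_perm, seed=1)["g"]
        sigma = np.sqrt(0.01 * 0.99 / n_perm)
        assert abs(p - 0.01) < 3 * sigma + 2 / n_perm

    def test_matches_exhaustive_enumeration_n5(self):
        """Monte-Carlo p agrees with enumeration over all C(5,2) rank subsets."""
        N, n, alpha = 5, 2, 1.0
        null_exact = [
            alpha_rra_gene_score([a / N, b / N], alpha)
            for a, b in combinations(range(1, N + 1), 2)
        ]
        n_perm = 20_000
        for obs_ranks in ([1, 2], [2, 4], [4, 5]):
            rho = alpha_rra_gene_score([r / N for r in obs_ranks], alpha)
            exact = sum(x <= rho + 1e-12 for x in null_exact) / len(null_exact)
            p = permutation_pvalues({"g": (rho, n)}, N, alpha, n_perm, seed=2)["g"]
            sigma = np.sqrt(exact * (1 - exact) / n_perm)
            assert abs(p - exact) < 3 * sigma + 2 / n_perm

    def test_deterministic_given_seed(self):
        args = ({"g": (0.05, 3)}, 50, 0.25, 500)
        assert permutation_pvalues(*args, seed=7).equals(
            permutation_pvalues(*args, seed=7)
        )

    def test_null_pvalues_uniform(self):
        """Under a global null, permutation p-values are ~Uniform(0,1) at
        alpha=1; with an alpha cutoff they stay valid (sub-uniform), since
        genes with no guide in the top fraction collect at p=1."""
        rng = np.random.default_rng(3)
        n_genes, n, N = 2000, 2, 4000
        ranks = rng.permutation(N) + 1
        per_gene = [ranks[2 * g : 2 * g + 2] / N for g in range(n_genes)]
        scores_full = {f"g{g}": (alpha_rra_gene_score(rr, 1.0), n)
                       for g, rr in enumerate(per_gene)}
        p = permutation_pvalues(scores_full, N, 1.0, n_permutations=2000, seed=4)
        ks = stats.kstest(p.to_numpy(), "uniform")
        assert ks.statistic < 0.05
        scores_cut = {f"g{g}": (alpha_rra_gene_score(rr, 0.25), n)
                      for g, rr in enumerate(per_gene)}
        p_cut = permutation_pvalues(scores_cut, N, 0.25, n_permutations=2000,
                                    seed=4).to_numpy()
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            frac = (p_cut <= t).mean()
            # error terms: per-gene sampling + shared-null Monte-Carlo shift
            # (null draws are reused across genes, so their error is correlated)
            tol = 3 * np.sqrt(t * (1 - t) / n_genes) + 3 * np.sqrt(t * (1 - t) / 2000)
            assert frac <= t + tol + 1e-3


class TestBh:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_monotone_and_at_least_raw_over_rank(self, ps):
        fdr = bh_adjust(ps)
        order = np.argsort(ps)
        ranked = fdr[order]
        assert (np.diff(ranked) >= -1e-12).all()
        assert (fdr >= np.asarray(ps) - 1e-12).all()
        assert (fdr <= 1.0 + 1e-12).all()


class TestHitsAndPipeline:
    def _toy_matrix(self):
        rng = np.random.default_rng(8)
        n = 60
        counts = pd.DataFrame(
            rng.integers(100, 1000, size=(n, 4)),
            index=[f"sg{i}" for i in range(n)],
            columns=["D0_r1", "D0_r2", "D14_r1", "D14_r2"],
        )
        counts.iloc[:5, 2:] //= 20  # one strongly depleted gene
        genes = pd.Series([f"G{i // 5}" for i in range(n)], index=counts.index)
        return ScreenCountMatrix(counts=counts, guide_gene=genes)

    def test_empty_results_empty_hits(self):
        cols = ["n_guides", "rra_score_neg", "p_neg", "fdr_neg",
                "rra_score_pos", "p_pos", "fdr_pos"]
        empty = pd.DataFrame(columns=cols)
        assert call_hits(empty, 0.25).empty

    def test_hit_sets_nested_across_thresholds(self):
        m = self._toy_matrix()
        res, _ = analyze_screen(m, ["D0_r1", "D0_r2"], ["D14_r1", "D14_r2"],
                                AnalysisConfig(n_permutations=2000, seed=1))
        strict = set(call_hits(res, 0.1).index)
        loose = set(call_hits(res, 0.25).index)
        assert strict <= loose

    def test_depleted_gene_is_top_hit(self):
        m = self._toy_matrix()
        res, guide_stats = analyze_screen(m, ["D0_r1", "D0_r2"], ["D14_r1", "D14_r2"],
                                          AnalysisConfig(n_permutations=2000, seed=1))
        assert res.index[0] == "G0"
        assert res.loc["G0", "fdr_neg"] < 0.25
        assert set(guide_stats.columns) >= {"lfc", "rank_neg", "gene"}

    def test_count_table_roundtrip(self, tmp_path):
        m = self._toy_matrix()
        p = tmp_path / "counts.tsv"
        m.to_tsv(p)
        back = ScreenCountMatrix.from_tsv(p)
        pd.testing.assert_frame_equal(back.counts.rename_axis(None), m.counts)
        pd.testing.assert_series_equal(back.guide_gene, m.guide_gene,
                                       check_names=False)

    def test_sample_correlation_shape(self):
        m = self._toy_matrix()
        norm, _ = median_ratio_normalize(m.counts)
        corr = sample_correlation(norm)
        assert corr.shape == (4, 4)
        np.testing.assert_allclose(np.diag(corr), 1.0)
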