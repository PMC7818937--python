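"""Pooled-screen scoring: normalization, guide ranking, α-RRA, permutation FDR.

The pipeline scores depletion (negative selection) or enrichment (positive
selection) of genes — circRNAs, positive-control essential genes, and
non-targeting controls — from a guide x sample count matrix:

1. median-of-ratios size-factor normalization across samples;
2. per-guide log2 fold change (LFC) of mean treatment vs mean control
   normalized counts, with a pseudocount;
3. guides ranked by LFC (ascending for negative selection); each gene's
   guides are summarized by the α-RRA score ρ — the minimum over its
   eligible guides (normalized rank r <= α) of the Beta(k, n-k+1) order
   statistic probability P(Beta <= r(k)), i.e. the probability that the
   k-th best of n uniformly placed guides would rank at least that high;
4. permutation p-values: ρ is compared against null scores from genes of the
   same size with ranks drawn uniformly without replacement;
5. Benjamini-Hochberg adjustment of permutation p-values to FDR.

ρ ∈ (0, 1], smaller = stronger selection. A gene with no guide in the top-α
fraction scores ρ = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnalysisConfig:
    """Tunables for screen scoring.

    ``alpha`` is the top fraction of the ranked guide list eligible for
    α-RRA (0.25); ``n_permutations`` controls p-value resolution (10^4);
    ``pseudocount`` stabilizes LFCs of low-count guides (1 normalized read).
    """

    alpha: float = 0.25
    n_permutations: int = 10_000
    pseudocount: float = 1.0
    seed: int = 0
    fdr_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class ScreenCountMatrix:
    """Guide x sample integer counts with a many-to-one guide -> gene map."""

    counts: pd.DataFrame  # index: guide ids; columns: sample ids
    guide_gene: pd.Series  # index: guide ids; values: gene ids
    conditions: dict[str, str] = field(default_factory=dict)  # sample -> label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.guide_gene.index):
            self.guide_gene = self.guide_gene.reindex(self.counts.index)
            if self.guide_gene.isna().any():
                raise ValueError("every guide must map to exactly one gene")

    @classmethod
    def from_tsv(cls, path: str | Path, conditions: Mapping[str, str] | None = None
                 ) -> "ScreenCountMatrix":
        """Read a MAGeCK-dialect count table (sgRNA, gene, one column per sample)."""
        df = pd.read_csv(path, sep="\t")
        guide_col, gene_col = df.columns[:2]
        df = df.set_index(guide_col)
        return cls(
            counts=df.drop(columns=[gene_col]),
            guide_gene=df[gene_col],
            conditions=dict(conditions or {}),
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene", self.guide_gene)
        out.index.name = "sgRNA"
        out.to_csv(path, sep="\t")


def median_ratio_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios (size-factor) normalization across samples.

    Per sample, the size factor is the median over guides (with positive
    counts in every sample) of count / geometric-mean(count across samples);
    normalized counts are raw counts divided by the size factor. If no guide
    is positive everywhere, falls back to total-count scaling with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        log_geo = np.log(mat[all_pos]).mean(axis=1, keepdims=True)
        ratios = mat[all_pos] / np.exp(log_geo)
        size_factors = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no guide has positive counts in all samples; falling back to "
            "total-count scaling",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        size_factors = totals / totals.mean()
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    return counts / sf, sf


def guide_lfc(
    normalized: pd.DataFrame,
    control_samples: Sequence[str],
    treatment_samples: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-guide log2 fold change of treatment vs control normalized counts.

    Returns a DataFrame indexed by guide with columns ``lfc``, and for each
    selection direction the rank (1..N, ascending LFC for negative selection,
    descending for positive) and normalized rank r = rank / N. Ties are
    broken by guide id for determinism.
    """
    control_samples = list(control_samples)
    treatment_samples = list(treatment_samples)
    if not control_samples or not treatment_samples:
        raise ValueError("both sample groups must be non-empty")
    if set(control_samples) & set(treatment_samples):
        raise ValueError("control and treatment sample groups must be disjoint")
    ctrl = normalized[control_samples].mean(axis=1)
    trt = normalized[treatment_samples].mean(axis=1)
    lfc = np.log2((trt + pseudocount) / (ctrl + pseudocount))
    df = pd.DataFrame({"lfc": lfc})
    df = df.loc[sorted(df.index)]  # stable sort below then breaks ties by guide id
    n = len(df)
    order_neg = df.sort_values("lfc", kind="mergesort").index
    df["rank_neg"] = pd.Series(np.arange(1, n + 1), index=order_neg)
    order_pos = df.sort_values("lfc", ascending=False, kind="mergesort").index
    df["rank_pos"] = pd.Series(np.arange(1, n + 1), index=order_pos)
    df["r_neg"] = df["rank_neg"] / n
    df["r_pos"] = df["rank_pos"] / n
    return df


def alpha_rra_gene_score(ranks_r: Sequence[float], alpha: float) -> float:
    """α-RRA score ρ for one gene from its guides' normalized ranks.

    With sorted normalized ranks r(1) <= ... <= r(n), ρ is the minimum over
    guides with r(k) <= α of P(Beta(k, n-k+1) <= r(k)) — equivalently the
    binomial tail P(Binomial(n, r(k)) >= k). If no guide falls in the top-α
    fraction, ρ = 1.
    """
    r = np.sort(np.asarray(list(ranks_r), dtype=float))
    if r.size == 0:
        raise ValueError("gene must have at least one guide")
    n = r.size
    k = np.arange(1, n + 1)
    eligible = r <= alpha
    if not eligible.any():
        return 1.0
    probs = stats.beta.cdf(r[eligible], k[eligible], n - k[eligible] + 1)
    return float(probs.min())


def _null_scores(
    n: int, N: int, alpha: float, order: np.ndarray
) -> np.ndarray:
    """α-RRA scores of permuted genes of size ``n`` given pre-drawn rank orders."""
    idx = np.sort(order[:, :n], axis=1)  # ranks-1 of the sampled guides
    r = (idx + 1) / N
    k = np.arange(1, n + 1)
    probs = stats.beta.cdf(r, k, n - k + 1)
    probs = np.where(r <= alpha, probs, np.inf)
    rho = probs.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def permutation_pvalues(
    gene_scores: Mapping[str, tuple[float, int]],
    n_guides_total: int,
    alpha: float,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.Series:
    """Permutation p-values for observed α-RRA scores.

    ``gene_scores`` maps gene -> (ρ, n_guides). For each gene size n, null
    scores are computed from genes of n guides whose ranks are drawn
    uniformly without replacement from 1..N; the p-value is
    ``(1 + #{null ρ <= observed ρ}) / (1 + n_permutations)``. Deterministic
    given ``seed``; null draws are shared across genes of equal size.
    """
    rng = np.random.default_rng(seed)
    keys = rng.random((n_permutations, n_guides_total))
    order = np.argsort(keys, axis=1)
    null_cache: dict[int, np.ndarray] = {}
    out = {}
    for gene, (rho, n) in gene_scores.items():
        if n not in null_cache:
            null_cache[n] = _null_scores(n, n_guides_total, alpha, order)
        null = null_cache[n]
        out[gene] = (1.0 + float((null <= rho).sum())) / (1.0 + n_permutations)
    return pd.Series(out, name="p")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (capped at 1, order-preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def score_genes(
    guide_stats: pd.DataFrame,
    guide_gene: pd.Series,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Aggregate guide ranks to per-gene α-RRA results in both directions.

    Returns a DataFrame indexed by gene with columns ``n_guides``,
    ``rra_score_neg``, ``p_neg``, ``fdr_neg`` and the ``_pos`` equivalents.
    """
    genes = guide_gene.loc[guide_stats.index]
    N = len(guide_stats)
    results: dict[str, dict] = {}
    scores_neg: dict[str, tuple[float, int]] = {}
    scores_pos: dict[str, tuple[float, int]] = {}
    for gene, grp in guide_stats.groupby(genes):
        n = len(grp)
        rho_neg = alpha_rra_gene_score(grp["r_neg"], config.alpha)
        rho_pos = alpha_rra_gene_score(grp["r_pos"], config.alpha)
        scores_neg[gene] = (rho_neg, n)
        scores_pos[gene] = (rho_pos, n)
        results[gene] = {"n_guides": n, "rra_score_neg": rho_neg, "rra_score_pos": rho_pos}
    p_neg = permutation_pvalues(
        scores_neg, N, config.alpha, config.n_permutations, config.seed
    )
    p_pos = permutation_pvalues(
        scores_pos, N, config.alpha, config.n_permutations, config.seed + 1
    )
    df = pd.DataFrame.from_dict(results, orient="index")
    df.index.name = "gene"
    df["p_neg"] = p_neg
    df["p_pos"] = p_pos
    df["fdr_neg"] = bh_adjust(df["p_neg"])
    df["fdr_pos"] = bh_adjust(df["p_pos"])
    return df.sort_values("rra_score_neg")


def analyze_screen(
    matrix: ScreenCountMatrix,
    control_samples: Sequence[str],
    treatment_samples: Sequence[str],
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scoring pipeline: normalize, rank guides, aggregate genes.

    Returns (gene_results, guide_stats)."""
    config = config or AnalysisConfig()
    normalized, _ = median_ratio_normalize(matrix.counts)
    stats_df = guide_lfc(
        normalized, control_samples, treatment_samples, config.pseudocount
    )
    gene_results = score_genes(stats_df, matrix.guide_gene, config)
    stats_df = stats_df.join(matrix.guide_gene.rename("gene"))
    return gene_results, stats_df


def call_hits(
    results: pd.DataFrame, fdr_threshold: float, direction: str = "negative"
) -> pd.DataFrame:
    """Genes selected in one direction at an FDR threshold, best ρ first."""
    if direction not in {"negative", "positive"}:
        raise ValueError("direction must be 'negative' or 'positive'")
    suffix = "neg" if direction == "negative" else "pos"
    hits = results[results[f"fdr_{suffix}"] < fdr_threshold]
    return hits.sort_values(f"rra_score_{suffix}")


def sample_correlation(normalized: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of log2(normalized count + 1) between samples."""
    return np.log2(normalized + 1).corr(method="pearson")
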