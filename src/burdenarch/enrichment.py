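"""Gene-set enrichment with matched backgrounds and gene tiering.

Two complementary enrichment tests are provided. The hypergeometric
test asks whether a fixed list of top-ranked genes over-represents a
set; the one-sided Wilcoxon rank-sum test asks whether the set's full
P-value distribution is shifted below that of a background of genes
matched on variant count and combined variant frequency (so that a
set's enrichment cannot be an artifact of its genes simply being more
testable). Tiering then grades genes from exome-wide significant
(tier 1) down to nominally significant members of enriched metabolic
sets (tier 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "BackgroundMatch",
    "TierAssignment",
    "hypergeometric_enrichment",
    "match_background",
    "rank_sum_enrichment",
    "cluster_combined_test",
    "filter_metabolic_sets",
    "bonferroni_threshold",
    "bh_qvalues",
    "classify_tiers",
    "DEFAULT_METABOLIC_KEYWORDS",
]

log = logging.getLogger(__name__)

DEFAULT_METABOLIC_KEYWORDS = (
    "diabetes", "hyperglycemia", "overweight", "waist", "insulin",
    "c-peptide",
)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigurationError(f"gene set '{self.name}' is empty")


@dataclass
class EnrichmentResult:
    name: str
    method: str  # hypergeometric | rank-sum | cluster-combined
    fold: float
    p: float
    contributing_genes: list[str] = field(default_factory=list)
    background: str = ""


@dataclass
class BackgroundMatch:
    genes: list[str]
    description: str


@dataclass
class TierAssignment:
    gene: str
    tier: int | None
    justification: str


def hypergeometric_enrichment(top_genes: list[str], gene_set: GeneSet,
                              universe: list[str]) -> EnrichmentResult:
    """One-sided hypergeometric over-representation of a set among the
    top-ranked genes.

    ``fold = (overlap/|top|) / (|set ∩ universe|/|universe|)``.
    """
    uni = set(universe)
    if not uni:
        raise ConfigurationError("empty universe")
    top = set(top_genes) & uni
    members = gene_set.genes & uni
    if not members:
        raise ConfigurationError(
            f"gene set '{gene_set.name}' has no genes in the universe")
    overlap = top & members
    k, n_top, n_set, n_uni = len(overlap), len(top), len(members), len(uni)
    p = float(stats.hypergeom.sf(k - 1, n_uni, n_set, n_top))
    fold = (k / n_top) / (n_set / n_uni) if n_top else 0.0
    return EnrichmentResult(gene_set.name, "hypergeometric", float(fold),
                            min(p, 1.0), sorted(overlap),
                            background=f"universe of {n_uni} genes")


def match_background(
    target_genes: list[str],
    gene_stats: pd.DataFrame,
    n_bins: int = 10,
    multiple: int = 10,
    rng: np.random.Generator | None = None,
) -> BackgroundMatch:
    """Background genes matched on variant count and combined MAF.

    Genes are binned into ``n_bins`` quantile bins on each of
    ``n_variants`` and ``combined_maf``; the background is all
    non-target genes sharing a (count, MAF) bin with at least one
    target, down-sampled (seeded) to ``multiple`` times the target
    size. A target bin with no candidates falls back to the nearest
    occupied bin (logged).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if not set(target_genes) <= set(gene_stats.index):
        missing = set(target_genes) - set(gene_stats.index)
        raise ConfigurationError(
            f"targets missing from gene stats: {sorted(missing)[:5]}")
    df = gene_stats.copy()

    def bin_of(series: pd.Series) -> np.ndarray:
        try:
            return pd.qcut(series.rank(method="first"), n_bins,
                           labels=False).to_numpy()
        except ValueError:
            return np.zeros(len(series), dtype=int)

    df["_b1"] = bin_of(df["n_variants"])
    df["_b2"] = bin_of(df["combined_maf"])
    is_target = df.index.isin(set(target_genes))
    target_bins = set(map(tuple, df.loc[is_target, ["_b1", "_b2"]]
                          .to_numpy()))
    cand_mask = ~is_target & [
        (b1, b2) in target_bins
        for b1, b2 in df[["_b1", "_b2"]].to_numpy()]
    candidates = df.index[np.asarray(cand_mask)].tolist()
    if not candidates:
        # nearest-bin fallback: take non-targets closest in bin space
        log.warning("no background candidates share a bin with the "
                    "targets; falling back to nearest bins")
        non_t = df[~is_target]
        if non_t.empty:
            raise ConfigurationError("no non-target genes available")
        dists = non_t.apply(
            lambda r: min(abs(r["_b1"] - b1) + abs(r["_b2"] - b2)
                          for b1, b2 in target_bins), axis=1)
        candidates = non_t.index[dists == dists.min()].tolist()
    size = min(len(candidates), multiple * len(set(target_genes)))
    chosen = sorted(rng.choice(sorted(candidates), size=size,
                               replace=False).tolist())
    return BackgroundMatch(
        chosen,
        f"{size} genes matched on {n_bins}x{n_bins} variant-count x "
        "combined-MAF bins")


def rank_sum_enrichment(
    gene_set: GeneSet,
    gene_pvalues: pd.Series,
    background: BackgroundMatch,
    nominal: float = 0.05,
    exclude: set[str] | None = None,
) -> EnrichmentResult:
    """One-sided Wilcoxon rank-sum test that the set's gene P-values are
    smaller than the matched background's.

    ``fold`` is the ratio of nominal-significance fractions
    (set vs background); it is reported as NaN when the background has
    no nominal hits (continuity guard). ``exclude`` supports leave-out
    re-testing: the named genes are dropped from the set before testing.
    """
    exclude = exclude or set()
    members = [g for g in gene_set.genes
               if g in gene_pvalues.index and g not in exclude]
    if len(members) < 2:
        raise ConfigurationError(
            f"set '{gene_set.name}': fewer than 2 genes with P-values")
    bg = [g for g in background.genes
          if g in gene_pvalues.index and g not in exclude
          and g not in gene_set.genes]
    if not bg:
        raise ConfigurationError("empty background")
    sp = gene_pvalues.loc[members].to_numpy(dtype=float)
    bp = gene_pvalues.loc[bg].to_numpy(dtype=float)
    stat = stats.mannwhitneyu(sp, bp, alternative="less")
    f_set = float((sp < nominal).mean())
    f_bg = float((bp < nominal).mean())
    fold = f_set / f_bg if f_bg > 0 else float("nan")
    contributing = sorted(g for g in members
                          if gene_pvalues.loc[g] < nominal)
    return EnrichmentResult(gene_set.name, "rank-sum", fold,
                            float(stat.pvalue), contributing,
                            background.description)


def cluster_combined_test(
    sets: list[GeneSet],
    gene_pvalues: pd.Series,
    gene_stats: pd.DataFrame,
    rng: np.random.Generator | None = None,
    nominal: float = 0.05,
    exclude: set[str] | None = None,
) -> EnrichmentResult:
    """Rank-sum enrichment of the deduplicated union of a cluster of
    sets, against a freshly matched background."""
    if not sets:
        raise ConfigurationError("empty cluster")
    union = frozenset().union(*(s.genes for s in sets))
    name = "+".join(s.name for s in sets)
    combined = GeneSet(name, union, source="cluster")
    targets = [g for g in union if g in gene_stats.index]
    if not targets:
        raise ConfigurationError("no cluster genes with statistics")
    bg = match_background(targets, gene_stats, rng=rng)
    res = rank_sum_enrichment(combined, gene_pvalues, bg, nominal, exclude)
    res.method = "cluster-combined"
    return res


def filter_metabolic_sets(
    sets: dict[str, list[str]] | list[GeneSet],
    keywords: tuple[str, ...] = DEFAULT_METABOLIC_KEYWORDS,
) -> list[str]:
    """Names of sets whose name contains any keyword (case-insensitive
    substring; underscores and hyphens are interchangeable)."""
    if not keywords:
        raise ConfigurationError("keyword list must be non-empty")
    names = (list(sets.keys()) if isinstance(sets, dict)
             else [s.name for s in sets])
    kws = {k.lower().replace("-", "_") for k in keywords}
    out = []
    for name in names:
        norm = name.lower().replace("-", "_")
        if any(k in norm for k in kws):
            out.append(name)
    return sorted(out)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    return alpha / n_tests


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0, 1)
    return q


def classify_tiers(
    gene_results: pd.DataFrame,
    known_lists: dict[str, set[str]] | None,
    enriched_sets: list[GeneSet],
    top_k: int = 50,
    exome_threshold: float = 2.5e-6,
    nominal: float = 0.05,
) -> list[TierAssignment]:
    """Four-tier gene classification from association and enrichment
    evidence.

    Tier 1: exome-wide significant corrected P.
    Tier 2: additionally, top-K genes that are in a monogenic-diabetes
        or causal-coding-variant list.
    Tier 3: additionally, top-K genes in at least two enriched metabolic
        sets.
    Tier 4: genes at nominal significance that are members of at least
        one enriched metabolic set.
    Each gene receives its smallest qualifying tier. ``gene_results``
    needs columns ``gene`` and ``corrected_p``.
    """
    import warnings

    df = gene_results.sort_values("corrected_p").reset_index(drop=True)
    top = set(df["gene"].head(top_k))
    known: set[str] = set()
    if known_lists:
        for role in ("monogenic_diabetes", "monogenic_omim", "causal_coding"):
            known |= set(known_lists.get(role, set()))
    elif known_lists is None:
        warnings.warn("known gene lists missing: tiers 2-3 skipped")
    membership: dict[str, int] = {}
    enriched_members: set[str] = set()
    for s in enriched_sets:
        for g in s.genes:
            membership[g] = membership.get(g, 0) + 1
            enriched_members.add(g)
    out: list[TierAssignment] = []
    for _, row in df.iterrows():
        g = row["gene"]
        p = row["corrected_p"]
        tier: int | None = None
        just = ""
        if p < exome_threshold:
            tier, just = 1, "exome-wide"
        elif known_lists is not None and g in top and g in known:
            tier, just = 2, "top-K+known"
        elif known_lists is not None and g in top and membership.get(g, 0) >= 2:
            tier, just = 3, "top-K+>=2-enriched-sets"
        elif p < nominal and g in enriched_members:
            tier, just = 4, "nominal-in-enriched-sets"
        out.append(TierAssignment(g, tier, just))
    return out
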