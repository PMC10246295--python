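"""Per-individual genetic contribution scores and phenotype coupling.

Each case receives a rare-variant score (sum of winner's-curse-corrected
log odds ratios over the rare-risk genes whose qualifying burden the
individual carries, one contribution per gene), a common-variant score
(dosage-weighted sum of common-variant log odds ratios), and a combined
score, their sum on the log scale. Carriers of pathogenic variants in a
monogenic-diabetes gene registry are flagged separately: a MODY-like
variant is a diagnosis-grade risk factor, not a score component. Samples
are then assigned to mutually exclusive risk bands (MODY > rare > common
> combined, at descending odds-ratio thresholds), and scores are
regressed on phenotypes to test whether the source of genetic risk
shapes clinical presentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import MaskDefinition, control_allele_freq
from .errors import ConfigurationError

__all__ = [
    "ScoreWeights",
    "mody_flag",
    "compute_scores",
    "assign_bands",
    "rare_fraction_trend",
    "phenotype_regression",
    "mody_group_comparison",
]

log = logging.getLogger(__name__)


@dataclass
class ScoreWeights:
    """Log-OR weights for the contribution scores.

    ``rare`` maps gene -> corrected log OR (scored once per sample at
    the carrier level); ``common`` maps variant id -> log OR (scored
    per allele). ``rare_mask`` names the mask whose qualifying variants
    define carriage for each rare gene (defaults to the loosest mask in
    the ladder).
    """

    rare: dict[str, float] = field(default_factory=dict)
    common: dict[str, float] = field(default_factory=dict)
    rare_mask: str | None = None

    def __post_init__(self) -> None:
        for d in (self.rare, self.common):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ConfigurationError(f"non-finite weight for {k}")


def mody_flag(dosages: np.ndarray, annotations: pd.DataFrame,
              registry: set[str]) -> np.ndarray:
    """Carrier flags: at least one pathogenic-flagged allele in a
    registry gene."""
    if registry is None:
        raise ConfigurationError("monogenic gene registry missing")
    ann = annotations.reset_index(drop=True)
    cols = np.where((ann["pathogenic_flag"].to_numpy() == 1)
                    & ann["gene"].isin(registry).to_numpy())[0]
    if cols.size == 0:
        return np.zeros(dosages.shape[0], dtype=bool)
    return (dosages[:, cols] > 0).any(axis=1)


def compute_scores(
    dosages: np.ndarray,
    annotations: pd.DataFrame,
    weights: ScoreWeights,
    sample_ids: list[str],
    is_case: np.ndarray | None = None,
    masks: MaskDefinition | None = None,
    mody_flags: np.ndarray | None = None,
    center_common: bool = True,
) -> pd.DataFrame:
    """Rare, common and combined contribution scores per sample.

    Rare weights count a gene once per sample (carrier of any
    qualifying variant under the scoring mask); common weights are
    multiplied by allele dosage and, by default, centered at the
    reference population's mean dosage (control allele frequency), so
    the common OR reads as risk relative to the population-average
    genotype rather than to a carrier of zero risk alleles. Samples
    carrying nothing score 0 (OR 1) on the rare side. Weights
    referencing absent units are logged and skipped.
    """
    ann = annotations.reset_index(drop=True)
    n = dosages.shape[0]
    masks = masks or MaskDefinition()
    mask_name = weights.rare_mask or masks.masks[-1].name
    if is_case is None:
        is_case = np.zeros(n, dtype=bool)
    ctrl_af = control_allele_freq(dosages, is_case)
    present = np.asarray((dosages > 0).any(axis=0))
    sets = masks.variant_sets(ann["category"].to_numpy(), ctrl_af, present)
    if mask_name not in sets:
        raise ConfigurationError(f"unknown scoring mask '{mask_name}'")
    qualifying = sets[mask_name]
    gene_arr = ann["gene"].to_numpy()

    rare = np.zeros(n)
    for gene, w in sorted(weights.rare.items()):
        cols = np.where((gene_arr == gene) & qualifying)[0]
        if cols.size == 0:
            log.warning("rare weight for %s: no qualifying variants; "
                        "skipped", gene)
            continue
        rare += (dosages[:, cols] > 0).any(axis=1) * w

    common = np.zeros(n)
    vidx = {v: i for i, v in enumerate(ann["variant_id"])}
    for vid, w in sorted(weights.common.items()):
        j = vidx.get(vid)
        if j is None:
            log.warning("common weight for %s: variant absent; skipped", vid)
            continue
        dose = dosages[:, j].astype(float)
        if center_common:
            dose = dose - 2.0 * ctrl_af[j]
        common += dose * w

    combined = rare + common
    out = pd.DataFrame(dict(
        sample_id=sample_ids,
        rare_log_or=rare,
        common_log_or=common,
        combined_log_or=combined,
        rare_or=np.exp(rare),
        common_or=np.exp(common),
        combined_or=np.exp(combined),
    ))
    out["mody"] = (np.asarray(mody_flags, dtype=bool)
                   if mody_flags is not None else False)
    return out


def assign_bands(scores: pd.DataFrame,
                 thresholds: tuple[float, ...] = (5.0, 3.0)) -> pd.DataFrame:
    """Mutually exclusive risk-band assignment.

    At each odds-ratio threshold, highest first, the precedence is
    MODY > rare > common > combined; the first qualifying band wins.
    MODY carriers are banded 'MODY' outright. ``thresholds`` must be
    strictly descending.
    """
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ConfigurationError("thresholds must be strictly descending")
    out = scores.copy()
    bands = np.full(len(out), "none", dtype=object)
    assigned = out["mody"].to_numpy(dtype=bool).copy()
    bands[assigned] = "MODY"
    prev: float | None = None
    for t in thresholds:
        suffix = f">={t:g}" if prev is None else f"{t:g}-{prev:g}"
        for comp in ("rare", "common", "combined"):
            hit = (out[f"{comp}_or"].to_numpy() >= t) & ~assigned
            bands[hit] = f"{comp} {suffix}"
            assigned |= hit
        prev = t
    out["band"] = bands
    return out


def rare_fraction_trend(scores: pd.DataFrame, bin_size: int = 50,
                        min_combined_or: float = 3.0
                        ) -> tuple[pd.DataFrame, float, float]:
    """Mean rare-share of the combined score by combined-score rank bin.

    Restricted to samples with combined OR at or above the floor and
    both components positive (OR > 1); ranked by combined score
    descending; the rare share is ``rare / (rare + common)`` on the log
    scale. Returns the per-bin table plus the Spearman correlation of
    bin index with bin mean (negative = rare variants dominate the most
    extreme cases) and its P-value.
    """
    sel = scores[(scores["combined_or"] >= min_combined_or)
                 & (scores["rare_log_or"] > 0)
                 & (scores["common_log_or"] > 0)].copy()
    if len(sel) < 1 or len(sel) < bin_size:
        raise ConfigurationError(
            f"fewer than one full bin of qualifying samples "
            f"({len(sel)} < {bin_size})")
    sel = sel.sort_values("combined_log_or", ascending=False)
    frac = (sel["rare_log_or"] / sel["combined_log_or"]).to_numpy()
    n_bins = len(sel) // bin_size
    rows = []
    for b in range(n_bins):
        chunk = frac[b * bin_size:(b + 1) * bin_size]
        rows.append(dict(bin=b, rank_lo=b * bin_size + 1,
                         rank_hi=(b + 1) * bin_size,
                         mean_rare_fraction=float(chunk.mean())))
    table = pd.DataFrame(rows)
    if n_bins >= 2 and table["mean_rare_fraction"].nunique() > 1:
        rho, p = stats.spearmanr(table["bin"], table["mean_rare_fraction"])
    else:
        rho, p = 0.0, 1.0
    return table, float(rho), float(p)


def phenotype_regression(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    score_col: str = "rare_log_or",
    phenotype_cols: tuple[str, ...] = ("age_at_diagnosis", "bmi_z",
                                       "log10_c_peptide"),
    exclude_mody: bool = True,
) -> pd.DataFrame:
    """OLS of each phenotype on the standardized score + sex + cluster.

    Cases only; MODY carriers excluded by default; C-peptide is
    log10-transformed. Returns one row per phenotype with the slope per
    1 s.d. of score, its SE and the two-sided P.
    """
    import statsmodels.api as sm

    df = scores.merge(phenotypes, on="sample_id")
    df = df[df["status"] == "case"] if "status" in df.columns else df
    if exclude_mody:
        df = df[~df["mody"].astype(bool)]
    if "c_peptide" in df.columns and "log10_c_peptide" not in df.columns:
        df = df.assign(log10_c_peptide=np.log10(df["c_peptide"]))
    s = df[score_col].to_numpy(dtype=float)
    if s.std() == 0:
        raise ConfigurationError(f"score '{score_col}' has zero variance")
    z = (s - s.mean()) / s.std()
    covs = [z]
    names = ["score_sd"]
    if "sex" in df.columns:
        covs.append(df["sex"].to_numpy(dtype=float))
        names.append("sex")
    if "cluster" in df.columns and df["cluster"].nunique() > 1:
        dummies = pd.get_dummies(df["cluster"], prefix="cl",
                                 drop_first=True).to_numpy(dtype=float)
        for k in range(dummies.shape[1]):
            covs.append(dummies[:, k])
            names.append(f"cluster_{k}")
    X = sm.add_constant(np.column_stack(covs))
    rows = []
    for pheno in phenotype_cols:
        if pheno not in df.columns:
            continue
        y = df[pheno].to_numpy(dtype=float)
        keep = np.isfinite(y)
        res = sm.OLS(y[keep], X[keep]).fit()
        rows.append(dict(phenotype=pheno, score=score_col,
                         beta_per_sd=float(res.params[1]),
                         se=float(res.bse[1]),
                         p=float(res.pvalues[1]),
                         n=int(keep.sum())))
    return pd.DataFrame(rows)


def mody_group_comparison(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    phenotype_cols: tuple[str, ...] = ("age_at_diagnosis", "bmi_z",
                                       "log10_c_peptide"),
    nonparametric: bool = False,
) -> pd.DataFrame:
    """Phenotype means of MODY carriers vs non-carriers among cases
    (two-sample t-test; Mann-Whitney behind a flag)."""
    df = scores.merge(phenotypes, on="sample_id")
    if "status" in df.columns:
        df = df[df["status"] == "case"]
    if "c_peptide" in df.columns and "log10_c_peptide" not in df.columns:
        df = df.assign(log10_c_peptide=np.log10(df["c_peptide"]))
    carrier = df["mody"].astype(bool)
    rows = []
    for pheno in phenotype_cols:
        if pheno not in df.columns:
            continue
        a = df.loc[carrier, pheno].dropna().to_numpy(dtype=float)
        b = df.loc[~carrier, pheno].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        if nonparametric:
            stat = stats.mannwhitneyu(a, b, alternative="two-sided")
            p = float(stat.pvalue)
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        se_diff = float(np.sqrt(a.var(ddof=1) / len(a)
                                + b.var(ddof=1) / len(b)))
        rows.append(dict(phenotype=pheno,
                         mean_mody=float(a.mean()), sd_mody=float(a.std()),
                         mean_other=float(b.mean()), sd_other=float(b.std()),
                         difference=float(a.mean() - b.mean()),
                         se_difference=se_diff,
                         p=p, n_mody=len(a), n_other=len(b)))
    return pd.DataFrame(rows)
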