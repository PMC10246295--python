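"""Single-variant and gene-level rare-variant association testing.

Gene-level tests collapse each gene's qualifying variants under a
ladder of nested masks (consequence-severity classes crossed with
minor-allele-frequency ceilings, evaluated on control-only frequency so
that case enrichment cannot leak into mask membership). Each mask's
carrier indicator is tested by Firth-penalized logistic regression, and
the per-gene minimum P over masks is corrected for the effective number
of tests, estimated from the eigenvalues of the inter-mask carrier
correlation matrix: ``P_corr = 1 - (1 - minP)^N_eff``.

Masks are made nested by construction: the variant set of mask k is the
union of the raw rule of mask k with every stricter mask's set, so the
carrier sets are monotone from strictest to loosest regardless of the
raw rules supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .firth import fit_logistic, lrt_test, wald_test

__all__ = [
    "Mask",
    "MaskDefinition",
    "DEFAULT_MASKS",
    "SYNONYMOUS_MASK",
    "VariantAssociation",
    "GeneAssociation",
    "control_allele_freq",
    "mask_variant_sets",
    "burden_collapse",
    "single_variant_test",
    "burden_test",
    "gene_level_test",
    "gene_level_scan",
    "inflation_diagnostics",
    "meta_fixed_effect",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Mask:
    name: str
    categories: frozenset[str]
    maf_ceiling: float

    def qualifies(self, category: np.ndarray, control_af: np.ndarray,
                  present: np.ndarray | None = None) -> np.ndarray:
        """Control-only frequency below the ceiling (case-only variants
        have control AF 0 and qualify as long as they are observed)."""
        in_cat = np.isin(category, list(self.categories))
        out = in_cat & (control_af < self.maf_ceiling)
        if present is not None:
            out &= present
        return out


_PTV = frozenset({"ptv"})
_STRICT = frozenset({"ptv", "missense_strict"})
_BROAD = frozenset({"ptv", "missense_strict", "missense_broad"})

DEFAULT_MASKS: tuple[Mask, ...] = (
    Mask("ptv_0.1pct", _PTV, 0.001),
    Mask("ptv_strict_0.1pct", _STRICT, 0.001),
    Mask("ptv_strict_0.5pct", _STRICT, 0.005),
    Mask("ptv_broad_0.1pct", _BROAD, 0.001),
    Mask("ptv_broad_0.5pct", _BROAD, 0.005),
    Mask("nonsyn_1pct", _BROAD, 0.01),
    Mask("nonsyn_5pct", _BROAD, 0.05),
)

SYNONYMOUS_MASK = Mask("synonymous_0.5pct", frozenset({"synonymous"}), 0.005)


@dataclass
class MaskDefinition:
    """Ordered mask ladder; sets are cumulative unions so nesting holds."""

    masks: tuple[Mask, ...] = DEFAULT_MASKS

    def __post_init__(self) -> None:
        if not self.masks:
            raise ConfigurationError("at least one mask required")
        names = [m.name for m in self.masks]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate mask names")

    def variant_sets(self, category: np.ndarray, control_af: np.ndarray,
                     present: np.ndarray | None = None
                     ) -> dict[str, np.ndarray]:
        """Boolean qualifying-variant array per mask (cumulative)."""
        out: dict[str, np.ndarray] = {}
        acc = np.zeros(len(category), dtype=bool)
        for m in self.masks:
            acc = acc | m.qualifies(category, control_af, present)
            out[m.name] = acc.copy()
        return out

    def verify_nesting(self, category: np.ndarray,
                       control_af: np.ndarray,
                       present: np.ndarray | None = None) -> None:
        sets = self.variant_sets(category, control_af, present)
        prev = None
        for name, cur in sets.items():
            if prev is not None and np.any(prev & ~cur):
                raise ConfigurationError(
                    f"mask '{name}' is not a superset of its predecessor")
            prev = cur


@dataclass
class VariantAssociation:
    variant_id: str
    beta: float
    se: float
    p: float
    maf: float
    n_carriers: int
    skipped: str | None = None
    per_cluster_beta: dict[int, float] = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class GeneAssociation:
    gene: str
    per_mask: pd.DataFrame  # mask, n_variants, n_carriers, combined_maf, beta, se, p
    min_p_mask: str
    min_p: float
    n_eff: float
    corrected_p: float
    direction: int  # sign of the min-P mask beta


def control_allele_freq(dosages: np.ndarray,
                        is_case: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency among controls (mask membership is
    always evaluated control-only)."""
    ctrl = dosages[~np.asarray(is_case, dtype=bool)]
    if ctrl.shape[0] == 0:
        return dosages.mean(axis=0) / 2.0
    return ctrl.mean(axis=0) / 2.0


def mask_variant_sets(annotations: pd.DataFrame, control_af: np.ndarray,
                      masks: MaskDefinition | None = None,
                      present: np.ndarray | None = None
                      ) -> dict[str, np.ndarray]:
    masks = masks or MaskDefinition()
    return masks.variant_sets(annotations["category"].to_numpy(), control_af,
                              present)


def burden_collapse(dosages: np.ndarray, variant_cols: np.ndarray,
                    coding: str = "carrier") -> np.ndarray:
    """Per-sample burden under one mask.

    ``carrier`` coding yields a 0/1 indicator of carrying at least one
    qualifying allele in the gene; ``count`` sums qualifying alleles.
    """
    if variant_cols.size == 0:
        return np.zeros(dosages.shape[0], dtype=np.int8)
    block = dosages[:, variant_cols]
    if coding == "carrier":
        return (block > 0).any(axis=1).astype(np.int8)
    if coding == "count":
        return block.sum(axis=1).astype(np.int32)
    raise ConfigurationError(f"unknown burden coding '{coding}'")


def _design(x: np.ndarray, y: np.ndarray,
            covariates: np.ndarray | None) -> np.ndarray:
    n = len(y)
    cols = [np.ones(n), x.astype(float)]
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    return np.column_stack(cols)


def _use_firth(x: np.ndarray, firth_threshold: int) -> bool:
    carriers = int(np.count_nonzero(x != np.round(np.median(x))))
    carriers = min(carriers, len(x) - carriers)
    return carriers < firth_threshold


def _assoc_fit(x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None,
               firth_threshold: int = 50):
    """Fit y ~ x + covariates; Firth when minor-exposure carriers are few."""
    X = _design(x, y, covariates)
    use_firth = _use_firth(x, firth_threshold)
    fit = fit_logistic(X, y, firth=use_firth)
    if not use_firth and not fit.converged:
        fit = fit_logistic(X, y, firth=True)  # rescue separation
    return fit


def burden_test(x: np.ndarray, y: np.ndarray,
                covariates: np.ndarray | None,
                firth_threshold: int = 50) -> tuple[float, float, float]:
    """One burden association: (penalized) likelihood-ratio P.

    The LRT is used instead of the Wald test because burden exposures
    are rare and the Wald statistic is conservative at low carrier
    counts. Returns ``(beta, se, p)``.
    """
    X = _design(x, y, covariates)
    use_firth = _use_firth(x, firth_threshold)
    fit = fit_logistic(X, y, firth=use_firth)
    if not use_firth and not fit.converged:
        use_firth = True
        fit = fit_logistic(X, y, firth=True)
    return lrt_test(X, y, 1, firth=use_firth, full_fit=fit)


def single_variant_test(
    dosages: np.ndarray,
    is_case: np.ndarray,
    covariates: np.ndarray | None,
    variant_ids: list[str],
    firth_threshold: int = 50,
    clusters: np.ndarray | None = None,
    per_cluster: bool = False,
) -> list[VariantAssociation]:
    """Per-variant logistic association with Wald P-values.

    Variants with no carriers of the minor allele, or identical
    genotypes in all samples, are returned with a ``skipped`` reason and
    a missing P rather than dropped silently.
    """
    y = np.asarray(is_case, dtype=float)
    out: list[VariantAssociation] = []
    for j, vid in enumerate(variant_ids):
        g = dosages[:, j].astype(float)
        af = g.mean() / 2.0
        maf = min(af, 1 - af)
        minor_carriers = int(((g > 0) if af <= 0.5 else (g < 2)).sum())
        if np.all(g == g[0]):
            out.append(VariantAssociation(vid, np.nan, np.nan, np.nan,
                                          maf, minor_carriers,
                                          skipped="monomorphic"))
            continue
        fit = _assoc_fit(g, y, covariates, firth_threshold)
        beta, se, p = wald_test(fit, 1)
        skipped = None
        if not np.isfinite(p):
            skipped = "separation"
        rec = VariantAssociation(vid, beta, se, p, maf, minor_carriers,
                                 skipped=skipped)
        if per_cluster and clusters is not None:
            for c in np.unique(clusters):
                rows = clusters == c
                if len(np.unique(g[rows])) < 2 or len(np.unique(y[rows])) < 2:
                    continue
                cf = _assoc_fit(g[rows], y[rows], None, firth_threshold)
                rec.per_cluster_beta[int(c)] = float(cf.beta[1])
        out.append(rec)
    return out


def effective_test_count(indicators: np.ndarray,
                         trace_threshold: float = 0.995) -> float:
    """Effective number of tests from the carrier-indicator correlation
    matrix: the count of leading eigenvalues needed to reach the trace
    threshold."""
    k = indicators.shape[1]
    if k == 1:
        return 1.0
    c = np.corrcoef(indicators, rowvar=False)
    c = np.nan_to_num(c, nan=1.0)
    eig = np.sort(np.linalg.eigvalsh(c))[::-1]
    eig = np.clip(eig, 0, None)
    cum = np.cumsum(eig)
    target = trace_threshold * k
    n_eff = int(np.searchsorted(cum, target - 1e-12) + 1)
    return float(min(n_eff, k))


def gene_level_test(
    dosages: np.ndarray,
    is_case: np.ndarray,
    covariates: np.ndarray | None,
    gene_variant_sets: dict[str, np.ndarray],
    gene: str,
    firth_threshold: int = 50,
    coding: str = "carrier",
    trace_threshold: float = 0.995,
    control_af: np.ndarray | None = None,
) -> GeneAssociation | None:
    """Nested-mask burden test for one gene.

    ``gene_variant_sets`` maps mask name to the columns of this gene's
    qualifying variants. Returns None (with a log entry) when every mask
    is empty or degenerate.
    """
    y = np.asarray(is_case, dtype=float)
    rows = []
    indicators = []
    tested_names = []
    for name, cols in gene_variant_sets.items():
        cols = np.asarray(cols)
        burden = burden_collapse(dosages, cols, coding)
        n_carriers = int((burden > 0).sum())
        combined_maf = (float(control_af[cols].sum())
                        if control_af is not None and cols.size
                        else float(dosages[:, cols].mean() / 2.0 * cols.size)
                        if cols.size else 0.0)
        row = dict(mask=name, n_variants=int(cols.size),
                   n_carriers=n_carriers, combined_maf=combined_maf,
                   beta=np.nan, se=np.nan, p=np.nan)
        if cols.size and 0 < n_carriers < len(y):
            beta, se, p = burden_test(burden, y, covariates, firth_threshold)
            row.update(beta=beta, se=se, p=p)
            if np.isfinite(p):
                indicators.append(burden.astype(float))
                tested_names.append(name)
        rows.append(row)
    per_mask = pd.DataFrame(rows)
    if not tested_names:
        log.info("gene %s: no non-degenerate mask; omitted", gene)
        return None
    ind = np.column_stack(indicators)
    # collapse duplicated indicators before the eigen decomposition is
    # unnecessary: perfectly correlated masks contribute one eigenvalue
    n_eff = effective_test_count(ind, trace_threshold)
    tested = per_mask[per_mask["mask"].isin(tested_names)]
    i_min = tested["p"].idxmin()
    min_p = float(per_mask.loc[i_min, "p"])
    corrected = float(1.0 - (1.0 - min_p) ** n_eff)
    corrected = max(corrected, min_p)
    direction = int(np.sign(per_mask.loc[i_min, "beta"])) or 1
    return GeneAssociation(gene, per_mask, str(per_mask.loc[i_min, "mask"]),
                           min_p, n_eff, corrected, direction)


def gene_level_scan(
    dosages: np.ndarray,
    is_case: np.ndarray,
    covariates: np.ndarray | None,
    annotations: pd.DataFrame,
    masks: MaskDefinition | None = None,
    genes: list[str] | None = None,
    firth_threshold: int = 50,
    coding: str = "carrier",
    synonymous_control: bool = False,
) -> pd.DataFrame:
    """Run the nested-mask gene-level test over every gene.

    Returns one row per testable gene with the min-P mask, the
    effective test count and the corrected P. With
    ``synonymous_control=True`` the scan uses the synonymous-only
    control mask instead of the main ladder (a negative control: it
    should produce no signal in a well-calibrated analysis).
    """
    masks = masks or MaskDefinition()
    if synonymous_control:
        masks = MaskDefinition((SYNONYMOUS_MASK,))
    ctrl_af = control_allele_freq(dosages, is_case)
    present = np.asarray((dosages > 0).any(axis=0))
    sets = masks.variant_sets(annotations["category"].to_numpy(), ctrl_af,
                              present)
    gene_arr = annotations["gene"].to_numpy()
    targets = genes if genes is not None else sorted(pd.unique(gene_arr))
    rows = []
    for gene in targets:
        gmask = gene_arr == gene
        gene_sets = {name: np.where(gmask & q)[0] for name, q in sets.items()}
        if all(v.size == 0 for v in gene_sets.values()):
            continue
        res = gene_level_test(dosages, is_case, covariates, gene_sets, gene,
                              firth_threshold, coding,
                              control_af=ctrl_af)
        if res is None:
            continue
        best = res.per_mask[res.per_mask["mask"] == res.min_p_mask].iloc[0]
        rows.append(dict(
            gene=gene, min_p_mask=res.min_p_mask, min_p=res.min_p,
            n_eff=res.n_eff, corrected_p=res.corrected_p,
            direction=res.direction, beta=float(best["beta"]),
            se=float(best["se"]),
            n_carriers=int(best["n_carriers"]),
            n_variants=int(best["n_variants"]),
            combined_maf=float(best["combined_maf"]),
        ))
    return pd.DataFrame(rows)


def meta_fixed_effect(betas: np.ndarray, ses: np.ndarray
                      ) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect meta-analysis across clusters."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(betas) & np.isfinite(ses) & (ses > 0)
    if not ok.any():
        return np.nan, np.nan, np.nan
    w = 1.0 / ses[ok] ** 2
    beta = float((w * betas[ok]).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def inflation_diagnostics(pvalues: np.ndarray) -> dict:
    """Genomic-control lambda and a QQ table.

    Lambda is the median observed chi-square(1) quantile divided by the
    null median (0.4549). Values near 1 indicate calibrated tests.
    """
    import warnings

    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ConfigurationError("no finite P-values")
    if p.size < 100:
        warnings.warn(f"only {p.size} tests: lambda_GC will be noisy")
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    lam = float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
    n = p.size
    obs = np.sort(p)
    exp = (np.arange(1, n + 1) - 0.5) / n
    qq = pd.DataFrame({
        "expected_neglog10": -np.log10(exp),
        "observed_neglog10": -np.log10(np.clip(obs, 1e-300, 1.0)),
    })
    return {"lambda_gc": lam, "n_tests": int(n), "qq": qq}
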