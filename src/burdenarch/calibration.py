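"""Study-scale reference configurations.

These functions pin down the synthetic conditions used for end-to-end
calibration and recovery runs: a case cohort whose risk-band fractions
emulate a youth-onset T2D exome study (about 2% pathogenic monogenic
carriers, a few percent of cases with rare-score OR >= 5, a common-score
tail around 6%), and a paired youth/adult summary-statistic architecture
whose liability-variance-explained (LVE) totals and fold-changes are
planted analytically (common LVE 6.7% vs 2.0%, i.e. 3.4-fold; rare LVE
1.5% vs 0.3%, i.e. 5.0-fold) so that pipeline estimates have exact
ground truth.

All quantities here are inputs (study design constants), never results:
the numbers the pipeline reports are always computed from simulated
data at run time.
"""

from __future__ import annotations

import numpy as np

from .architecture import (AssociationSummary, LiabilityModel, _lve_vec,
                           overlap_correlation)
from .cohort import (CommonVariantParams, ModyParams, RareGeneParams,
                     SimulationConfig, SyntheticCohort)
from .scores import ScoreWeights

__all__ = [
    "YOUTH_COUNTS",
    "ADULT_COUNTS",
    "SHARED_CONTROLS",
    "band_calibration_config",
    "true_score_weights",
    "planted_architecture",
    "exceedance_comparison_config",
]

# study design constants: youth cohort matched to external controls,
# adult comparison study sharing the youth study's control pool
YOUTH_COUNTS = (3005, 9777)
ADULT_COUNTS = (20791, 24440)
SHARED_CONTROLS = 9777

YOUTH_PREVALENCE = 0.01
ADULT_PREVALENCE = 0.10

# planted LVE architecture: totals per variant class and study
LVE_COMMON_YOUTH = 0.067
LVE_RARE_YOUTH = 0.015
COMMON_FOLD = 3.4
RARE_FOLD = 5.0


def band_calibration_config(seed: int = 0, n_cases: int = 3005,
                            n_controls: int = 1000) -> SimulationConfig:
    """Cohort whose true-weight contribution scores land in the
    risk-band proportions of a youth-onset study.

    Architecture: two high-impact rare genes (carrier OR 7.5 at combined
    MAF 1.1e-3, the HNF1A-like stratum that drives the rare-score >= 5
    band), one moderate gene (OR 3.2) and two weak genes (OR 1.8)
    feeding the 3-5 band and the combined score; 45 common variants at
    OR 1.18 across the 0.10-0.50 frequency range giving the common
    score a ~6% OR >= 5 tail; and pathogenic monogenic variants
    calibrated to a 2.1% case-carrier rate with penetrance 0.7.
    """
    freqs = np.linspace(0.10, 0.50, 45)
    common = tuple(CommonVariantParams(float(f), 1.18) for f in freqs)
    rare = (
        RareGeneParams(0.0011, 7.5, 0.8),
        RareGeneParams(0.0011, 7.5, 0.8),
        RareGeneParams(0.0022, 3.2, 0.8),
        RareGeneParams(0.0030, 1.8, 0.8),
        RareGeneParams(0.0030, 1.8, 0.8),
    )
    return SimulationConfig(
        seed=seed,
        n_clusters=1,
        cases_per_cluster=n_cases,
        controls_per_cluster=n_controls,
        fst_per_cluster=0.0,
        prevalence=YOUTH_PREVALENCE,
        common_variant_params=common,
        n_causal_genes=len(rare),
        rare_gene_params=rare,
        mody_params=ModyParams(case_carrier_rate=0.021, penetrance=0.7),
        n_null_genes=5,
        n_common_null=10,
        variants_per_gene_range=(6, 12),
    )


def null_calibration_config(seed: int = 0, n_null_genes: int = 1000,
                            n_cases: int = 600, n_controls: int = 1400,
                            n_common_null: int = 1000) -> SimulationConfig:
    """Global-null cohort for type-I-error and inflation checks.

    No causal variants of any class; a single undifferentiated cluster;
    null genes sized so burden carrier counts land in the tens (where
    the Firth machinery actually operates). Disease status is therefore
    independent of every genotype.
    """
    return SimulationConfig(
        seed=seed,
        n_clusters=1,
        cases_per_cluster=n_cases,
        controls_per_cluster=n_controls,
        fst_per_cluster=0.0,
        prevalence=0.3,
        n_common_causal=0,
        n_causal_genes=0,
        rare_gene_params=(),
        mody_params=ModyParams(case_carrier_rate=0.0, penetrance=0.7),
        mody_residual_or=0.0,
        n_null_genes=n_null_genes,
        n_common_null=n_common_null,  # lambda stability scales with this
        variants_per_gene_range=(4, 8),
        null_rare_maf_range=(5e-4, 5e-3),
    )


def leave_out_config(seed: int = 1) -> SimulationConfig:
    """Two monogenic genes for the leave-carriers-out contrast.

    The first registry gene carries only pathogenic high-penetrance
    variants (its burden association exists solely through flagged
    carriers); the second additionally carries ordinary rare risk
    variants (OR 4 at combined MAF 0.6%), so its association must
    survive removal of the flagged carriers.
    """
    return SimulationConfig(
        seed=seed,
        n_clusters=1,
        cases_per_cluster=700,
        controls_per_cluster=1400,
        fst_per_cluster=0.0,
        prevalence=0.05,
        n_common_causal=0,
        n_causal_genes=0,
        rare_gene_params=(),
        mody_params=ModyParams(case_carrier_rate=0.05, penetrance=0.9,
                               n_genes=2),
        mody_residual_or=4.0,
        mody_residual_maf=0.006,
        n_null_genes=5,
        n_common_null=10,
        variants_per_gene_range=(6, 10),
    )


def phenotype_recovery_config(seed: int) -> SimulationConfig:
    """Cohort for phenotype-effect recovery: planted age, C-peptide and
    MODY-shift couplings at the study's effect sizes, with rare and
    common architecture strong enough that the true-weight scores have
    non-degenerate variance among cases."""
    return SimulationConfig(
        seed=seed,
        n_clusters=1,
        cases_per_cluster=600,
        controls_per_cluster=300,
        fst_per_cluster=0.0,
        prevalence=0.05,
        n_common_causal=10,
        common_or_range=(1.15, 1.4),
        n_causal_genes=3,
        rare_gene_params=(
            RareGeneParams(0.004, 5.0, 0.8),
            RareGeneParams(0.006, 3.0, 0.8),
            RareGeneParams(0.008, 2.0, 0.8),
        ),
        mody_params=ModyParams(case_carrier_rate=0.021, penetrance=0.7),
        n_null_genes=3,
        n_common_null=5,
        variants_per_gene_range=(6, 10),
    )


def true_score_weights(cohort: SyntheticCohort) -> ScoreWeights:
    """Contribution-score weights read off the cohort's truth tables
    (the generating gene-level and variant-level log odds ratios)."""
    tg = cohort.truth_genes
    tv = cohort.truth_variants
    rare = {r["gene"]: float(np.log(r["odds_ratio"]))
            for _, r in tg.iterrows() if r["kind"] == "rare"}
    common = {r["variant_id"]: float(r["true_log_or"])
              for _, r in tv.iterrows() if r["role"] == "common_causal"}
    return ScoreWeights(rare=rare, common=common)


def _solve_scale(freqs: np.ndarray, model: LiabilityModel,
                 target_total: float) -> float:
    """Common per-unit log-OR scale such that the summed LVE of units at
    ``freqs`` equals the target (bisection; LVE is increasing in |beta|)."""
    lo, hi = 0.0, 5.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        total = float(_lve_vec(np.full(len(freqs), mid), freqs, model).sum())
        if total < target_total:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _se_log_or(n_cases: int, n_controls: int, freq: np.ndarray) -> np.ndarray:
    """Asymptotic SE of a log OR at the given exposure frequency."""
    return np.sqrt((1.0 / n_cases + 1.0 / n_controls)
                   / (2.0 * freq * (1.0 - freq)))


def planted_architecture() -> dict:
    """Paired youth/adult association units with exact LVE ground truth.

    Ten common variants (frequencies 0.12-0.45) and ten rare gene
    burdens (carrier frequencies 0.002-0.011) per study; per-class true
    log ORs are solved so the youth totals equal 6.7% (common) and 1.5%
    (rare) of liability variance at prevalence 1%, and adult totals are
    3.4- and 5.0-fold smaller at prevalence 10%. Standard errors follow
    each study's case/control counts; the estimate correlation induced
    by the shared control pool is included.
    """
    youth = LiabilityModel(YOUTH_PREVALENCE)
    adult = LiabilityModel(ADULT_PREVALENCE)
    common_freq = np.linspace(0.12, 0.45, 10)
    rare_freq = np.geomspace(0.002, 0.011, 10)
    out = {
        "youth_model": youth,
        "adult_model": adult,
        "overlap_r": overlap_correlation(*YOUTH_COUNTS, *ADULT_COUNTS,
                                         SHARED_CONTROLS),
    }
    targets = {
        ("common", "youth"): (common_freq, youth, LVE_COMMON_YOUTH,
                              YOUTH_COUNTS),
        ("common", "adult"): (common_freq, adult,
                              LVE_COMMON_YOUTH / COMMON_FOLD, ADULT_COUNTS),
        ("rare", "youth"): (rare_freq, youth, LVE_RARE_YOUTH, YOUTH_COUNTS),
        ("rare", "adult"): (rare_freq, adult, LVE_RARE_YOUTH / RARE_FOLD,
                            ADULT_COUNTS),
    }
    for (kind, study), (freq, model, total, counts) in targets.items():
        beta = _solve_scale(freq, model, total)
        se = _se_log_or(*counts, freq)
        out[f"{kind}_{study}"] = [
            AssociationSummary(f"{kind[0]}u{i+1:02d}", float(beta),
                               float(se[i]), float(freq[i]), study=study)
            for i in range(len(freq))
        ]
        out[f"{kind}_{study}_total"] = total
    return out


def exceedance_comparison_config() -> dict:
    """Inputs for the cross-study effect-size exceedance expectation.

    Emulates the known-gene comparison between the youth study and the
    adult discovery study: a shared true carrier-level effect (log OR
    0.433, i.e. OR ~1.54), SEs implied by each study's counts at a 1%
    carrier frequency, the shared-control estimate correlation, and
    nominal (|z| >= 1.96) selection in both studies, with the adult
    (discovery) estimates winner's-curse corrected. Under these
    conditions the expected frequency of a larger youth estimate is
    about 60%.
    """
    q = 0.01
    return dict(
        true_beta=0.433,
        se_youth=float(_se_log_or(*YOUTH_COUNTS, np.array([q]))[0]),
        se_adult=float(_se_log_or(*ADULT_COUNTS, np.array([q]))[0]),
        overlap_r=overlap_correlation(*YOUTH_COUNTS, *ADULT_COUNTS,
                                      SHARED_CONTROLS),
        z_c=1.96,
    )
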