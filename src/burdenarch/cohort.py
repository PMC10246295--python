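"""Seeded synthetic case-control exome cohorts with known ground truth.

The generator emulates the statistical structure of a multi-ancestry
youth-onset type 2 diabetes exome study:

* population structure via Balding-Nichols drift around shared ancestral
  frequencies, one differentiation parameter per ancestry cluster;
* a liability-threshold disease model: liability = genetic score +
  standard-normal residual, disease iff liability exceeds the threshold
  implied by the configured prevalence; cases are oversampled by
  rejection until the configured per-cluster counts are reached;
* common causal variants with modest odds ratios, rare causal gene
  burdens with effects specified at the gene level and spread over each
  gene's deleterious variants, and rare high-penetrance "MODY-like"
  pathogenic variants whose carriers become cases with a fixed
  penetrance rather than through the liability score;
* phenotypes (age at diagnosis, BMI Z-score, C-peptide) generated as
  linear functions of the true rare / common genetic scores and
  MODY-carrier status plus independent noise.

Every random draw flows from a single seeded generator, and the truth
tables record exactly which variants are causal and what each sample's
true scores are, so downstream recovery tests have an unambiguous
target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .architecture import LiabilityModel, genotype_liability_means
from .errors import AscertainmentError, ConfigurationError

__all__ = [
    "RareGeneParams",
    "CommonVariantParams",
    "ModyParams",
    "PhenotypeEffects",
    "PhenotypeNoise",
    "SimulationConfig",
    "GenotypeMatrix",
    "SyntheticCohort",
    "simulate_frequencies",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "CATEGORIES",
    "DELETERIOUSNESS_WEIGHT",
]

CATEGORIES = ("ptv", "missense_strict", "missense_broad", "synonymous")

# relative share of a gene's burden effect carried by each consequence
# class; synonymous variants never carry signal
DELETERIOUSNESS_WEIGHT = {
    "ptv": 1.0,
    "missense_strict": 0.7,
    "missense_broad": 0.3,
    "synonymous": 0.0,
}


@dataclass(frozen=True)
class RareGeneParams:
    """Burden-level truth for one rare causal gene."""

    combined_maf: float  # sum of the gene's rare allele frequencies
    odds_ratio: float  # carrier-level odds ratio
    frac_deleterious: float = 0.7  # fraction of variants carrying signal


@dataclass(frozen=True)
class CommonVariantParams:
    """Explicit truth for one common causal variant (overrides the
    randomly drawn frequency/OR when supplied)."""

    freq: float
    odds_ratio: float


@dataclass(frozen=True)
class ModyParams:
    """High-penetrance pathogenic variants.

    ``case_carrier_rate`` is the target fraction of *cases* carrying a
    pathogenic-flagged allele; the population carrier frequency is
    derived from it via Bayes at the configured prevalence.
    """

    case_carrier_rate: float = 0.021
    penetrance: float = 0.7
    n_genes: int = 2


@dataclass(frozen=True)
class PhenotypeEffects:
    """Linear couplings of phenotypes to true genetic scores.

    Slopes are per 1 s.d. of the corresponding score among non-MODY
    cases; MODY shifts are mean differences of carriers vs
    non-carriers.
    """

    age_beta_per_sd_rare: float = -0.102  # years
    cpep_beta_per_sd_common: float = 0.040  # log10 units
    mody_age_shift: float = -0.9  # 12.7 vs 13.6 years
    mody_bmiz_shift: float = -0.38  # 1.80 vs 2.18 SD units
    mody_cpep_shift: float = -0.12  # 0.43 vs 0.55 log10 units


@dataclass(frozen=True)
class PhenotypeNoise:
    """Residual phenotype SDs and baselines."""

    age_mean: float = 13.6
    age_sd: float = 2.3
    bmiz_case_mean: float = 2.18
    bmiz_control_mean: float = 1.2
    bmiz_sd: float = 0.57
    cpep_log10_mean: float = 0.55
    cpep_log10_sd: float = 0.33


def _default_rare_genes() -> tuple[RareGeneParams, ...]:
    # ten genes spanning the combined MAF 1e-3..1e-2 / OR 1.5..20 range,
    # anchored by an HNF1A-like (0.0038, ~7.5) and an MC4R-like
    # (0.011, ~3.5) configuration
    mafs = np.geomspace(1.0e-3, 1.1e-2, 10)
    ors = np.geomspace(20.0, 1.5, 10)
    return tuple(RareGeneParams(float(m), float(o), 0.7)
                 for m, o in zip(mafs, ors))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with validation.

    Defaults reflect the study design being emulated: three ancestry
    clusters, roughly 3,000 cases matched to roughly 9,800 controls,
    a youth-onset prevalence of 1%, ten common and ten rare causal
    units, and ~2% of cases carrying a pathogenic MODY-like variant.
    """

    seed: int = 0
    n_clusters: int = 3
    cases_per_cluster: int = 1000
    controls_per_cluster: int = 3259
    fst_per_cluster: tuple[float, ...] | float = 0.1
    prevalence: float = 0.01
    n_common_causal: int = 10
    common_or_range: tuple[float, float] = (1.1, 1.5)
    common_variant_params: tuple[CommonVariantParams, ...] | None = None
    n_causal_genes: int = 10
    rare_gene_params: tuple[RareGeneParams, ...] | None = None
    mody_params: ModyParams = field(default_factory=ModyParams)
    mody_residual_or: float = 3.0  # extra non-pathogenic signal in the
    mody_residual_maf: float = 0.002  # last MODY gene (mixed-signal gene)
    n_null_genes: int = 100
    n_common_null: int = 200
    variants_per_gene_range: tuple[int, int] = (10, 30)
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    null_rare_maf_range: tuple[float, float] = (1e-4, 5e-3)
    drift_maf_floor: float = 0.01  # rare variants below this do not drift
    phenotype_effects: PhenotypeEffects = field(default_factory=PhenotypeEffects)
    phenotype_noise: PhenotypeNoise = field(default_factory=PhenotypeNoise)
    max_liability_draws: int | None = None

    def __post_init__(self) -> None:
        if self.rare_gene_params is None:
            self.rare_gene_params = _default_rare_genes()[: self.n_causal_genes]
        if self.common_variant_params is not None:
            self.common_variant_params = tuple(self.common_variant_params)
            self.n_common_causal = len(self.common_variant_params)
            for cv in self.common_variant_params:
                if not 0.0 < cv.freq < 1.0 or cv.odds_ratio < 1.0:
                    raise ConfigurationError(
                        "common variant params need freq in (0,1), OR >= 1")
        if isinstance(self.fst_per_cluster, (int, float)):
            self.fst_per_cluster = (float(self.fst_per_cluster),) * self.n_clusters
        self.validate()

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if len(self.fst_per_cluster) != self.n_clusters:
            raise ConfigurationError("fst_per_cluster length != n_clusters")
        for f in self.fst_per_cluster:
            if not 0.0 <= f <= 0.25:
                raise ConfigurationError(
                    f"differentiation parameter {f} outside [0, 0.25]")
        if self.cases_per_cluster * self.n_clusters <= 0:
            raise ConfigurationError("need at least one case")
        if not 0.0 < self.prevalence < 0.5:
            raise ConfigurationError("prevalence must be in (0, 0.5)")
        lo, hi = self.common_or_range
        if not 1.0 <= lo <= hi:
            raise ConfigurationError("common_or_range must be ordered, >= 1")
        if len(self.rare_gene_params) != self.n_causal_genes:
            raise ConfigurationError(
                "rare_gene_params length != n_causal_genes")
        for g in self.rare_gene_params:
            if not 0.0 < g.combined_maf < 1.0:
                raise ConfigurationError("gene combined MAF outside (0,1)")
            if g.odds_ratio < 1.0:
                raise ConfigurationError("gene odds ratio must be >= 1")
            if not 0.0 <= g.frac_deleterious <= 1.0:
                raise ConfigurationError("frac_deleterious outside [0,1]")
        m = self.mody_params
        if not 0.0 <= m.case_carrier_rate < 1.0:
            raise ConfigurationError("case carrier rate outside [0,1)")
        if m.case_carrier_rate > 0 and not (
                self.prevalence < m.penetrance <= 1.0):
            raise ConfigurationError(
                "penetrance must be in (prevalence, 1]")
        vlo, vhi = self.variants_per_gene_range
        if not 1 <= vlo <= vhi:
            raise ConfigurationError("variants_per_gene_range invalid")

    @property
    def n_cases(self) -> int:
        return self.cases_per_cluster * self.n_clusters

    @property
    def n_controls(self) -> int:
        return self.controls_per_cluster * self.n_clusters

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rare_gene_params"] = [asdict(g) for g in self.rare_gene_params]
        return d


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage store with per-sample cluster labels."""

    dosages: np.ndarray  # (n_samples, n_variants) int8, values 0/1/2
    sample_ids: list[str]
    variant_ids: list[str]
    clusters: np.ndarray  # (n_samples,) int cluster id

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.variant_ids) != m:
            raise ValueError("GenotypeMatrix dimension mismatch")
        if len(self.clusters) != n:
            raise ValueError("cluster labels do not match samples")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        d = self.dosages if sample_mask is None else self.dosages[sample_mask]
        if d.shape[0] == 0:
            return np.zeros(self.n_variants)
        return d.mean(axis=0) / 2.0

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variant_ids)}


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    annotations: pd.DataFrame  # variant_id, gene, category, af_cluster_*, pathogenic_flag
    samples: pd.DataFrame  # sample_id, status, cluster, age_at_diagnosis, bmi_z, c_peptide, sex
    truth_variants: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_samples: pd.DataFrame
    config: SimulationConfig
    realized_prevalence: float = float("nan")  # pre-ascertainment case rate
    liability_draws: int = 0  # individuals drawn during rejection sampling

    @property
    def case_mask(self) -> np.ndarray:
        return (self.samples["status"] == "case").to_numpy()


# ---------------------------------------------------------------------------
# variant plan and allele frequencies
# ---------------------------------------------------------------------------

def _balding_nichols(rng: np.random.Generator, p: np.ndarray,
                     fst: float) -> np.ndarray:
    if fst == 0.0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-7, 1.0 - 1e-7)


def _split_maf(rng: np.random.Generator, total: float, m: int) -> np.ndarray:
    """Distribute a combined MAF over m variants (Dirichlet split)."""
    w = rng.dirichlet(np.ones(m))
    return total * w


def simulate_frequencies(config: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Build the variant plan: ids, genes, categories, ancestral and
    per-cluster allele frequencies.

    Per-cluster frequencies follow a Balding-Nichols beta around the
    shared ancestral frequency with that cluster's differentiation
    parameter; variants rarer than ``drift_maf_floor`` keep their
    ancestral frequency (rare alleles are young and nearly undrifted,
    and letting them drift would destroy the configured combined MAF).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows: list[dict] = []

    def add(vid, gene, cat, anc, role, flag=0):
        rows.append(dict(variant_id=vid, gene=gene, category=cat,
                         ancestral_af=anc, role=role, pathogenic_flag=flag))

    lo, hi = config.common_maf_range
    # common causal variants, one per pseudo-gene
    for i in range(config.n_common_causal):
        if config.common_variant_params is not None:
            anc = float(config.common_variant_params[i].freq)
        else:
            anc = float(rng.uniform(lo, hi))
        add(f"cv{i+1:03d}", f"CVG{i+1:03d}", "missense_broad",
            anc, "common_causal")
    # common null variants (structure / PCA fodder)
    for i in range(config.n_common_null):
        add(f"cn{i+1:04d}", f"CNG{i+1:04d}",
            "synonymous" if i % 2 else "missense_broad",
            float(rng.uniform(lo, hi)), "common_null")
    # rare causal genes
    vlo, vhi = config.variants_per_gene_range
    for gi, gp in enumerate(config.rare_gene_params):
        gene = f"RG{gi+1:02d}"
        m = int(rng.integers(vlo, vhi + 1))
        mafs = _split_maf(rng, gp.combined_maf, m)
        n_del = max(1, int(round(gp.frac_deleterious * m)))
        cats = (["ptv"] * ((n_del + 1) // 2)
                + ["missense_strict"] * (n_del // 2))
        n_rest = m - n_del
        cats += ["missense_broad"] * ((n_rest + 1) // 2)
        cats += ["synonymous"] * (n_rest // 2)
        rng.shuffle(cats)
        for vi, (p, c) in enumerate(zip(mafs, cats)):
            add(f"{gene.lower()}v{vi+1:02d}", gene, c, float(p), "rare_causal")
    # null genes
    nlo, nhi = config.null_rare_maf_range
    for gi in range(config.n_null_genes):
        gene = f"NG{gi+1:03d}"
        m = int(rng.integers(vlo, vhi + 1))
        cats = rng.choice(CATEGORIES, size=m, p=[0.1, 0.2, 0.4, 0.3])
        mafs = np.exp(rng.uniform(np.log(nlo), np.log(nhi), m))
        for vi, (p, c) in enumerate(zip(mafs, cats)):
            add(f"{gene.lower()}v{vi+1:02d}", gene, str(c), float(p), "null_gene")
    # pathogenic MODY-like variants
    mp = config.mody_params
    if mp.case_carrier_rate > 0:
        carrier_freq = mp.case_carrier_rate * config.prevalence / mp.penetrance
        allele_total = carrier_freq / 2.0
        # even split across registry genes keeps per-gene carrier counts
        # predictable
        per_gene = np.full(mp.n_genes, allele_total / mp.n_genes)
        for gi in range(mp.n_genes):
            gene = f"MG{gi+1:02d}"
            nv = 4
            mafs = _split_maf(rng, float(per_gene[gi]), nv)
            for vi, p in enumerate(mafs):
                cat = "ptv" if vi % 2 == 0 else "missense_strict"
                add(f"{gene.lower()}p{vi+1:02d}", gene, cat, float(p),
                    "mody", flag=1)
        # mixed-signal gene: the last MODY gene also carries ordinary
        # rare causal variants (non-pathogenic), so that leaving MODY
        # carriers out attenuates the pure gene but not this one
        if config.mody_residual_or > 1.0 and mp.n_genes > 0:
            gene = f"MG{mp.n_genes:02d}"
            mafs = _split_maf(rng, config.mody_residual_maf, 6)
            for vi, p in enumerate(mafs):
                add(f"{gene.lower()}r{vi+1:02d}", gene,
                    "ptv" if vi % 2 == 0 else "missense_strict",
                    float(p), "mody_residual")

    plan = pd.DataFrame(rows)
    # per-cluster frequencies
    anc = plan["ancestral_af"].to_numpy()
    drift = anc >= config.drift_maf_floor
    for c, fst in enumerate(config.fst_per_cluster):
        f = anc.copy()
        f[drift] = _balding_nichols(rng, anc[drift], fst)
        plan[f"af_cluster_{c}"] = f
    return plan


# ---------------------------------------------------------------------------
# effects on the liability scale
# ---------------------------------------------------------------------------

def _carrier_liability_shift(odds_ratio: float, carrier_freq: float,
                             k: float) -> float:
    """Liability-mean gap (carrier minus non-carrier) reproducing a
    carrier-level odds ratio at prevalence k."""
    beta = np.log(odds_ratio)
    # two-group penetrance: q*f1 + (1-q)*f0 = k, odds(f1) = OR*odds(f0)
    q = carrier_freq

    def mean_pen(x):
        return (1 - q) * special.expit(x) + q * special.expit(x + beta)

    lo_x, hi_x = -60.0, 60.0
    for _ in range(200):
        mid = 0.5 * (lo_x + hi_x)
        if mean_pen(mid) < k:
            lo_x = mid
        else:
            hi_x = mid
    x0 = 0.5 * (lo_x + hi_x)
    t = float(stats.norm.isf(k))
    f0 = special.expit(x0)
    f1 = special.expit(x0 + beta)
    mu0 = t + special.ndtri(f0)
    mu1 = t + special.ndtri(f1)
    return float(mu1 - mu0)


def _assign_effects(plan: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Attach truth: per-variant log-OR weights, per-allele liability
    shifts (rare) or per-genotype liability means (common), and the
    per-gene truth table."""
    model = LiabilityModel(config.prevalence)
    m = len(plan)
    shift = np.zeros(m)  # per-allele liability shift (rare variants)
    logor = np.zeros(m)  # true per-unit log odds ratio
    mu_geno = np.zeros((m, 3))  # per-genotype liability means (common)
    causal = np.zeros(m, dtype=bool)
    gene_rows = []

    # common causal variants
    cc = plan.index[plan["role"] == "common_causal"]
    if len(cc):
        if config.common_variant_params is not None:
            ors = np.array([cv.odds_ratio
                            for cv in config.common_variant_params])
        else:
            ors = np.exp(rng.uniform(np.log(config.common_or_range[0]),
                                     np.log(config.common_or_range[1]),
                                     len(cc)))
        for idx, or_ in zip(cc, ors):
            p = plan.at[idx, "ancestral_af"]
            mus = genotype_liability_means(np.log(or_), p, model)[0]
            w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            mus = mus - float(w @ mus)
            mu_geno[idx] = mus
            logor[idx] = np.log(or_)
            causal[idx] = True
            gene_rows.append(dict(gene=plan.at[idx, "gene"], kind="common",
                                  odds_ratio=float(or_),
                                  combined_maf=float(p), causal=True))

    # rare causal genes: burden-level OR spread over deleterious variants
    def plant_gene(gene: str, sub: pd.DataFrame, or_: float,
                   kind: str = "rare") -> None:
        mafs = sub["ancestral_af"].to_numpy()
        carrier_freq = float(1.0 - np.prod((1.0 - mafs) ** 2))
        delta = _carrier_liability_shift(or_, carrier_freq, config.prevalence)
        w = sub["category"].map(DELETERIOUSNESS_WEIGHT).to_numpy()
        qv = 2.0 * mafs
        denom = float((qv * w).sum())
        scale = delta * float(qv.sum()) / denom if denom > 0 else 0.0
        shift[sub.index] = w * scale
        logor[sub.index] = np.where(w > 0, np.log(or_), 0.0)
        causal[sub.index] = w > 0
        gene_rows.append(dict(gene=gene, kind=kind, odds_ratio=float(or_),
                              combined_maf=float(mafs.sum()), causal=True))

    for gi, gp in enumerate(config.rare_gene_params):
        gene = f"RG{gi+1:02d}"
        sub = plan[plan["gene"] == gene]
        plant_gene(gene, sub, gp.odds_ratio)

    res = plan[plan["role"] == "mody_residual"]
    if len(res):
        gene = str(res["gene"].iloc[0])
        plant_gene(gene, res, config.mody_residual_or, kind="mody_residual")

    for gi in range(config.mody_params.n_genes
                    if config.mody_params.case_carrier_rate > 0 else 0):
        gene = f"MG{gi+1:02d}"
        sub = plan[(plan["gene"] == gene) & (plan["pathogenic_flag"] == 1)]
        gene_rows.append(dict(gene=gene, kind="mody",
                              odds_ratio=float("nan"),
                              combined_maf=float(sub["ancestral_af"].sum()),
                              causal=True))
        causal[sub.index] = True

    truth = plan[["variant_id", "gene", "category", "role",
                  "pathogenic_flag", "ancestral_af"]].copy()
    truth["causal"] = causal
    truth["true_log_or"] = logor
    truth["liability_shift_per_allele"] = shift
    truth_genes = pd.DataFrame(gene_rows)
    return truth, mu_geno, truth_genes


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort under the liability-threshold model.

    Cases are collected by rejection sampling within each cluster: batches
    of individuals are drawn (genotypes at liability-relevant variants
    only), their liabilities evaluated, and cases/controls kept until the
    configured counts are exact. Genotypes at null variants, which cannot
    influence ascertainment, are drawn afterwards for the kept samples
    only. MODY-like pathogenic carriers receive their case status from
    the configured penetrance directly.
    """
    rng = np.random.default_rng(config.seed)
    plan = simulate_frequencies(config, rng)
    truth_var, mu_geno, truth_genes = _assign_effects(plan, config, rng)

    m = len(plan)
    af = plan[[f"af_cluster_{c}" for c in range(config.n_clusters)]].to_numpy()
    shift = truth_var["liability_shift_per_allele"].to_numpy()
    role = plan["role"].to_numpy()
    flag = plan["pathogenic_flag"].to_numpy() == 1
    liab_idx = np.where((role == "common_causal") | (shift != 0.0) | flag)[0]
    null_idx = np.setdiff1d(np.arange(m), liab_idx)
    common_causal_rows = np.where(role == "common_causal")[0]

    # liability threshold by normal approximation to the genetic score,
    # using pooled (across clusters) moments of the exact per-variant
    # genotype distributions
    mean_g, var_g = _score_moments(af, mu_geno, shift, liab_idx,
                                   common_causal_rows)
    t = mean_g + stats.norm.isf(config.prevalence) * np.sqrt(var_g + 1.0)

    mp = config.mody_params
    max_draws = config.max_liability_draws
    if max_draws is None:
        max_draws = int(60 * config.n_cases / config.prevalence) + 10_000

    kept_dos = []
    kept_cluster = []
    kept_case = []
    total_drawn = 0
    total_cases_drawn = 0
    for c in range(config.n_clusters):
        need_case = config.cases_per_cluster
        need_ctrl = config.controls_per_cluster
        fc = af[liab_idx, c]
        while need_case > 0 or need_ctrl > 0:
            exp_rate = max(config.prevalence, 1e-6)
            batch = int(min(
                200_000,
                max(5_000, 1.3 * need_case / exp_rate, 1.3 * need_ctrl)))
            if total_drawn + batch > max_draws:
                raise AscertainmentError(
                    f"cluster {c}: exceeded {max_draws} liability draws "
                    f"before reaching {config.cases_per_cluster} cases; "
                    "prevalence too small for the requested cohort size")
            total_drawn += batch
            d = rng.binomial(2, fc, size=(batch, len(liab_idx))).astype(np.int8)
            g = d @ shift[liab_idx]
            # per-genotype means for common causal variants
            for pos, row in enumerate(liab_idx):
                if mu_geno[row].any():
                    g = g + mu_geno[row][d[:, pos]]
            liab = g + rng.standard_normal(batch)
            is_case = liab > t
            if mp.case_carrier_rate > 0:
                path_pos = np.where(flag[liab_idx])[0]
                if len(path_pos):
                    carrier = (d[:, path_pos] > 0).any(axis=1)
                    is_case = np.where(
                        carrier,
                        rng.random(batch) < mp.penetrance,
                        is_case)
            total_cases_drawn += int(is_case.sum())
            case_rows = np.where(is_case)[0][:need_case]
            ctrl_rows = np.where(~is_case)[0][:need_ctrl]
            take = np.concatenate([case_rows, ctrl_rows])
            if take.size:
                kept_dos.append(d[take])
                kept_cluster.append(np.full(take.size, c, dtype=np.int32))
                kept_case.append(is_case[take])
            need_case -= len(case_rows)
            need_ctrl -= len(ctrl_rows)

    dos_liab = (np.concatenate(kept_dos, axis=0) if kept_dos
                else np.zeros((0, len(liab_idx)), dtype=np.int8))
    clusters = (np.concatenate(kept_cluster) if kept_cluster
                else np.zeros(0, dtype=np.int32))
    is_case = (np.concatenate(kept_case) if kept_case
               else np.zeros(0, dtype=bool))
    n = dos_liab.shape[0]

    # null genotypes for kept samples only (independent of ascertainment)
    dosages = np.zeros((n, m), dtype=np.int8)
    dosages[:, liab_idx] = dos_liab
    for c in range(config.n_clusters):
        rows = np.where(clusters == c)[0]
        if rows.size and null_idx.size:
            dosages[np.ix_(rows, null_idx)] = rng.binomial(
                2, af[null_idx, c], size=(rows.size, len(null_idx))
            ).astype(np.int8)

    # order: cases first within cluster blocks is fine; build ids
    sample_ids = [f"S{i+1:06d}" for i in range(n)]
    gm = GenotypeMatrix(dosages, sample_ids,
                        plan["variant_id"].tolist(), clusters)

    # true scores on the log-OR scale (what contribution scores estimate)
    rare_mask = (truth_var["causal"] & (shift != 0.0)).to_numpy()
    rare_genes = sorted(plan.loc[rare_mask, "gene"].unique())
    rare_score = np.zeros(n)
    for gene in rare_genes:
        cols = np.where((plan["gene"] == gene).to_numpy() & rare_mask)[0]
        carrier = (dosages[:, cols] > 0).any(axis=1)
        gor = truth_genes.loc[truth_genes["gene"] == gene,
                              "odds_ratio"].iloc[0]
        rare_score += carrier * np.log(gor)
    common_score = dosages[:, common_causal_rows].astype(float) @ \
        truth_var["true_log_or"].to_numpy()[common_causal_rows]
    mody_carrier = (dosages[:, flag] > 0).any(axis=1) if flag.any() \
        else np.zeros(n, dtype=bool)

    samples, truth_samples = _make_phenotypes(
        config, rng, sample_ids, clusters, is_case, rare_score,
        common_score, mody_carrier)

    return SyntheticCohort(
        gm, _annotation_table(plan), samples, truth_var, truth_genes,
        truth_samples, config,
        realized_prevalence=(total_cases_drawn / total_drawn
                             if total_drawn else float("nan")),
        liability_draws=total_drawn)


def _score_moments(af, mu_geno, shift, liab_idx, common_rows):
    """Pooled mean and variance of the genetic liability score."""
    n_clusters = af.shape[1]
    means = np.zeros(n_clusters)
    variances = np.zeros(n_clusters)
    common_set = set(common_rows.tolist())
    for c in range(n_clusters):
        mu_c = 0.0
        var_c = 0.0
        for row in liab_idx:
            p = af[row, c]
            w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
            if row in common_set:
                vals = mu_geno[row]
            else:
                vals = shift[row] * np.arange(3)
            ev = float(w @ vals)
            mu_c += ev
            var_c += float(w @ vals**2) - ev**2
        means[c] = mu_c
        variances[c] = var_c
    mean = float(means.mean())
    var = float(variances.mean() + means.var())
    return mean, var


def _make_phenotypes(config, rng, sample_ids, clusters, is_case,
                     rare_score, common_score, mody_carrier):
    n = len(sample_ids)
    eff = config.phenotype_effects
    noise = config.phenotype_noise
    ref = is_case & ~mody_carrier  # standardization reference: non-MODY cases

    def z(score):
        if ref.sum() >= 2 and score[ref].std() > 0:
            return (score - score[ref].mean()) / score[ref].std()
        return np.zeros_like(score)

    z_rare = z(rare_score)
    z_common = z(common_score)
    sex = rng.integers(0, 2, n)
    age = (noise.age_mean + eff.age_beta_per_sd_rare * z_rare
           + eff.mody_age_shift * mody_carrier
           + rng.normal(0, noise.age_sd, n))
    age = np.where(is_case, age, np.nan)
    bmi = np.where(is_case, noise.bmiz_case_mean, noise.bmiz_control_mean) \
        + eff.mody_bmiz_shift * mody_carrier \
        + rng.normal(0, noise.bmiz_sd, n)
    cpep_log10 = (noise.cpep_log10_mean
                  + eff.cpep_beta_per_sd_common * z_common
                  + eff.mody_cpep_shift * mody_carrier
                  + rng.normal(0, noise.cpep_log10_sd, n))
    samples = pd.DataFrame(dict(
        sample_id=sample_ids,
        status=np.where(is_case, "case", "control"),
        cluster=clusters,
        sex=sex,
        age_at_diagnosis=age,
        bmi_z=bmi,
        c_peptide=10.0 ** cpep_log10,
    ))
    truth_samples = pd.DataFrame(dict(
        sample_id=sample_ids,
        rare_score=rare_score,
        common_score=common_score,
        mody_carrier=mody_carrier,
    ))
    return samples, truth_samples


def _annotation_table(plan: pd.DataFrame) -> pd.DataFrame:
    cols = (["variant_id", "gene", "category"]
            + [c for c in plan.columns if c.startswith("af_cluster_")]
            + ["pathogenic_flag"])
    return plan[cols].copy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict:
    """Write the cohort as VCF + TSVs + a JSON manifest; returns the
    manifest. Genotype round-trips are bit exact."""
    from . import io as bio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "genotypes": "genotypes.vcf",
        "annotations": "annotations.tsv",
        "phenotypes": "phenotypes.tsv",
        "truth_variants": "truth_variants.tsv",
        "truth_genes": "truth_genes.tsv",
        "truth_samples": "truth_samples.tsv",
    }
    try:
        bio.write_vcf(out / files["genotypes"], cohort.genotypes)
        cohort.annotations.to_csv(out / files["annotations"], sep="\t",
                                  index=False)
        cohort.samples.to_csv(out / files["phenotypes"], sep="\t",
                              index=False)
        cohort.truth_variants.to_csv(out / files["truth_variants"], sep="\t",
                                     index=False)
        cohort.truth_genes.to_csv(out / files["truth_genes"], sep="\t",
                                  index=False)
        cohort.truth_samples.to_csv(out / files["truth_samples"], sep="\t",
                                    index=False)
    except OSError as exc:
        raise OSError(f"writing cohort to {out}: {exc}") from exc
    manifest = {
        "seed": cohort.config.seed,
        "n_samples": cohort.genotypes.n_samples,
        "n_variants": cohort.genotypes.n_variants,
        "files": files,
        "config": cohort.config.to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(in_dir: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    from . import io as bio

    d = Path(in_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    cfgd = dict(manifest["config"])
    cfgd["rare_gene_params"] = tuple(
        RareGeneParams(**g) for g in cfgd["rare_gene_params"])
    cfgd["mody_params"] = ModyParams(**cfgd["mody_params"])
    if cfgd.get("common_variant_params") is not None:
        cfgd["common_variant_params"] = tuple(
            CommonVariantParams(**d) for d in cfgd["common_variant_params"])
    cfgd["phenotype_effects"] = PhenotypeEffects(**cfgd["phenotype_effects"])
    cfgd["phenotype_noise"] = PhenotypeNoise(**cfgd["phenotype_noise"])
    for key in ("fst_per_cluster", "common_or_range", "variants_per_gene_range",
                "common_maf_range", "null_rare_maf_range"):
        cfgd[key] = tuple(cfgd[key])
    config = SimulationConfig(**cfgd)
    files = manifest["files"]

    def read_tsv(name: str) -> pd.DataFrame:
        try:
            return pd.read_csv(d / files[name], sep="\t")
        except pd.errors.EmptyDataError:
            return pd.DataFrame()

    samples = pd.read_csv(d / files["phenotypes"], sep="\t",
                          dtype={"sample_id": str})
    sample_ids = samples["sample_id"].tolist()
    clusters = samples["cluster"].to_numpy() if len(samples) else \
        np.zeros(0, dtype=int)
    gm = bio.read_vcf(d / files["genotypes"], clusters=clusters)
    if gm.sample_ids != sample_ids:
        raise ValueError("VCF samples do not match phenotype table")
    return SyntheticCohort(
        gm,
        read_tsv("annotations"),
        samples,
        read_tsv("truth_variants"),
        read_tsv("truth_genes"),
        read_tsv("truth_samples"),
        config,
    )
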