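"""End-to-end pipeline: simulate -> match -> assoc -> enrich ->
architecture -> scores -> report.

Each stage consumes the previous stage's in-memory state and writes its
tables under the output directory; a stage that is toggled off leaves a
hole that downstream stages refuse to cross (with a stage-named error).
A run manifest records the config hash, seed, per-stage row counts and
runtimes, so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .architecture import (AssociationSummary, LiabilityModel, aggregate_lve,
                           effective_sample_size)
from .association import (MaskDefinition, control_allele_freq,
                          gene_level_scan, inflation_diagnostics,
                          single_variant_test)
from .cohort import (SimulationConfig, SyntheticCohort, simulate_cohort,
                     write_cohort)
from .enrichment import (GeneSet, classify_tiers, filter_metabolic_sets,
                         hypergeometric_enrichment, match_background,
                         rank_sum_enrichment)
from .errors import ConfigurationError
from .io import format_pvalues, read_toml
from .matching import compute_pcs, match_controls, project
from .scores import (ScoreWeights, assign_bands, compute_scores, mody_flag,
                     mody_group_comparison, phenotype_regression,
                     rare_fraction_trend)
from .architecture import winners_curse_correct

log = logging.getLogger("burdenarch.pipeline")

STAGES = ("simulate", "match", "assoc", "enrich", "architecture",
          "scores", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "burdenarch_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    simulate: dict = field(default_factory=dict)
    n_pcs: int = 4
    max_ratio: int = 4
    caliper: float | None = None
    k_clusters: int | None = None
    exome_wide_p: float = 2.5e-6
    nominal_p: float = 0.05
    or_bands: tuple[float, ...] = (5.0, 3.0)
    top_k: int = 20
    prevalence: float = 0.01
    prevalence_grid: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05)
    n_bootstrap: int = 500

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = read_toml(path)
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown config key '{key}'")
            if key in ("or_bands", "prevalence_grid"):
                val = tuple(val)
            if key == "stages":
                bad = set(val) - set(STAGES)
                if bad:
                    raise ConfigurationError(f"unknown stages {sorted(bad)}")
                merged = {s: True for s in STAGES}
                merged.update(val)
                val = merged
            setattr(cfg, key, val)
        return cfg

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, n_rows: int, seconds: float) -> None:
        self.stages[stage] = {"rows": n_rows,
                              "seconds": round(seconds, 3)}


class PipelineState:
    """Artifacts handed from stage to stage."""

    def __init__(self) -> None:
        self.cohort: SyntheticCohort | None = None
        self.matched_ids: list[str] | None = None
        self.covariates: np.ndarray | None = None
        self.analysis_rows: np.ndarray | None = None
        self.assoc_gene: pd.DataFrame | None = None
        self.assoc_single: pd.DataFrame | None = None
        self.gene_sets: list[GeneSet] | None = None
        self.enriched_sets: list[GeneSet] | None = None
        self.tiers: pd.DataFrame | None = None
        self.scores: pd.DataFrame | None = None

    def require(self, attr: str, needed_by: str, produced_by: str):
        val = getattr(self, attr)
        if val is None:
            raise ConfigurationError(
                f"stage '{needed_by}' requires output of stage "
                f"'{produced_by}', which did not run")
        return val


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.hash(), config.seed, __version__)
    state = PipelineState()
    for stage in STAGES:
        if not config.stages.get(stage, True):
            log.info("[%s] skipped (toggled off)", stage)
            continue
        t0 = time.time()
        try:
            n = _STAGE_FUNCS[stage](config, state, out)
        except Exception as exc:
            raise type(exc)(f"stage '{stage}': {exc}") from exc
        manifest.record(stage, n, time.time() - t0)
        log.info("[%s] done: %d rows in %.2fs", stage, n,
                 time.time() - t0)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, state: PipelineState,
                    out: Path) -> int:
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    sim_kwargs.setdefault("prevalence", config.prevalence)
    sim = SimulationConfig(**sim_kwargs)
    state.cohort = simulate_cohort(sim)
    write_cohort(state.cohort, out / "cohort")
    return state.cohort.genotypes.n_samples


def _stage_match(config: PipelineConfig, state: PipelineState,
                 out: Path) -> int:
    cohort = state.require("cohort", "match", "simulate")
    gm = cohort.genotypes
    case = cohort.case_mask
    pcs = compute_pcs(gm.dosages[case], config.n_pcs)
    ctrl_coords = project(pcs, gm.dosages[~case])
    case_ids = [s for s, c in zip(gm.sample_ids, case) if c]
    ctrl_ids = [s for s, c in zip(gm.sample_ids, case) if not c]
    res = match_controls(pcs.coords, ctrl_coords, case_ids, ctrl_ids,
                         max_ratio=config.max_ratio,
                         caliper=config.caliper,
                         k_clusters=config.k_clusters, seed=config.seed)
    state.matched_ids = sorted(set(case_ids) | set(res.selected_controls))
    id_to_row = {s: i for i, s in enumerate(gm.sample_ids)}
    state.analysis_rows = np.array([id_to_row[s] for s in state.matched_ids])
    # covariates: top PCs + cluster indicators for the analysis set
    all_coords = np.zeros((gm.n_samples, config.n_pcs))
    all_coords[case] = pcs.coords
    all_coords[~case] = ctrl_coords
    rows = state.analysis_rows
    covs = [all_coords[rows]]
    clus = gm.clusters[rows]
    for c in np.unique(clus)[1:]:
        covs.append((clus == c).astype(float)[:, None])
    state.covariates = np.column_stack([np.asarray(c) for c in covs])
    pd.DataFrame(all_coords[rows],
                 columns=[f"pc{i+1}" for i in range(config.n_pcs)],
                 index=state.matched_ids).rename_axis("sample_id") \
        .to_csv(out / "pcs.tsv", sep="\t")
    pd.DataFrame({"sample_id": state.matched_ids,
                  "cluster": clus}).to_csv(out / "clusters.tsv", sep="\t",
                                           index=False)
    pd.DataFrame({"control_id": res.selected_controls}).to_csv(
        out / "matched_controls.tsv", sep="\t", index=False)
    with open(out / "matching.json", "w") as fh:
        json.dump({"n_cases": len(case_ids),
                   "n_controls": len(res.selected_controls),
                   "effective_n": effective_sample_size(
                       len(case_ids), max(len(res.selected_controls), 1)),
                   "dropped_clusters": res.dropped_clusters}, fh, indent=2)
    return len(state.matched_ids)


def _analysis_arrays(state: PipelineState):
    cohort = state.cohort
    rows = state.analysis_rows
    dos = cohort.genotypes.dosages[rows]
    case = cohort.case_mask[rows]
    return dos, case


def _stage_assoc(config: PipelineConfig, state: PipelineState,
                 out: Path) -> int:
    cohort = state.require("cohort", "assoc", "simulate")
    state.require("analysis_rows", "assoc", "match")
    dos, case = _analysis_arrays(state)
    ann = cohort.annotations
    # single-variant tests on common variants
    af = dos.mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    common_idx = np.where(maf >= 0.01)[0]
    singles = single_variant_test(
        dos[:, common_idx], case, state.covariates,
        [cohort.genotypes.variant_ids[j] for j in common_idx])
    state.assoc_single = pd.DataFrame(
        [dict(variant_id=v.variant_id, beta=v.beta, se=v.se, p=v.p,
              odds_ratio=np.exp(v.beta) if np.isfinite(v.beta) else np.nan,
              maf=v.maf, n_carriers=v.n_carriers,
              skipped=v.skipped or "") for v in singles])
    state.assoc_gene = gene_level_scan(dos, case, state.covariates, ann)
    syn = gene_level_scan(dos, case, state.covariates, ann,
                          synonymous_control=True)
    diag: dict = {}
    pv = state.assoc_single["p"].dropna().to_numpy()
    if pv.size >= 2:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diag["lambda_single"] = inflation_diagnostics(pv)["lambda_gc"]
            gp = state.assoc_gene["corrected_p"].dropna().to_numpy()
            if gp.size:
                diag["lambda_gene"] = inflation_diagnostics(gp)["lambda_gc"]
    diag["synonymous_significant"] = int(
        (syn["corrected_p"] < config.exome_wide_p).sum()) if len(syn) else 0
    format_pvalues(state.assoc_single, ("p",)).to_csv(
        out / "assoc_single.tsv", sep="\t", index=False)
    format_pvalues(state.assoc_gene, ("min_p", "corrected_p")).to_csv(
        out / "assoc_gene.tsv", sep="\t", index=False)
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2)
    return len(state.assoc_gene)


def _default_gene_sets(cohort: SyntheticCohort,
                       rng: np.random.Generator) -> list[GeneSet]:
    """Synthetic stand-in gene sets built from the cohort's gene universe
    (labelled synthetic; real analyses supply a GMT)."""
    genes = sorted(cohort.annotations["gene"].unique())
    causal = set(cohort.truth_genes.loc[
        cohort.truth_genes["kind"].isin(["rare", "mody_residual"]),
        "gene"])
    nulls = [g for g in genes if g not in causal]
    sets = []
    causal_sorted = sorted(causal)
    pad = list(rng.choice(nulls, size=min(10, len(nulls)), replace=False))
    sets.append(GeneSet("HP_SYNTH_DIABETES", frozenset(causal_sorted + pad),
                        source="synthetic"))
    half = causal_sorted[: max(1, len(causal_sorted) // 2)]
    pad2 = list(rng.choice(nulls, size=min(15, len(nulls)), replace=False))
    sets.append(GeneSet("HP_SYNTH_INSULIN_SECRETION",
                        frozenset(half + pad2), source="synthetic"))
    for i in range(4):
        members = rng.choice(nulls, size=min(20, len(nulls)), replace=False)
        sets.append(GeneSet(f"HP_SYNTH_NULL_{i+1}",
                            frozenset(members.tolist()), source="synthetic"))
    return sets


def _stage_enrich(config: PipelineConfig, state: PipelineState,
                  out: Path) -> int:
    cohort = state.require("cohort", "enrich", "simulate")
    gene_res = state.require("assoc_gene", "enrich", "assoc")
    rng = np.random.default_rng(config.seed + 1)
    if state.gene_sets is None:
        state.gene_sets = _default_gene_sets(cohort, rng)
    universe = gene_res["gene"].tolist()
    pvals = gene_res.set_index("gene")["corrected_p"]
    stats_df = gene_res.set_index("gene")[["n_variants", "combined_maf"]]
    top = gene_res.nsmallest(config.top_k, "corrected_p")["gene"].tolist()
    rows = []
    metabolic = filter_metabolic_sets(
        state.gene_sets, ("diabetes", "insulin", "hyperglycemia",
                          "overweight", "waist", "c-peptide"))
    enriched = []
    for gs in state.gene_sets:
        try:
            hyper = hypergeometric_enrichment(top, gs, universe)
        except ConfigurationError:
            continue
        bg = match_background(
            [g for g in gs.genes if g in stats_df.index], stats_df, rng=rng)
        try:
            ranks = rank_sum_enrichment(gs, pvals, bg, config.nominal_p)
        except ConfigurationError:
            continue
        rows.append(dict(set=gs.name, method="hypergeometric",
                         fold=hyper.fold, p=hyper.p,
                         contributing=",".join(hyper.contributing_genes)))
        rows.append(dict(set=gs.name, method="rank-sum", fold=ranks.fold,
                         p=ranks.p,
                         contributing=",".join(ranks.contributing_genes)))
        if gs.name in metabolic and ranks.p < config.nominal_p:
            enriched.append(gs)
    state.enriched_sets = enriched
    known = {"monogenic_diabetes": set(
        cohort.truth_genes.loc[cohort.truth_genes["kind"] == "mody", "gene"])}
    tiers = classify_tiers(gene_res, known, enriched, top_k=config.top_k,
                           exome_threshold=config.exome_wide_p,
                           nominal=config.nominal_p)
    state.tiers = pd.DataFrame(
        [dict(gene=t.gene, tier=t.tier if t.tier else 0,
              justification=t.justification) for t in tiers])
    enr = pd.DataFrame(rows)
    format_pvalues(enr, ("p",)).to_csv(out / "enrichment.tsv", sep="\t",
                                       index=False)
    state.tiers.to_csv(out / "tiers.tsv", sep="\t", index=False)
    return len(enr)


def _stage_architecture(config: PipelineConfig, state: PipelineState,
                        out: Path) -> int:
    gene_res = state.require("assoc_gene", "architecture", "assoc")
    single = state.require("assoc_single", "architecture", "assoc")
    from scipy import stats as sps

    z_nominal = float(sps.norm.isf(config.nominal_p / 2))
    rare_units = []
    for _, r in gene_res.nsmallest(10, "corrected_p").iterrows():
        if not np.isfinite(r["beta"]) or r["combined_maf"] <= 0 or \
                r["p" if "p" in r else "min_p"] >= config.nominal_p:
            continue
        if abs(r["beta"]) / r["se"] < z_nominal:
            continue
        rare_units.append(AssociationSummary(
            r["gene"], float(r["beta"]), float(r["se"]),
            min(max(float(r["combined_maf"]), 1e-6), 0.99),
            study="cohort", z_c=z_nominal))
    ok = single.dropna(subset=["p"])
    common_units = []
    for _, r in ok.nsmallest(10, "p").iterrows():
        if abs(r["beta"]) / r["se"] < z_nominal:
            continue
        common_units.append(AssociationSummary(
            r["variant_id"], float(r["beta"]), float(r["se"]),
            min(max(float(r["maf"]), 1e-6), 0.99),
            study="cohort", z_c=z_nominal))
    rng = np.random.default_rng(config.seed + 2)
    report: dict = {"prevalence_sensitivity": []}
    rows = []
    for k in config.prevalence_grid:
        model = LiabilityModel(k)
        est_r = aggregate_lve(rare_units, model,
                              n_bootstrap=config.n_bootstrap, rng=rng)
        est_c = aggregate_lve(common_units, model,
                              n_bootstrap=config.n_bootstrap, rng=rng)
        report["prevalence_sensitivity"].append(dict(
            prevalence=k,
            rare_lve=est_r.point, rare_ci=[est_r.ci_low, est_r.ci_high],
            common_lve=est_c.point,
            common_ci=[est_c.ci_low, est_c.ci_high]))
        if abs(k - config.prevalence) < 1e-12:
            for unit, v in est_r.per_unit.items():
                rows.append(dict(unit=unit, kind="rare", lve=v))
            for unit, v in est_c.per_unit.items():
                rows.append(dict(unit=unit, kind="common", lve=v))
    pd.DataFrame(rows).to_csv(out / "lve.tsv", sep="\t", index=False)
    with open(out / "architecture_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return len(rows)


def _stage_scores(config: PipelineConfig, state: PipelineState,
                  out: Path) -> int:
    cohort = state.require("cohort", "scores", "simulate")
    gene_res = state.require("assoc_gene", "scores", "assoc")
    single = state.require("assoc_single", "scores", "assoc")
    from scipy import stats as sps

    dos, case = _analysis_arrays(state)
    ids = [cohort.genotypes.sample_ids[i] for i in state.analysis_rows]
    z_nom = float(sps.norm.isf(config.nominal_p / 2))
    rare_w = {}
    pool = state.tiers[state.tiers["tier"].isin([1, 2, 3, 4])]["gene"] \
        if state.tiers is not None else gene_res[
            gene_res["min_p"] < config.nominal_p]["gene"]
    for _, r in gene_res[gene_res["gene"].isin(set(pool))].iterrows():
        if not np.isfinite(r["beta"]) or abs(r["beta"]) / r["se"] < z_nom:
            continue
        rare_w[r["gene"]] = float(winners_curse_correct(
            r["beta"], r["se"], z_nom))
    common_w = {}
    for _, r in single.dropna(subset=["p"]).nsmallest(20, "p").iterrows():
        if abs(r["beta"]) / r["se"] < z_nom:
            continue
        common_w[r["variant_id"]] = float(winners_curse_correct(
            r["beta"], r["se"], z_nom))
    registry = set(cohort.truth_genes.loc[
        cohort.truth_genes["kind"] == "mody", "gene"])
    flags = mody_flag(dos, cohort.annotations, registry)
    weights = ScoreWeights(rare=rare_w, common=common_w)
    sc = compute_scores(dos, cohort.annotations, weights, ids,
                        is_case=case, mody_flags=flags)
    sc = assign_bands(sc, config.or_bands)
    state.scores = sc
    phen = cohort.samples
    sc.to_csv(out / "scores.tsv", sep="\t", index=False)
    sc[["sample_id", "band"]].to_csv(out / "bands.tsv", sep="\t",
                                     index=False)
    regs = []
    for col in ("rare_log_or", "common_log_or"):
        try:
            regs.append(phenotype_regression(sc, phen, score_col=col))
        except ConfigurationError:
            pass
    reg_df = pd.concat(regs, ignore_index=True) if regs else pd.DataFrame()
    if len(reg_df):
        format_pvalues(reg_df, ("p",)).to_csv(
            out / "phenotype_assoc.tsv", sep="\t", index=False)
    comp = mody_group_comparison(sc, phen)
    if len(comp):
        format_pvalues(comp, ("p",)).to_csv(out / "mody_comparison.tsv",
                                            sep="\t", index=False)
    try:
        trend, rho, p = rare_fraction_trend(sc, bin_size=25)
        trend.to_csv(out / "rare_fraction_trend.tsv", sep="\t", index=False)
    except ConfigurationError:
        pass
    return len(sc)


def _stage_report(config: PipelineConfig, state: PipelineState,
                  out: Path) -> int:
    summary = {}
    if state.assoc_gene is not None:
        summary["n_genes_tested"] = int(len(state.assoc_gene))
        summary["n_exome_wide"] = int(
            (state.assoc_gene["corrected_p"] < config.exome_wide_p).sum())
    if state.scores is not None:
        bands = state.scores["band"].value_counts().to_dict()
        summary["band_counts"] = {k: int(v) for k, v in bands.items()}
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return len(summary)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "match": _stage_match,
    "assoc": _stage_assoc,
    "enrich": _stage_enrich,
    "architecture": _stage_architecture,
    "scores": _stage_scores,
    "report": _stage_report,
}
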