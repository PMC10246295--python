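"""Synthetic cohort generator: frequencies, ascertainment, truth, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burdenarch.cohort import (ModyParams, RareGeneParams, SimulationConfig,
                               simulate_cohort, simulate_frequencies,
                               read_cohort, write_cohort)
from burdenarch.errors import AscertainmentError, ConfigurationError
from burdenarch.firth import fit_logistic

from oracles import draw_case_control_genotypes


def small_config(**kw):
    base = dict(seed=1, n_clusters=2, cases_per_cluster=100,
                controls_per_cluster=200, fst_per_cluster=0.1,
                prevalence=0.1, n_null_genes=10, n_common_null=30,
                variants_per_gene_range=(4, 8))
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_bad_fst_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(fst_per_cluster=0.4)

    def test_penetrance_must_exceed_prevalence(self):
        with pytest.raises(ConfigurationError):
            small_config(mody_params=ModyParams(0.02, penetrance=0.05))

    def test_or_range_ordered(self):
        with pytest.raises(ConfigurationError):
            small_config(common_or_range=(1.5, 1.1))


class TestFrequencies:
    def test_zero_fst_is_identity(self):
        cfg = small_config(fst_per_cluster=0.0)
        plan = simulate_frequencies(cfg)
        for c in range(cfg.n_clusters):
            np.testing.assert_allclose(plan[f"af_cluster_{c}"],
                                       plan["ancestral_af"])

    def test_balding_nichols_variance(self, rng):
        # Var(cluster freq) = F p (1-p) for the Balding-Nichols beta
        from burdenarch.cohort import _balding_nichols
        p = np.full(10_000, 0.5)
        draws = _balding_nichols(rng, p, 0.1)
        expected = 0.1 * 0.5 * 0.5
        assert draws.var() == pytest.approx(expected, rel=0.1)

    def test_configured_combined_maf_realized(self, rng):
        # a 21-variant gene at combined MAF 0.0038 keeps that frequency
        # in a 100k-haplotype draw
        cfg = small_config(
            n_causal_genes=1,
            rare_gene_params=(RareGeneParams(0.0038, 7.5, 0.8),),
            variants_per_gene_range=(21, 21))
        plan = simulate_frequencies(cfg)
        gene = plan[plan["gene"] == "RG01"]
        assert len(gene) == 21
        mafs = gene["af_cluster_0"].to_numpy()
        alt = rng.binomial(100_000, mafs).sum()
        assert 0.003 <= alt / 100_000 <= 0.005

    def test_every_variant_has_one_gene(self):
        plan = simulate_frequencies(small_config())
        assert plan["variant_id"].is_unique
        assert plan.groupby("variant_id")["gene"].nunique().max() == 1


class TestCohortSimulation:
    def test_counts_exact(self, signal_cohort):
        cfg = signal_cohort.config
        status = signal_cohort.samples["status"]
        assert (status == "case").sum() == cfg.n_cases
        assert (status == "control").sum() == cfg.n_controls
        for c in range(cfg.n_clusters):
            sub = signal_cohort.samples[signal_cohort.samples.cluster == c]
            assert (sub.status == "case").sum() == cfg.cases_per_cluster

    def test_hwe_within_cluster_under_null(self, null_cohort):
        # chi-square GOF not rejected at alpha=0.001 for >=99% of
        # common variants
        gm = null_cohort.genotypes
        af = gm.allele_freq()
        common = np.where(np.minimum(af, 1 - af) >= 0.05)[0]
        n = gm.n_samples
        rejected = 0
        for j in common:
            counts = np.bincount(gm.dosages[:, j], minlength=3)
            p = af[j]
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            chi2 = ((counts - exp) ** 2 / np.maximum(exp, 1e-9)).sum()
            if stats.chi2.sf(chi2, df=1) < 0.001:
                rejected += 1
        assert rejected / len(common) <= 0.01

    def test_null_cohort_status_independent_of_genotype(self, null_cohort):
        # carrier frequencies agree between cases and controls
        gm = null_cohort.genotypes
        case = null_cohort.case_mask
        af_case = gm.allele_freq(case)
        af_ctrl = gm.allele_freq(~case)
        af = gm.allele_freq()
        common = af > 0.05
        n1, n2 = case.sum(), (~case).sum()
        se = np.sqrt(af * (1 - af) * (1 / (2 * n1) + 1 / (2 * n2)))
        z = np.abs(af_case - af_ctrl)[common] / se[common]
        assert (z > 4).mean() < 0.01

    def test_realized_prevalence_near_configured(self):
        cfg = small_config(seed=5, prevalence=0.08,
                           cases_per_cluster=300, controls_per_cluster=300)
        cohort = simulate_cohort(cfg)
        prev = cohort.realized_prevalence
        n = cohort.liability_draws
        se = np.sqrt(0.08 * 0.92 / n)
        assert abs(prev - 0.08) < 3 * se + 0.01

    def test_mody_case_carrier_rate(self):
        cfg = SimulationConfig(
            seed=8, n_clusters=1, cases_per_cluster=3000,
            controls_per_cluster=500, fst_per_cluster=0.0, prevalence=0.05,
            n_common_causal=0, n_causal_genes=0, rare_gene_params=(),
            mody_params=ModyParams(0.021, 0.7), mody_residual_or=0.0,
            n_null_genes=3, n_common_null=5)
        cohort = simulate_cohort(cfg)
        rate = cohort.truth_samples.loc[cohort.case_mask,
                                        "mody_carrier"].mean()
        assert 0.015 <= rate <= 0.027

    def test_infeasible_ascertainment_raises(self):
        cfg = small_config(prevalence=0.001, cases_per_cluster=5000,
                           max_liability_draws=20_000)
        with pytest.raises(AscertainmentError):
            simulate_cohort(cfg)

    def test_truth_identifies_causal_variants(self, signal_cohort):
        tv = signal_cohort.truth_variants
        causal_genes = set(tv.loc[tv.causal, "gene"])
        assert {"RG01", "RG02", "RG03", "RG04"} <= causal_genes
        assert not any(g.startswith("NG") for g in causal_genes)
        # causal variants with expected carriers >= 10 all have carriers
        gm = signal_cohort.genotypes
        counts = (gm.dosages > 0).sum(axis=0)
        exp = 2 * gm.n_samples * tv["ancestral_af"].to_numpy()
        hot = tv.causal.to_numpy() & (exp >= 10)
        assert counts[hot].min() > 0

    def test_age_only_for_cases(self, signal_cohort):
        s = signal_cohort.samples
        assert s.loc[s.status == "case", "age_at_diagnosis"].notna().all()
        assert s.loc[s.status == "control", "age_at_diagnosis"].isna().all()
        assert (s["c_peptide"] > 0).all()

    def test_common_or_coverage(self, rng):
        # logistic CI covers the generating OR: genotypes drawn straight
        # from the penetrance model (independent generating route)
        beta = np.log(1.5)
        cover = 0
        reps = 150
        for _ in range(reps):
            gc, gt = draw_case_control_genotypes(beta, 0.3, 0.05,
                                                 600, 1800, rng)
            g = np.concatenate([gc, gt]).astype(float)
            y = np.r_[np.ones(len(gc)), np.zeros(len(gt))]
            X = np.column_stack([np.ones(len(g)), g])
            fit = fit_logistic(X, y, firth=False)
            lo = fit.beta[1] - 1.96 * fit.se[1]
            hi = fit.beta[1] + 1.96 * fit.se[1]
            cover += lo <= beta <= hi
        assert cover / reps >= 0.90


class TestCohortIO:
    def test_round_trip_identity(self, tmp_path):
        cohort = simulate_cohort(small_config(seed=3))
        write_cohort(cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        np.testing.assert_array_equal(back.genotypes.dosages,
                                      cohort.genotypes.dosages)
        assert back.genotypes.variant_ids == cohort.genotypes.variant_ids
        assert back.genotypes.sample_ids == cohort.genotypes.sample_ids
        pd.testing.assert_frame_equal(back.annotations, cohort.annotations)

    def test_vcf_samples_match_phenotypes(self, tmp_path):
        cohort = simulate_cohort(small_config(seed=4))
        manifest = write_cohort(cohort, tmp_path / "c")
        assert manifest["n_samples"] == len(cohort.samples)
        vcf_header = None
        with open(tmp_path / "c" / "genotypes.vcf") as fh:
            for line in fh:
                if line.startswith("#CHROM"):
                    vcf_header = line.rstrip("\n").split("\t")
                    break
        assert len(vcf_header) - 9 == len(cohort.samples)

    def test_empty_cohort_files_headered(self, tmp_path):
        from burdenarch.cohort import GenotypeMatrix, SyntheticCohort
        cfg = small_config()
        empty = SyntheticCohort(
            GenotypeMatrix(np.zeros((0, 0), dtype=np.int8), [], [],
                           np.zeros(0, dtype=int)),
            pd.DataFrame(columns=["variant_id", "gene", "category",
                                  "af_cluster_0", "pathogenic_flag"]),
            pd.DataFrame(columns=["sample_id", "status", "cluster", "sex",
                                  "age_at_diagnosis", "bmi_z", "c_peptide"]),
            pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), cfg)
        write_cohort(empty, tmp_path / "e")
        back = read_cohort(tmp_path / "e")
        assert back.genotypes.n_samples == 0
        assert list(back.samples.columns)[:2] == ["sample_id", "status"]
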