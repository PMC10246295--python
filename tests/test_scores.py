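"""Contribution scores, risk bands, trend and phenotype regressions."""

import numpy as np
import pandas as pd
import pytest

from burdenarch.errors import ConfigurationError
from burdenarch.scores import (ScoreWeights, assign_bands, compute_scores,
                               mody_flag, mody_group_comparison,
                               phenotype_regression, rare_fraction_trend)


def _toy_cohort():
    ann = pd.DataFrame(dict(
        variant_id=["a1", "a2", "b1", "c1", "p1"],
        gene=["GA", "GA", "GB", "GC", "GM"],
        category=["ptv", "missense_strict", "ptv", "missense_broad", "ptv"],
        af_cluster_0=[1e-3] * 5,
        pathogenic_flag=[0, 0, 0, 0, 1]))
    # sample 0: carries GA+GB; 1: GB; 2: nothing; 3: pathogenic.
    # 50 samples keep the sample allele frequencies below mask ceilings.
    n = 50
    dos = np.zeros((n, 5), dtype=np.int8)
    dos[0, 0] = 1
    dos[0, 2] = 1
    dos[1, 2] = 1
    dos[3, 4] = 1
    ids = [f"s{i}" for i in range(n)]
    return ann, dos, ids


class TestComputeScores:
    def test_carrier_of_two_genes_multiplies_ors(self):
        ann, dos, ids = _toy_cohort()
        w = ScoreWeights(rare={"GA": np.log(2.0), "GB": np.log(3.0)})
        sc = compute_scores(dos, ann, w, ids)
        assert sc.loc[0, "rare_or"] == pytest.approx(6.0)
        assert sc.loc[1, "rare_or"] == pytest.approx(3.0)

    def test_no_carriage_scores_or_one(self):
        ann, dos, ids = _toy_cohort()
        w = ScoreWeights(rare={"GA": 0.7})
        sc = compute_scores(dos, ann, w, ids)
        assert sc.loc[2, "rare_or"] == pytest.approx(1.0)
        assert sc.loc[2, "combined_or"] == pytest.approx(1.0)

    def test_combined_is_log_sum(self, rng):
        ann, dos, ids = _toy_cohort()
        w = ScoreWeights(rare={"GA": 0.5}, common={"a2": 0.2})
        sc = compute_scores(dos, ann, w, ids, center_common=False)
        np.testing.assert_allclose(
            sc["combined_log_or"], sc["rare_log_or"] + sc["common_log_or"])

    def test_doubling_weights_doubles_log_scores(self):
        ann, dos, ids = _toy_cohort()
        w1 = ScoreWeights(rare={"GA": 0.5, "GB": 0.3}, common={"c1": 0.1})
        w2 = ScoreWeights(rare={"GA": 1.0, "GB": 0.6}, common={"c1": 0.2})
        s1 = compute_scores(dos, ann, w1, ids)
        s2 = compute_scores(dos, ann, w2, ids)
        np.testing.assert_allclose(2 * s1["combined_log_or"],
                                   s2["combined_log_or"], atol=1e-12)

    def test_permutation_equivariance(self, rng):
        ann, dos, ids = _toy_cohort()
        w = ScoreWeights(rare={"GA": 0.5, "GB": 0.3})
        perm = rng.permutation(len(ids))
        s1 = compute_scores(dos, ann, w, ids)
        s2 = compute_scores(dos[perm], ann, w, [ids[i] for i in perm])
        merged = s1.merge(s2, on="sample_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["rare_log_or_a"],
                                   merged["rare_log_or_b"])

    def test_absent_unit_skipped(self, caplog):
        ann, dos, ids = _toy_cohort()
        w = ScoreWeights(rare={"NOPE": 0.5}, common={"missing": 0.1})
        sc = compute_scores(dos, ann, w, ids)
        assert (sc["combined_log_or"] == 0).all()

    def test_nonfinite_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            ScoreWeights(rare={"GA": float("inf")})


class TestModyFlag:
    def test_no_pathogenic_variants_no_flags(self):
        ann, dos, ids = _toy_cohort()
        ann = ann.assign(pathogenic_flag=0)
        flags = mody_flag(dos, ann, {"GM"})
        assert not flags.any()

    def test_registry_restricts_flags(self):
        ann, dos, ids = _toy_cohort()
        assert mody_flag(dos, ann, {"GM"}).sum() == 1
        assert mody_flag(dos, ann, {"GA"}).sum() == 0

    def test_planted_carrier_rate_recovered(self, signal_cohort):
        registry = set(signal_cohort.truth_genes.loc[
            signal_cohort.truth_genes["kind"] == "mody", "gene"])
        flags = mody_flag(signal_cohort.genotypes.dosages,
                          signal_cohort.annotations, registry)
        case = signal_cohort.case_mask
        rate = flags[case].mean()
        n = int(case.sum())
        target = signal_cohort.config.mody_params.case_carrier_rate
        se = np.sqrt(target * (1 - target) / n)
        assert abs(rate - target) < 3 * se


class TestBands:
    def _scores(self, rows):
        df = pd.DataFrame(rows, columns=["rare_or", "common_or", "mody"])
        for c in ("rare", "common"):
            df[f"{c}_log_or"] = np.log(df[f"{c}_or"])
        df["combined_log_or"] = df["rare_log_or"] + df["common_log_or"]
        df["combined_or"] = np.exp(df["combined_log_or"])
        df["sample_id"] = [f"s{i}" for i in range(len(df))]
        return df

    def test_mody_precedence_over_high_common(self):
        sc = assign_bands(self._scores([(1.0, 10.0, True)]))
        assert sc["band"].iloc[0] == "MODY"

    def test_mid_band_rare_precedence(self):
        sc = assign_bands(self._scores([(4.2, 1.1, False)]))
        assert sc["band"].iloc[0] == "rare 3-5"

    def test_combined_only_band(self):
        sc = assign_bands(self._scores([(2.4, 2.4, False)]))
        assert sc["band"].iloc[0] == "combined >=5"

    def test_partition_of_cohort(self, rng):
        n = 500
        rows = [(float(np.exp(rng.normal(0, 0.8))),
                 float(np.exp(rng.normal(0, 0.8))),
                 bool(rng.random() < 0.02)) for _ in range(n)]
        sc = assign_bands(self._scores(rows))
        assert sc["band"].notna().all()
        assert len(sc) == n  # every sample exactly one band incl. 'none'
        assert sc["band"].value_counts().sum() == n

    def test_non_descending_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_bands(self._scores([(1.0, 1.0, False)]),
                         thresholds=(3.0, 5.0))


class TestRareFractionTrend:
    def _mk(self, rare, common):
        df = pd.DataFrame(dict(rare_log_or=rare, common_log_or=common))
        df["combined_log_or"] = df["rare_log_or"] + df["common_log_or"]
        for c in ("rare", "common", "combined"):
            df[f"{c}_or"] = np.exp(df[f"{c}_log_or"])
        df["sample_id"] = [f"s{i}" for i in range(len(df))]
        df["mody"] = False
        return df

    def test_identical_scores_flat(self):
        sc = self._mk([1.0] * 200, [0.8] * 200)
        table, rho, _ = rare_fraction_trend(sc, bin_size=50)
        assert rho == pytest.approx(0.0)
        assert table["mean_rare_fraction"].nunique() == 1

    def test_planted_fraction_recovered(self, rng):
        # one bin of 50 with rare share planted at 0.50
        total = rng.uniform(1.2, 2.5, 50)
        frac = rng.normal(0.50, 0.02, 50)
        sc = self._mk(total * frac, total * (1 - frac))
        table, _, _ = rare_fraction_trend(sc, bin_size=50)
        assert 0.45 <= table["mean_rare_fraction"].iloc[0] <= 0.55

    def test_planted_decreasing_trend_detected(self, rng):
        hits = 0
        reps = 25
        for i in range(reps):
            r = np.random.default_rng(i)
            n = 400
            total = np.sort(r.uniform(1.2, 3.0, n))[::-1]
            frac = np.clip(0.55 - 0.3 * np.arange(n) / n
                           + r.normal(0, 0.05, n), 0.05, 0.95)
            sc = self._mk(total * frac, total * (1 - frac))
            _, rho, p = rare_fraction_trend(sc, bin_size=50)
            hits += (rho < 0) and (p < 0.05)
        assert hits / reps >= 0.8

    def test_too_few_samples_error(self):
        sc = self._mk([1.0] * 10, [1.0] * 10)
        with pytest.raises(ConfigurationError):
            rare_fraction_trend(sc, bin_size=50)


class TestPhenotypeRegression:
    def _phen(self, rng, n, score, beta):
        return pd.DataFrame(dict(
            sample_id=[f"s{i}" for i in range(n)],
            status="case",
            sex=rng.integers(0, 2, n),
            cluster=rng.integers(0, 2, n),
            age_at_diagnosis=13.6 + beta * score + rng.normal(0, 2.3, n),
            bmi_z=rng.normal(2.2, 0.6, n),
            c_peptide=10 ** rng.normal(0.55, 0.33, n)))

    def test_null_type_one_error(self, rng):
        n, reps, hits = 150, 400, 0
        for _ in range(reps):
            score = rng.standard_normal(n)
            sc = pd.DataFrame(dict(sample_id=[f"s{i}" for i in range(n)],
                                   rare_log_or=score, mody=False))
            phen = self._phen(rng, n, np.zeros(n), 0.0)
            res = phenotype_regression(sc, phen,
                                       phenotype_cols=("age_at_diagnosis",))
            hits += res["p"].iloc[0] < 0.05
        assert 0.025 <= hits / reps <= 0.075

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(7)
        n = 3000
        score = rng.standard_normal(n)
        z = (score - score.mean()) / score.std()
        sc = pd.DataFrame(dict(sample_id=[f"s{i}" for i in range(n)],
                               rare_log_or=score, mody=False))
        phen = self._phen(rng, n, z, -0.102)
        res = phenotype_regression(sc, phen,
                                   phenotype_cols=("age_at_diagnosis",))
        b, se = res["beta_per_sd"].iloc[0], res["se"].iloc[0]
        assert b - 1.96 * se <= -0.102 <= b + 1.96 * se

    def test_zero_variance_score_rejected(self, rng):
        n = 50
        sc = pd.DataFrame(dict(sample_id=[f"s{i}" for i in range(n)],
                               rare_log_or=np.zeros(n), mody=False))
        phen = self._phen(rng, n, np.zeros(n), 0.0)
        with pytest.raises(ConfigurationError):
            phenotype_regression(sc, phen)

    def test_mody_group_shifts_recovered(self, rng):
        n = 2000
        mody = rng.random(n) < 0.05
        phen = self._phen(rng, n, np.zeros(n), 0.0)
        phen["age_at_diagnosis"] -= 0.9 * mody
        sc = pd.DataFrame(dict(sample_id=phen["sample_id"],
                               rare_log_or=rng.standard_normal(n),
                               mody=mody))
        comp = mody_group_comparison(sc, phen)
        age = comp[comp["phenotype"] == "age_at_diagnosis"].iloc[0]
        assert age["difference"] == pytest.approx(-0.9, abs=0.5)
        assert age["p"] < 0.05
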