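"""Hypergeometric and rank-sum enrichment, backgrounds, tiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from burdenarch.enrichment import (GeneSet, bh_qvalues, bonferroni_threshold,
                                   classify_tiers, cluster_combined_test,
                                   filter_metabolic_sets,
                                   hypergeometric_enrichment,
                                   match_background, rank_sum_enrichment)
from burdenarch.errors import ConfigurationError

from oracles import hypergeom_tail_exact


def _universe(n):
    return [f"G{i:05d}" for i in range(n)]


class TestHypergeometric:
    @pytest.mark.parametrize("n_uni,n_set,n_top,overlap", [
        (100, 20, 10, 4),
        (200, 50, 25, 10),
        (150, 10, 30, 1),
        (60, 30, 30, 20),
    ])
    def test_matches_enumeration_oracle(self, n_uni, n_set, n_top, overlap):
        uni = _universe(n_uni)
        gs = GeneSet("s", frozenset(uni[:n_set]))
        top = uni[:overlap] + uni[n_set:n_set + n_top - overlap]
        res = hypergeometric_enrichment(top, gs, uni)
        assert res.p == pytest.approx(
            hypergeom_tail_exact(overlap, n_uni, n_set, n_top), rel=1e-9)

    def test_study_scale_case(self):
        uni = _universe(18_000)
        gs = GeneSet("s", frozenset(uni[:100]))
        top = uni[:5] + uni[100:145]
        res = hypergeometric_enrichment(top, gs, uni)
        oracle = hypergeom_tail_exact(5, 18_000, 100, 50)
        assert res.p == pytest.approx(oracle, rel=1e-9)
        assert res.fold == pytest.approx((5 / 50) / (100 / 18_000))

    def test_saturation(self):
        uni = _universe(50)
        gs = GeneSet("all", frozenset(uni))
        res = hypergeometric_enrichment(uni[:10], gs, uni)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_overlap(self):
        uni = _universe(100)
        gs = GeneSet("s", frozenset(uni[:20]))
        res = hypergeometric_enrichment(uni[50:60], gs, uni)
        assert res.fold == 0.0
        assert res.p == pytest.approx(1.0)

    def test_empty_universe_error(self):
        with pytest.raises(ConfigurationError):
            hypergeometric_enrichment(["a"], GeneSet("s", frozenset("a")), [])


def _gene_stats(rng, n=400):
    return pd.DataFrame(
        dict(n_variants=rng.integers(2, 60, n),
             combined_maf=rng.uniform(1e-4, 0.02, n)),
        index=_universe(n))


class TestBackground:
    def test_background_matches_target_distribution(self, rng):
        ok = 0
        reps = 40
        from scipy import stats as sps
        for i in range(reps):
            stats_df = _gene_stats(np.random.default_rng(i))
            targets = list(np.random.default_rng(1000 + i).choice(
                stats_df.index, 25, replace=False))
            bg = match_background(targets, stats_df, rng=rng)
            p = sps.mannwhitneyu(
                stats_df.loc[targets, "n_variants"],
                stats_df.loc[bg.genes, "n_variants"]).pvalue
            ok += p > 0.05
        assert ok / reps >= 0.9

    def test_single_target_gene(self, rng):
        stats_df = _gene_stats(rng)
        bg = match_background([stats_df.index[0]], stats_df, rng=rng)
        assert stats_df.index[0] not in bg.genes
        assert 1 <= len(bg.genes) <= 10

    def test_identical_genes_degenerate(self, rng):
        stats_df = pd.DataFrame(dict(n_variants=[5] * 50,
                                     combined_maf=[0.01] * 50),
                                index=_universe(50))
        bg = match_background(_universe(50)[:5], stats_df, rng=rng)
        assert set(bg.genes) <= set(_universe(50)[5:])


class TestRankSum:
    def test_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 1000
        stats_df = _gene_stats(rng)
        genes = list(stats_df.index)
        gs = GeneSet("s", frozenset(genes[:20]))
        from burdenarch.enrichment import BackgroundMatch
        bg = BackgroundMatch(genes[20:220], "fixed")
        for _ in range(reps):
            pv = pd.Series(rng.random(len(genes)), index=genes)
            res = rank_sum_enrichment(gs, pv, bg)
            hits += res.p < 0.05
        assert 0.035 <= hits / reps <= 0.065

    def test_strong_enrichment_detected(self, rng):
        genes = _universe(300)
        gs = GeneSet("s", frozenset(genes[:13]))
        pv = pd.Series(np.r_[np.full(13, 1e-6), rng.random(287)],
                       index=genes)
        from burdenarch.enrichment import BackgroundMatch
        res = rank_sum_enrichment(gs, pv, BackgroundMatch(genes[13:], "u"))
        assert res.p < 1e-4
        assert set(res.contributing_genes) == set(genes[:13])

    def test_invariant_to_monotone_transform(self, rng):
        genes = _universe(200)
        gs = GeneSet("s", frozenset(genes[:15]))
        pv = pd.Series(rng.random(200) * 0.9 + 0.01, index=genes)
        from burdenarch.enrichment import BackgroundMatch
        bg = BackgroundMatch(genes[15:], "u")
        p1 = rank_sum_enrichment(gs, pv, bg).p
        p2 = rank_sum_enrichment(gs, pv**3, bg).p  # strictly monotone
        assert p1 == pytest.approx(p2)

    def test_subsumption_vanishes_on_leave_out(self):
        # a superset's enrichment driven purely by a hot subset goes
        # away when the subset's genes are excluded
        rng = np.random.default_rng(6)
        genes = _universe(400)
        hot = set(genes[:12])
        superset = GeneSet("outer", frozenset(genes[:60]))
        pv = pd.Series(rng.random(400), index=genes)
        pv[list(hot)] = rng.random(12) * 1e-4
        from burdenarch.enrichment import BackgroundMatch
        bg = BackgroundMatch(genes[60:], "u")
        with_hot = rank_sum_enrichment(superset, pv, bg)
        without = rank_sum_enrichment(superset, pv, bg, exclude=hot)
        assert with_hot.p < 0.01
        assert without.p > 0.25


class TestClusterCombined:
    def test_single_set_cluster_equals_rank_sum(self, rng):
        stats_df = _gene_stats(rng)
        genes = list(stats_df.index)
        gs = GeneSet("s", frozenset(genes[:20]))
        pv = pd.Series(rng.random(len(genes)), index=genes)
        bg_rng1 = np.random.default_rng(7)
        bg_rng2 = np.random.default_rng(7)
        res_c = cluster_combined_test([gs], pv, stats_df, rng=bg_rng1)
        bg = match_background(genes[:20], stats_df, rng=bg_rng2)
        res_r = rank_sum_enrichment(gs, pv, bg)
        assert res_c.p == pytest.approx(res_r.p)

    def test_planted_signal_detected_with_power(self, rng):
        stats_df = _gene_stats(rng)
        genes = list(stats_df.index)
        s1 = GeneSet("a", frozenset(genes[:15]))
        s2 = GeneSet("b", frozenset(genes[15:30]))
        hits = 0
        reps = 50
        for i in range(reps):
            r = np.random.default_rng(i)
            pv = pd.Series(r.random(len(genes)), index=genes)
            pv[genes[:15]] = r.random(15) ** 4  # strongly shifted down
            res = cluster_combined_test([s1, s2], pv, stats_df,
                                        rng=np.random.default_rng(i + 1))
            hits += res.p < 0.05
        assert hits / reps >= 0.8


class TestKeywordFilter:
    def test_named_set_retained(self):
        sets = {"HP_ELEVATED_HEMOGLOBIN_A1C": ["a", "b"],
                "HP_SOMETHING_ELSE": ["c"]}
        kept = filter_metabolic_sets(sets, ("hemoglobin_a1c",))
        assert kept == ["HP_ELEVATED_HEMOGLOBIN_A1C"]

    def test_default_keywords_match_insulin(self):
        sets = {"HP_INSULIN_RESISTANCE": ["a"], "HP_DEAFNESS": ["b"]}
        assert filter_metabolic_sets(sets) == ["HP_INSULIN_RESISTANCE"]

    def test_no_match_empty(self):
        assert filter_metabolic_sets({"X": ["a"]}, ("zzz",)) == []

    def test_duplicate_keywords_idempotent(self):
        sets = {"HP_DIABETES_MELLITUS": ["a"], "HP_OTHER": ["b"]}
        once = filter_metabolic_sets(sets, ("diabetes",))
        twice = filter_metabolic_sets(sets, ("diabetes", "diabetes"))
        assert once == twice

    def test_empty_keywords_error(self):
        with pytest.raises(ConfigurationError):
            filter_metabolic_sets({"X": ["a"]}, ())


class TestThresholds:
    @pytest.mark.parametrize("n,alpha,expected", [
        (25, 0.05, 0.002),
        (20_000, 0.05, 2.5e-6),
        (1, 0.05, 0.05),
    ])
    def test_bonferroni(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected)

    def test_bh_qvalues_monotone_and_bounded(self, rng):
        p = rng.random(500)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all() and (q <= 1).all()


def _tier_inputs():
    """Gene results and memberships shaped like the study's tiering:
    3 exome-wide genes, 4 top-K known genes, 4 top-K genes in >=2
    enriched sets, 46 further nominal genes in enriched sets."""
    n = 300
    genes = [f"T{i:03d}" for i in range(n)]
    p = np.linspace(0.011, 0.9, n)
    p[:3] = 1e-7  # exome-wide significant
    p[3:7] = 1e-4  # top-K, in known lists
    p[7:11] = 5e-4  # top-K, in >=2 enriched sets
    p[11:57] = np.linspace(0.001, 0.049, 46)  # nominal, in enriched sets
    res = pd.DataFrame(dict(gene=genes, corrected_p=p))
    known = {"monogenic_diabetes": set(genes[3:5]),
             "causal_coding": set(genes[5:7])}
    enr1 = GeneSet("HP_A", frozenset(genes[7:11] + genes[11:57]))
    enr2 = GeneSet("HP_B", frozenset(genes[7:11]))
    return res, known, [enr1, enr2]


class TestTiers:
    def test_planted_tier_sizes(self):
        res, known, enriched = _tier_inputs()
        tiers = classify_tiers(res, known, enriched, top_k=50)
        counts = pd.Series([t.tier for t in tiers]).value_counts()
        assert counts[1] == 3
        assert counts[2] == 4
        assert counts[3] == 4
        assert counts[4] == 46

    def test_precedence_tier1_wins(self):
        res, known, enriched = _tier_inputs()
        # make an exome-wide gene also a member of an enriched set
        enriched.append(GeneSet("HP_C", frozenset({res.gene[0], "x", "y"})))
        tiers = {t.gene: t.tier for t in classify_tiers(res, known, enriched)}
        assert tiers[res.gene[0]] == 1

    def test_empty_tier1_later_tiers_computable(self):
        res, known, enriched = _tier_inputs()
        res = res.copy()
        res.loc[res["corrected_p"] < 1e-5, "corrected_p"] = 1e-4
        tiers = classify_tiers(res, known, enriched, top_k=50)
        counts = pd.Series([t.tier for t in tiers]).value_counts()
        assert 1 not in counts
        assert counts[2] == 4

    def test_missing_known_lists_warns_and_skips(self):
        res, _, enriched = _tier_inputs()
        with pytest.warns(UserWarning):
            tiers = classify_tiers(res, None, enriched, top_k=50)
        assert all(t.tier in (1, 4, None) for t in tiers)

    def test_deterministic(self):
        res, known, enriched = _tier_inputs()
        a = classify_tiers(res, known, enriched)
        b = classify_tiers(res, known, enriched)
        assert [(t.gene, t.tier) for t in a] == [(t.gene, t.tier) for t in b]
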