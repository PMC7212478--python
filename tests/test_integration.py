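import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from clonediv.annotation import GeneRecord
from clonediv import integration as integ

SAMPLES = ["Pa", "Pb", "Ra", "Rb"]


def seg(sample, chrom, start, end, cn, b=1):
    return (sample, chrom, start, end, cn, b)


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "total_cn", "b_allele_cn"])


class TestGenesInCna:
    def genes(self):
        return [
            GeneRecord("g1", "chr1", "+", 1_000, 2_000),
            GeneRecord("g2", "chr1", "+", 10_000, 12_000),
            GeneRecord("g3", "chr2", "+", 1_000, 2_000),
        ]

    def test_dosage_classes(self):
        segs = seg_frame([
            seg("Pa", "chr1", 1, 5_000, 4),
            seg("Pa", "chr1", 5_001, 20_000, 3),
            seg("Pa", "chr2", 1, 20_000, 1),
        ])
        out = integ.genes_in_cna(segs, self.genes(), baseline_ploidy=3)
        d = out.set_index("gene")
        assert d.loc["g1", "dosage_class"] == "gain"
        assert d.loc["g2", "dosage_class"] == "neutral"
        assert d.loc["g3", "dosage_class"] == "loss"

    def test_straddling_gene_flagged(self):
        segs = seg_frame([
            seg("Pa", "chr1", 1, 1_500, 4),
            seg("Pa", "chr1", 1_501, 20_000, 3),
            seg("Pa", "chr2", 1, 20_000, 3),
        ])
        out = integ.genes_in_cna(segs, self.genes()).set_index("gene")
        assert bool(out.loc["g1", "straddles"])
        assert not bool(out.loc["g2", "straddles"])

    def test_matches_containment_oracle(self):
        rng = np.random.default_rng(0)
        bounds = np.sort(rng.choice(np.arange(2, 100) * 1_000, size=5, replace=False))
        edges = [1, *bounds.tolist(), 200_000]
        cns = rng.integers(1, 6, size=len(edges) - 1)
        segs = seg_frame([seg("Pa", "chr1", s, e - 1, int(c))
                          for s, e, c in zip(edges[:-1], edges[1:], cns)])
        genes = [GeneRecord(f"g{i}", "chr1", "+", int(p), int(p) + 500)
                 for i, p in enumerate(rng.integers(1, 150_000, size=30))]
        out = integ.genes_in_cna(segs, genes).set_index("gene")
        for g in genes:
            expected = next(c for s, e, c in zip(edges[:-1], edges[1:], cns)
                            if s <= g.tss < e)
            assert out.loc[g.gene_id, "copy_number"] == expected


class TestKsDosage:
    def dosage(self, rel_cn: dict[str, int]):
        rows = []
        for g, rel in rel_cn.items():
            rows.append((g, "Ra", 3 + rel, "x", False))
            rows.append((g, "Pa", 3, "x", False))
        return pd.DataFrame(rows, columns=["gene", "sample", "copy_number",
                                           "dosage_class", "straddles"])

    def test_null_gain_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        rel = {g: (1 if i < 5 else 0) for i, g in enumerate(genes)}
        vals = pd.DataFrame({"Ra": np.arange(10.0), "Pa": np.zeros(10)}, index=genes)
        # gain genes have the same change values as neutral genes
        vals["Ra"] = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        out = integ.ks_dosage_test(self.dosage(rel), vals, ("Ra", "Pa"))
        assert out["D_gain"] == pytest.approx(0.0)
        assert out["p_gain"] == pytest.approx(1.0)

    def test_d_statistic_matches_cdf_oracle(self):
        genes = [f"g{i}" for i in range(10)]
        rel = {g: (1 if i < 5 else 0) for i, g in enumerate(genes)}
        gain_vals = [0.3, 1.2, 2.5, 2.6, 3.1]
        neut_vals = [-0.5, 0.0, 0.4, 0.9, 1.1]
        vals = pd.DataFrame({"Ra": gain_vals + neut_vals, "Pa": np.zeros(10)}, index=genes)
        out = integ.ks_dosage_test(self.dosage(rel), vals, ("Ra", "Pa"))
        # one-sided D in the 'gain shifted up' direction: max(CDF_neutral - CDF_gain)
        grid = sorted(gain_vals + neut_vals)
        d_oracle = max(
            np.mean([v <= x for v in neut_vals]) - np.mean([v <= x for v in gain_vals])
            for x in grid
        )
        assert out["D_gain"] == pytest.approx(d_oracle, abs=1e-9)

    def test_empty_class_skipped(self):
        genes = ["g0", "g1", "g2"]
        rel = {g: 0 for g in genes}
        vals = pd.DataFrame({"Ra": [1.0, 2.0, 3.0], "Pa": np.zeros(3)}, index=genes)
        out = integ.ks_dosage_test(self.dosage(rel), vals, ("Ra", "Pa"))
        assert np.isnan(out["D_gain"]) and np.isnan(out["D_loss"])


class TestDmlExpressionCorrelation:
    def dmf(self, deltas):
        return pd.DataFrame({
            "owner_id": [f"g{i}" for i in range(len(deltas))],
            "delta_ml": deltas,
        }, index=[f"r{i}" for i in range(len(deltas))])

    def test_perfect_linearity(self):
        deltas = [0.1, 0.2, 0.3, 0.4]
        fc = pd.Series([0.5, 1.0, 1.5, 2.0], index=[f"g{i}" for i in range(4)])
        res = integ.dml_expression_correlation(self.dmf(deltas), fc)
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        deltas = [0.3, 0.3, 0.3]
        fc = pd.Series([0.5, 1.0, 1.5], index=[f"g{i}" for i in range(3)])
        res = integ.dml_expression_correlation(self.dmf(deltas), fc)
        assert res["degenerate"] and np.isnan(res["pearson_r"])

    def test_too_few_pairs_refused(self):
        fc = pd.Series([0.5], index=["g0"])
        with pytest.raises(ValueError):
            integ.dml_expression_correlation(self.dmf([0.1]), fc)


class TestSampleSpecificCna:
    def dosage(self, cns: dict[str, tuple]):
        rows = []
        for g, per_sample in cns.items():
            for s, cn in zip(SAMPLES, per_sample):
                rows.append((g, s, cn, "x", False))
        return pd.DataFrame(rows, columns=["gene", "sample", "copy_number",
                                           "dosage_class", "straddles"])

    def test_focal_specific_gain(self):
        # order Pa, Pb, Ra, Rb
        out = integ.sample_specific_cna_genes(self.dosage({"g1": (3, 3, 4, 3)}), "Ra")
        assert out.loc["g1", "direction"] == "up" and out.loc["g1", "delta_cn"] == 1

    def test_others_disagree_not_specific(self):
        out = integ.sample_specific_cna_genes(self.dosage({"g1": (4, 3, 4, 3)}), "Ra")
        assert len(out) == 0

    def test_matches_rule_scan_oracle(self):
        rng = np.random.default_rng(1)
        cns = {f"g{i}": tuple(rng.integers(1, 6, size=4)) for i in range(40)}
        out = integ.sample_specific_cna_genes(self.dosage(cns), "Ra")
        for g, (pa, pb, ra, rb) in cns.items():
            expected = (pa == pb == rb) and ra != pa
            assert (g in out.index) == expected


class TestDrivenClassification:
    def test_printed_accounting_identities(self):
        s = integ.driven_summary(n_cna_overlap=330, n_cna_consistent=249,
                                 n_dmgb_overlap=580, n_dmgb_consistent=540, n_both=25)
        assert s["pct_cna"] == 75.45
        assert s["pct_dmgb"] == 93.10
        assert s["n_union"] == 764

    def test_direction_mismatch_excluded(self):
        cna = pd.DataFrame({"delta_cn": [1, -1]}, index=["g_up", "g_down"])
        dmgb = pd.DataFrame({"owner_id": [], "delta_ml": []})
        degs = pd.DataFrame({"log2fc": [-2.0, -2.0]}, index=["g_up", "g_down"])
        out = integ.classify_driven(cna, dmgb, degs)
        assert list(out.calls.index) == ["g_down"]
        assert out.calls.loc["g_down", "mechanism"] == "cna"

    def test_both_mechanism_and_union_identity(self):
        cna = pd.DataFrame({"delta_cn": [1, 1]}, index=["g1", "g2"])
        dmgb = pd.DataFrame({"owner_id": ["g1", "g3"], "delta_ml": [0.3, -0.4]},
                            index=["r1", "r3"])
        degs = pd.DataFrame({"log2fc": [2.0, 1.0, -1.0]}, index=["g1", "g2", "g3"])
        out = integ.classify_driven(cna, dmgb, degs)
        assert out.calls.loc["g1", "mechanism"] == "both"
        s = out.summary
        assert s["n_union"] == s["n_cna_consistent"] + s["n_dmgb_consistent"] - s["n_both"]
        assert s["n_union"] == len(out.calls)


class TestMutationDegOverlap:
    def test_zero_overlap_depletion_closed_form(self):
        universe = {f"g{i}" for i in range(100)}
        mutated = {f"g{i}" for i in range(10)}
        degs = {f"g{i}" for i in range(80, 100)}
        res = integ.mutation_deg_overlap(mutated, degs, universe)
        assert res["k_observed"] == 0
        assert res["binomial_p_depletion"] == pytest.approx(0.8**10, rel=1e-12)

    def test_null_center_two_sided_near_one(self):
        universe = {f"g{i}" for i in range(100)}
        mutated = {f"g{i}" for i in range(10)}
        degs = {f"g{i}" for i in range(2)} | {f"g{i}" for i in range(50, 68)}  # p0 = 0.2, k = 2
        res = integ.mutation_deg_overlap(mutated, degs, universe)
        assert res["k_observed"] == 2
        assert res["binomial_p_two_sided"] > 0.5

    def test_matches_binomial_sum_oracle(self):
        universe = {f"g{i}" for i in range(50)}
        mutated = {f"g{i}" for i in range(8)}
        degs = {f"g{i}" for i in range(4, 24)}
        res = integ.mutation_deg_overlap(mutated, degs, universe)
        n, p0, k = res["n"], res["p0"], res["k_observed"]
        pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
        assert res["binomial_p_depletion"] == pytest.approx(sum(pmf[: k + 1]), abs=1e-12)
        assert res["binomial_p_enrichment"] == pytest.approx(sum(pmf[k:]), abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            integ.mutation_deg_overlap(set(), set(), set())


class TestGeneSetEnrichment:
    def test_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(100)}
        members = {f"g{i}" for i in range(10)}
        out = integ.gene_set_enrichment(members, {"s": members}, universe)
        expected = 1 / comb(100, 10)  # C(10,10)*C(90,0)/C(100,10)
        assert out.loc["s", "pvalue"] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_set_not_significant(self):
        universe = {f"g{i}" for i in range(100)}
        out = integ.gene_set_enrichment(
            {f"g{i}" for i in range(10)}, {"s": {f"g{i}" for i in range(50, 60)}}, universe
        )
        assert out.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        universe = {f"g{i}" for i in range(30)}
        gene_list = {f"g{i}" for i in range(8)}
        sets = {"a": {f"g{i}" for i in range(5, 15)},
                "b": {f"g{i}" for i in range(20, 28)},
                "c": {f"g{i}" for i in range(0, 4)}}
        out = integ.gene_set_enrichment(gene_list, sets, universe)
        N, n = 30, 8
        for name, members in sets.items():
            K = len(members)
            k_obs = len(gene_list & members)
            p_oracle = sum(
                comb(K, k) * comb(N - K, n - k) / comb(N, n)
                for k in range(k_obs, min(K, n) + 1)
            )
            assert out.loc[name, "pvalue"] == pytest.approx(p_oracle, abs=1e-12)
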