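import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from clonediv import methylation as meth
from clonediv.stats import bh_adjust, fisher_exact_two_sided


def cov_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])


def site_table(per_sample: dict[str, list[tuple[int, int]]], chrom="chr1"):
    """Build a retained-site table from (meth, total) tuples per sample."""
    n = len(next(iter(per_sample.values())))
    idx = pd.MultiIndex.from_tuples([(chrom, 100 + i) for i in range(n)],
                                    names=["chrom", "pos"])
    data = {}
    for s, pairs in per_sample.items():
        data[f"{s}_meth"] = [m for m, _ in pairs]
        data[f"{s}_total"] = [t for _, t in pairs]
        data[f"{s}_level"] = [m / t for m, t in pairs]
    return pd.DataFrame(data, index=idx)


class TestLoadAndFilter:
    def coverage(self, depths):
        out = {}
        for s, ds in depths.items():
            out[s] = cov_frame([("chr1", 100 + i, d // 2, d - d // 2) for i, d in enumerate(ds)])
        return out

    def test_strictly_greater_than_min_depth(self):
        cov = self.coverage({"Pa": [12, 12], "Ra": [15, 15], "Rb": [11, 10]})
        table = meth.load_and_filter_sites(cov, min_depth=10, merge_strands=False)
        assert len(table) == 1  # the depth-10 site is dropped

    def test_matches_scan_oracle(self):
        rng = np.random.default_rng(0)
        depths = {s: rng.integers(5, 30, size=40) for s in ("Pa", "Ra")}
        cov = self.coverage(depths)
        table = meth.load_and_filter_sites(cov, min_depth=10, merge_strands=False)
        expected = [i for i in range(40) if all(depths[s][i] > 10 for s in depths)]
        assert list(table.index.get_level_values("pos")) == [100 + i for i in expected]

    def test_counts_preserved_exactly(self):
        cov = self.coverage({"Pa": [20], "Ra": [25]})
        table = meth.load_and_filter_sites(cov, min_depth=10, merge_strands=False)
        assert table.iloc[0]["Pa_meth"] == 10 and table.iloc[0]["Pa_total"] == 20

    def test_negative_counts_rejected(self):
        cov = {"Pa": cov_frame([("chr1", 100, -1, 10)])}
        with pytest.raises(meth.CoverageFormatError):
            meth.load_and_filter_sites(cov)

    def test_strand_merge_pools_adjacent_cytosines(self):
        cov = cov_frame([("chr1", 100, 5, 5), ("chr1", 101, 3, 7), ("chr1", 200, 8, 4)])
        merged = meth.merge_cpg_strands(cov)
        assert len(merged) == 2
        row = merged[merged["pos"] == 100].iloc[0]
        assert (row["meth"], row["unmeth"]) == (8, 12)


class TestCallDms:
    def test_worked_fisher_example(self):
        table = site_table({"Pa": [(5, 15)], "Ra": [(0, 15)]})
        # counts 5/10 methylated vs 0/10 -> build that exact 2x2
        table = site_table({"Pa": [(5, 15)], "Ra": [(0, 15)]})
        p = fisher_exact_two_sided(np.array([5]), np.array([5]), np.array([0]), np.array([10]))
        assert p[0] == pytest.approx(0.03250773993808048, abs=1e-9)

    def test_identical_counts_never_dms(self):
        table = site_table({"Pa": [(8, 20), (3, 15)], "Ra": [(8, 20), (3, 15)]})
        out = meth.call_dms(table, ("Pa", "Ra"))
        assert (out["pvalue"] == 1.0).all()
        assert not out["is_dms"].any()

    def test_site_order_invariance(self):
        rng = np.random.default_rng(1)
        pairs = [(int(m), 20) for m in rng.integers(0, 20, size=30)]
        pairs2 = [(int(m), 20) for m in rng.integers(0, 20, size=30)]
        table = site_table({"Pa": pairs, "Ra": pairs2})
        out = meth.call_dms(table, ("Pa", "Ra"))
        shuffled = table.sample(frac=1, random_state=2)
        out2 = meth.call_dms(shuffled, ("Pa", "Ra")).loc[out.index]
        assert np.allclose(out["qvalue"], out2["qvalue"])

    def test_fisher_symmetry_and_delta_sign_flip(self):
        table = site_table({"Pa": [(12, 20)], "Ra": [(4, 18)]})
        ab = meth.call_dms(table, ("Pa", "Ra"))
        ba = meth.call_dms(table, ("Ra", "Pa"))
        assert ab["pvalue"].iloc[0] == pytest.approx(ba["pvalue"].iloc[0], abs=1e-12)
        assert ab["delta_ml"].iloc[0] == pytest.approx(-ba["delta_ml"].iloc[0])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    @settings(max_examples=40, derandomize=True)
    def test_bh_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRegionLevels:
    def regions(self):
        return pd.DataFrame({
            "region_id": ["r1", "r2"], "chrom": ["chr1", "chr1"],
            "start": [100, 500], "end": [102, 600],
            "category": ["gene_body", "promoter"], "owner_id": ["g1", "g2"],
        })

    def test_mean_of_site_levels(self):
        table = site_table({"Pa": [(4, 20), (8, 20), (12, 20)]})  # levels .2 .4 .6
        out = meth.region_levels(table, self.regions(), min_sites=3)
        assert out.loc["r1", "Pa_level"] == pytest.approx(0.4)
        assert out.loc["r1", "n_sites"] == 3

    def test_sparse_region_missing(self):
        table = site_table({"Pa": [(4, 20)]})
        out = meth.region_levels(table, self.regions(), min_sites=3)
        assert len(out) == 0

    def test_single_site_region_equals_site_level(self):
        table = site_table({"Pa": [(7, 14)]})
        out = meth.region_levels(table, self.regions(), min_sites=1)
        assert out.loc["r1", "Pa_level"] == pytest.approx(0.5)

    def test_matches_scan_oracle(self):
        rng = np.random.default_rng(2)
        n = 25
        pairs = [(int(m), 20) for m in rng.integers(1, 20, size=n)]
        table = site_table({"Pa": pairs})
        regions = pd.DataFrame({
            "region_id": ["a", "b"], "chrom": "chr1",
            "start": [100, 110], "end": [109, 200],
            "category": "gene_body", "owner_id": "",
        })
        out = meth.region_levels(table, regions, min_sites=1)
        levels = table["Pa_level"].to_numpy()
        assert out.loc["a", "Pa_level"] == pytest.approx(levels[:10].mean())
        assert out.loc["b", "Pa_level"] == pytest.approx(levels[10:].mean())


class TestCallDmf:
    def region_frame(self, a, b):
        (ma, ta), (mb, tb) = a, b
        return pd.DataFrame({
            "category": ["gene_body"], "owner_id": ["g1"], "n_sites": [5],
            "Pa_meth": [ma], "Pa_total": [ta], "Pa_level": [ma / ta],
            "Ra_meth": [mb], "Ra_total": [tb], "Ra_level": [mb / tb],
        }, index=pd.Index(["r1"], name="region_id"))

    def test_large_difference_is_dmf(self):
        out = meth.call_dmf(self.region_frame((80, 100), (40, 100)), ("Pa", "Ra"))
        assert out["is_dmf"].iloc[0]
        assert out["delta_ml"].iloc[0] == pytest.approx(0.40)
        assert out["pvalue"].iloc[0] < 1e-6

    def test_delta_gate_blocks_small_differences(self):
        out = meth.call_dmf(self.region_frame((550, 1000), (400, 1000)), ("Pa", "Ra"))
        assert out["pvalue"].iloc[0] < 0.05 and not out["is_dmf"].iloc[0]

    def test_underpowered_region_not_dmf(self):
        out = meth.call_dmf(self.region_frame((2, 3), (1, 3)), ("Pa", "Ra"))
        assert out["pvalue"].iloc[0] > 0.05 and not out["is_dmf"].iloc[0]


class TestGlobalCompare:
    def test_identical_samples_degenerate(self):
        pairs = [(i, 20) for i in range(1, 15)]
        table = site_table({"Pa": pairs, "Ra": pairs})
        out = meth.global_compare(table, ("Pa", "Ra"))
        assert out["degenerate"] and out["pvalue"] == 1.0

    def test_uniform_shift_is_maximally_significant(self):
        rng = np.random.default_rng(3)
        m = rng.integers(5, 15, size=60)
        table = site_table({"Pa": [(int(x), 40) for x in m],
                            "Ra": [(int(x) + 4, 40) for x in m]})
        out = meth.global_compare(table, ("Pa", "Ra"))
        ref = sps.wilcoxon(table["Pa_level"], table["Ra_level"], zero_method="wilcox")
        assert out["pvalue"] == pytest.approx(float(ref.pvalue))
        assert out["pvalue"] < 1e-9

    def test_genome_mean(self):
        table = site_table({"Pa": [(5, 10), (10, 20), (15, 20)]})
        assert meth.genome_mean(table, "Pa") == pytest.approx((0.5 + 0.5 + 0.75) / 3)


class TestClusterMethylomes:
    def test_duplicate_sample_merges_first(self):
        rng = np.random.default_rng(4)
        pairs = [(int(m), 30) for m in rng.integers(0, 30, size=50)]
        noisy = [(min(30, int(m) + int(rng.integers(0, 8))), 30) for m, _ in pairs]
        table = site_table({"Pa": pairs, "Pb": pairs, "Ra": noisy})
        newick, order = meth.cluster_methylomes(table)
        assert order[0] in ({frozenset({"Pa"}), frozenset({"Pb"})},
                            (frozenset({"Pa"}), frozenset({"Pb"})),
                            (frozenset({"Pb"}), frozenset({"Pa"})))
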