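import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonediv.phylogeny import (
    CapabilityError,
    classify_shared_polymorphic,
    filter_snvs,
    fitch_score,
    mask_loh,
    presence_matrix,
    topology_clades,
    wagner_tree,
)

SAMPLES = ["Pa", "Pb", "Ra", "Rb"]


def snv_row(chrom="chr1", pos=100, normal_var=0, **per_sample):
    row = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "T", "normal_var": normal_var}
    for s in SAMPLES:
        fwd, rev, depth = per_sample.get(s, (0, 0, 50))
        row[f"{s}_var_fwd"] = fwd
        row[f"{s}_var_rev"] = rev
        row[f"{s}_depth"] = depth
    return row


class TestFilterSnvs:
    def test_passing_variant_is_present(self):
        # 6 reads (3F/3R) at depth 50 -> VAF 0.12 > 0.10, reads 6 > 5, both strands
        df = pd.DataFrame([snv_row(Pa=(3, 3, 50))])
        out = filter_snvs(df, SAMPLES)
        assert len(out) == 1 and bool(out.loc[0, "present_Pa"])

    def test_single_strand_support_absent(self):
        df = pd.DataFrame([snv_row(Pa=(6, 0, 50))])
        assert len(filter_snvs(df, SAMPLES)) == 0

    def test_normal_support_drops_variant(self):
        df = pd.DataFrame([snv_row(Pa=(3, 3, 50), normal_var=1)])
        assert len(filter_snvs(df, SAMPLES)) == 0

    @pytest.mark.parametrize(
        "fwd,rev,depth,expect",
        [
            (3, 3, 60, False),   # VAF exactly 0.10 -> strict
            (3, 3, 59, True),    # VAF just above 0.10
            (3, 2, 40, False),   # 5 reads not > 5
            (4, 2, 40, True),
        ],
    )
    def test_threshold_boundaries(self, fwd, rev, depth, expect):
        df = pd.DataFrame([snv_row(Pa=(fwd, rev, depth))])
        out = filter_snvs(df, SAMPLES)
        assert (len(out) == 1 and bool(out.loc[0, "present_Pa"])) is expect

    def test_inconsistent_counts_rejected(self):
        df = pd.DataFrame([snv_row(Pa=(30, 30, 50)), snv_row(pos=200, Pa=(4, 3, 50))])
        out = filter_snvs(df, SAMPLES)
        assert list(out["pos"]) == [200]


class TestSharedPolymorphic:
    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.integers(0, 2, size=(10, 4)).astype(bool),
                           columns=SAMPLES, index=[f"v{i}" for i in range(10)])
        mat.iloc[0] = True  # guarantee one shared
        shared, poly = classify_shared_polymorphic(mat)
        for vid, row in mat.iterrows():
            if row.sum() == 4:
                assert vid in shared
            elif row.sum() > 0:
                assert vid in poly
            else:
                assert vid not in shared and vid not in poly


class TestMaskLoh:
    def segments(self):
        return pd.DataFrame(
            [
                ("Ra", "chr1", 1_000, 2_000, 2, 0),
                ("Pa", "chr1", 5_000, 6_000, 2, 1),
            ],
            columns=["sample", "chrom", "start", "end", "total_cn", "b_allele_cn"],
        )

    def test_any_sample_loh_excludes(self):
        variants = pd.DataFrame([snv_row(pos=1_500, Pa=(3, 3, 30))])
        out = mask_loh(variants, self.segments(), SAMPLES)
        assert len(out) == 0

    def test_b_allele_one_retained(self):
        variants = pd.DataFrame([snv_row(pos=5_500, Pa=(3, 3, 30))])
        out = mask_loh(variants, self.segments(), SAMPLES)
        assert len(out) == 1

    def test_matches_interval_oracle(self):
        rng = np.random.default_rng(5)
        variants = pd.DataFrame([snv_row(pos=int(p)) for p in rng.integers(1, 10_000, 20)])
        segs = pd.DataFrame(
            [("Ra", "chr1", 500, 1_500, 2, 0), ("Pb", "chr1", 3_000, 4_000, 1, 0),
             ("Pa", "chr1", 8_000, 9_000, 2, 1)],
            columns=["sample", "chrom", "start", "end", "total_cn", "b_allele_cn"],
        )
        out = mask_loh(variants, segs, SAMPLES)
        loh = [(500, 1_500), (3_000, 4_000)]
        expected = [p for p in variants["pos"] if not any(s <= p <= e for s, e in loh)]
        assert sorted(out["pos"]) == sorted(expected)


def make_presence(rows: dict[frozenset, int], samples=SAMPLES) -> pd.DataFrame:
    data, ids = [], []
    i = 0
    for carriers, count in rows.items():
        for _ in range(count):
            data.append([s in carriers for s in samples])
            ids.append(f"v{i}")
            i += 1
    return pd.DataFrame(data, columns=samples, index=ids)


class TestWagnerTree:
    def spec_matrix(self):
        return make_presence({
            frozenset({"Pa", "Pb"}): 3,
            frozenset({"Ra", "Rb"}): 2,
            frozenset({"Pa"}): 1, frozenset({"Pb"}): 1,
            frozenset({"Ra"}): 1, frozenset({"Rb"}): 1,
        })

    def test_recovers_clonal_topology_with_score_nine(self):
        tree = wagner_tree(self.spec_matrix(), outgroup="TIL")
        assert tree.total_score == 9
        clades = topology_clades(tree.topology)
        assert frozenset({"Pa", "Pb"}) in clades
        assert frozenset({"Ra", "Rb"}) in clades
        assert len(tree.tied_newicks) == 1

    def test_wrong_topology_scores_fourteen(self):
        presence = self.spec_matrix()
        states = {s: presence[s].to_numpy(dtype=np.uint8) for s in SAMPLES}
        states["TIL"] = np.zeros(len(presence), dtype=np.uint8)
        bad = ((("Pa", "Ra"), ("Pb", "Rb")), "TIL")
        assert fitch_score(bad, states) == 14

    def test_all_zero_matrix_scores_zero(self):
        mat = make_presence({})
        mat = pd.DataFrame(False, index=["v0"], columns=SAMPLES)
        tree = wagner_tree(mat, outgroup="TIL")
        assert tree.total_score == 0
        assert all(v == 0 for v in tree.branch_changes.values())

    def test_single_shared_character_changes_on_trunk(self):
        mat = make_presence({frozenset(SAMPLES): 1})
        tree = wagner_tree(mat, outgroup="TIL")
        assert tree.total_score == 1
        assert tree.branch_changes[frozenset(SAMPLES)] == 1

    def test_branch_changes_sum_to_score(self):
        tree = wagner_tree(self.spec_matrix(), outgroup="TIL")
        assert sum(tree.branch_changes.values()) == tree.total_score

    def test_too_many_taxa_rejected(self):
        taxa = [f"t{i}" for i in range(13)]
        mat = pd.DataFrame(True, index=["v0"], columns=taxa)
        with pytest.raises(CapabilityError):
            wagner_tree(mat, outgroup="TIL")

    @given(st.integers(0, 2**20 - 1))
    @settings(max_examples=40, derandomize=True)
    def test_score_invariant_under_permutations(self, bits):
        # 5 random characters over 4 taxa, encoded in the integer
        mat = np.array([[(bits >> (4 * c + t)) & 1 for t in range(4)] for c in range(5)],
                       dtype=bool)
        base = pd.DataFrame(mat, columns=SAMPLES, index=[f"v{i}" for i in range(5)])
        score = wagner_tree(base, outgroup="TIL").total_score
        shuffled = base.sample(frac=1, random_state=1)[["Rb", "Pa", "Ra", "Pb"]]
        assert wagner_tree(shuffled, outgroup="TIL").total_score == score

    def test_lower_bound_and_perfect_phylogeny_equality(self):
        perfect = self.spec_matrix()
        tree = wagner_tree(perfect, outgroup="TIL")
        assert tree.total_score == len(perfect)  # compatible characters: 1 change each
        conflicted = make_presence({
            frozenset({"Pa", "Pb"}): 1,
            frozenset({"Pa", "Ra"}): 1,
            frozenset({"Pb", "Ra"}): 1,
        })
        tree2 = wagner_tree(conflicted, outgroup="TIL")
        assert tree2.total_score > len(conflicted)


class TestPresenceMatrix:
    def test_all_absent_rows_dropped(self):
        df = pd.DataFrame([snv_row(Pa=(3, 3, 30)), snv_row(pos=200)])
        for s in SAMPLES:
            df[f"present_{s}"] = [s == "Pa", False]
        mat = presence_matrix(df, SAMPLES)
        assert len(mat) == 1
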