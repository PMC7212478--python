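"""Somatic SNV filtering and Wagner-parsimony tree reconstruction.

The variant filter keeps an SNV present in a tumor sample when its variant
allele fraction exceeds ``min_vaf``, its variant read count exceeds
``min_reads`` and both strands contribute support; a variant survives at all
only when it is present in at least one tumor sample and the matched normal
shows zero variant reads. Variants falling in a loss-of-heterozygosity
segment (B-allele copy number 0) of any sample are masked before tree
building, because allele loss corrupts presence/absence coding for every
taxon.

On binary presence/absence characters Wagner parsimony coincides with Fitch
parsimony, so the tree search enumerates every rooted topology over the
ingroup (the outgroup, an all-absent taxon, attaches at the root), scores
each with the Fitch pass, and returns the minimum-change tree. Exhaustive
enumeration is exact — no heuristic search — and is the reason the taxon
count is capped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAX_INGROUP_TAXA = 12

SNV_SAMPLE_COLUMNS = ("var_fwd", "var_rev", "depth")


class CapabilityError(RuntimeError):
    pass


def variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


# ---------------------------------------------------------------------------
# SNV filtering and bookkeeping
# ---------------------------------------------------------------------------

def filter_snvs(
    raw: pd.DataFrame,
    samples: list[str],
    min_vaf: float = 0.10,
    min_reads: int = 5,
    per_strand_min: int = 1,
) -> pd.DataFrame:
    """Apply the somatic filter and derive per-sample presence flags.

    ``raw`` carries columns ``chrom, pos, ref, alt, normal_var`` plus, per
    sample ``s``: ``{s}_var_fwd, {s}_var_rev, {s}_depth``. Presence in a
    sample requires VAF > ``min_vaf`` (strict), variant reads > ``min_reads``
    (strict) and at least ``per_strand_min`` variant reads on each strand.
    A variant is retained iff present in >= 1 sample and ``normal_var == 0``.
    Records whose strand counts are inconsistent (negative depth remainder)
    are rejected with a log entry.

    Returns the retained rows with added boolean ``present_{s}`` columns.
    """
    df = raw.copy()
    bad = pd.Series(False, index=df.index)
    for s in samples:
        var = df[f"{s}_var_fwd"] + df[f"{s}_var_rev"]
        bad |= (df[f"{s}_var_fwd"] < 0) | (df[f"{s}_var_rev"] < 0) | (var > df[f"{s}_depth"])
    if bad.any():
        logger.warning("rejected %d SNV records with inconsistent strand/depth counts", int(bad.sum()))
        df = df[~bad]

    any_present = pd.Series(False, index=df.index)
    for s in samples:
        fwd = df[f"{s}_var_fwd"]
        rev = df[f"{s}_var_rev"]
        var = fwd + rev
        depth = df[f"{s}_depth"]
        vaf = np.where(depth > 0, var / depth.replace(0, 1), 0.0)
        present = (
            (vaf > min_vaf)
            & (var > min_reads)
            & (fwd >= per_strand_min)
            & (rev >= per_strand_min)
        )
        df[f"present_{s}"] = present
        any_present |= present
    keep = any_present & (df["normal_var"] == 0)
    dropped = len(df) - int(keep.sum())
    logger.info("filter_snvs: retained %d of %d variants (%d dropped)", int(keep.sum()), len(df), dropped)
    return df[keep].reset_index(drop=True)


def presence_matrix(filtered: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Variants x samples binary matrix; all-absent rows are dropped and logged."""
    ids = [
        variant_id(c, int(p), r, a)
        for c, p, r, a in zip(filtered["chrom"], filtered["pos"], filtered["ref"], filtered["alt"])
    ]
    mat = pd.DataFrame(
        {s: filtered[f"present_{s}"].to_numpy(dtype=bool) for s in samples}, index=ids
    )
    empty = ~mat.any(axis=1)
    if empty.any():
        logger.info("dropping %d all-absent variants from presence matrix", int(empty.sum()))
        mat = mat[~empty]
    return mat


def classify_shared_polymorphic(presence: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Partition variants into shared (present in all samples) and polymorphic."""
    if presence.empty:
        raise ValueError("empty presence matrix")
    row_sums = presence.sum(axis=1)
    shared = set(presence.index[row_sums == presence.shape[1]])
    polymorphic = set(presence.index[(row_sums > 0) & (row_sums < presence.shape[1])])
    return shared, polymorphic


def mask_loh(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    samples: list[str] | None = None,
    any_sample: bool = True,
) -> pd.DataFrame:
    """Drop variants inside LOH segments (``b_allele_cn == 0``).

    With ``any_sample=True`` (default) a variant is excluded when it lies in
    an LOH segment of *any* sample: a character lost in one taxon corrupts
    its coding for all. ``any_sample=False`` masks only where the carrying
    sample itself has LOH (per-sample presence flags are then cleared instead
    of dropping the row).
    """
    loh = segments[segments["b_allele_cn"] == 0]
    if samples is not None:
        loh = loh[loh["sample"].isin(samples)]
    keep = pd.Series(True, index=variants.index)
    if any_sample:
        for chrom, sub in loh.groupby("chrom"):
            in_chrom = variants["chrom"] == chrom
            if not in_chrom.any():
                continue
            pos = variants.loc[in_chrom, "pos"].to_numpy()
            hit = np.zeros(len(pos), dtype=bool)
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                hit |= (pos >= s) & (pos <= e)
            keep.loc[in_chrom] = keep.loc[in_chrom] & ~hit
    else:
        variants = variants.copy()
        for (sample, chrom), sub in loh.groupby(["sample", "chrom"]):
            col = f"present_{sample}"
            if col not in variants.columns:
                continue
            in_chrom = variants["chrom"] == chrom
            pos = variants.loc[in_chrom, "pos"].to_numpy()
            hit = np.zeros(len(pos), dtype=bool)
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                hit |= (pos >= s) & (pos <= e)
            variants.loc[variants.index[in_chrom][hit], col] = False
        return variants
    n_dropped = len(variants) - int(keep.sum())
    logger.info("mask_loh: excluded %d variants in LOH regions", n_dropped)
    return variants[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Wagner/Fitch parsimony by exhaustive topology enumeration
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyTree:
    topology: tuple
    branch_changes: dict[frozenset, int]
    total_score: int
    newick: str
    tied_newicks: list[str] = field(default_factory=list)


def _rooted_topologies(taxa: list[str]):
    """All rooted binary topologies over ``taxa`` as nested 2-tuples."""
    if len(taxa) == 1:
        yield taxa[0]
        return
    first, rest = taxa[0], taxa[1:]
    for sub in _rooted_topologies(rest):
        for t in _insert_everywhere(sub, first):
            yield t


def _insert_everywhere(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insert_everywhere(left, leaf):
            yield (t, right)
        for t in _insert_everywhere(right, leaf):
            yield (left, t)


def _leaves(tree) -> list[str]:
    if not isinstance(tree, tuple):
        return [tree]
    return _leaves(tree[0]) + _leaves(tree[1])


def _fitch_sets(tree, states: dict[str, np.ndarray]):
    """Bottom-up Fitch pass; state sets as bitmasks (1=absent, 2=present).

    Returns (set-array, change-count-array, node_list) where node_list holds
    (subtree, set-array) in post-order for the refinement pass.
    """
    if not isinstance(tree, tuple):
        s = np.where(states[tree] > 0, 2, 1).astype(np.uint8)
        return s, 0, [(tree, s)]
    ls, lc, ln = _fitch_sets(tree[0], states)
    rs, rc, rn = _fitch_sets(tree[1], states)
    inter = ls & rs
    union = ls | rs
    s = np.where(inter > 0, inter, union).astype(np.uint8)
    changes = lc + rc + (inter == 0)
    return s, changes, ln + rn + [(tree, s)]


def fitch_score(tree, states: dict[str, np.ndarray], weights: np.ndarray | None = None) -> int:
    """Total Fitch change count of ``tree`` (rooted; outgroup state 0 enters
    via a root child whose states are all zero)."""
    _, changes, _ = _fitch_sets(tree, states)
    if np.ndim(changes) == 0:
        return 0
    if weights is None:
        weights = np.ones_like(changes, dtype=np.int64)
    return int(np.sum(changes * weights))


def _refine(tree, sets: dict[int, np.ndarray], parent_state: np.ndarray, weights: np.ndarray,
            branch_changes: dict[frozenset, int]):
    """Top-down Fitch refinement, ties resolved toward state 0 (absent)."""
    s = sets[id(tree)]
    has_parent = (s & parent_state) > 0
    # prefer the parent state; otherwise prefer absent (bit 1) when available
    state = np.where(has_parent, parent_state, np.where(s & 1, 1, 2)).astype(np.uint8)
    clade = frozenset(_leaves(tree))
    branch_changes[clade] = int(np.sum((state != parent_state) * weights))
    if isinstance(tree, tuple):
        _refine(tree[0], sets, state, weights, branch_changes)
        _refine(tree[1], sets, state, weights, branch_changes)


def _canonical_newick(tree, branch_changes: dict[frozenset, int] | None = None) -> str:
    def render(t):
        if not isinstance(t, tuple):
            body = t
        else:
            parts = sorted(render(c) for c in t)
            body = "(" + ",".join(parts) + ")"
        if branch_changes is not None:
            body += f":{branch_changes.get(frozenset(_leaves(t)), 0)}"
        return body

    return render(tree) + ";"


def wagner_tree(presence: pd.DataFrame, outgroup: str = "TIL") -> ParsimonyTree:
    """Exact minimum-change (Wagner/Fitch) tree rooted at an all-absent outgroup.

    Enumerates every rooted topology over the ingroup, scores each character by
    the Fitch pass (weighted by pattern multiplicity), and reports one
    most-parsimonious change assignment with ties resolved toward the ancestral
    absent state. When several topologies tie, all canonical Newick strings are
    returned and the lexicographically smallest is primary.
    """
    ingroup = [s for s in presence.columns if s != outgroup]
    if len(ingroup) > MAX_INGROUP_TAXA:
        raise CapabilityError(
            f"{len(ingroup)} ingroup taxa exceed the exhaustive-search cap of "
            f"{MAX_INGROUP_TAXA}; heuristic search is out of scope"
        )
    mat = presence[ingroup].to_numpy(dtype=np.uint8)
    # collapse identical character patterns; Fitch cost is pattern-additive
    patterns, counts = np.unique(mat, axis=0, return_counts=True)
    states = {s: patterns[:, i] for i, s in enumerate(ingroup)}
    states[outgroup] = np.zeros(len(patterns), dtype=np.uint8)
    weights = counts.astype(np.int64)

    best: list[tuple] = []
    best_score = None
    for top in _rooted_topologies(ingroup):
        full = (top, outgroup)
        score = fitch_score(full, states, weights)
        if best_score is None or score < best_score:
            best_score = score
            best = [full]
        elif score == best_score:
            best.append(full)

    newicks = {}
    for full in best:
        _, _, nodes = _fitch_sets(full, states)
        sets = {id(t): s for t, s in nodes}
        root_set = sets[id(full)]
        root_state = np.where(root_set & 1, 1, 2).astype(np.uint8)
        branch_changes: dict[frozenset, int] = {}
        _refine(full[0], sets, root_state, weights, branch_changes)
        _refine(full[1], sets, root_state, weights, branch_changes)
        newicks[_canonical_newick(full, branch_changes)] = (full, branch_changes)

    ordered = sorted(newicks)
    primary_newick = ordered[0]
    full, branch_changes = newicks[primary_newick]
    return ParsimonyTree(
        topology=full,
        branch_changes=branch_changes,
        total_score=int(best_score or 0),
        newick=primary_newick,
        tied_newicks=ordered,
    )


def topology_clades(tree) -> set[frozenset]:
    """Nontrivial ingroup clades of a nested-tuple topology (for recovery checks)."""
    out: set[frozenset] = set()

    def walk(t):
        if isinstance(t, tuple):
            leaves = frozenset(_leaves(t))
            if len(leaves) > 1:
                out.add(leaves)
            walk(t[0])
            walk(t[1])

    walk(tree)
    return out
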