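"""Functional genomic categories and site-to-category assignment.

Coordinates are 1-based inclusive everywhere inside the package; BED-style
0-based half-open intervals are converted at the reader boundary (see
:mod:`clonediv.io`).

Categories follow the usual methylome-annotation geometry: promoters span
1500 bp upstream to 500 bp downstream of the TSS (strand-aware), gene bodies
run from TSS to TES, CpG-island shores are the 2-kb flanks of islands and
shelves the 2-kb flanks of shores, with precedence island > shore > shelf
when flanks of neighbouring islands collide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
SHORE_WIDTH = 2000
SHELF_WIDTH = 2000

REPEAT_CATEGORIES = ("line", "sine", "ltr", "satellite", "other_repeat")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneRecord:
    """One representative transcript per gene.

    ``tss``/``tes`` are genomic coordinates of the transcription start/end
    site; on the minus strand ``tss > tes``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        lo, hi = self.span
        for s, e in self.exons:
            if not (lo <= s <= e <= hi):
                raise AnnotationError(f"{self.gene_id}: exon [{s},{e}] outside gene span [{lo},{hi}]")

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.tss, self.tes), max(self.tss, self.tes))


@dataclass(frozen=True)
class CategoryInterval:
    category: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    owner_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"{self.category} {self.owner_id}: start {self.start} > end {self.end}"
            )


def promoter_of(
    gene: GeneRecord,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    chrom_length: int | None = None,
) -> CategoryInterval:
    """Strand-aware promoter interval around the TSS (clipped to the chromosome)."""
    if chrom_length is not None and not (1 <= gene.tss <= chrom_length):
        raise AnnotationError(f"{gene.gene_id}: TSS {gene.tss} outside chromosome (len {chrom_length})")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(1, start)
    if chrom_length is not None:
        end = min(chrom_length, end)
    return CategoryInterval("promoter", gene.chrom, start, end, gene.gene_id)


def gene_body_of(gene: GeneRecord) -> CategoryInterval:
    """Gene body = TSS..TES, orientation-normalized."""
    lo, hi = gene.span
    if lo == hi:
        logger.info("gene %s has zero-length body (tss == tes == %d)", gene.gene_id, lo)
    return CategoryInterval("gene_body", gene.chrom, lo, hi, gene.gene_id)


def _subtract(start: int, end: int, blockers: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Subtract sorted, merged blocker intervals from [start, end]."""
    pieces: list[tuple[int, int]] = []
    cur = start
    for bs, be in blockers:
        if be < cur or bs > end:
            continue
        if bs > cur:
            pieces.append((cur, bs - 1))
        cur = max(cur, be + 1)
        if cur > end:
            break
    if cur <= end:
        pieces.append((cur, end))
    return pieces


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def cgi_context(
    cgis: Sequence[CategoryInterval],
    chrom_lengths: dict[str, int] | None = None,
) -> list[CategoryInterval]:
    """Shores and shelves of CpG islands with precedence island > shore > shelf.

    Shores are the 2-kb flanks of each island minus any island; shelves are the
    2-kb flanks of the shores minus shores and islands. Adjacent islands whose
    flanks collide are resolved by that precedence, so the per-base labelling
    {island, shore, shelf, none} is a partition.
    """
    out: list[CategoryInterval] = []
    by_chrom: dict[str, list[CategoryInterval]] = {}
    for cgi in cgis:
        by_chrom.setdefault(cgi.chrom, []).append(cgi)
    for chrom, islands in by_chrom.items():
        islands = sorted(islands, key=lambda c: c.start)
        for a, b in zip(islands, islands[1:]):
            if b.start <= a.end:
                raise AnnotationError(f"overlapping CpG islands on {chrom}: {a} and {b}")
        limit = chrom_lengths.get(chrom) if chrom_lengths else None
        island_iv = [(c.start, c.end) for c in islands]

        def clip(s: int, e: int) -> tuple[int, int] | None:
            s = max(1, s)
            if limit is not None:
                e = min(limit, e)
            return (s, e) if s <= e else None

        shore_raw = []
        for c in islands:
            for cand in (clip(c.start - SHORE_WIDTH, c.start - 1), clip(c.end + 1, c.end + SHORE_WIDTH)):
                if cand:
                    shore_raw.append(cand)
        shore_iv = []
        for s, e in _merge(shore_raw):
            shore_iv.extend(_subtract(s, e, island_iv))
        shore_iv = _merge(shore_iv)

        shelf_raw = []
        for c in islands:
            for cand in (
                clip(c.start - SHORE_WIDTH - SHELF_WIDTH, c.start - SHORE_WIDTH - 1),
                clip(c.end + SHORE_WIDTH + 1, c.end + SHORE_WIDTH + SHELF_WIDTH),
            ):
                if cand:
                    shelf_raw.append(cand)
        blockers = _merge(island_iv + shore_iv)
        shelf_iv = []
        for s, e in _merge(shelf_raw):
            shelf_iv.extend(_subtract(s, e, blockers))
        shelf_iv = _merge(shelf_iv)

        out.extend(CategoryInterval("cgi_shore", chrom, s, e) for s, e in shore_iv)
        out.extend(CategoryInterval("cgi_shelf", chrom, s, e) for s, e in shelf_iv)
    return out


def build_category_intervals(
    genes: Sequence[GeneRecord],
    cgis: Sequence[CategoryInterval] = (),
    repeats: Sequence[CategoryInterval] = (),
    chrom_lengths: dict[str, int] | None = None,
) -> list[CategoryInterval]:
    """All category intervals: promoters, gene bodies, exons/introns, CGI
    islands + shores/shelves, repeats."""
    out: list[CategoryInterval] = []
    for g in genes:
        out.append(promoter_of(g, chrom_length=(chrom_lengths or {}).get(g.chrom)))
        out.append(gene_body_of(g))
        lo, hi = g.span
        exon_iv = _merge(g.exons)
        for s, e in exon_iv:
            out.append(CategoryInterval("exon", g.chrom, s, e, g.gene_id))
        for s, e in _subtract(lo, hi, exon_iv):
            out.append(CategoryInterval("intron", g.chrom, s, e, g.gene_id))
    out.extend(cgis)
    out.extend(cgi_context(cgis, chrom_lengths))
    out.extend(repeats)
    return out


def assign_sites(
    sites: pd.DataFrame,
    categories: Sequence[CategoryInterval],
) -> pd.Series:
    """Map each site to the set of categories containing it.

    ``sites`` needs columns ``chrom`` and ``pos`` (1-based). Sites covered by
    no interval are labelled ``{"intergenic"}``. Runs one sorted sweep per
    (chromosome, category) via searchsorted, near-linear in sites + intervals.
    """
    result = [set() for _ in range(len(sites))]
    idx_by_chrom: dict[str, np.ndarray] = {}
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        idx_by_chrom[str(chrom)] = sub.index.to_numpy()[order]
        pos_by_chrom[str(chrom)] = sub["pos"].to_numpy()[order]
    pos_lookup = {sites.index[i]: i for i in range(len(sites))}

    known_chroms = {c.chrom for c in categories}
    missing = set(idx_by_chrom) - known_chroms
    if missing and categories:
        logger.warning("sites on chromosomes absent from annotation: %s", sorted(missing))

    for cat in categories:
        pos = pos_by_chrom.get(cat.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, cat.start, side="left")
        hi = np.searchsorted(pos, cat.end, side="right")
        for row_label in idx_by_chrom[cat.chrom][lo:hi]:
            result[pos_lookup[row_label]].add(cat.category)
    for s in result:
        if not s:
            s.add("intergenic")
    return pd.Series(result, index=sites.index, name="categories")
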