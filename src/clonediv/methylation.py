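"""Site-level methylation calling, differential methylation, and clustering.

Methylation level of a CpG site is methylated reads / total reads. Only sites
covered by more than ``min_depth`` reads in every sample enter the analysis.
Differentially methylated sites (DMS) between two samples are called with a
two-sided Fisher exact test on the per-site read counts, Benjamini–Hochberg
adjusted across all retained sites of that comparison. Differentially
methylated functional categories (DMF; promoters = DMP, gene bodies = DMGB)
require a methylation-level difference > 20 percentage points together with a
two-sided Fisher exact test on the counts pooled over the region's sites at
unadjusted p < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust, fisher_exact_two_sided
from .expression import hierarchical_cluster

logger = logging.getLogger(__name__)


class CoverageFormatError(ValueError):
    pass


def merge_cpg_strands(cov: pd.DataFrame) -> pd.DataFrame:
    """Merge opposite-strand cytosines of one CpG (adjacent positions) into one site.

    Bismark coverage files report each cytosine separately; the two cytosines
    of a CpG sit at consecutive positions. Rows at position p and p+1 are
    pooled onto p (greedy, per chromosome, on sorted positions). Data with
    one row per CpG pass through unchanged.
    """
    parts = []
    for chrom, sub in cov.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        anchor = np.empty(len(pos), dtype=pos.dtype)
        prev_anchor = None
        for i, p in enumerate(pos):
            if prev_anchor is not None and p == prev_anchor + 1:
                anchor[i] = prev_anchor
                prev_anchor = None  # do not chain CGCG runs
            else:
                anchor[i] = p
                prev_anchor = p
        sub = sub.assign(pos=anchor)
        parts.append(
            sub.groupby(["chrom", "pos"], as_index=False)[["meth", "unmeth"]].sum()
        )
    return pd.concat(parts, ignore_index=True)


def load_and_filter_sites(
    coverage: dict[str, pd.DataFrame],
    min_depth: int = 10,
    merge_strands: bool = True,
) -> pd.DataFrame:
    """Join per-sample coverage tables into a site table, keep deep sites.

    ``coverage`` maps sample name to a frame with columns
    ``chrom, pos, meth, unmeth`` (1-based positions; see :mod:`clonediv.io`
    for the Bismark reader). A site is retained iff total reads > ``min_depth``
    (strict) in every sample. Output columns per sample ``s``:
    ``{s}_meth, {s}_total, {s}_level``; indexed by (chrom, pos).
    """
    joined: pd.DataFrame | None = None
    for sample, cov in coverage.items():
        if (cov["meth"] < 0).any() or (cov["unmeth"] < 0).any():
            raise CoverageFormatError(f"{sample}: negative counts in coverage table")
        if merge_strands:
            cov = merge_cpg_strands(cov)
        part = cov.set_index(["chrom", "pos"])[["meth", "unmeth"]]
        part = part.rename(columns={"meth": f"{sample}_meth", "unmeth": f"{sample}_unmeth"})
        joined = part if joined is None else joined.join(part, how="inner")
    if joined is None:
        raise ValueError("no coverage tables given")
    samples = list(coverage)
    keep = pd.Series(True, index=joined.index)
    for s in samples:
        total = joined[f"{s}_meth"] + joined[f"{s}_unmeth"]
        joined[f"{s}_total"] = total
        keep &= total > min_depth
    table = joined[keep].copy()
    for s in samples:
        table[f"{s}_level"] = table[f"{s}_meth"] / table[f"{s}_total"]
        table.drop(columns=f"{s}_unmeth", inplace=True)
    logger.info("retained %d of %d common sites at depth > %d in all samples",
                len(table), len(joined), min_depth)
    return table.sort_index()


def samples_of(table: pd.DataFrame) -> list[str]:
    return [c[: -len("_level")] for c in table.columns if c.endswith("_level")]


def call_dms(table: pd.DataFrame, pair: tuple[str, str], alpha: float = 0.05) -> pd.DataFrame:
    """Differentially methylated sites between two samples.

    Two-sided Fisher exact on [methylated, unmethylated] x [a, b] per site,
    BH adjustment across all retained sites, DMS iff adjusted p < alpha.
    Returns the full per-site frame with ``pvalue, qvalue, delta_ml, is_dms``
    (delta_ml = level_a - level_b).
    """
    a, b = pair
    m1 = table[f"{a}_meth"].to_numpy()
    u1 = (table[f"{a}_total"] - table[f"{a}_meth"]).to_numpy()
    m2 = table[f"{b}_meth"].to_numpy()
    u2 = (table[f"{b}_total"] - table[f"{b}_meth"]).to_numpy()
    p = fisher_exact_two_sided(m1, u1, m2, u2)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "pvalue": p,
            "qvalue": q,
            "delta_ml": table[f"{a}_level"] - table[f"{b}_level"],
            "is_dms": q < alpha,
        },
        index=table.index,
    )
    return out


def region_levels(
    table: pd.DataFrame,
    regions: pd.DataFrame,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Per-region methylation: unweighted mean of site levels, plus pooled counts.

    ``regions`` needs columns ``region_id, chrom, start, end`` (1-based,
    inclusive) and may carry ``category`` / ``owner_id``. Regions with fewer
    than ``min_sites`` retained sites are dropped (logged). Pooled counts
    (sums of per-site methylated/total reads) feed the category-level Fisher
    test of :func:`call_dmf`.
    """
    samples = samples_of(table)
    chroms = table.index.get_level_values(0).to_numpy()
    pos = table.index.get_level_values(1).to_numpy()
    rows = []
    for chrom, sub in regions.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        cpos = pos[mask]
        block = table[mask]
        order = np.argsort(cpos)
        cpos = cpos[order]
        block = block.iloc[order]
        lo = np.searchsorted(cpos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(cpos, sub["end"].to_numpy(), side="right")
        for (_, reg), i, j in zip(sub.iterrows(), lo, hi):
            n = j - i
            if n < min_sites:
                continue
            row = {
                "region_id": reg["region_id"],
                "category": reg.get("category", ""),
                "owner_id": reg.get("owner_id", ""),
                "n_sites": int(n),
            }
            sites = block.iloc[i:j]
            for s in samples:
                row[f"{s}_level"] = float(sites[f"{s}_level"].mean())
                row[f"{s}_meth"] = int(sites[f"{s}_meth"].sum())
                row[f"{s}_total"] = int(sites[f"{s}_total"].sum())
            rows.append(row)
    n_skipped = len(regions) - len(rows)
    if n_skipped:
        logger.info("region_levels: %d regions below min_sites=%d reported as missing",
                    n_skipped, min_sites)
    return pd.DataFrame(rows).set_index("region_id") if rows else pd.DataFrame(
        columns=["category", "owner_id", "n_sites"]).rename_axis("region_id")


def call_dmf(
    regions: pd.DataFrame,
    pair: tuple[str, str],
    delta: float = 0.20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differentially methylated functional categories between two samples.

    DMF iff |delta_ml| > ``delta`` and the two-sided Fisher exact test on the
    pooled region counts gives unadjusted p < ``alpha``. delta_ml keeps its
    sign (level_a - level_b). Restrict ``regions`` to promoters or gene bodies
    upstream to obtain DMPs or DMGBs.
    """
    if regions.empty:
        return regions.assign(pvalue=[], delta_ml=[], is_dmf=[])
    a, b = pair
    m1 = regions[f"{a}_meth"].to_numpy()
    u1 = (regions[f"{a}_total"] - regions[f"{a}_meth"]).to_numpy()
    m2 = regions[f"{b}_meth"].to_numpy()
    u2 = (regions[f"{b}_total"] - regions[f"{b}_meth"]).to_numpy()
    p = fisher_exact_two_sided(m1, u1, m2, u2)
    dml = regions[f"{a}_level"] - regions[f"{b}_level"]
    out = regions[["category", "owner_id", "n_sites"]].copy()
    out["delta_ml"] = dml
    out["pvalue"] = p
    out["is_dmf"] = (dml.abs() > delta) & (p < alpha)
    return out


def sample_specific_dmf(
    regions: pd.DataFrame,
    focal: str,
    others: list[str],
    delta: float = 0.20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regions that are DMFs of the focal sample against every other sample,
    with a consistent sign; delta_ml reported as the mean focal-minus-other."""
    calls = []
    for other in others:
        calls.append(call_dmf(regions, (focal, other), delta=delta, alpha=alpha))
    is_all = np.logical_and.reduce([c["is_dmf"].to_numpy() for c in calls])
    signs = np.stack([np.sign(c["delta_ml"].to_numpy()) for c in calls])
    consistent = is_all & (np.abs(signs.sum(axis=0)) == len(others))
    out = calls[0][["category", "owner_id", "n_sites"]].copy()
    out["delta_ml"] = np.mean([c["delta_ml"].to_numpy() for c in calls], axis=0)
    out["is_specific"] = consistent
    return out[out["is_specific"]].drop(columns="is_specific")


def global_compare(table: pd.DataFrame, pair: tuple[str, str]) -> dict:
    """Paired Wilcoxon signed-rank on per-site levels (zeros dropped)."""
    a, b = pair
    x = table[f"{a}_level"].to_numpy()
    y = table[f"{b}_level"].to_numpy()
    if len(x) < 10:
        raise ValueError("need >= 10 common sites for the global comparison")
    if np.all(x == y):
        logger.info("global_compare %s: all per-site differences zero; test undefined", pair)
        return {"statistic": float("nan"), "pvalue": 1.0, "degenerate": True}
    res = stats.wilcoxon(x, y, zero_method="wilcox")
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue), "degenerate": False}


def genome_mean(table: pd.DataFrame, sample: str) -> float:
    """Genome-wide mean methylation level (unweighted over retained sites)."""
    return float(table[f"{sample}_level"].mean())


def cluster_methylomes(table: pd.DataFrame, dms_only: pd.Index | None = None,
                       method: str = "complete") -> tuple[str, list[tuple]]:
    """Hierarchical clustering of samples on per-site methylation levels.

    By default all common retained sites are used; pass ``dms_only`` (an index
    of sites) to cluster on the DMS union across pairs instead — on data of
    this structure the two give the same sample topology.
    """
    sub = table.loc[dms_only] if dms_only is not None else table
    levels = sub[[f"{s}_level" for s in samples_of(table)]]
    levels = levels.rename(columns={f"{s}_level": s for s in samples_of(table)})
    return hierarchical_cluster(levels, method=method)
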