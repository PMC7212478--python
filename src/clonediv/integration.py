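"""Joining the genomic, epigenomic, and transcriptomic layers.

Covers the dosage effect of copy-number alterations on expression (one-sided
Kolmogorov–Smirnov against neutral genes), the correlation between
differential promoter/gene-body methylation and expression fold change,
sample-specific CNA genes, the directional classification of CNA-driven and
methylation-driven genes, the binomial overlap test of sample-specific
mutated genes against DEGs, and hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneRecord
from .stats import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gene copy number and dosage
# ---------------------------------------------------------------------------

def genes_in_cna(
    segments: pd.DataFrame,
    genes: list[GeneRecord],
    baseline_ploidy: int = 3,
) -> pd.DataFrame:
    """Per-gene, per-sample copy number and dosage class relative to baseline.

    A gene takes the copy number of the segment containing its TSS; genes
    whose body straddles a segment boundary are flagged (``straddles``) and
    should be excluded from dosage tests. Genes on chromosomes without
    segments are neutral with a warning. Returns a frame with columns
    ``gene, sample, copy_number, dosage_class, straddles``.
    """
    rows = []
    for sample, per_sample in segments.groupby("sample"):
        by_chrom = {c: sub.sort_values("start") for c, sub in per_sample.groupby("chrom")}
        warned: set[str] = set()
        for g in genes:
            sub = by_chrom.get(g.chrom)
            lo, hi = g.span
            if sub is None:
                if g.chrom not in warned:
                    logger.warning("sample %s: no segments on %s; genes set neutral", sample, g.chrom)
                    warned.add(g.chrom)
                cn, straddles = baseline_ploidy, False
            else:
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                cns = sub["total_cn"].to_numpy()
                i = np.searchsorted(starts, g.tss, side="right") - 1
                if i >= 0 and ends[i] >= g.tss:
                    cn = int(cns[i])
                    j_lo = np.searchsorted(starts, lo, side="right") - 1
                    j_hi = np.searchsorted(starts, hi, side="right") - 1
                    straddles = j_lo != j_hi
                else:
                    cn, straddles = baseline_ploidy, False
            klass = "gain" if cn > baseline_ploidy else ("loss" if cn < baseline_ploidy else "neutral")
            rows.append((g.gene_id, sample, cn, klass, straddles))
    return pd.DataFrame(rows, columns=["gene", "sample", "copy_number", "dosage_class", "straddles"])


def ks_dosage_test(
    dosage: pd.DataFrame,
    log2_means: pd.DataFrame,
    pair: tuple[str, str],
    expression_floor: float = 1.0,
    sample_means: pd.DataFrame | None = None,
) -> dict:
    """One-sided KS tests of dosage effect on expression change.

    For ``pair = (focal, other)``: genes are classed by focal copy number
    relative to the other sample's copy number; the focal-minus-other change
    in log2 mean expression of gain (loss) genes is tested against neutral
    genes with the alternative that gains are shifted up (losses down).
    Genes with mean count < ``expression_floor`` in either sample, or genes
    straddling a segment boundary, are excluded.
    """
    focal, other = pair
    cn = dosage.pivot_table(index="gene", columns="sample", values="copy_number")
    straddle = dosage.groupby("gene")["straddles"].any()
    genes = cn.index.intersection(log2_means.index)
    cn = cn.loc[genes]
    keep = ~straddle.loc[genes]
    if sample_means is not None:
        sm = sample_means.loc[genes]
        keep &= (sm[focal] >= expression_floor) & (sm[other] >= expression_floor)
    genes = genes[keep]
    change = (log2_means.loc[genes, focal] - log2_means.loc[genes, other]).to_numpy()
    rel = cn.loc[genes, focal].to_numpy() - cn.loc[genes, other].to_numpy()

    out: dict = {"n_gain": int((rel > 0).sum()), "n_loss": int((rel < 0).sum()),
                 "n_neutral": int((rel == 0).sum())}
    neutral = change[rel == 0]
    for klass, mask, alternative in (("gain", rel > 0, "less"), ("loss", rel < 0, "greater")):
        vals = change[mask]
        if len(vals) == 0 or len(neutral) == 0:
            logger.info("ks_dosage_test %s: empty %s class; test skipped", pair, klass)
            out[f"D_{klass}"] = float("nan")
            out[f"p_{klass}"] = float("nan")
            continue
        # scipy's alternative 'less' asserts CDF(first) < CDF(second), i.e.
        # the first sample is stochastically LARGER — the gain direction.
        res = stats.ks_2samp(vals, neutral, alternative=alternative)
        out[f"D_{klass}"] = float(res.statistic)
        out[f"p_{klass}"] = float(res.pvalue)
    return out


# ---------------------------------------------------------------------------
# Methylation-expression correlation
# ---------------------------------------------------------------------------

def dml_expression_correlation(
    dmf: pd.DataFrame,
    log2fc: pd.Series,
) -> dict:
    """Pearson correlation between region delta_ml and gene log2 fold change.

    ``dmf`` is a DMP or DMGB table (indexed by region, with ``owner_id`` the
    gene and ``delta_ml``); ``log2fc`` maps gene -> focal-vs-other log2 fold
    change oriented the same way as delta_ml. Returns r, two-sided p, n, and
    the paired table (for density plotting).
    """
    paired = dmf[["owner_id", "delta_ml"]].copy()
    paired["log2fc"] = paired["owner_id"].map(log2fc)
    paired = paired.dropna(subset=["log2fc"])
    if len(paired) < 3:
        raise ValueError("need >= 3 genes with both methylation and expression values")
    x = paired["delta_ml"].to_numpy()
    y = paired["log2fc"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        logger.info("dml_expression_correlation: zero-variance input; r undefined")
        return {"pearson_r": float("nan"), "pvalue": float("nan"), "n": len(paired),
                "table": paired, "degenerate": True}
    r, p = stats.pearsonr(x, y)
    return {"pearson_r": float(r), "pvalue": float(p), "n": len(paired),
            "table": paired, "degenerate": False}


# ---------------------------------------------------------------------------
# Sample-specific CNA genes and driven-gene classification
# ---------------------------------------------------------------------------

def sample_specific_cna_genes(
    dosage: pd.DataFrame,
    focal: str,
    relaxed: bool = False,
) -> pd.DataFrame:
    """Genes whose copy number is specific to the focal sample.

    Strict rule (default): the focal copy number differs from every other
    sample's and the other samples all agree. Relaxed rule: the focal copy
    number differs from the modal copy number of the others. Returns a frame
    indexed by gene with ``delta_cn`` (focal minus others) and ``direction``.
    """
    cn = dosage.pivot_table(index="gene", columns="sample", values="copy_number")
    others = [s for s in cn.columns if s != focal]
    straddle = dosage.groupby("gene")["straddles"].any()
    rows = []
    for g, row in cn.iterrows():
        if straddle.get(g, False):
            continue
        other_vals = row[others]
        if relaxed:
            ref = other_vals.mode().iloc[0]
            specific = row[focal] != ref
        else:
            specific = other_vals.nunique() == 1 and row[focal] != other_vals.iloc[0]
            ref = other_vals.iloc[0]
        if specific:
            delta = int(row[focal] - ref)
            rows.append((g, delta, "up" if delta > 0 else "down"))
    return pd.DataFrame(rows, columns=["gene", "delta_cn", "direction"]).set_index("gene")


def driven_summary(n_cna_overlap: int, n_cna_consistent: int,
                   n_dmgb_overlap: int, n_dmgb_consistent: int,
                   n_both: int) -> dict:
    """Accounting identities of the driven-gene classification.

    Percent consistent = consistent / overlap * 100 (2 dp);
    union = cna_consistent + dmgb_consistent - both.
    """
    out = {
        "n_cna_overlap": n_cna_overlap,
        "n_cna_consistent": n_cna_consistent,
        "pct_cna": round(100.0 * n_cna_consistent / n_cna_overlap, 2) if n_cna_overlap else float("nan"),
        "n_dmgb_overlap": n_dmgb_overlap,
        "n_dmgb_consistent": n_dmgb_consistent,
        "pct_dmgb": round(100.0 * n_dmgb_consistent / n_dmgb_overlap, 2) if n_dmgb_overlap else float("nan"),
        "n_both": n_both,
        "n_union": n_cna_consistent + n_dmgb_consistent - n_both,
    }
    return out


def shared_fraction_percent(k: int, n: int, ndigits: int = 2) -> float:
    """Percentage of shared events among all events, rounded for reporting."""
    return round(100.0 * k / n, ndigits)


@dataclass
class DrivenGenes:
    calls: pd.DataFrame  # gene, mechanism, direction, delta_cn, delta_ml, log2fc
    summary: dict


def classify_driven(
    focal_cna_genes: pd.DataFrame,
    focal_dmgb_genes: pd.DataFrame,
    focal_degs: pd.DataFrame,
) -> DrivenGenes:
    """Directional classification of sample-specific DEGs by mechanism.

    CNA-driven: sample-specific CNA gene that is a sample-specific DEG with
    sign(delta_cn) == sign(log2fc). Methylation-driven: sample-specific DMGB
    gene that is a DEG with sign(delta_ml) == sign(log2fc) (gene-body
    methylation couples positively to expression). ``both`` satisfies both.

    Inputs: ``focal_cna_genes`` indexed by gene with ``delta_cn``;
    ``focal_dmgb_genes`` with columns ``owner_id, delta_ml`` (one row per
    gene-body region); ``focal_degs`` indexed by gene with ``log2fc``.
    """
    deg_fc = focal_degs["log2fc"]
    dmgb_by_gene = (
        focal_dmgb_genes.groupby("owner_id")["delta_ml"].mean()
        if len(focal_dmgb_genes)
        else pd.Series(dtype=float)
    )

    cna_overlap = focal_cna_genes.index.intersection(deg_fc.index)
    cna_consistent = [
        g for g in cna_overlap
        if np.sign(focal_cna_genes.loc[g, "delta_cn"]) == np.sign(deg_fc.loc[g])
    ]
    dmgb_overlap = dmgb_by_gene.index.intersection(deg_fc.index)
    dmgb_consistent = [
        g for g in dmgb_overlap
        if np.sign(dmgb_by_gene.loc[g]) == np.sign(deg_fc.loc[g])
    ]
    both = sorted(set(cna_consistent) & set(dmgb_consistent))

    rows = []
    for g in sorted(set(cna_consistent) | set(dmgb_consistent)):
        mech = "both" if g in both else ("cna" if g in set(cna_consistent) else "methylation")
        rows.append({
            "gene": g,
            "mechanism": mech,
            "direction": "up" if deg_fc.loc[g] > 0 else "down",
            "delta_cn": int(focal_cna_genes.loc[g, "delta_cn"]) if g in focal_cna_genes.index else 0,
            "delta_ml": float(dmgb_by_gene.loc[g]) if g in dmgb_by_gene.index else float("nan"),
            "log2fc": float(deg_fc.loc[g]),
        })
    calls = pd.DataFrame(rows, columns=["gene", "mechanism", "direction",
                                        "delta_cn", "delta_ml", "log2fc"]).set_index("gene")
    summary = driven_summary(
        n_cna_overlap=len(cna_overlap),
        n_cna_consistent=len(cna_consistent),
        n_dmgb_overlap=len(dmgb_overlap),
        n_dmgb_consistent=len(dmgb_consistent),
        n_both=len(both),
    )
    return DrivenGenes(calls=calls, summary=summary)


# ---------------------------------------------------------------------------
# Overlap and enrichment tests
# ---------------------------------------------------------------------------

def mutation_deg_overlap(
    specific_mutated_genes: set[str],
    specific_degs: set[str],
    universe: set[str],
) -> dict:
    """Exact binomial test of the overlap between mutated genes and DEGs.

    k = |overlap|, n = |mutated|, p0 = |DEGs| / |universe|. Both tail
    directions are reported since a 'no overlap' narrative is a depletion
    claim while enrichment is the conventional alternative.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not (specific_mutated_genes <= universe and specific_degs <= universe):
        raise ValueError("universe must contain both gene sets")
    n = len(specific_mutated_genes)
    p0 = len(specific_degs) / len(universe)
    k = len(specific_mutated_genes & specific_degs)
    return {
        "k_observed": k,
        "n": n,
        "p0": p0,
        "expected": n * p0,
        "binomial_p_two_sided": float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue),
        "binomial_p_depletion": float(stats.binomtest(k, n, p0, alternative="less").pvalue),
        "binomial_p_enrichment": float(stats.binomtest(k, n, p0, alternative="greater").pvalue),
    }


def gene_set_enrichment(
    gene_list: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set, BH across sets."""
    N = len(universe)
    n = len(gene_list & universe)
    rows = []
    for name, members in gene_sets.items():
        K = len(members & universe)
        if K == 0:
            logger.info("gene set %s has no universe members; skipped", name)
            continue
        k = len(gene_list & members & universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "pvalue"]).set_index("set")
    if len(out):
        out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["qvalue"] = []
    return out
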