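"""Synthetic multi-omics dataset with planted clonal structure.

The generator plants (i) a perfect-phylogeny clonal tree whose branches carry
known somatic SNVs, (ii) branch-shared and sample-specific copy-number events
on a triploid baseline, with a configurable fraction of losses rendered as
LOH, (iii) a CpG methylome with sample-specific global levels, region-level
baselines shared across samples, sample-specific regional drift (larger for
the designated divergent sample), and planted gene-body / promoter
methylation differences specific to the divergent sample, and (iv) replicate
negative-binomial expression counts whose means respond multiplicatively to
gene copy number and to the *planted* gene-body methylation differences —
promoter methylation is decoupled from expression by construction.

``generate_truth`` lays out the genome and the planted effects;
``render_dataset`` draws the observable read-count data. Both are
deterministic for a fixed config + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneRecord
from .config import ConfigurationError, SimulationConfig

_BASES = np.array(list("ACGT"))


@dataclass
class TruthSet:
    """Planted ground truth for recovery tests."""

    config: SimulationConfig
    tree: tuple                              # ingroup topology
    branch_variants: dict[str, list[str]]    # branch name -> variant ids
    snv_assignments: dict[str, frozenset]    # variant id -> carrier sample set
    snv_table: pd.DataFrame                  # chrom, pos, ref, alt, branch
    cna_truth: pd.DataFrame                  # sample, chrom, start, end, total_cn, b_allele_cn
    loh_truth: pd.DataFrame                  # sample, chrom, start, end
    driven_truth: pd.DataFrame               # gene-indexed: mechanism, direction, delta_cn, delta_ml, expected_log2fc
    methylation_truth: pd.DataFrame          # region_id, sample columns of target levels
    genes: list[GeneRecord] = field(default_factory=list)
    gene_table: pd.DataFrame | None = None
    cgi: pd.DataFrame | None = None
    repeats: pd.DataFrame | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    regions: pd.DataFrame | None = None      # region_id, chrom, start, end, kind, owner
    site_regions: pd.DataFrame | None = None # chrom, pos, region_id
    expression_means: pd.DataFrame | None = None  # gene x sample expected normalized mean


@dataclass
class DatasetBundle:
    """In-memory rendering of the observable data files."""

    config: SimulationConfig
    snv: pd.DataFrame
    segments: pd.DataFrame
    coverage: dict[str, pd.DataFrame]
    counts: pd.DataFrame
    gene_table: pd.DataFrame
    cgi: pd.DataFrame
    repeats: pd.DataFrame
    truth: TruthSet

    def write(self, outdir: str | Path) -> dict[str, str]:
        from . import io as cio
        return cio.write_bundle(self, Path(outdir))


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def _layout_genome(cfg: SimulationConfig, rng: np.random.Generator):
    genes: list[GeneRecord] = []
    chrom_lengths = {f"chr{i+1}": cfg.chrom_length_bp for i in range(cfg.n_chromosomes)}
    per_chrom = cfg.n_genes // cfg.n_chromosomes
    remainder = cfg.n_genes - per_chrom * cfg.n_chromosomes
    gene_rows = []
    for ci, chrom in enumerate(chrom_lengths):
        quota = per_chrom + (1 if ci < remainder else 0)
        pos = 50_000
        for gi in range(quota):
            gap = int(rng.integers(6_000, 14_000))
            span = int(rng.integers(3_000, 10_000))
            start = pos + gap
            end = start + span
            if end > cfg.chrom_length_bp - 50_000:
                raise ConfigurationError(
                    f"{chrom}: ran out of space at gene {gi + 1}/{quota}; "
                    "increase chrom_length_bp or lower n_genes"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[start], cuts, [end]])
            exons = tuple((int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons))
            tss, tes = (start, end) if strand == "+" else (end, start)
            gid = f"G{len(genes) + 1:05d}"
            genes.append(GeneRecord(gid, chrom, strand, tss, tes, exons))
            gene_rows.append((gid, chrom, strand, tss, tes,
                              ";".join(f"{s}-{e}" for s, e in exons)))
            pos = end
    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "tss", "tes", "exons"])

    # CpG islands sit inside promoters of a random gene subset
    cgi_genes = rng.choice(len(genes), size=min(cfg.n_cgi, len(genes)), replace=False)
    cgi_rows = []
    for k, idx in enumerate(sorted(cgi_genes)):
        g = genes[idx]
        start = g.tss - 200 if g.strand == "+" else g.tss - 800
        end = start + 1000
        cgi_rows.append((f"CGI{k + 1:04d}", g.chrom, int(start), int(end), g.gene_id))
    cgi = pd.DataFrame(cgi_rows, columns=["cgi_id", "chrom", "start", "end", "gene_id"])

    fams = np.array(["line", "sine", "ltr", "satellite"])
    rep_rows = []
    for k in range(cfg.n_repeats):
        chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
        start = int(rng.integers(1, cfg.chrom_length_bp - 5_000))
        rep_rows.append((chrom, start, start + int(rng.integers(500, 4_000)), str(rng.choice(fams))))
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "family"])
    return genes, gene_table, cgi, repeats, chrom_lengths


def _methylation_regions(cfg, rng, genes, gene_table, chrom_lengths):
    """Region units of the methylome generative model: one promoter and one
    body region per gene, plus the intergenic gaps between genes."""
    rows = []
    for g in genes:
        lo, hi = g.span
        # generative promoter region = upstream flank only, so planted body and
        # promoter methylation targets never share CpG sites
        if g.strand == "+":
            p_lo, p_hi = max(1, g.tss - 1500), g.tss - 1
        else:
            p_lo, p_hi = g.tss + 1, g.tss + 1500
        rows.append((f"prom_{g.gene_id}", g.chrom, p_lo, p_hi, "promoter", g.gene_id))
        rows.append((f"body_{g.gene_id}", g.chrom, lo, hi, "gene_body", g.gene_id))
    # intergenic gaps, tiled into <= 10 kb windows so no single region
    # baseline draw dominates the genome-wide mean
    tile = 10_000
    k = 0

    def add_gap(chrom: str, lo: int, hi: int):
        nonlocal k
        for s in range(lo, hi + 1, tile):
            e = min(s + tile - 1, hi)
            if e - s >= 200:
                rows.append((f"ig_{k:05d}", chrom, s, e, "intergenic", ""))
                k += 1

    for chrom, sub in gene_table.groupby("chrom", sort=False):
        spans = np.stack([np.minimum(sub["tss"], sub["tes"]) - 2_000,
                          np.maximum(sub["tss"], sub["tes"]) + 2_000], axis=1)
        prev = 1
        for s, e in spans:
            if s - 1 > prev + 500:
                add_gap(chrom, int(prev), int(s - 1))
            prev = max(prev, int(e) + 1)
        if chrom_lengths[chrom] > prev + 500:
            add_gap(chrom, prev, chrom_lengths[chrom])
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "kind", "owner"])


def _place_cpg_sites(cfg, rng, regions):
    """Allocate CpG sites to regions: genic and promoter regions are
    CpG-dense, intergenic space takes the remainder."""
    prom = regions[regions["kind"] == "promoter"]
    body = regions[regions["kind"] == "gene_body"]
    inter = regions[regions["kind"] == "intergenic"]
    n_body = int(0.35 * cfg.n_cpg_sites)
    n_prom = int(0.25 * cfg.n_cpg_sites)
    n_inter = cfg.n_cpg_sites - n_body - n_prom

    chunks = []

    def scatter(sub: pd.DataFrame, total: int):
        starts = sub["start"].to_numpy()
        widths = (sub["end"] - sub["start"] + 1).to_numpy()
        alloc = rng.multinomial(total, widths / widths.sum())
        rep = np.repeat(np.arange(len(sub)), alloc)
        pos = starts[rep] + (rng.random(len(rep)) * widths[rep]).astype(np.int64)
        chunks.append(pd.DataFrame({
            "chrom": sub["chrom"].to_numpy()[rep],
            "pos": pos,
            "region_id": sub["region_id"].to_numpy()[rep],
        }))

    scatter(body, n_body)
    scatter(prom, n_prom)
    scatter(inter, n_inter)
    sites = pd.concat(chunks, ignore_index=True)
    sites = sites.drop_duplicates(subset=["chrom", "pos"]).sort_values(["chrom", "pos"])
    return sites.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _draw_magnitude(rng, probs: dict[int, float]) -> int:
    mags = sorted(probs)
    p = np.array([probs[m] for m in mags], dtype=float)
    return int(rng.choice(mags, p=p / p.sum()))


def _plant_cna(cfg, rng, genes, gene_table, branches):
    """Branch-shared and divergent-sample CNA events snapped to gene runs."""
    used = np.zeros(len(genes), dtype=bool)
    gene_idx_by_chrom = {c: sub.index.to_numpy() for c, sub in gene_table.groupby("chrom")}
    events = []  # (carriers, chrom, start, end, total_cn, b_cn, gene_indices)

    def try_place(carriers) -> bool:
        for _ in range(60):
            chrom = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
            idx = gene_idx_by_chrom[chrom]
            run = int(rng.integers(cfg.cna_genes_per_event[0], cfg.cna_genes_per_event[1] + 1))
            if len(idx) <= run:
                continue
            start_i = int(rng.integers(0, len(idx) - run))
            sel = idx[start_i: start_i + run]
            if used[sel].any():
                continue
            used[sel] = True
            first, last = genes[sel[0]], genes[sel[-1]]
            # boundaries fall in the inter-gene gaps (>= 6 kb), so no gene is split
            seg_start = max(1, first.span[0] - 2_000)
            seg_end = last.span[1] + 2_000
            if rng.random() < cfg.gain_fraction:
                cn = cfg.baseline_ploidy + _draw_magnitude(rng, cfg.gain_magnitude_probs)
                b = 1
            else:
                cn = max(1, cfg.baseline_ploidy - _draw_magnitude(rng, cfg.loss_magnitude_probs))
                if cn <= 1:
                    b = 0
                else:
                    b = 0 if rng.random() < cfg.loh_fraction else 1
            events.append((carriers, chrom, seg_start, seg_end, cn, b, sel))
            return True
        return False

    for branch, carriers in branches.items():
        n = cfg.cna_events_per_branch
        if branch == cfg.divergent_sample:
            n += cfg.divergent_extra_cna_events
        for _ in range(n):
            try_place(carriers)
    return events


def generate_truth(config: SimulationConfig) -> TruthSet:
    """Lay out the genome and plant all ground-truth structure."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 101])
    genes, gene_table, cgi, repeats, chrom_lengths = _layout_genome(config, rng)
    regions = _methylation_regions(config, rng, genes, gene_table, chrom_lengths)
    site_regions = _place_cpg_sites(config, rng, regions)

    branches = config.branches()

    # --- SNVs -------------------------------------------------------------
    snv_rows = []
    branch_variants: dict[str, list[str]] = {b: [] for b in branches}
    assignments: dict[str, frozenset] = {}
    seen_loci: set[tuple[str, int]] = set()
    for branch, carriers in branches.items():
        count = config.branch_snv_counts.get(branch, 0)
        for _ in range(count):
            while True:
                chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
                pos = int(rng.integers(1, chrom_lengths[chrom]))
                if (chrom, pos) not in seen_loci:
                    seen_loci.add((chrom, pos))
                    break
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            vid = f"{chrom}:{pos}:{ref}>{alt}"
            snv_rows.append((chrom, pos, str(ref), str(alt), branch))
            branch_variants[branch].append(vid)
            assignments[vid] = carriers
    snv_table = pd.DataFrame(snv_rows, columns=["chrom", "pos", "ref", "alt", "branch"])

    # --- CNA / LOH ----------------------------------------------------------
    events = _plant_cna(config, rng, genes, gene_table, branches)
    cna_rows, loh_rows = [], []
    gene_cn = pd.DataFrame(config.baseline_ploidy,
                           index=gene_table["gene_id"], columns=list(config.samples))
    for carriers, chrom, start, end, cn, b, sel in events:
        for s in carriers:
            cna_rows.append((s, chrom, start, end, cn, b))
            if b == 0:
                loh_rows.append((s, chrom, start, end))
            gene_cn.loc[gene_table.loc[sel, "gene_id"], s] = cn
    cna_truth = pd.DataFrame(cna_rows, columns=["sample", "chrom", "start", "end",
                                                "total_cn", "b_allele_cn"])
    loh_truth = pd.DataFrame(loh_rows, columns=["sample", "chrom", "start", "end"])

    # --- methylome targets --------------------------------------------------
    meth_samples = config.methylation_samples
    div = config.divergent_sample
    n_regions = len(regions)
    base = rng.normal(0.0, config.region_baseline_sd, size=n_regions)
    targets = {}
    for s in meth_samples:
        sd = config.divergent_region_noise_sd if s == div else config.region_noise_sd
        drift = rng.normal(0.0, sd, size=n_regions)
        targets[s] = config.global_methylation_level[s] + base + drift
    methylation_truth = pd.DataFrame(targets, index=regions["region_id"])

    # --- planted divergent-sample effects ------------------------------------
    # A gene-body (promoter) methylation difference is only defined where the
    # region contains CpGs, so plantings are drawn from genes whose region
    # carries at least 3 simulated sites.
    all_gene_ids = gene_table["gene_id"].to_list()
    site_counts = site_regions["region_id"].value_counts()
    body_ok = {g for g in all_gene_ids if site_counts.get(f"body_{g}", 0) >= 3}
    prom_ok = {g for g in all_gene_ids if site_counts.get(f"prom_{g}", 0) >= 3}
    perm = [all_gene_ids[i] for i in rng.permutation(len(all_gene_ids))]
    dmgb_genes = [g for g in perm if g in body_ok][: config.n_planted_dmgb]
    dmp_genes = [g for g in perm
                 if g in prom_ok and g not in set(dmgb_genes)][: config.n_planted_dmp]
    planted = set(dmgb_genes) | set(dmp_genes)
    rest = [g for g in perm if g not in planted]
    ra_specific_cna = _divergent_specific_genes(gene_cn, div, config.baseline_ploidy)
    extra_pool = [g for g in rest if g not in ra_specific_cna]
    extra_deg = extra_pool[: config.n_extra_deg]

    d = config.dmgb_delta_ml
    dmgb_delta = pd.Series(
        rng.uniform(0.7 * d, 1.3 * d, size=len(dmgb_genes))
        * rng.choice([-1.0, 1.0], size=len(dmgb_genes)),
        index=dmgb_genes,
    )
    dmp_delta = pd.Series(
        rng.uniform(0.7 * d, 1.3 * d, size=len(dmp_genes))
        * rng.choice([-1.0, 1.0], size=len(dmp_genes)),
        index=dmp_genes,
    )
    extra_fc = pd.Series(
        rng.uniform(0.8, 1.4, size=len(extra_deg)) * config.extra_deg_log2fc
        * rng.choice([-1.0, 1.0], size=len(extra_deg)),
        index=extra_deg,
    )
    lo, hi = 0.02, 0.98
    if div in methylation_truth.columns:
        body_ids = [f"body_{g}" for g in dmgb_genes]
        before = methylation_truth.loc[body_ids, div].clip(lo, hi).to_numpy()
        methylation_truth.loc[body_ids, div] += dmgb_delta.to_numpy()
        methylation_truth.loc[[f"prom_{g}" for g in dmp_genes], div] += dmp_delta.to_numpy()
        # the achievable (realized) difference after the [0, 1] boundary;
        # truth records this, and expression couples to it, so the planted
        # effect is internally consistent even when a hypomethylation planting
        # hits the floor
        after = methylation_truth.loc[body_ids, div].clip(lo, hi).to_numpy()
        dmgb_delta = pd.Series(after - before, index=dmgb_genes)
    methylation_truth = methylation_truth.clip(lo, hi)

    # --- expected expression means -------------------------------------------
    w = rng.lognormal(mean=0.0, sigma=1.2, size=len(all_gene_ids))
    baseline = w / w.sum() * config.library_size_mean
    means = pd.DataFrame(
        np.repeat(baseline[:, None], len(config.samples), axis=1),
        index=all_gene_ids, columns=list(config.samples),
    )
    means *= (gene_cn / config.baseline_ploidy) ** config.dosage_coupling
    coup = config.methylation_expression_coupling
    means.loc[dmgb_genes, div] *= 2.0 ** (coup * dmgb_delta.to_numpy())
    means.loc[extra_deg, div] *= 2.0 ** extra_fc.to_numpy()

    # --- driven-gene truth ----------------------------------------------------
    other_samples = [s for s in config.samples if s != div]
    rows = []
    for g in sorted(set(dmgb_genes) | set(ra_specific_cna)):
        is_cna = g in ra_specific_cna
        is_meth = g in set(dmgb_genes)
        mech = "both" if (is_cna and is_meth) else ("cna" if is_cna else "methylation")
        delta_cn = int(gene_cn.loc[g, div] - gene_cn.loc[g, other_samples[0]]) if is_cna else 0
        delta_ml = float(dmgb_delta.get(g, 0.0))
        exp_fc = float(np.log2(means.loc[g, div])
                       - np.mean([np.log2(means.loc[g, s]) for s in other_samples]))
        rows.append((g, mech, "up" if exp_fc > 0 else "down", delta_cn, delta_ml, exp_fc))
    driven_truth = pd.DataFrame(
        rows, columns=["gene", "mechanism", "direction", "delta_cn", "delta_ml",
                       "expected_log2fc"]).set_index("gene")

    return TruthSet(
        config=config,
        tree=config.tree_topology,
        branch_variants=branch_variants,
        snv_assignments=assignments,
        snv_table=snv_table,
        cna_truth=cna_truth,
        loh_truth=loh_truth,
        driven_truth=driven_truth,
        methylation_truth=methylation_truth,
        genes=genes,
        gene_table=gene_table,
        cgi=cgi,
        repeats=repeats,
        chrom_lengths=chrom_lengths,
        regions=regions,
        site_regions=site_regions,
        expression_means=means,
    )


def _divergent_specific_genes(gene_cn: pd.DataFrame, div: str, baseline: int) -> set[str]:
    others = [c for c in gene_cn.columns if c != div]
    other_vals = gene_cn[others]
    agree = other_vals.nunique(axis=1) == 1
    differs = gene_cn[div] != other_vals.iloc[:, 0]
    return set(gene_cn.index[agree & differs])


# ---------------------------------------------------------------------------
# Rendering observable data
# ---------------------------------------------------------------------------

def _copy_number_at(cna: pd.DataFrame, sample: str, chrom: str, pos: np.ndarray,
                    baseline: int) -> np.ndarray:
    cn = np.full(len(pos), baseline, dtype=np.int64)
    sub = cna[(cna["sample"] == sample) & (cna["chrom"] == chrom)]
    for s, e, c in zip(sub["start"], sub["end"], sub["total_cn"]):
        cn[(pos >= s) & (pos <= e)] = c
    return cn


def render_dataset(truth: TruthSet, config: SimulationConfig | None = None) -> DatasetBundle:
    """Draw the observable data (read counts) from the planted truth."""
    config = config or truth.config
    rng = np.random.default_rng([int(config.seed), 202])

    # --- SNV read counts -----------------------------------------------------
    snv = truth.snv_table.copy()
    n = len(snv)
    snv["normal_var"] = 0
    for s in config.samples:
        depth = rng.poisson(config.snv_depth_mean, size=n)
        carrier = np.array([s in truth.snv_assignments[f"{c}:{p}:{r}>{a}"]
                            for c, p, r, a in zip(snv["chrom"], snv["pos"], snv["ref"], snv["alt"])])
        vaf = np.zeros(n)
        for chrom in snv["chrom"].unique():
            m = (snv["chrom"] == chrom).to_numpy()
            cn = _copy_number_at(truth.cna_truth, s, chrom, snv.loc[m, "pos"].to_numpy(),
                                 config.baseline_ploidy)
            vaf[m] = 1.0 / cn
        var = np.where(carrier, rng.binomial(np.maximum(depth, 1), vaf), 0)
        var = np.minimum(var, depth)
        fwd = rng.binomial(var, 0.5)
        snv[f"{s}_var_fwd"] = fwd
        snv[f"{s}_var_rev"] = var - fwd
        snv[f"{s}_depth"] = depth
    snv[f"{config.outgroup}_depth"] = rng.poisson(config.snv_depth_mean, size=n)
    snv = snv.drop(columns="branch").sort_values(["chrom", "pos"]).reset_index(drop=True)

    # --- SEG: whole-chromosome tiling per sample ------------------------------
    seg_rows = []
    for s in config.samples:
        sub = truth.cna_truth[truth.cna_truth["sample"] == s]
        for chrom, length in truth.chrom_lengths.items():
            ev = sub[sub["chrom"] == chrom].sort_values("start")
            prev = 1
            for _, r in ev.iterrows():
                if r["start"] > prev:
                    seg_rows.append((s, chrom, prev, r["start"] - 1, config.baseline_ploidy, 1))
                seg_rows.append((s, chrom, r["start"], r["end"], r["total_cn"], r["b_allele_cn"]))
                prev = r["end"] + 1
            if prev <= length:
                seg_rows.append((s, chrom, prev, length, config.baseline_ploidy, 1))
    segments = pd.DataFrame(seg_rows, columns=["sample", "chrom", "start", "end",
                                               "total_cn", "b_allele_cn"])

    # --- methylation coverage --------------------------------------------------
    sites = truth.site_regions
    target_by_region = truth.methylation_truth
    kappa = config.beta_precision
    coverage = {}
    region_targets_idx = sites["region_id"].to_numpy()
    for s in config.methylation_samples:
        t = target_by_region[s].reindex(region_targets_idx).to_numpy()
        p = rng.beta(t * kappa, (1 - t) * kappa)
        cov = rng.poisson(config.cpg_coverage_mean, size=len(sites))
        meth = rng.binomial(cov, p)
        coverage[s] = pd.DataFrame({
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "meth": meth,
            "unmeth": cov - meth,
        })

    # --- expression counts -------------------------------------------------------
    means = truth.expression_means
    cols = {}
    phi = config.nb_dispersion
    for s in config.samples:
        for r in range(1, config.n_replicates + 1):
            lib = rng.lognormal(0.0, 0.08)
            mu = means[s].to_numpy() * lib
            lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
            cols[f"{s}.rep{r}"] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=means.index)
    counts.index.name = "gene_id"

    return DatasetBundle(
        config=config,
        snv=snv,
        segments=segments,
        coverage=coverage,
        counts=counts,
        gene_table=truth.gene_table,
        cgi=truth.cgi,
        repeats=truth.repeats,
        truth=truth,
    )


def truth_summary_json(truth: TruthSet) -> str:
    """Flat machine-readable truth record (written alongside the dataset)."""
    payload = {
        "tree": _nested(truth.tree),
        "branch_variant_counts": {b: len(v) for b, v in truth.branch_variants.items()},
        "n_variants": int(len(truth.snv_table)),
        "n_cna_segments": int(len(truth.cna_truth)),
        "n_loh_segments": int(len(truth.loh_truth)),
        "driven_counts": truth.driven_truth["mechanism"].value_counts().to_dict(),
        "global_methylation_level": truth.config.global_methylation_level,
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def _nested(node):
    return [_nested(c) for c in node] if isinstance(node, tuple) else node
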