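"""End-to-end orchestration of the analysis stages.

Stages run in dependency order: simulate -> variants -> phylogeny ->
expression -> methylation -> integrate -> report. Each stage reads the
standard-format files written by its upstream stages (so stages can be re-run
individually) and writes its artifacts under the output directory; a manifest
with SHA-256 content hashes records every file written.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr
from . import integration as integ
from . import io as cio
from . import methylation as meth
from . import phylogeny as phylo
from .config import PipelineConfig
from .simulate import generate_truth, render_dataset

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "variants", "phylogeny", "expression", "methylation",
               "integrate", "report"]


class DependencyError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.outdir = Path(config.outdir)
        self.datadir = self.outdir / "data"
        self.artifacts: dict[str, Path] = {}

    # -- helpers ---------------------------------------------------------

    def _write(self, name: str, path: Path) -> Path:
        self.artifacts[name] = path
        return path

    def _require(self, path: Path, producer: str) -> Path:
        if not path.exists():
            raise DependencyError(f"missing artifact {path}; run the {producer!r} stage first")
        return path

    def _input(self, kind: str, sample: str | None = None) -> Path:
        cfg = self.config
        explicit = {
            "snv": cfg.snv_path, "counts": cfg.counts_path, "genes": cfg.genes_path,
            "cgi": cfg.cgi_path, "repeats": cfg.repeats_path,
        }
        if sample is None and explicit.get(kind):
            return Path(explicit[kind])
        if kind == "seg" and sample in cfg.seg_paths:
            return Path(cfg.seg_paths[sample])
        if kind == "coverage" and sample in cfg.coverage_paths:
            return Path(cfg.coverage_paths[sample])
        names = {"snv": "snv.tsv", "counts": "counts.tsv", "genes": "genes.tsv",
                 "cgi": "cgi.bed", "repeats": "repeats.bed",
                 "seg": f"{sample}.seg.tsv", "coverage": f"{sample}.cov.tsv"}
        return self._require(self.datadir / names[kind], "simulate")

    def _coverage_samples(self) -> list[str]:
        if self.config.coverage_paths:
            return list(self.config.coverage_paths)
        if self.config.simulate is not None:
            return self.config.simulate.methylation_samples
        return [s for s in self.config.samples if (self.datadir / f"{s}.cov.tsv").exists()]

    # -- stages -----------------------------------------------------------

    def stage_simulate(self) -> None:
        if self.config.simulate is None:
            raise DependencyError("no simulate block in the config; provide input paths instead")
        sim = self.config.simulate
        truth = generate_truth(sim)
        bundle = render_dataset(truth)
        paths = bundle.write(self.datadir)
        for name, p in paths.items():
            self._write(f"data/{name}", Path(p))
        self._truth = truth

    def stage_variants(self) -> None:
        cfg = self.config
        raw = cio.read_snv_table(self._input("snv"))
        segments = pd.concat(
            [cio.read_seg(self._input("seg", s), s) for s in cfg.samples], ignore_index=True
        )
        filtered = phylo.filter_snvs(raw, list(cfg.samples),
                                     min_vaf=cfg.min_vaf, min_reads=cfg.min_reads)
        n_filtered = len(filtered)
        presence_all = phylo.presence_matrix(filtered, list(cfg.samples))
        shared, polymorphic = phylo.classify_shared_polymorphic(presence_all)
        masked = phylo.mask_loh(filtered, segments, list(cfg.samples))
        presence = phylo.presence_matrix(masked, list(cfg.samples))

        p = self.outdir / "presence_matrix.tsv"
        presence.astype(int).to_csv(p, sep="\t")
        self._write("presence_matrix", p)
        summary = {
            "n_filtered_snvs": int(n_filtered),
            "n_shared": len(shared),
            "n_polymorphic": len(polymorphic),
            "pct_shared": integ.shared_fraction_percent(len(shared), n_filtered)
            if n_filtered else float("nan"),
            "n_after_loh_mask": int(len(masked)),
        }
        p = self.outdir / "variants_summary.json"
        p.write_text(json.dumps(summary, indent=2) + "\n")
        self._write("variants_summary", p)
        self._segments = segments
        self._filtered_snvs = masked

    def stage_phylogeny(self) -> None:
        p = self._require(self.outdir / "presence_matrix.tsv", "variants")
        presence = pd.read_csv(p, sep="\t", index_col=0).astype(bool)
        presence[self.config.outgroup] = False
        tree = phylo.wagner_tree(presence, outgroup=self.config.outgroup)
        out = self.outdir / "phylogeny.nwk"
        cio.write_newick(tree.newick, out)
        self._write("phylogeny", out)
        summary = {
            "newick": tree.newick,
            "total_score": tree.total_score,
            "n_tied_topologies": len(tree.tied_newicks),
        }
        p = self.outdir / "phylogeny_summary.json"
        p.write_text(json.dumps(summary, indent=2) + "\n")
        self._write("phylogeny_summary", p)
        self._tree = tree

    def stage_expression(self) -> None:
        cfg = self.config
        counts = cio.read_counts(self._input("counts"))
        rep_map = expr.replicate_map(list(counts.columns))
        normalized, factors = expr.upper_quartile_normalize(counts)
        p = self.outdir / "normalized_counts.tsv"
        normalized.to_csv(p, sep="\t", float_format="%.4f")
        self._write("normalized_counts", p)

        corr = expr.transcriptome_divergence(normalized, rep_map, method="spearman")
        p = self.outdir / "transcriptome_correlation.tsv"
        corr.to_csv(p, sep="\t", float_format="%.6f")
        self._write("transcriptome_correlation", p)

        means = expr.sample_means(normalized, rep_map)
        keep = expr.expressed_genes(normalized, rep_map)
        newick, merge_order = expr.hierarchical_cluster(np.log2(means.loc[keep] + 1))
        p = self.outdir / "expression_dendrogram.nwk"
        cio.write_newick(newick, p)
        self._write("expression_dendrogram", p)

        deg_tables = []
        focal = cfg.focal_sample
        for other in [s for s in cfg.samples if s != focal]:
            dt = expr.call_degs(normalized, (other, focal), rep_map,
                                score_threshold=cfg.score_threshold,
                                fc_threshold=cfg.fc_threshold, normalized=True)
            deg_tables.append(dt)
            p = self.outdir / f"deg_{other}_vs_{focal}.tsv"
            dt.table.to_csv(p, sep="\t", float_format="%.6g")
            self._write(f"deg_{other}_vs_{focal}", p)
        specific = expr.sample_specific_degs(deg_tables, focal)
        p = self.outdir / f"degs_specific_{focal}.tsv"
        specific.to_csv(p, sep="\t", float_format="%.6g")
        self._write("degs_specific", p)

        self._normalized = normalized
        self._rep_map = rep_map
        self._sample_means = means
        self._expressed = keep
        self._expr_merge_order = merge_order
        self._specific_degs = specific

    def stage_methylation(self) -> None:
        cfg = self.config
        samples = self._coverage_samples()
        coverage = {s: cio.read_bismark_coverage(self._input("coverage", s)) for s in samples}
        table = meth.load_and_filter_sites(coverage, min_depth=cfg.min_depth)

        means = {s: meth.genome_mean(table, s) for s in samples}
        wilcoxon = {
            f"{a}_vs_{b}": meth.global_compare(table, (a, b))
            for a, b in itertools.combinations(samples, 2)
        }
        newick, merge_order = meth.cluster_methylomes(table)
        p = self.outdir / "methylome_dendrogram.nwk"
        cio.write_newick(newick, p)
        self._write("methylome_dendrogram", p)

        genes = cio.read_gene_table(self._input("genes"))
        from .annotation import gene_body_of, promoter_of
        region_rows = []
        for g in genes:
            pr = promoter_of(g)
            gb = gene_body_of(g)
            region_rows.append((f"prom_{g.gene_id}", pr.chrom, pr.start, pr.end, "promoter", g.gene_id))
            region_rows.append((f"body_{g.gene_id}", gb.chrom, gb.start, gb.end, "gene_body", g.gene_id))
        regions = pd.DataFrame(region_rows, columns=["region_id", "chrom", "start", "end",
                                                     "category", "owner_id"])
        region_meth = meth.region_levels(table, regions, min_sites=cfg.min_region_sites)
        p = self.outdir / "region_methylation.tsv"
        region_meth.to_csv(p, sep="\t", float_format="%.6g")
        self._write("region_methylation", p)

        focal = cfg.focal_sample
        others = [s for s in samples if s != focal]
        if focal in samples and others:
            for category, label in (("gene_body", "dmgb"), ("promoter", "dmp")):
                sub = region_meth[region_meth["category"] == category]
                specific = meth.sample_specific_dmf(sub, focal, others,
                                                    delta=cfg.delta, alpha=cfg.alpha)
                p = self.outdir / f"{label}_specific_{focal}.tsv"
                specific.to_csv(p, sep="\t", float_format="%.6g")
                self._write(f"{label}_specific", p)
                setattr(self, f"_specific_{label}", specific)

        summary = {"genome_mean_methylation": means,
                   "wilcoxon": {k: v["pvalue"] for k, v in wilcoxon.items()},
                   "n_sites": int(len(table))}
        p = self.outdir / "methylation_summary.json"
        p.write_text(json.dumps(summary, indent=2) + "\n")
        self._write("methylation_summary", p)

        self._meth_table = table
        self._meth_samples = samples
        self._region_meth = region_meth
        self._meth_merge_order = merge_order
        self._genes = genes

    def stage_integrate(self) -> None:
        cfg = self.config
        focal = cfg.focal_sample
        genes = getattr(self, "_genes", None) or cio.read_gene_table(self._input("genes"))
        segments = getattr(self, "_segments", None)
        if segments is None:
            segments = pd.concat(
                [cio.read_seg(self._input("seg", s), s) for s in cfg.samples], ignore_index=True
            )
        if not hasattr(self, "_sample_means"):
            raise DependencyError("expression results missing; run the 'expression' stage first")

        dosage = integ.genes_in_cna(segments, genes, baseline_ploidy=cfg.baseline_ploidy)
        p = self.outdir / "gene_dosage.tsv"
        dosage.to_csv(p, sep="\t", index=False)
        self._write("gene_dosage", p)

        means = self._sample_means
        log2_means = np.log2(means + 1)
        ks = {}
        for a, b in itertools.combinations(cfg.samples, 2):
            ks[f"{a}_vs_{b}"] = integ.ks_dosage_test(dosage, log2_means, (a, b),
                                                     sample_means=means)
        p = self.outdir / "ks_dosage.json"
        p.write_text(json.dumps(ks, indent=2) + "\n")
        self._write("ks_dosage", p)

        cna_specific = integ.sample_specific_cna_genes(dosage, focal)
        p = self.outdir / f"cna_specific_{focal}.tsv"
        cna_specific.to_csv(p, sep="\t")
        self._write("cna_specific", p)

        correlations = {}
        meth_samples = getattr(self, "_meth_samples", [])
        if focal in meth_samples:
            others = [s for s in meth_samples if s != focal]
            region_meth = self._region_meth
            for category, label in (("gene_body", "dmgb"), ("promoter", "dmp")):
                sub = region_meth[region_meth["category"] == category]
                for other in others:
                    dmf = meth.call_dmf(sub, (focal, other), delta=cfg.delta, alpha=cfg.alpha)
                    dmf = dmf[dmf["is_dmf"]]
                    fc = log2_means[focal] - log2_means[other]
                    try:
                        res = integ.dml_expression_correlation(dmf, fc)
                    except ValueError:
                        continue
                    correlations[f"{label}_{focal}_vs_{other}"] = {
                        "pearson_r": res["pearson_r"], "pvalue": res["pvalue"], "n": res["n"],
                    }
        p = self.outdir / "dml_expression_correlation.json"
        p.write_text(json.dumps(correlations, indent=2) + "\n")
        self._write("dml_expression_correlation", p)

        specific_degs = self._specific_degs
        dmgb = getattr(self, "_specific_dmgb", pd.DataFrame(columns=["owner_id", "delta_ml"]))
        driven = integ.classify_driven(cna_specific, dmgb, specific_degs)
        p = self.outdir / f"driven_genes_{focal}.tsv"
        driven.calls.to_csv(p, sep="\t", float_format="%.6g")
        self._write("driven_genes", p)

        mutated = self._sample_specific_mutated_genes(genes, focal)
        universe = set(map(str, means.index))
        overlap = integ.mutation_deg_overlap(mutated & universe,
                                             set(specific_degs.index) & universe, universe)

        enrichment = None
        if cfg.gmt_path:
            sets = cio.read_gmt(Path(cfg.gmt_path))
            enrichment = integ.gene_set_enrichment(set(driven.calls.index), sets, universe)
            p = self.outdir / "enrichment.tsv"
            enrichment.to_csv(p, sep="\t", float_format="%.6g")
            self._write("enrichment", p)

        summary = {"driven_summary": driven.summary, "mutation_deg_overlap": overlap,
                   "ks": ks}
        p = self.outdir / "integration_summary.json"
        p.write_text(json.dumps(summary, indent=2) + "\n")
        self._write("integration_summary", p)
        self._driven = driven

    def _sample_specific_mutated_genes(self, genes, focal: str) -> set[str]:
        """Genes whose body contains an SNV present only in the focal sample."""
        snvs = getattr(self, "_filtered_snvs", None)
        if snvs is None:
            raise DependencyError("filtered SNVs missing; run the 'variants' stage first")
        others = [s for s in self.config.samples if s != focal]
        focal_only = snvs[
            snvs[f"present_{focal}"]
            & ~np.logical_or.reduce([snvs[f"present_{o}"].to_numpy() for o in others])
        ]
        by_chrom: dict[str, list] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        out = set()
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: g.span[0])
            starts = np.array([g.span[0] for g in gs])
            ends = np.array([g.span[1] for g in gs])
            for pos in focal_only.loc[focal_only["chrom"] == chrom, "pos"]:
                i = np.searchsorted(starts, pos, side="right") - 1
                if i >= 0 and ends[i] >= pos:
                    out.add(gs[i].gene_id)
        return out

    def stage_report(self) -> None:
        for name in ("phylogeny_summary.json", "integration_summary.json"):
            self._require(self.outdir / name, "phylogeny/integrate")
        report = {}
        for name in ("variants_summary", "phylogeny_summary", "methylation_summary",
                     "integration_summary"):
            path = self.outdir / f"{name}.json"
            if path.exists():
                report[name] = json.loads(path.read_text())
        p = self.outdir / "report.json"
        p.write_text(json.dumps(report, indent=2) + "\n")
        self._write("report", p)

        lines = ["clonediv pipeline report", "========================", ""]
        v = report.get("variants_summary", {})
        if v:
            lines += [
                f"Somatic SNVs after filtering: {v['n_filtered_snvs']}",
                f"  shared in all samples:      {v['n_shared']}",
                f"  polymorphic:                {v['n_polymorphic']}",
                f"  shared percentage:          {v['pct_shared']}%",
                f"  after LOH masking:          {v['n_after_loh_mask']}", "",
            ]
        ph = report.get("phylogeny_summary", {})
        if ph:
            lines += [f"Parsimony tree: {ph['newick']} (score {ph['total_score']})", ""]
        it = report.get("integration_summary", {})
        if it:
            d = it["driven_summary"]
            lines += [
                "Driven-gene accounting:",
                f"  CNA overlap {d['n_cna_overlap']}, consistent {d['n_cna_consistent']} ({d['pct_cna']}%)",
                f"  DMGB overlap {d['n_dmgb_overlap']}, consistent {d['n_dmgb_consistent']} ({d['pct_dmgb']}%)",
                f"  both {d['n_both']}, union {d['n_union']}", "",
            ]
        p = self.outdir / "report.txt"
        p.write_text("\n".join(lines) + "\n")
        self._write("report_txt", p)

    # -- driver --------------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> dict[str, str]:
        stages = stages or STAGE_ORDER
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.config.simulate is None and "simulate" in stages:
            stages = [s for s in stages if s != "simulate"]
        self.outdir.mkdir(parents=True, exist_ok=True)
        for stage in STAGE_ORDER:
            if stage in stages:
                logger.info("running stage %s", stage)
                getattr(self, f"stage_{stage}")()
        manifest = {name: {"path": str(p), "sha256": _sha256(Path(p))}
                    for name, p in sorted(self.artifacts.items())}
        p = self.outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2) + "\n")
        return {name: rec["sha256"] for name, rec in manifest.items()}


def run(config: PipelineConfig, stages: list[str] | None = None) -> Pipeline:
    """Run the pipeline; returns the Pipeline object with in-memory results."""
    pipe = Pipeline(config)
    pipe.run(stages)
    return pipe
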