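"""Readers and writers for the standard text formats the pipeline consumes.

Internal coordinates are 1-based inclusive. BED input (0-based, half-open) is
converted exactly at this boundary: BED ``[start, end)`` becomes internal
``[start + 1, end]``. Bismark coverage files are position records (start ==
end, 1-based). Malformed lines raise with the file name and line number.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import CategoryInterval, GeneRecord

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    def __init__(self, path, lineno: int | None, message: str):
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")


# --- SNV table / minimal VCF -------------------------------------------------

def write_snv_table(snv: pd.DataFrame, path: Path) -> None:
    snv.to_csv(path, sep="\t", index=False)


def read_snv_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt", "normal_var"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(path, None, f"missing SNV columns: {sorted(missing)}")
    return df


def write_vcf(snv: pd.DataFrame, samples: list[str], path: Path) -> None:
    """Minimal VCF 4.2 with strand-split allele depths in a custom FORMAT.

    FORMAT ``DP:VF:VR`` = total depth, variant reads forward, variant reads
    reverse per sample; the matched normal's variant reads go in INFO NV.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=NV,Number=1,Type=Integer,Description="Variant reads in matched normal">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=VF,Number=1,Type=Integer,Description="Variant reads, forward strand">\n')
        fh.write('##FORMAT=<ID=VR,Number=1,Type=Integer,Description="Variant reads, reverse strand">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for _, r in snv.iterrows():
            cells = [
                str(r["chrom"]), str(int(r["pos"])), ".", str(r["ref"]), str(r["alt"]),
                ".", "PASS", f"NV={int(r['normal_var'])}", "DP:VF:VR",
            ]
            for s in samples:
                cells.append(f"{int(r[f'{s}_depth'])}:{int(r[f'{s}_var_fwd'])}:{int(r[f'{s}_var_rev'])}")
            fh.write("\t".join(cells) + "\n")


def read_vcf(path: Path) -> pd.DataFrame:
    """Read the minimal VCF back into the flat SNV-table layout."""
    rows = []
    samples: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(path, lineno, f"expected >= 10 VCF columns, got {len(parts)}")
            info = dict(kv.split("=") for kv in parts[7].split(";") if "=" in kv)
            row = {
                "chrom": parts[0], "pos": int(parts[1]), "ref": parts[3], "alt": parts[4],
                "normal_var": int(info.get("NV", 0)),
            }
            keys = parts[8].split(":")
            for s, cell in zip(samples, parts[9:]):
                vals = dict(zip(keys, cell.split(":")))
                row[f"{s}_depth"] = int(vals["DP"])
                row[f"{s}_var_fwd"] = int(vals["VF"])
                row[f"{s}_var_rev"] = int(vals["VR"])
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df["pos"].is_monotonic_increasing:
        by_chrom = df.groupby("chrom")["pos"].is_monotonic_increasing
        if not by_chrom.all():
            logger.warning("%s: unsorted positions; sorting internally", path)
            df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return df


# --- SEG -----------------------------------------------------------------------

SEG_COLUMNS = ["chrom", "start", "end", "total_cn", "b_allele_cn"]


def write_seg(segments: pd.DataFrame, sample: str, path: Path) -> None:
    sub = segments[segments["sample"] == sample][SEG_COLUMNS]
    sub.to_csv(path, sep="\t", index=False)


def read_seg(path: Path, sample: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(path, None, f"missing SEG columns: {sorted(missing)}")
    if (df["b_allele_cn"] > df["total_cn"]).any():
        bad = int(np.argmax((df["b_allele_cn"] > df["total_cn"]).to_numpy())) + 2
        raise FormatError(path, bad, "b_allele_cn exceeds total_cn")
    df.insert(0, "sample", sample)
    return df


# --- Bismark coverage ------------------------------------------------------------

def write_bismark_coverage(cov: pd.DataFrame, path: Path) -> None:
    """chrom, start, end, methylation %, count methylated, count unmethylated."""
    total = cov["meth"] + cov["unmeth"]
    pct = np.where(total > 0, 100.0 * cov["meth"] / np.maximum(total, 1), 0.0)
    out = pd.DataFrame({
        "chrom": cov["chrom"], "start": cov["pos"], "end": cov["pos"],
        "pct": np.round(pct, 6), "meth": cov["meth"], "unmeth": cov["unmeth"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bismark_coverage(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "pct", "meth", "unmeth"])
    if df[["meth", "unmeth"]].lt(0).any().any():
        bad = int(df[["meth", "unmeth"]].lt(0).any(axis=1).idxmax()) + 1
        raise FormatError(path, bad, "negative count")
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["start"],
                         "meth": df["meth"], "unmeth": df["unmeth"]})


# --- counts ------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: Path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise FormatError(path, None, "negative counts")
    return df


# --- gene annotation / BED -----------------------------------------------------------

def write_gene_table(gene_table: pd.DataFrame, path: Path) -> None:
    gene_table.to_csv(path, sep="\t", index=False)


def read_gene_table(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for i, r in df.iterrows():
        exons = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in str(r["exons"]).split(";") if part and part != "nan"
        )
        try:
            genes.append(GeneRecord(r["gene_id"], r["chrom"], r["strand"],
                                    int(r["tss"]), int(r["tes"]), exons))
        except ValueError as exc:
            raise FormatError(path, int(i) + 2, str(exc)) from exc
    return genes


def write_bed(intervals: pd.DataFrame, path: Path, name_col: str | None = None) -> None:
    """Write internal 1-based inclusive intervals as BED (0-based half-open)."""
    out = pd.DataFrame({
        "chrom": intervals["chrom"],
        "start": intervals["start"] - 1,
        "end": intervals["end"],
    })
    out["name"] = intervals[name_col] if name_col else "."
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: Path, category: str | None = None) -> list[CategoryInterval]:
    """BED [start, end) -> internal [start+1, end]; name column becomes the
    owner id, or the category when ``category`` is None (repeat BEDs)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(path, lineno, "BED line has fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(path, lineno, f"empty BED interval [{start},{end})")
            name = parts[3] if len(parts) > 3 else ""
            cat = category if category is not None else name
            out.append(CategoryInterval(cat, chrom, start + 1, end, name if category else ""))
    return out


# --- GMT ---------------------------------------------------------------------------

def read_gmt(path: Path) -> dict[str, set[str]]:
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(path, lineno, "GMT line needs name, description, >= 1 gene")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "."] + sorted(members)) + "\n")


# --- Newick ------------------------------------------------------------------------

def write_newick(newick: str, path: Path) -> None:
    Path(path).write_text(newick + "\n")


# --- dataset bundle ------------------------------------------------------------------

def write_bundle(bundle, outdir: Path) -> dict[str, str]:
    """Write every file of a rendered dataset; returns name -> path."""
    from .simulate import truth_summary_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def record(name: str, path: Path):
        paths[name] = str(path)

    p = outdir / "snv.tsv"
    write_snv_table(bundle.snv, p)
    record("snv", p)
    p = outdir / "snv.vcf"
    write_vcf(bundle.snv, list(bundle.config.samples), p)
    record("vcf", p)
    for s in bundle.config.samples:
        p = outdir / f"{s}.seg.tsv"
        write_seg(bundle.segments, s, p)
        record(f"seg_{s}", p)
    for s, cov in bundle.coverage.items():
        p = outdir / f"{s}.cov.tsv"
        write_bismark_coverage(cov, p)
        record(f"coverage_{s}", p)
    p = outdir / "counts.tsv"
    write_counts(bundle.counts, p)
    record("counts", p)
    p = outdir / "genes.tsv"
    write_gene_table(bundle.gene_table, p)
    record("genes", p)
    p = outdir / "cgi.bed"
    write_bed(bundle.cgi, p, name_col="cgi_id")
    record("cgi", p)
    p = outdir / "repeats.bed"
    write_bed(bundle.repeats, p, name_col="family")
    record("repeats", p)
    p = outdir / "truth.json"
    p.write_text(truth_summary_json(bundle.truth) + "\n")
    record("truth", p)
    p = outdir / "truth_driven.tsv"
    bundle.truth.driven_truth.to_csv(p, sep="\t")
    record("truth_driven", p)
    p = outdir / "truth_snv.tsv"
    bundle.truth.snv_table.to_csv(p, sep="\t", index=False)
    record("truth_snv", p)
    return paths
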