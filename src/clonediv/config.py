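"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


class ConfigurationError(ValueError):
    pass


def _default_branch_snv_counts() -> dict[str, int]:
    return {
        "trunk": 300,
        "Pa+Pb": 50,
        "Ra+Rb": 50,
        "Pa": 25,
        "Pb": 25,
        "Ra": 25,
        "Rb": 25,
    }


def _default_global_methylation() -> dict[str, float]:
    # WGBS layer mirrors the three-sample study design
    return {"Pa": 0.46, "Ra": 0.41, "Rb": 0.41}


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic multi-omics dataset.

    The defaults describe four tumor subclones (Pa, Pb from a primary tumor;
    Ra, Rb from the recurrence) plus a lymphocyte outgroup, on a triploid
    genome, with the recurrent subclone Ra carrying the sample-specific
    copy-number, methylome, and expression divergence.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length_bp: int = 20_000_000
    n_genes: int = 3000
    n_cgi: int = 600
    n_cpg_sites: int = 60_000
    n_repeats: int = 300
    samples: tuple[str, ...] = ("Pa", "Pb", "Ra", "Rb")
    outgroup: str = "TIL"
    tree_topology: tuple = (("Pa", "Pb"), ("Ra", "Rb"))
    branch_snv_counts: dict[str, int] = field(default_factory=_default_branch_snv_counts)
    baseline_ploidy: int = 3
    cna_events_per_branch: int = 2
    divergent_extra_cna_events: int = 3
    cna_genes_per_event: tuple[int, int] = (15, 30)
    gain_magnitude_probs: dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    loss_magnitude_probs: dict[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.4})
    gain_fraction: float = 0.5
    loh_fraction: float = 0.5
    global_methylation_level: dict[str, float] = field(default_factory=_default_global_methylation)
    region_baseline_sd: float = 0.12
    region_noise_sd: float = 0.02
    divergent_region_noise_sd: float = 0.06
    beta_precision: float = 30.0
    cpg_coverage_mean: float = 25.0
    snv_depth_mean: float = 60.0
    n_planted_dmgb: int = 150
    n_planted_dmp: int = 100
    dmgb_delta_ml: float = 0.35
    methylation_expression_coupling: float = 5.0
    dosage_coupling: float = 1.0
    n_extra_deg: int = 150
    extra_deg_log2fc: float = 1.5
    nb_dispersion: float = 0.02
    n_replicates: int = 2
    library_size_mean: float = 1_000_000.0
    divergent_sample: str = "Ra"

    def validate(self) -> None:
        leaves = _topology_leaves(self.tree_topology)
        sample_set = set(self.samples)
        for leaf in leaves:
            if leaf not in sample_set:
                raise ConfigurationError(f"topology leaf {leaf!r} is not in the sample list")
        for s in self.samples:
            if s not in set(leaves):
                raise ConfigurationError(f"sample {s!r} missing from the topology")
        if self.outgroup in sample_set or self.outgroup in set(leaves):
            raise ConfigurationError(f"outgroup {self.outgroup!r} must not appear in the ingroup topology")
        if len(leaves) != len(set(leaves)):
            raise ConfigurationError("duplicate leaves in topology")
        for name, level in self.global_methylation_level.items():
            if not 0.0 <= level <= 1.0:
                raise ConfigurationError(f"methylation level for {name} outside [0, 1]: {level}")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if not 0.0 <= self.loh_fraction <= 1.0:
            raise ConfigurationError("loh_fraction outside [0, 1]")
        if self.divergent_sample not in sample_set:
            raise ConfigurationError(f"divergent sample {self.divergent_sample!r} not in samples")
        for branch, count in self.branch_snv_counts.items():
            if count < 0:
                raise ConfigurationError(f"negative SNV count for branch {branch}")
            if branch != "trunk":
                for leaf in branch.split("+"):
                    if leaf not in sample_set:
                        raise ConfigurationError(f"branch {branch!r} names unknown leaf {leaf!r}")
        if self.baseline_ploidy < 1:
            raise ConfigurationError("baseline_ploidy must be >= 1")

    @property
    def methylation_samples(self) -> list[str]:
        return [s for s in self.samples if s in self.global_methylation_level]

    def branches(self) -> dict[str, frozenset]:
        """Branch name -> carrier leaf set, derived from the topology."""
        out: dict[str, frozenset] = {"trunk": frozenset(self.samples)}

        def walk(node):
            if isinstance(node, tuple):
                leaves = frozenset(_topology_leaves(node))
                if leaves != frozenset(self.samples):
                    out["+".join(sorted(leaves))] = leaves
                for child in node:
                    walk(child)
            else:
                out[node] = frozenset([node])

        walk(self.tree_topology)
        return out

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["samples"] = list(self.samples)
        d["tree_topology"] = _topology_to_nested_lists(self.tree_topology)
        d["cna_genes_per_event"] = list(self.cna_genes_per_event)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "samples" in d:
            d["samples"] = tuple(d["samples"])
        if "tree_topology" in d:
            d["tree_topology"] = _nested_lists_to_topology(d["tree_topology"])
        if "cna_genes_per_event" in d:
            d["cna_genes_per_event"] = tuple(d["cna_genes_per_event"])
        for key in ("gain_magnitude_probs", "loss_magnitude_probs"):
            if key in d:
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _topology_leaves(node) -> list[str]:
    if isinstance(node, (tuple, list)):
        out: list[str] = []
        for child in node:
            out.extend(_topology_leaves(child))
        return out
    return [node]


def _topology_to_nested_lists(node):
    if isinstance(node, (tuple, list)):
        return [_topology_to_nested_lists(c) for c in node]
    return node


def _nested_lists_to_topology(node):
    if isinstance(node, (tuple, list)):
        return tuple(_nested_lists_to_topology(c) for c in node)
    return node


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; inputs come either from ``simulate`` or
    from paths to standard-format files."""

    outdir: str = "clonediv_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    # input paths, used when not simulating
    snv_path: str | None = None
    seg_paths: dict[str, str] = field(default_factory=dict)
    coverage_paths: dict[str, str] = field(default_factory=dict)
    counts_path: str | None = None
    genes_path: str | None = None
    cgi_path: str | None = None
    repeats_path: str | None = None
    gmt_path: str | None = None
    samples: tuple[str, ...] = ("Pa", "Pb", "Ra", "Rb")
    outgroup: str = "TIL"
    focal_sample: str = "Ra"
    # thresholds
    min_vaf: float = 0.10
    min_reads: int = 5
    min_depth: int = 10
    delta: float = 0.20
    alpha: float = 0.05
    score_threshold: float = 0.99
    fc_threshold: float = 1.5
    baseline_ploidy: int = 3
    min_region_sites: int = 3

    def validate(self) -> None:
        if self.focal_sample not in self.samples:
            raise ConfigurationError(f"focal sample {self.focal_sample!r} not in samples")
        for name, value, lo, hi in (
            ("min_vaf", self.min_vaf, 0.0, 1.0),
            ("delta", self.delta, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
            ("score_threshold", self.score_threshold, 0.0, 1.0),
        ):
            if not lo <= value <= hi:
                raise ConfigurationError(f"{name} = {value} outside [{lo}, {hi}]")
        if self.fc_threshold < 1.0:
            raise ConfigurationError("fc_threshold must be >= 1")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: (tuple(v) if k == "samples" else v) for k, v in raw.items()})
        if sim is not None:
            cfg.simulate = SimulationConfig.from_dict(sim)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["samples"] = list(self.samples)
        d["simulate"] = self.simulate.to_dict() if self.simulate else None
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
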