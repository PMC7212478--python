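"""Expression normalization, differential expression, and divergence.

Counts are normalized to the overall upper quartile: each library is scaled
so that its 75th percentile over genes with nonzero count equals the mean of
the raw per-library upper quartiles. Differential expression between two
samples (each with replicate libraries) uses an overdispersed-count z-test:
a single negative-binomial dispersion is estimated by the method of moments
pooled across genes, the log2 of the per-sample normalized means is compared
with a normal approximation, and the per-gene evidence score is one minus the
Benjamini–Hochberg adjusted p-value. A gene is a DEG when score > 0.99 and
fold change > 1.5 (either direction). This reproduces the decision surface of
an empirical-Bayes posterior gate without re-implementing such a model; the
score is not a posterior probability.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

from .stats import bh_adjust

logger = logging.getLogger(__name__)

_REP_RE = re.compile(r"^(?P<sample>.+)\.rep\d+$")

LOG2 = np.log(2.0)


class NormalizationError(ValueError):
    pass


def replicate_map(columns: list[str]) -> dict[str, str]:
    """Column -> sample from the ``sample.repN`` naming convention."""
    out = {}
    for c in columns:
        m = _REP_RE.match(c)
        if not m:
            raise ValueError(f"column {c!r} does not follow the sample.repN convention")
        out[c] = m.group("sample")
    return out


def upper_quartile_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each column so its nonzero-gene upper quartile hits the common target.

    Target = mean of the raw per-column upper quartiles. Returns the scaled
    matrix and the per-column scale factors.
    """
    uq = {}
    for col in matrix.columns:
        vals = matrix[col].to_numpy(dtype=float)
        nz = vals[vals > 0]
        if nz.size == 0:
            raise NormalizationError(f"column {col!r} is all zero; cannot normalize")
        uq[col] = float(np.percentile(nz, 75))
    uq = pd.Series(uq)
    target = float(uq.mean())
    factors = target / uq
    normalized = matrix * factors
    logger.info("upper-quartile normalization: target %.4g, factors %s", target,
                {k: round(v, 4) for k, v in factors.items()})
    return normalized, factors


def sample_means(normalized: pd.DataFrame, rep_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-sample mean of normalized counts over replicate columns."""
    rep_map = rep_map or replicate_map(list(normalized.columns))
    groups: dict[str, list[str]] = {}
    for col, s in rep_map.items():
        groups.setdefault(s, []).append(col)
    return pd.DataFrame({s: normalized[cols].mean(axis=1) for s, cols in groups.items()})


def expressed_genes(normalized: pd.DataFrame, rep_map: dict[str, str] | None = None,
                    threshold: float = 1.0) -> pd.Index:
    """Genes with mean normalized count > ``threshold`` in at least one sample."""
    means = sample_means(normalized, rep_map)
    return means.index[(means > threshold).any(axis=1)]


def _common_dispersion(normalized: pd.DataFrame, rep_map: dict[str, str]) -> float:
    """Method-of-moments NB dispersion pooled across genes and samples."""
    groups: dict[str, list[str]] = {}
    for col, s in rep_map.items():
        groups.setdefault(s, []).append(col)
    phis = []
    for s, cols in groups.items():
        if len(cols) < 2:
            continue
        sub = normalized[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 5
        if ok.any():
            phis.append((v[ok] - m[ok]) / m[ok] ** 2)
    if not phis:
        return 0.01
    phi = float(np.median(np.concatenate(phis)))
    return max(phi, 1e-3)


@dataclass
class DegTable:
    pair: tuple[str, str]
    table: pd.DataFrame  # columns: mean_a, mean_b, fold_change, log2fc, pvalue, score, is_deg


def call_degs(
    matrix: pd.DataFrame,
    pair: tuple[str, str],
    rep_map: dict[str, str] | None = None,
    score_threshold: float = 0.99,
    fc_threshold: float = 1.5,
    normalized: bool = False,
) -> DegTable:
    """Differential expression between ``pair = (a, b)``.

    ``fold_change`` is the ratio of normalized means, b over a. Genes with
    zero mean in both samples are excluded (logged). ``is_deg`` requires
    score > ``score_threshold`` and max(FC, 1/FC) > ``fc_threshold``.
    """
    rep_map = rep_map or replicate_map(list(matrix.columns))
    norm = matrix if normalized else upper_quartile_normalize(matrix)[0]
    a, b = pair
    cols_a = [c for c, s in rep_map.items() if s == a]
    cols_b = [c for c, s in rep_map.items() if s == b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"both samples need >= 2 replicates; got {len(cols_a)} and {len(cols_b)}")

    m_a = norm[cols_a].mean(axis=1)
    m_b = norm[cols_b].mean(axis=1)
    testable = (m_a > 0) | (m_b > 0)
    if (~testable).any():
        logger.info("call_degs %s: excluding %d genes with zero mean in both samples",
                    pair, int((~testable).sum()))

    phi = _common_dispersion(norm, rep_map)
    na, nb = len(cols_a), len(cols_b)
    mu_a = m_a[testable].to_numpy() + 0.5
    mu_b = m_b[testable].to_numpy() + 0.5
    # Var(log2 mean) ~ (1/mu + phi) / (n * ln2^2) under NB(mu, phi)
    v = (1 / mu_a + phi) / (na * LOG2**2) + (1 / mu_b + phi) / (nb * LOG2**2)
    log2fc = np.log2(mu_b) - np.log2(mu_a)
    z = log2fc / np.sqrt(v)
    pvals = 2 * stats.norm.sf(np.abs(z))
    score = 1.0 - bh_adjust(pvals)

    fc = mu_b / mu_a
    table = pd.DataFrame(
        {
            "mean_a": m_a[testable],
            "mean_b": m_b[testable],
            "fold_change": fc,
            "log2fc": log2fc,
            "pvalue": pvals,
            "score": score,
            "is_deg": (score > score_threshold) & (np.maximum(fc, 1 / fc) > fc_threshold),
        },
        index=norm.index[testable],
    )
    return DegTable(pair=pair, table=table)


def sample_specific_degs(deg_tables: list[DegTable], focal: str) -> pd.DataFrame:
    """Genes that are DEGs in the focal sample against every other sample.

    Each table's pair must include ``focal``; direction (up/down in the focal
    sample) must agree across all comparisons to be labelled, otherwise the
    gene is flagged discordant and excluded. Returns a frame indexed by gene
    with ``direction`` and mean focal-vs-other ``log2fc``.
    """
    per_gene_dir: list[pd.Series] = []
    per_gene_fc: list[pd.Series] = []
    deg_sets = []
    for dt in deg_tables:
        a, b = dt.pair
        if focal not in (a, b):
            raise ValueError(f"pair {dt.pair} does not involve focal sample {focal}")
        sign = 1.0 if b == focal else -1.0  # log2fc is b-over-a
        focal_fc = sign * dt.table["log2fc"]
        deg = dt.table.index[dt.table["is_deg"]]
        deg_sets.append(set(deg))
        per_gene_dir.append(np.sign(focal_fc))
        per_gene_fc.append(focal_fc)
    common = set.intersection(*deg_sets) if deg_sets else set()
    rows = []
    for g in sorted(common):
        dirs = {d.loc[g] for d in per_gene_dir}
        fc = float(np.mean([f.loc[g] for f in per_gene_fc]))
        if len(dirs) == 1 and 0.0 not in dirs:
            rows.append((g, "up" if dirs == {1.0} else "down", fc, False))
        else:
            rows.append((g, "discordant", fc, True))
    out = pd.DataFrame(rows, columns=["gene", "direction", "log2fc", "discordant"]).set_index("gene")
    n_disc = int(out["discordant"].sum()) if len(out) else 0
    if n_disc:
        logger.info("sample_specific_degs(%s): %d discordant-direction genes flagged", focal, n_disc)
    return out[~out["discordant"]].drop(columns="discordant")


def transcriptome_divergence(
    normalized: pd.DataFrame,
    rep_map: dict[str, str] | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Sample x sample correlation of log2(normalized mean + 1) over expressed genes."""
    means = sample_means(normalized, rep_map)
    means = means.loc[expressed_genes(normalized, rep_map)]
    if len(means) < 3:
        raise ValueError("fewer than 3 expressed genes; correlation refused")
    logvals = np.log2(means + 1)
    return logvals.corr(method=method)


def hierarchical_cluster(values: pd.DataFrame, method: str = "complete") -> tuple[str, list[tuple]]:
    """Agglomerative clustering of columns on Euclidean distance.

    ``values``: rows = features (genes or CpG sites), columns = samples.
    Returns (newick, merge_order) where merge_order lists, per linkage step,
    the frozensets of sample names merged.
    """
    labels = list(values.columns)
    if len(labels) < 2 or len(values) < 3:
        raise ValueError("need >= 2 samples and >= 3 features to cluster")
    X = values.to_numpy(dtype=float).T
    Z = linkage(X, method=method, metric="euclidean")
    clusters: dict[int, tuple] = {i: (labels[i], frozenset([labels[i]])) for i in range(len(labels))}
    merge_order = []
    for step, (i, j, dist, _) in enumerate(Z):
        left, lset = clusters[int(i)]
        right, rset = clusters[int(j)]
        merge_order.append((lset, rset))
        node = "(" + ",".join(sorted([_render(left), _render(right)])) + ")"
        clusters[len(labels) + step] = (node, lset | rset)
    newick = clusters[len(labels) + len(Z) - 1][0] + ";"
    return newick, merge_order


def _render(node) -> str:
    return node if isinstance(node, str) else str(node)


def merges_last(merge_order: list[tuple], sample: str) -> bool:
    """True when ``sample`` joins only at the final merge (isolated sample)."""
    if not merge_order:
        return False
    final_left, final_right = merge_order[-1]
    for lset, rset in merge_order[:-1]:
        if sample in lset or sample in rset:
            return False
    return frozenset([sample]) in (final_left, final_right)
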