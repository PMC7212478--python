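"""Shared statistical primitives.

The only hand-rolled primitive here is a vectorized two-sided Fisher exact
test for batches of 2x2 tables. Differential-methylation calling runs one
exact test per CpG site, so tens of thousands of tables per sample pair;
``scipy.stats.fisher_exact`` is a scalar call and dominates runtime if used
per site. The implementation below evaluates the full hypergeometric pmf of
every table (support is bounded by sequencing depth, so the padded pmf matrix
stays small) and sums probabilities not exceeding the observed one, with the
customary ``1 + 1e-7`` relative tie tolerance — the same definition scipy and
R use, which tests verify by direct comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

_TIE_REL = 1 + 1e-7


def fisher_exact_two_sided(
    m1: np.ndarray, u1: np.ndarray, m2: np.ndarray, u2: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher exact p for 2x2 tables [[m1, u1], [m2, u2]], vectorized.

    Rows are the two samples, columns success/failure counts (for methylation:
    methylated / unmethylated reads). Returns an array of p-values in [0, 1].
    """
    m1 = np.asarray(m1, dtype=np.int64)
    u1 = np.asarray(u1, dtype=np.int64)
    m2 = np.asarray(m2, dtype=np.int64)
    u2 = np.asarray(u2, dtype=np.int64)
    if np.any(m1 < 0) or np.any(u1 < 0) or np.any(m2 < 0) or np.any(u2 < 0):
        raise ValueError("negative counts in contingency table")

    N = m1 + u1 + m2 + u2
    K = m1 + m2          # successes margin
    n = m1 + u1          # sample-1 margin
    kmin = np.maximum(0, n - (u1 + u2))
    kmax = np.minimum(K, n)
    width = int((kmax - kmin).max()) + 1 if len(np.atleast_1d(N)) else 1

    k = kmin[:, None] + np.arange(width)[None, :]
    valid = k <= kmax[:, None]
    k = np.where(valid, k, kmin[:, None])  # safe values for the masked tail

    logpmf = (
        gammaln(K + 1)[:, None]
        - gammaln(k + 1)
        - gammaln(K[:, None] - k + 1)
        + gammaln(N - K + 1)[:, None]
        - gammaln(n[:, None] - k + 1)
        - gammaln((N - K - n)[:, None] + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))[:, None]
    )
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    rows = np.arange(len(N))
    p_obs = pmf[rows, m1 - kmin]
    p = np.sum(pmf * (pmf <= p_obs[:, None] * _TIE_REL), axis=1)
    return np.clip(p, 0.0, 1.0)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]
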