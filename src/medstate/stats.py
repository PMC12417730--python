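"""Shared statistical machinery: BH-FDR, a permutation engine, t utilities.

Pure computation, no file I/O.  The Benjamini-Hochberg step-up and the
permutation p-value are implemented here directly (they are the backbone of
the time-frequency significance maps); Student-t quantiles come from scipy.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .containers import FdrResult


def bh_fdr(pvals: Sequence[float], q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Rejects all hypotheses with sorted p-value p(i) for i up to the largest i
    such that p(i) <= i * q / m.  Returns per-test rejection flags in the
    input order plus the largest passing p (0.0 when nothing is rejected).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(sorted_p <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1]
        p_threshold = float(sorted_p[k])
        reject[order[: k + 1]] = True
    else:
        p_threshold = 0.0
    return FdrResult(pvals=p, q=q, reject=reject, p_threshold=p_threshold)


def permutation_pvalue(
    stat_fn: Callable[[np.ndarray, np.ndarray], float],
    group_a: Sequence[float] | np.ndarray,
    group_b: Sequence[float] | np.ndarray,
    n_perm: int = 500,
    seed: int | None = None,
    two_sided: bool = True,
) -> float:
    """Label-permutation p-value with the add-one convention.

    p = (1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_perm), so the returned p
    is never zero and remains a valid p-value under exchangeability.  The
    exchangeability unit is whatever one element of each group represents
    (trials or subjects) - the caller decides by how it groups the data.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = stat_fn(a, b)
    obs = abs(observed) if two_sided else observed
    pooled = np.concatenate([a, b])
    n_a = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        s = stat_fn(perm[:n_a], perm[n_a:])
        s = abs(s) if two_sided else s
        if s >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def t_quantile(level: float, df: float) -> float:
    """Inverse CDF of Student's t at probability ``level`` with ``df`` dof."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly inside (0, 1)")
    return float(sps.t.ppf(level, df))


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Paired two-sided t-test: returns (t, df, p).

    Zero variance of the differences yields an infinite t (sign of the mean
    difference) with p = 0, flagged by the caller.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    diff = a - b
    n = diff.size
    sd = diff.std(ddof=1)
    mean = diff.mean()
    if sd == 0:
        t = np.inf * np.sign(mean) if mean != 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
        return float(t), n - 1, float(p)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)
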