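"""Paired statistical comparisons: Wilcoxon signed-rank and Bonferroni.

The signed-rank test is two-sided.  Pairs with zero difference are dropped
before ranking (the classical convention).  For n <= 12 usable pairs the
null distribution is enumerated exactly over all 2^n sign patterns (ties in
the absolute differences receive average ranks, which the enumeration
honours); for larger n the normal approximation with tie-corrected variance
and a continuity correction is used.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["WilcoxonResult", "wilcoxon_signed_rank", "bonferroni"]

EXACT_LIMIT = 12


class WilcoxonResult(NamedTuple):
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float
    n_used: int  # pairs remaining after dropping zero differences
    method: str  # "exact" or "normal"


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d sequences")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, method="exact")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        # exact null: distribution of W+ over all 2^n sign patterns.
        # use doubled ranks so average ranks stay integral.
        r2 = np.rint(2 * ranks).astype(int)
        dist = np.zeros(r2.sum() + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: len(dist) - r]
            dist = dist + shifted
        dist /= 2.0**n
        w2 = int(round(2 * w_plus))
        p_le = dist[: w2 + 1].sum()
        p_ge = dist[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_plus, float(p), n, "exact")
    # normal approximation with tie and continuity corrections
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    dev = abs(w_plus - mean)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(z)
    return WilcoxonResult(w_plus, float(min(p, 1.0)), n, "normal")


def bonferroni(
    p_values: Sequence[float], m: Optional[int] = None
) -> list:
    """Bonferroni-adjusted p-values: min(1, p * m); m defaults to len(p)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * m) for p in p_values]
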