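"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: scalar statistics
come from direct formula evaluation (scipy/numpy), the sliding-window map
from a naive double loop, and the rank tests from exhaustive enumeration of
rank assignments at small n.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.stats


def oracle_stat(values, name: str, bins: int = 32, value_range=None) -> float:
    """Direct-formula first-order statistic of a 1D sample."""
    x = np.asarray(values, dtype=float)
    if name == "mean":
        return float(np.mean(x))
    if name == "median":
        return float(np.median(x))
    if name == "std":
        return float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    if name == "cv":
        m = x.mean()
        return 0.0 if m == 0 else oracle_stat(x, "std") / m
    if name == "iqr":
        return float(np.percentile(x, 75) - np.percentile(x, 25))
    if name == "mad":
        return float(np.median(np.abs(x - np.median(x))))
    if name == "skewness":
        m2 = np.mean((x - x.mean()) ** 2)
        if m2 == 0:
            return 0.0
        return float(scipy.stats.skew(x, bias=True))
    if name == "kurtosis":
        m2 = np.mean((x - x.mean()) ** 2)
        if m2 == 0:
            return 3.0
        return float(scipy.stats.kurtosis(x, bias=True, fisher=False))
    if name in ("entropy", "uniformity"):
        lo, hi = (x.min(), x.max()) if value_range is None else value_range
        if hi <= lo:
            return 0.0 if name == "entropy" else 1.0
        edges = np.linspace(lo, hi, bins + 1)
        idx = np.minimum(np.searchsorted(edges, x, side="right") - 1, bins - 1)
        p = np.bincount(idx, minlength=bins) / len(x)
        p = p[p > 0]
        if name == "entropy":
            return float(-(p * np.log2(p)).sum())
        return float((p**2).sum())
    raise ValueError(name)


def naive_local_map(pixels, gland, stat, window, bins=32, min_support=0.5):
    """O(N * w^2) double-loop sliding-window map (the independent oracle)."""
    pixels = np.asarray(pixels, dtype=float)
    gland = np.asarray(gland, dtype=bool)
    h, w = pixels.shape
    half = window // 2
    gvals = pixels[gland]
    vrange = (gvals.min(), gvals.max())
    out = np.full(pixels.shape, np.nan)
    need = max(2, math.ceil(min_support * window * window))
    for r in range(h):
        for c in range(w):
            if not gland[r, c]:
                continue
            vals = []
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and gland[rr, cc]:
                        vals.append(pixels[rr, cc])
            if len(vals) >= need:
                out[r, c] = oracle_stat(np.array(vals), stat, bins, vrange)
    return out


def exact_ranksum_p(a, b, tail: str = "two-sided") -> float:
    """Exact Wilcoxon rank-sum p by enumerating all C(m+n, m) assignments.

    Uses mid-ranks for ties; the observed statistic is the rank sum of
    sample ``a``.
    """
    a, b = list(a), list(b)
    pooled = np.asarray(a + b, dtype=float)
    ranks = scipy.stats.rankdata(pooled)
    m = len(a)
    observed = ranks[:m].sum()
    sums = [sum(combo) for combo in itertools.combinations(ranks, m)]
    sums = np.asarray(sums)
    eps = 1e-9
    if tail == "greater":
        return float(np.mean(sums >= observed - eps))
    if tail == "less":
        return float(np.mean(sums <= observed + eps))
    mu = sums.mean()
    dev = abs(observed - mu)
    return float(np.mean(np.abs(sums - mu) >= dev - eps))


def exact_kruskal_p(groups) -> float:
    """Exact Kruskal-Wallis p by enumerating group assignments (tiny n)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    ranks = scipy.stats.rankdata(pooled)

    def h_stat(rank_groups):
        h = 12.0 / (n * (n + 1)) * sum(
            len(g) * (np.mean(g) - (n + 1) / 2) ** 2 for g in rank_groups
        )
        ties = np.unique(pooled, return_counts=True)[1]
        correction = 1 - (ties**3 - ties).sum() / (n**3 - n)
        return h / correction if correction > 0 else 0.0

    start = 0
    obs_groups = []
    for s in sizes:
        obs_groups.append(ranks[start : start + s])
        start += s
    observed = h_stat(obs_groups)

    count = 0
    total = 0
    idx = list(range(n))
    for first in itertools.combinations(idx, sizes[0]):
        rest = [i for i in idx if i not in first]
        for second in itertools.combinations(rest, sizes[1]):
            third = [i for i in rest if i not in second]
            groups_r = [ranks[list(first)], ranks[list(second)], ranks[third]]
            total += 1
            if h_stat(groups_r) >= observed - 1e-9:
                count += 1
    return count / total


def ansari_statistic(a, b) -> float:
    """Hand-computed Ansari-Bradley statistic of sample ``a``.

    Ranks 1, 2, 3, ... are assigned symmetrically from both extremes of the
    pooled ordered sample (mid-ranks for ties); AB is the sum over ``a``.
    """
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n = len(pooled)
    symmetric = np.minimum(np.arange(1, n + 1), np.arange(n, 0, -1))
    order = np.argsort(pooled, kind="stable")
    scores = np.empty(n)
    scores[order] = symmetric
    # mid-scores for tied values
    for v in np.unique(pooled):
        mask = pooled == v
        scores[mask] = scores[mask].mean()
    return float(scores[: len(a)].sum())
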