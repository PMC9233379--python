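"""Jenks natural-breaks classification with GVF-based class-count selection.

The optimiser is the exact Fisher dynamic program over contiguous
partitions of the sorted values, not the heuristic move-based variant, so
its output can be checked against exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BreaksResult", "jenks_breaks", "select_k"]


@dataclass
class BreaksResult:
    """Optimal k-class partition of a 1-D value set.

    ``breaks`` are the k-1 interior upper boundaries plus the maximum:
    class c is the right-closed interval (breaks[c-1], breaks[c]] (with an
    implicit lower bound of -inf for class 0). ``labels[i]`` is the class
    of ``values[i]`` in input order. ``gvf = 1 - SDCM/SDAM``.
    """

    k: int
    breaks: np.ndarray
    labels: np.ndarray
    gvf: float
    sdcm: float
    sdam: float


def _sdcm_matrix(x: np.ndarray):
    """Prefix-sum helper: cost(i, j) = within-class sum of squared
    deviations of x[i:j+1] about its mean, O(1) per query."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:
        n = j - i + 1
        s = s1[j + 1] - s1[i]
        q = s2[j + 1] - s2[i]
        return max(q - s * s / n, 0.0)

    return cost


def jenks_breaks(values, k: int) -> BreaksResult:
    """Exact natural-breaks partition of ``values`` into ``k`` classes.

    Minimises SDCM (the total within-class squared deviation) over all
    contiguous partitions of the sorted values via dynamic programming.
    Values equal to a break boundary fall in the lower class.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("jenks_breaks: empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("jenks_breaks: non-finite values")
    distinct = np.unique(values)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > distinct.size:
        raise ValueError(
            f"k={k} exceeds the number of distinct values ({distinct.size})"
        )

    x = np.sort(values)
    n = x.size
    cost = _sdcm_matrix(x)

    # dp[c][j] = minimal SDCM for x[0:j+1] split into c+1 classes
    dp = np.full((k, n), np.inf)
    arg = np.zeros((k, n), dtype=int)
    for j in range(n):
        dp[0, j] = cost(0, j)
    for c in range(1, k):
        for j in range(c, n):
            best, best_i = np.inf, c
            for i in range(c, j + 1):
                v = dp[c - 1, i - 1] + cost(i, j)
                if v < best:
                    best, best_i = v, i
            dp[c, j] = best
            arg[c, j] = best_i

    # backtrack class start indices
    starts = [0] * k
    j = n - 1
    for c in range(k - 1, 0, -1):
        starts[c] = int(arg[c, j])
        j = starts[c] - 1
    sdcm = float(dp[k - 1, n - 1])

    upper = np.array([x[starts[c + 1] - 1] for c in range(k - 1)] + [x[-1]])
    mean = x.mean()
    sdam = float(np.sum((x - mean) ** 2))
    gvf = 1.0 - sdcm / sdam if sdam > 0 else 1.0

    # right-closed classes: value belongs to the first class whose upper
    # boundary is >= value
    labels = np.searchsorted(upper, values, side="left").astype(int)
    return BreaksResult(k=k, breaks=upper, labels=labels, gvf=gvf,
                        sdcm=sdcm, sdam=sdam)


def select_k(values, k_range=range(2, 10), gvf_target: float = 0.85) -> int:
    """Smallest class count in ``k_range`` reaching the GVF target.

    Falls back to the GVF-maximising k when no candidate reaches the
    target. Candidates exceeding the number of distinct values are
    skipped.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("select_k: empty k_range")
    values = np.asarray(values, dtype=float)
    n_distinct = np.unique(values).size
    best_k, best_gvf = None, -np.inf
    for k in ks:
        if k < 1 or k > n_distinct:
            continue
        gvf = jenks_breaks(values, k).gvf
        if gvf >= gvf_target:
            return k
        if gvf > best_gvf:
            best_k, best_gvf = k, gvf
    if best_k is None:
        raise ValueError("select_k: no feasible k in range")
    return best_k
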