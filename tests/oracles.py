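"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's computational kernels: plain
Python loops, shapely containment, and exhaustive enumeration.
"""

import itertools
import math

import numpy as np
from shapely.geometry import Point


def oracle_weight(cx, cy, r, window, n_arc=2048):
    """Numeric arc-containment integration (midpoint rule over n_arc
    circumference samples, shapely covers)."""
    theta = 2.0 * math.pi * (np.arange(n_arc) + 0.5) / n_arc
    cnt = sum(
        1 for a in theta
        if window.covers(Point(cx + r * math.cos(a), cy + r * math.sin(a))))
    return max(cnt, 1) / n_arc


def oracle_k(points, window, radii, n_arc=2048):
    """Brute-force edge-corrected K: double loop over ordered pairs."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    area = window.area
    out = np.zeros(len(radii))
    wcache = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.dist(points[i], points[j])
            if (i, j) not in wcache:
                wcache[(i, j)] = oracle_weight(points[i][0], points[i][1],
                                               d, window, n_arc)
            w = wcache[(i, j)]
            for m, t in enumerate(radii):
                if d < t:
                    out[m] += 1.0 / w
    return out * area / n**2


def oracle_global_moran(values, w):
    """Double-loop global Moran's I with row-standardised weights."""
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    num = s0 = 0.0
    pos = {b: i for i, b in enumerate(w.ids)}
    for i in w.ids:
        k = len(w.neighbors[i])
        for j in w.neighbors[i]:
            num += (1.0 / k) * z[pos[i]] * z[pos[j]]
            s0 += 1.0 / k
    return len(w.ids) / s0 * num / float((z**2).sum())


def oracle_sdcm(values, k):
    """Minimal within-class squared deviation over all contiguous
    k-partitions of the sorted values (exhaustive enumeration)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        total = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            grp = x[a:b]
            total += float(((grp - grp.mean()) ** 2).sum())
        best = min(best, total)
    return best
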