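"""Local spatial autocorrelation: queen-contiguity weights, local Moran's
I, conditional-permutation pseudo p-values, and the five-way LISA
categorisation (High-High, Low-Low, Low-High, High-Low, not significant).

For unit i with mean-deviation z_i,

    I_i = (z_i / m2) · Σ_j w_ij z_j,   m2 = Σ_i z_i² / n,

with row-standardised queen weights w_ij. Significance is assessed by
conditional permutation: z_i is held fixed and its neighbours' values are
drawn without replacement from the remaining n-1 units; the pseudo p is
one-sided in the direction of the observed I_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.strtree import STRtree

from . import _kernels
from .core import BlockGroupSet

__all__ = [
    "WeightsMatrix",
    "LisaResult",
    "queen_weights",
    "local_moran",
    "permutation_pvalues",
    "categorize",
    "global_moran",
    "lisa_analysis",
]

CATEGORIES = ("HH", "LL", "LH", "HL", "NS")


@dataclass
class WeightsMatrix:
    """Row-standardised neighbour structure over areal units."""

    ids: list
    neighbors: dict  # id -> list of neighbor ids
    row_standardized: bool = True

    def __post_init__(self) -> None:
        index = {b: i for i, b in enumerate(self.ids)}
        for i, nbrs in self.neighbors.items():
            if i not in index:
                raise ValueError(f"neighbor list for unknown id {i!r}")
            for j in nbrs:
                if j == i:
                    raise ValueError(f"self-neighbour at {i!r}")
                if i not in self.neighbors.get(j, []):
                    raise ValueError(f"asymmetric neighbour pair ({i!r}, {j!r})")
        self._index = index

    @property
    def islands(self) -> list:
        return [i for i in self.ids if not self.neighbors[i]]

    @property
    def n(self) -> int:
        return len(self.ids)

    def weight(self, i, j) -> float:
        """w_ij (0 when not neighbours)."""
        nbrs = self.neighbors[i]
        if j not in nbrs:
            return 0.0
        return 1.0 / len(nbrs) if self.row_standardized else 1.0

    def to_flat_arrays(self):
        """(flat neighbor positions, start offsets, counts) in id order."""
        starts = np.zeros(self.n, dtype=np.int64)
        counts = np.zeros(self.n, dtype=np.int64)
        flat = []
        pos = 0
        for a, i in enumerate(self.ids):
            nbrs = self.neighbors[i]
            starts[a] = pos
            counts[a] = len(nbrs)
            flat.extend(self._index[j] for j in nbrs)
            pos += len(nbrs)
        return np.asarray(flat, dtype=np.int64), starts, counts

    def to_sparse_text(self, path) -> None:
        """Write `id: neighbor,weight neighbor,weight ...` lines."""
        with open(path, "w") as fh:
            for i in self.ids:
                nbrs = self.neighbors[i]
                parts = " ".join(f"{j},{self.weight(i, j):.10g}" for j in nbrs)
                fh.write(f"{i}: {parts}\n")


def queen_weights(blocks: BlockGroupSet, tolerance: float = 0.0) -> WeightsMatrix:
    """Queen contiguity: units are neighbours iff their polygons share at
    least one boundary point (any touch, edge or corner).

    ``tolerance`` > 0 snaps near-misses: polygons within that distance
    are treated as touching (for dirty real-world geometries).
    """
    for bid, geom in zip(blocks.ids, blocks.geometries):
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for block {bid!r}")
    tree = STRtree(blocks.geometries)
    neighbors = {bid: [] for bid in blocks.ids}
    for a, geom in enumerate(blocks.geometries):
        if tolerance > 0:
            cand = tree.query(geom.buffer(tolerance))
        else:
            cand = tree.query(geom)
        for b in cand:
            b = int(b)
            if b == a:
                continue
            other = blocks.geometries[b]
            if tolerance > 0:
                hit = geom.distance(other) <= tolerance
            else:
                hit = geom.intersects(other)
            if hit:
                neighbors[blocks.ids[a]].append(blocks.ids[b])
    order = {bid: a for a, bid in enumerate(blocks.ids)}
    for bid in neighbors:
        neighbors[bid] = sorted(neighbors[bid], key=order.__getitem__)
    return WeightsMatrix(ids=list(blocks.ids), neighbors=neighbors)


@dataclass
class LisaResult:
    """Per-unit local Moran's I with permutation inference."""

    table: pd.DataFrame  # index: unit id; value, z, lag, local_i, pseudo_p, category
    m2: float
    n: int
    n_permutations: int | None = None
    alpha: float | None = None
    seed: int | None = None

    def category_counts(self) -> dict:
        c = self.table["category"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in CATEGORIES}


def _validate_alignment(values: pd.Series, w: WeightsMatrix) -> pd.Series:
    if isinstance(values, pd.Series):
        if set(values.index) != set(w.ids):
            raise ValueError("values index does not match weights ids")
        return values.reindex(w.ids).astype(float)
    arr = np.asarray(values, dtype=float)
    if arr.shape[0] != w.n:
        raise ValueError("values length does not match weights")
    return pd.Series(arr, index=w.ids)


def local_moran(values, w: WeightsMatrix) -> LisaResult:
    """Local Moran's I_i and spatial lag for every unit.

    Islands get lag 0 and I_i = 0 (no neighbours to compare against);
    they are categorised NS downstream.
    """
    vals = _validate_alignment(values, w)
    non_island = [i for i in w.ids if w.neighbors[i]]
    if len(non_island) < 3:
        raise ValueError("local_moran needs at least 3 connected units")
    x = vals.to_numpy()
    n = w.n
    z = x - x.mean()
    m2 = float((z**2).sum() / n)
    pos = {b: i for i, b in enumerate(w.ids)}
    lag = np.zeros(n)
    for a, i in enumerate(w.ids):
        nbrs = w.neighbors[i]
        if nbrs:
            lag[a] = np.mean([z[pos[j]] for j in nbrs])
    if m2 == 0.0:
        local_i = np.zeros(n)  # constant values: all I_i = 0 by convention
    else:
        local_i = z / m2 * lag
    table = pd.DataFrame(
        {"value": x, "z": z, "lag": lag, "local_i": local_i},
        index=pd.Index(w.ids, name="block_id"),
    )
    return LisaResult(table=table, m2=m2, n=n)


def global_moran(values, w: WeightsMatrix) -> float:
    """Global Moran's I with row-standardised weights:
    I = (n / S0) Σ_ij w_ij z_i z_j / Σ z_i²."""
    vals = _validate_alignment(values, w)
    x = vals.to_numpy()
    z = x - x.mean()
    denom = float((z**2).sum())
    if denom == 0.0:
        return 0.0
    pos = {b: i for i, b in enumerate(w.ids)}
    num = 0.0
    s0 = 0.0
    for a, i in enumerate(w.ids):
        for j in w.neighbors[i]:
            wij = w.weight(i, j)
            num += wij * z[a] * z[pos[j]]
            s0 += wij
    return w.n / s0 * num / denom


def permutation_pvalues(values, w: WeightsMatrix, n_permutations: int = 9999,
                        seed: int = 0) -> pd.Series:
    """Conditional-permutation pseudo p-values, one per unit.

    pseudo_p = (#{permuted I_i at least as extreme as observed, in the
    direction of the observed I_i} + 1) / (n_permutations + 1). Islands
    get NaN.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    vals = _validate_alignment(values, w)
    x = vals.to_numpy()
    z = x - x.mean()
    m2 = float((z**2).sum() / w.n)
    if m2 == 0.0:
        return pd.Series(np.ones(w.n), index=vals.index)
    flat, starts, counts = w.to_flat_arrays()
    if counts.max(initial=0) > 64:
        raise ValueError("more than 64 neighbours for a unit is unsupported")
    p = _kernels.lisa_conditional_pvalues(z, m2, flat, starts, counts,
                                          int(n_permutations), int(seed))
    return pd.Series(p, index=pd.Index(w.ids, name="block_id"))


def categorize(lisa: LisaResult, alpha: float = 0.01) -> pd.Series:
    """Five-way LISA categories at level ``alpha``.

    Significant units (pseudo_p <= alpha): HH when z > 0 and lag > 0, LL
    when both negative, LH when z < 0 < lag, HL when z > 0 > lag. Units
    that are insignificant, islands, or have a zero z/lag (quadrant
    undefined) are NS.
    """
    t = lisa.table
    if "pseudo_p" not in t.columns:
        raise ValueError("LisaResult lacks pseudo_p; run permutation_pvalues")
    cats = []
    for _, row in t.iterrows():
        p, z, lag = row["pseudo_p"], row["z"], row["lag"]
        if not np.isfinite(p) or p > alpha or z == 0.0 or lag == 0.0:
            cats.append("NS")
        elif z > 0 and lag > 0:
            cats.append("HH")
        elif z < 0 and lag < 0:
            cats.append("LL")
        elif z < 0 and lag > 0:
            cats.append("LH")
        else:
            cats.append("HL")
    return pd.Series(cats, index=t.index)


def lisa_analysis(values, w: WeightsMatrix, n_permutations: int = 9999,
                  alpha: float = 0.01, seed: int = 0) -> LisaResult:
    """Full local analysis: I_i, lag, pseudo p, category per unit."""
    res = local_moran(values, w)
    res.table["pseudo_p"] = permutation_pvalues(values, w, n_permutations,
                                                seed).to_numpy()
    res.n_permutations = n_permutations
    res.alpha = alpha
    res.seed = seed
    res.table["category"] = categorize(res, alpha=alpha).to_numpy()
    return res
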