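"""Conditional LISA cluster tables: median splits of covariates, 2x2
cross-tabulation of hot/cold spots, the conditional-probability screen,
and hot-vs-cold covariate profiles."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConditionalTable",
    "SpotProfile",
    "median_split",
    "conditional_cluster_table",
    "screen_pairs",
    "spot_profile",
    "facility_conditional",
    "all_pair_tables",
]

LEVELS = ("low", "high")


def median_split(values: pd.Series) -> pd.Series:
    """Two-level split at the median: "low" iff value <= median.

    Rank-based, so invariant to monotone transforms. All-equal input
    degenerates to all-"low" (warned)."""
    if len(values) == 0:
        raise ValueError("median_split: empty input")
    v = values.astype(float)
    med = v.median()
    if (v == v.iloc[0]).all():
        warnings.warn("median_split: all values equal; everything is 'low'")
    return pd.Series(np.where(v <= med, "low", "high"), index=v.index)


@dataclass
class ConditionalTable:
    """Cross-tabulation of LISA categories over the 2x2 strata of a
    variable pair, with spot fractions per variable level.

    ``hot_fraction[var][level]`` is P(level | HH) — the share of hot
    spots falling in that level of that variable; ``cold_fraction``
    analogously for LL. The inverse conditioning P(HH | stratum) is kept
    in ``spot_given_level`` for transparency.
    """

    var_a: str
    var_b: str
    counts: pd.DataFrame  # index (a_level, b_level), columns categories
    hot_fraction: dict
    cold_fraction: dict
    spot_given_level: dict
    n_hot: int
    n_cold: int

    def retained(self, threshold: float = 0.6) -> bool:
        """Screen: some (a, b) level pair has hot fraction > threshold
        for both variables."""
        if self.n_hot == 0:
            return False
        for la, lb in itertools.product(LEVELS, LEVELS):
            if (self.hot_fraction[self.var_a][la] > threshold
                    and self.hot_fraction[self.var_b][lb] > threshold):
                return True
        return False


def _fractions(cats: pd.Series, levels: pd.Series, which: str) -> dict:
    spots = cats == which
    n = int(spots.sum())
    out = {}
    for lev in LEVELS:
        out[lev] = (
            float((spots & (levels == lev)).sum() / n) if n > 0 else np.nan
        )
    return out


def conditional_cluster_table(categories: pd.Series, levels_a: pd.Series,
                              levels_b: pd.Series, var_a: str = "A",
                              var_b: str = "B") -> ConditionalTable:
    """Cross-tabulate LISA categories over the 2x2 strata of two
    median-split variables."""
    if not (categories.index.equals(levels_a.index)
            and categories.index.equals(levels_b.index)):
        raise ValueError("categories and level series must share an index")
    idx = pd.MultiIndex.from_product([LEVELS, LEVELS], names=[var_a, var_b])
    counts = pd.DataFrame(0, index=idx,
                          columns=["HH", "LL", "LH", "HL", "NS"])
    for la, lb in itertools.product(LEVELS, LEVELS):
        sel = (levels_a == la) & (levels_b == lb)
        vc = categories[sel].value_counts()
        for cat in counts.columns:
            counts.loc[(la, lb), cat] = int(vc.get(cat, 0))

    hot = {var_a: _fractions(categories, levels_a, "HH"),
           var_b: _fractions(categories, levels_b, "HH")}
    cold = {var_a: _fractions(categories, levels_a, "LL"),
            var_b: _fractions(categories, levels_b, "LL")}
    n_hot = int((categories == "HH").sum())
    n_cold = int((categories == "LL").sum())
    if n_hot == 0:
        warnings.warn(
            f"({var_a}, {var_b}): no hot spots; fractions undefined")

    # inverse conditioning: P(HH | stratum)
    sgl = {}
    for la, lb in itertools.product(LEVELS, LEVELS):
        tot = int(counts.loc[(la, lb)].sum())
        sgl[(la, lb)] = (
            float(counts.loc[(la, lb), "HH"] / tot) if tot else np.nan
        )
    return ConditionalTable(var_a=var_a, var_b=var_b, counts=counts,
                            hot_fraction=hot, cold_fraction=cold,
                            spot_given_level=sgl, n_hot=n_hot, n_cold=n_cold)


def screen_pairs(tables, threshold: float = 0.6) -> list:
    """Variable pairs passing the conditional-probability screen: some
    joint level has hot-spot fraction strictly above the threshold for
    both variables."""
    return [t for t in tables if t.retained(threshold)]


def all_pair_tables(categories: pd.Series, covariates: pd.DataFrame,
                    columns=None) -> list:
    """Conditional tables for every unordered pair of covariate columns."""
    cols = list(columns) if columns is not None else list(covariates.columns)
    levels = {c: median_split(covariates[c]) for c in cols}
    return [
        conditional_cluster_table(categories, levels[a], levels[b], a, b)
        for a, b in itertools.combinations(cols, 2)
    ]


@dataclass
class SpotProfile:
    """Covariate medians over hot spots, cold spots, and all analyzed
    blocks, with the sign of (hot median - overall median)."""

    table: pd.DataFrame  # index covariate; columns hot_median, cold_median, overall_median, hot_vs_overall


def spot_profile(categories: pd.Series, covariates: pd.DataFrame) -> SpotProfile:
    if not categories.index.equals(covariates.index):
        raise ValueError("categories and covariates must share an index")
    hh = categories == "HH"
    ll = categories == "LL"
    rows = {}
    for col in covariates.columns:
        v = covariates[col].astype(float)
        hot_med = float(v[hh].median()) if hh.any() else np.nan
        cold_med = float(v[ll].median()) if ll.any() else np.nan
        overall = float(v.median())
        if np.isnan(hot_med):
            sign = "undefined"
        elif hot_med > overall:
            sign = "higher"
        elif hot_med < overall:
            sign = "lower"
        else:
            sign = "equal"
        rows[col] = {"hot_median": hot_med, "cold_median": cold_med,
                     "overall_median": overall, "hot_vs_overall": sign}
    return SpotProfile(table=pd.DataFrame(rows).T)


def facility_conditional(categories: pd.Series,
                         facility_distances: pd.DataFrame) -> pd.DataFrame:
    """Per facility type: fraction of hot spots in the shorter-than-median
    distance stratum (and the cold-spot analogue).

    Blocks with undefined distances are excluded from that type's split
    with a warning.
    """
    if not categories.index.equals(facility_distances.index):
        raise ValueError("categories and distances must share an index")
    out = {}
    for col in facility_distances.columns:
        d = facility_distances[col].astype(float)
        ok = d.notna()
        if not ok.all():
            warnings.warn(f"{col}: {int((~ok).sum())} blocks with undefined "
                          "distance excluded")
        if not ok.any():
            out[col] = {"hot_shorter_fraction": np.nan,
                        "cold_shorter_fraction": np.nan, "n_hot": 0, "n_cold": 0}
            continue
        levels = median_split(d[ok])
        cats = categories[ok]
        hot = cats == "HH"
        cold = cats == "LL"
        n_hot, n_cold = int(hot.sum()), int(cold.sum())
        if n_hot == 0:
            warnings.warn(f"{col}: no hot spots; fraction undefined")
        out[col] = {
            "hot_shorter_fraction": (
                float((hot & (levels == "low")).sum() / n_hot)
                if n_hot else np.nan),
            "cold_shorter_fraction": (
                float((cold & (levels == "low")).sum() / n_cold)
                if n_cold else np.nan),
            "n_hot": n_hot,
            "n_cold": n_cold,
        }
    return pd.DataFrame(out).T
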