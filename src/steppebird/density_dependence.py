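"""Density-dependence comparison: adult pair density vs nest density.

Joins plot-level nest density estimates (from distance sampling) with
adult pair densities (posterior means from the double-observer model)
and tests their linear association with a Pearson correlation, plus a
pair-to-nest density ratio summary.  Under the monogamy assumption two
same-species adults form one pair, so a population where every pair
nests should show a ratio near 1 and a strong positive correlation.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = ["join_densities", "pearson_test", "density_ratio_summary",
           "CorrelationResult"]

log = logging.getLogger("steppebird")


def join_densities(nest: pd.DataFrame, adult: pd.DataFrame,
                   keys: list[str] | None = None) -> pd.DataFrame:
    """Inner-join nest and adult density estimates on shared keys.

    ``nest`` needs a ``nest_density`` column and ``adult`` a
    ``pair_density`` column.  Unmatched records are logged with the
    side they were missing from (a plot can legitimately drop out of
    the nest table through the >= 2-detections rule).  Duplicate keys
    on either side raise a ``ValueError``.
    """
    keys = keys or [k for k in ("plot_id", "year", "species")
                    if k in nest.columns and k in adult.columns]
    if not keys:
        raise ValueError("no shared join keys")
    for name, df in (("nest", nest), ("adult", adult)):
        if df.duplicated(subset=keys).any():
            raise ValueError(f"duplicate {keys} keys in {name} estimates")
    joined = nest.merge(adult, on=keys, how="inner",
                        suffixes=("_nest", "_adult"))
    if joined.empty:
        raise ValueError("join produced no paired records")
    n_only = len(nest) - len(joined)
    a_only = len(adult) - len(joined)
    if n_only:
        log.warning("%d nest-density records had no adult match", n_only)
    if a_only:
        log.warning("%d adult-density records had no nest match "
                    "(e.g. plot excluded by the >=2-nest rule)", a_only)
    return joined


class CorrelationResult:
    """Pearson correlation with its two-sided t-test."""

    def __init__(self, r: float, p: float, n: int, species: str = "all",
                 ratio_mean: float = math.nan):
        self.r, self.p, self.n = r, p, n
        self.species = species
        self.ratio_mean = ratio_mean

    def __repr__(self):
        return (f"CorrelationResult(species={self.species!r}, "
                f"r={self.r:.3f}, p={self.p:.3f}, n={self.n})")


def pearson_test(x, y, species: str = "all") -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value.

    r = sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) sum((y-ybar)^2));
    the p-value comes from t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees
    of freedom.  Requires n >= 3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson test requires n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx2, sy2 = float(xd @ xd), float(yd @ yd)
    if sx2 == 0.0 or sy2 == 0.0:
        raise ValueError("correlation undefined: zero variance")
    r = float(xd @ yd) / math.sqrt(sx2 * sy2)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(t_dist.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n, species=species)


def density_ratio_summary(records: pd.DataFrame,
                          by_enrollment: bool = True) -> pd.DataFrame:
    """Distribution of pair density / nest density per species.

    Rows with zero nest density have an undefined ratio and are dropped
    with a log entry.  Returns mean, min and max of the ratio per
    species (and per enrollment stratum when available).
    """
    recs = records.copy()
    zero = recs["nest_density"] <= 0
    if zero.any():
        log.warning("%d records with zero nest density excluded from "
                    "ratio summary", int(zero.sum()))
        recs = recs[~zero]
    if recs.empty:
        raise ValueError("no records with positive nest density")
    recs["ratio"] = recs["pair_density"] / recs["nest_density"]
    group_cols = ["species"] if "species" in recs.columns else []
    out = []
    groups = recs.groupby(group_cols) if group_cols else [("all", recs)]
    for key, grp in groups:
        label = key[0] if isinstance(key, tuple) else key
        out.append({"species": label, "stratum": "all",
                    "ratio_mean": grp["ratio"].mean(),
                    "ratio_min": grp["ratio"].min(),
                    "ratio_max": grp["ratio"].max(),
                    "n": len(grp)})
        enroll_col = next((c for c in ("enrollment", "enrollment_nest")
                           if c in grp.columns), None)
        if by_enrollment and enroll_col:
            for ekey, egrp in grp.groupby(enroll_col):
                out.append({"species": label, "stratum": ekey,
                            "ratio_mean": egrp["ratio"].mean(),
                            "ratio_min": egrp["ratio"].min(),
                            "ratio_max": egrp["ratio"].max(),
                            "n": len(egrp)})
    return pd.DataFrame(out)


def compare(nest: pd.DataFrame, adult: pd.DataFrame,
            by: str = "plot") -> pd.DataFrame:
    """Full comparison per species: r, p, n and ratio summary.

    ``by="plot"`` pools across years (mean density per plot) before
    correlating; ``by="plot-year"`` keeps plot-years as pairing units.
    """
    joined = join_densities(nest, adult)
    if by == "plot":
        group_keys = [k for k in ("plot_id", "species") if k in joined]
        joined = (joined.groupby(group_keys, as_index=False)
                  [["nest_density", "pair_density"]].mean())
    rows = []
    species_list = (sorted(joined["species"].unique())
                    if "species" in joined else ["all"])
    for sp in species_list:
        sub = joined[joined["species"] == sp] if "species" in joined \
            else joined
        res = pearson_test(sub["nest_density"], sub["pair_density"],
                           species=sp)
        ratio = (sub["pair_density"] / sub["nest_density"]
                 .replace(0, np.nan)).dropna()
        rows.append({"species": sp, "r": res.r, "p": res.p, "n": res.n,
                     "ratio_mean": float(ratio.mean()),
                     "ratio_min": float(ratio.min()),
                     "ratio_max": float(ratio.max())})
    return pd.DataFrame(rows)
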