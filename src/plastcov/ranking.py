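"""Age-binned ranking of subnucleus volume change and expression trends.

Two descriptive summaries of the longitudinal signal:

* per age bin, the 18 amygdala subnuclei ranked by the median of the raw
  (mm^3) volume change, ascending from strongest atrophy (rank 1, most
  negative) to strongest growth;
* per (age, sex) cell, the median covariation-pattern expression with
  bootstrap 5th/95th percentile bands and one count-weighted least-squares
  line of best fit per sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconfound import ChangeMatrix


@dataclass
class AgeGroupRanking:
    """Per-bin median change and rank for each subnucleus."""

    table: pd.DataFrame  # bin, bin_left, bin_right, label, median, rank, n
    bin_edges: np.ndarray


def _resolve_bins(age: np.ndarray, bins: int | np.ndarray) -> np.ndarray:
    if np.isscalar(bins):
        return np.linspace(age.min(), age.max(), int(bins) + 1)
    edges = np.asarray(bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    return edges


def rank_subregion_change(
    change: ChangeMatrix, age: pd.Series, bins: int | np.ndarray = 6
) -> AgeGroupRanking:
    """Rank subnuclei by median raw change within each age bin.

    Requires a raw (non-standardized) change matrix so atrophy/growth keeps
    its physical sign. Ranks ascend with the median; ties break by label
    order. Empty bins are reported with zero counts and no ranks.
    """
    if change.state != "raw":
        raise ValueError(
            f"ranking requires the raw change matrix, got state {change.state!r}"
        )
    age = age.reindex(change.values.index)
    if age.isna().any():
        raise ValueError("every subject needs an age")
    ages = age.to_numpy(dtype=float)
    edges = _resolve_bins(ages, bins)
    # right-inclusive last bin so the oldest subject is covered
    which = np.clip(np.digitize(ages, edges[1:-1]), 0, len(edges) - 2)

    labels = change.region_labels
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        n_in = int(sel.sum())
        if n_in == 0:
            for lab in labels:
                rows.append(
                    {"bin": b, "bin_left": edges[b], "bin_right": edges[b + 1],
                     "label": lab, "median_change": np.nan, "rank": np.nan, "n": 0}
                )
            continue
        med = np.median(change.to_numpy()[sel], axis=0)
        # stable sort on medians; labels are already in registry order, so
        # ties resolve by label order deterministically
        order = np.argsort(med, kind="stable")
        rank = np.empty(len(labels), dtype=int)
        rank[order] = np.arange(1, len(labels) + 1)
        for j, lab in enumerate(labels):
            rows.append(
                {"bin": b, "bin_left": edges[b], "bin_right": edges[b + 1],
                 "label": lab, "median_change": med[j], "rank": int(rank[j]),
                 "n": n_in}
            )
    return AgeGroupRanking(table=pd.DataFrame(rows), bin_edges=edges)


@dataclass
class ExpressionTrend:
    """Per-(age, sex) median expression with bootstrap bands and sex trends."""

    cells: pd.DataFrame  # age, sex, median, lo5, hi95, n
    lines: pd.DataFrame  # sex, slope, intercept


def expression_trend(
    scores: pd.Series,
    age: pd.Series,
    sex: pd.Series,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    min_cell: int = 5,
    pct: tuple[float, float] = (5.0, 95.0),
) -> ExpressionTrend:
    """Median pattern expression per (age, sex) cell with bootstrap bands.

    The median of each cell is bootstrapped by resampling within the cell;
    cells below ``min_cell`` subjects report the median without bands. One
    least-squares line per sex is fitted through the (age, cell median)
    pairs, weighted by cell counts.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = pd.DataFrame(
        {"score": scores, "age": age.astype(int), "sex": sex.astype(int)}
    ).dropna()
    rows = []
    for (a, s), grp in df.groupby(["age", "sex"], sort=True):
        v = grp["score"].to_numpy()
        med = float(np.median(v))
        if len(v) >= min_cell:
            boots = np.median(
                v[rng.integers(0, len(v), size=(n_boot, len(v)))], axis=1
            )
            lo, hi = np.percentile(boots, pct)
        else:
            lo = hi = np.nan
        rows.append({"age": a, "sex": s, "median": med, "lo": lo, "hi": hi,
                     "n": len(v)})
    cells = pd.DataFrame(rows)

    lines = []
    for s, grp in cells.groupby("sex"):
        if len(grp) < 2:
            lines.append({"sex": s, "slope": np.nan, "intercept": np.nan})
            continue
        w = grp["n"].to_numpy(dtype=float)
        coeffs = np.polyfit(grp["age"], grp["median"], 1, w=np.sqrt(w))
        lines.append({"sex": s, "slope": coeffs[0], "intercept": coeffs[1]})
    return ExpressionTrend(cells=cells, lines=pd.DataFrame(lines))
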