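"""Phenome-wide screen of covariation-pattern expressions.

A wide phenotype table (numerical / binary / categorical-ordered /
categorical-unordered columns, each with a domain category tag) is first
harmonized: unordered categoricals are expanded one binary column per level,
columns with fewer than 500 complete values are discarded, and among pairs
correlating above |r| = 0.99 only the first in column order is kept. Each
retained phenotype is then screened against a latent score column by Pearson
correlation on pairwise-complete observations, with Bonferroni (alpha / m)
and Benjamini-Hochberg FDR control. A mode is retained for interpretation
when its permutation p-value is significant AND at least one phenotype
survives FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DATATYPES = ("numerical", "binary", "categorical-ordered", "categorical-unordered")
MIN_COMPLETE = 500
DEDUP_R = 0.99


@dataclass
class PhenotypeTable:
    """Wide phenotype table with per-column datatype and category tags."""

    values: pd.DataFrame
    datatypes: dict[str, str]
    categories: dict[str, str] = field(default_factory=dict)
    drop_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        untagged = [c for c in self.values.columns if c not in self.datatypes]
        if untagged:
            raise ValueError(f"untagged phenotype columns: {untagged}")
        bad = {c: t for c, t in self.datatypes.items() if t not in DATATYPES}
        if bad:
            raise ValueError(f"unknown datatypes: {bad}; expected one of {DATATYPES}")

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


def harmonize(
    raw: PhenotypeTable,
    min_complete: int = MIN_COMPLETE,
    dedup_r: float = DEDUP_R,
) -> PhenotypeTable:
    """Apply the harmonization rules; idempotent.

    Order: (1) one-hot expand unordered categoricals, (2) drop columns with
    fewer than ``min_complete`` complete values, (3) deduplicate pairs with
    pairwise-complete |r| > ``dedup_r`` keeping the first in column order.
    A drop log records every removal with its reason.
    """
    values = raw.values
    datatypes = dict(raw.datatypes)
    categories = dict(raw.categories)
    drop_log: list[dict] = []

    # (1) expand unordered categoricals into per-level binaries
    out_cols: dict[str, pd.Series] = {}
    for col in values.columns:
        if datatypes[col] == "categorical-unordered":
            s = values[col]
            for level in sorted(s.dropna().unique()):
                name = f"{col}__{level:g}" if isinstance(level, float) else f"{col}__{level}"
                binary = (s == level).astype(float)
                binary[s.isna()] = np.nan
                out_cols[name] = binary
                datatypes[name] = "binary"
                categories[name] = categories.get(col, "")
            drop_log.append({"column": col, "reason": "expanded_unordered"})
            datatypes.pop(col)
            categories.pop(col, None)
        else:
            out_cols[col] = values[col]
    table = pd.DataFrame(out_cols, index=values.index)

    # (2) missingness filter: strictly fewer than min_complete complete -> drop
    complete = table.notna().sum()
    thin = complete[complete < min_complete].index.tolist()
    for col in thin:
        drop_log.append(
            {"column": col, "reason": f"fewer_than_{min_complete}_complete",
             "n_complete": int(complete[col])}
        )
        datatypes.pop(col)
        categories.pop(col, None)
    table = table.drop(columns=thin)

    # (3) dedup highly correlated pairs, first-in-order kept
    cols = list(table.columns)
    dropped: set[str] = set()
    corr = table.corr(min_periods=3).abs()
    for i, ci in enumerate(cols):
        if ci in dropped:
            continue
        for cj in cols[i + 1 :]:
            if cj in dropped:
                continue
            r = corr.at[ci, cj]
            if pd.notna(r) and r > dedup_r:
                dropped.add(cj)
                drop_log.append(
                    {"column": cj, "reason": "high_correlation", "with": ci,
                     "r": float(r)}
                )
                datatypes.pop(cj)
                categories.pop(cj, None)
    table = table.drop(columns=sorted(dropped, key=cols.index))

    return PhenotypeTable(
        values=table,
        datatypes=datatypes,
        categories=categories,
        drop_log=raw.drop_log + drop_log,
    )


@dataclass
class PhewasResult:
    """Per-phenotype screen output plus the applied thresholds."""

    table: pd.DataFrame  # phenotype, r, p, n, category, flags
    alpha: float
    fdr_q: float
    m: int  # retained phenotype count (Bonferroni denominator)
    skipped: list[str] = field(default_factory=list)

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.m

    @property
    def n_bonferroni(self) -> int:
        return int(self.table["bonferroni_significant"].sum())

    @property
    def n_fdr(self) -> int:
        return int(self.table["fdr_significant"].sum())

    @property
    def fdr_threshold_empirical(self) -> float | None:
        """Largest rejected p-value (the data-dependent FDR line), if any."""
        rejected = self.table.loc[self.table["fdr_significant"], "p"]
        return float(rejected.max()) if len(rejected) else None


def screen(
    scores: pd.Series,
    phenos: PhenotypeTable,
    alpha: float = 0.05,
    fdr_q: float = 0.05,
) -> PhewasResult:
    """Mass-univariate Pearson screen of one latent score column.

    Correlations use pairwise-complete observations; p-values come from the
    exact t-transform with n-2 degrees of freedom. Phenotypes with fewer than
    3 complete pairs are skipped with a warning. The Bonferroni denominator m
    is the retained phenotype count (skipped columns excluded).
    """
    scores = scores.reindex(phenos.values.index)
    rows = []
    skipped: list[str] = []
    for col in phenos.values.columns:
        x = phenos.values[col]
        mask = x.notna() & scores.notna()
        n = int(mask.sum())
        if n < 3:
            skipped.append(col)
            continue
        xv = x[mask].to_numpy(dtype=float)
        sv = scores[mask].to_numpy(dtype=float)
        if xv.std() == 0 or sv.std() == 0:
            skipped.append(col)
            continue
        r, p = stats.pearsonr(sv, xv)
        rows.append(
            {"phenotype": col, "r": r, "p": p, "n": n,
             "category": phenos.categories.get(col, "")}
        )
    if skipped:
        warnings.warn(f"skipped {len(skipped)} phenotypes with <3 complete pairs or zero variance", stacklevel=2)
    table = pd.DataFrame(rows)
    m = len(table)
    if m == 0:
        raise ValueError("no phenotype could be screened")
    table["bonferroni_significant"] = table["p"] < alpha / m
    reject, *_ = multipletests(table["p"].to_numpy(), alpha=fdr_q, method="fdr_bh")
    table["fdr_significant"] = reject
    return PhewasResult(table=table, alpha=alpha, fdr_q=fdr_q, m=m, skipped=skipped)


def select_modes(
    perm_pvalues: np.ndarray,
    phewas_results: list[PhewasResult],
    perm_alpha: float = 0.005,
) -> list[int]:
    """Mode-retention rule (0-based indices).

    A mode is retained when its permutation p-value is below ``perm_alpha``
    AND its screen shows at least one FDR-significant phenotype. An empty
    retention is allowed (logged).
    """
    if len(perm_pvalues) != len(phewas_results):
        raise ValueError("one screen result per mode required")
    retained = [
        l
        for l, (p, res) in enumerate(zip(perm_pvalues, phewas_results))
        if p < perm_alpha and res.n_fdr >= 1
    ]
    if not retained:
        warnings.warn("no mode met the retention rule", stacklevel=2)
    return retained


def manhattan_table(result: PhewasResult) -> pd.DataFrame:
    """Plot-ready table: -log10 p per phenotype plus both threshold lines.

    Two FDR lines are emitted: the nominal rate q and the data-dependent
    largest rejected p (NaN when nothing was rejected).
    """
    t = result.table.copy()
    t["neg_log10_p"] = -np.log10(t["p"])
    t["bonferroni_line"] = -np.log10(result.bonferroni_threshold)
    emp = result.fdr_threshold_empirical
    t["fdr_line_empirical"] = -np.log10(emp) if emp is not None else np.nan
    t["fdr_line_nominal"] = -np.log10(result.fdr_q)
    return t[
        ["phenotype", "category", "r", "p", "n", "neg_log10_p",
         "bonferroni_significant", "fdr_significant",
         "bonferroni_line", "fdr_line_empirical", "fdr_line_nominal"]
    ]


def plot_manhattan(result: PhewasResult, path: str) -> None:
    """Save a Manhattan plot (phenotypes grouped/colored by category)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = manhattan_table(result).sort_values("category").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(10, 4))
    for cat, grp in t.groupby("category", sort=True):
        ax.scatter(grp.index, grp["neg_log10_p"], s=8, label=str(cat))
    ax.axhline(t["bonferroni_line"].iloc[0], color="k", ls="--", lw=0.8, label="Bonferroni")
    if np.isfinite(t["fdr_line_empirical"].iloc[0]):
        ax.axhline(t["fdr_line_empirical"].iloc[0], color="gray", ls=":", lw=0.8, label="FDR")
    ax.set_xlabel("phenotype")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=6, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
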