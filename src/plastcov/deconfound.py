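"""Change-matrix construction and nuisance removal.

Within-subject volume change is the second-visit volume minus the first-visit
volume, per region. Nuisance variation (BMI, head size, motion, head/table
position, acquisition site, and an age/sex polynomial basis: age, age^2, sex,
sex*age, sex*age^2) is removed from each change column by ordinary
least-squares residualization, then columns are z-scored. The pipeline order
is fixed — raw change -> residualized -> standardized — and enforced through
a state flag on the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATES = ("raw", "residualized", "standardized")

#: covariate columns always included in the confound design
CORE_COVARIATES = ("bmi", "head_size", "motion_task", "motion_rest")
#: optional covariates (synthetic cohorts may omit them)
OPTIONAL_COVARIATES = ("head_pos_x", "head_pos_y", "head_pos_z", "table_pos")


@dataclass
class ChangeMatrix:
    """n x k labeled matrix of within-subject volume differences."""

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("change matrix contains non-finite entries")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated region labels: {dups}")

    @property
    def region_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, labels: list[str]) -> "ChangeMatrix":
        missing = [l for l in labels if l not in self.values.columns]
        if missing:
            raise KeyError(f"regions not in matrix: {missing}")
        return ChangeMatrix(self.values[labels].copy(), state=self.state)


def compute_change(cohort: pd.DataFrame, region_set: list[str]) -> ChangeMatrix:
    """Per-subject volume change (visit 2 minus visit 1) for listed regions.

    Subjects with any missing volume among the listed regions are excluded
    listwise (logged via warning) — the downstream co-decomposition requires
    complete matrices.
    """
    for region in region_set:
        for suffix in ("_t1", "_t2"):
            if f"{region}{suffix}" not in cohort.columns:
                raise KeyError(
                    f"region {region!r} missing column {region}{suffix} in cohort"
                )
    t1 = cohort[[f"{r}_t1" for r in region_set]].to_numpy(dtype=float)
    t2 = cohort[[f"{r}_t2" for r in region_set]].to_numpy(dtype=float)
    delta = pd.DataFrame(t2 - t1, index=cohort.index, columns=region_set)
    incomplete = delta.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"excluding {int(incomplete.sum())} subjects with missing volumes",
            stacklevel=2,
        )
        delta = delta.loc[~incomplete]
    return ChangeMatrix(delta, state="raw")


def build_confound_design(
    cohort: pd.DataFrame,
    include_site: bool = True,
    include_position: bool = True,
) -> pd.DataFrame:
    """Confound design: intercept, scanner nuisances, site dummies, and the
    age/sex basis (age, age^2, sex, sex*age, sex*age^2).

    Continuous columns are mean-centered; site is one-hot with the first level
    dropped. Zero-variance columns are dropped with a warning.
    """
    required = ["cov_age", "cov_sex"] + [f"cov_{c}" for c in CORE_COVARIATES]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise KeyError(f"missing covariate columns: {missing}")

    parts: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    names = list(CORE_COVARIATES)
    if include_position:
        names += [c for c in OPTIONAL_COVARIATES if f"cov_{c}" in cohort.columns]
    for c in names:
        parts[c] = cohort[f"cov_{c}"].to_numpy(dtype=float)

    if include_site and "cov_site" in cohort.columns:
        dummies = pd.get_dummies(
            cohort["cov_site"].astype("category"), prefix="site", drop_first=True
        )
        for col in dummies.columns:
            parts[str(col)] = dummies[col].to_numpy(dtype=float)

    age = cohort["cov_age"].to_numpy(dtype=float)
    sex = cohort["cov_sex"].to_numpy(dtype=float)
    parts["age"] = age
    parts["age2"] = age**2
    parts["sex"] = sex
    parts["sex_x_age"] = sex * age
    parts["sex_x_age2"] = sex * age**2

    design = pd.DataFrame(parts, index=cohort.index)
    kept = ["intercept"]
    for col in design.columns[1:]:
        if design[col].std() == 0:
            warnings.warn(f"dropping zero-variance confound column {col!r}", stacklevel=2)
        else:
            kept.append(col)
    design = design[kept]
    centered = design.iloc[:, 1:] - design.iloc[:, 1:].mean()
    return pd.concat([design[["intercept"]], centered], axis=1)


def residualize(m: ChangeMatrix, design: pd.DataFrame) -> ChangeMatrix:
    """Replace each column by its OLS residual against the confound design."""
    if m.state == "standardized":
        raise ValueError(
            "residualize expects a raw/residualized matrix; z-score afterwards"
        )
    if len(design) != m.n_subjects:
        raise ValueError(
            f"design has {len(design)} rows but matrix has {m.n_subjects} subjects"
        )
    D = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify the collinear columns via QR pivoting on the gram structure
        _, R = np.linalg.qr(D)
        bad = [
            design.columns[j]
            for j in range(D.shape[1])
            if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))
        ]
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(D, m.to_numpy(), rcond=None)
    resid = m.to_numpy() - D @ beta
    return ChangeMatrix(
        pd.DataFrame(resid, index=m.values.index, columns=m.values.columns),
        state="residualized",
    )


def zscore_columns(m: ChangeMatrix, ddof: int = 1) -> ChangeMatrix:
    """Column-wise z-scoring to zero mean and unit (sample) variance."""
    X = m.to_numpy()
    sd = X.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance region columns: {[m.region_labels[j] for j in zero]}"
        )
    Z = (X - X.mean(axis=0)) / sd
    return ChangeMatrix(
        pd.DataFrame(Z, index=m.values.index, columns=m.values.columns),
        state="standardized",
    )


def prepare_change_matrix(
    cohort: pd.DataFrame,
    region_set: list[str],
    include_site: bool = True,
    include_position: bool = True,
) -> tuple[ChangeMatrix, ChangeMatrix]:
    """Full preparatory chain: change -> residualize -> z-score.

    Returns ``(raw, standardized)`` — the raw mm^3 change matrix is retained
    because the age-binned ranking works on physical change, while the
    co-decomposition uses the standardized matrix.
    """
    raw = compute_change(cohort, region_set)
    design = build_confound_design(
        cohort.loc[raw.values.index],
        include_site=include_site,
        include_position=include_position,
    )
    return raw, zscore_columns(residualize(raw, design))
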