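"""Synthetic two-visit cohorts with planted low-rank covariation.

The generator emulates the data regime of a longitudinal population-imaging
study: ~1400 participants scanned twice about 2.3 years apart, 18 amygdala
subnuclei volumes (9 per hemisphere) and 109 (sub)cortical region volumes per
visit, nuisance covariates, and a wide phenotype table. The within-subject
volume change is built as a low-rank signal

    dX = sum_k s_k * z_k a_k^T + noise + confounds,   dY likewise with b_k,

so every downstream stage (deconfounding, PLSC, hemisphere contrast,
phenome screen, ranking) can be tested against known ground truth.
Hemispheric asymmetry is planted as additive offsets on the left-half
amygdala loadings; phenotypes are linearly coupled to chosen latent columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import amygdala_labels, brain_labels

CONFOUND_NAMES = (
    "bmi",
    "head_size",
    "motion_task",
    "motion_rest",
    "head_pos_x",
    "head_pos_y",
    "head_pos_z",
    "table_pos",
)


@dataclass
class PhenotypeSpec:
    """One phenotype column: optionally coupled to a latent mode.

    mode: latent mode index (0-based) the column tracks, or None for pure noise.
    effect: linear coupling strength in SD units of the latent score.
    datatype: numerical | binary | categorical-ordered | categorical-unordered.
    missing_rate: independent per-entry missingness probability.
    n_levels: category count for categorical datatypes.
    category: domain tag carried through to the screen output.
    """

    mode: int | None = None
    effect: float = 0.0
    datatype: str = "numerical"
    missing_rate: float = 0.0
    n_levels: int = 3
    category: str = "lifestyle"
    name: str | None = None


@dataclass
class SynthConfig:
    n_subjects: int = 1414
    n_amygdala: int = 18
    n_brain: int = 109
    n_modes: int = 1
    mode_strengths: Sequence[float] = (5.0,)
    noise_sd: float = 1.0
    amygdala_loadings: np.ndarray | None = None  # K x p, unit rows
    brain_loadings: np.ndarray | None = None  # K x q, unit rows
    confound_effects: dict[str, float] = field(default_factory=dict)
    asymmetry: np.ndarray | None = None  # K x (p//2) offsets on left loadings
    phenotype_spec: list[PhenotypeSpec] = field(default_factory=list)
    age_range: tuple[int, int] = (48, 81)
    interval_years_mean: float = 2.3
    interval_years_sd: float = 0.42  # 5 months
    n_sites: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_amygdala % 2 != 0:
            raise ValueError("n_amygdala must be even (mirrored hemispheres)")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if len(self.mode_strengths) != self.n_modes:
            raise ValueError("mode_strengths length must equal n_modes")
        s = np.asarray(self.mode_strengths, dtype=float)
        if np.any(s < 0):
            raise ValueError("mode_strengths must be non-negative")
        if self.n_modes > 1 and not np.all(np.diff(s) < 0) and np.any(s > 0):
            raise ValueError("mode_strengths must be strictly decreasing")
        for mat, n_cols, side in (
            (self.amygdala_loadings, self.n_amygdala, "amygdala"),
            (self.brain_loadings, self.n_brain, "brain"),
        ):
            if mat is not None:
                mat = np.asarray(mat, dtype=float)
                if mat.shape != (self.n_modes, n_cols):
                    raise ValueError(
                        f"{side}_loadings must have shape ({self.n_modes}, {n_cols}),"
                        f" got {mat.shape}"
                    )
        if self.asymmetry is not None:
            asym = np.asarray(self.asymmetry, dtype=float)
            if asym.shape != (self.n_modes, self.n_amygdala // 2):
                raise ValueError(
                    "asymmetry must have shape (n_modes, n_amygdala//2), got "
                    f"{asym.shape}"
                )


@dataclass
class GroundTruth:
    """Planted quantities retained for oracle checks."""

    latent_scores: pd.DataFrame  # n x K
    amygdala_loadings: np.ndarray  # K x p, effective (asymmetry applied)
    brain_loadings: np.ndarray  # K x q
    mode_strengths: np.ndarray
    asymmetry: np.ndarray  # K x (p//2)
    delta_amygdala: pd.DataFrame  # total planted change (signal+noise+confounds)
    delta_brain: pd.DataFrame
    delta_amygdala_clean: pd.DataFrame  # before confound contamination
    delta_brain_clean: pd.DataFrame
    confound_coefs: dict[str, tuple[np.ndarray, np.ndarray]]
    phenotype_effects: dict[str, tuple[int | None, float]]


def _random_unit_rows(rng: np.random.Generator, k: int, n: int) -> np.ndarray:
    m = rng.standard_normal((k, n))
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a two-visit cohort table and its ground truth.

    Returns a wide per-subject DataFrame (index ``subject_id``) with columns
    ``am_*_t1/_t2``, ``brain_*_t1/_t2``, ``cov_*`` and ``phen_*``, plus a
    :class:`GroundTruth` holding the planted latent scores, loadings and the
    exact change matrices (with and without confound contamination).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, q, K = config.n_subjects, config.n_amygdala, config.n_brain, config.n_modes
    am_labels = amygdala_labels(p)
    br_labels = brain_labels(q)
    subjects = pd.Index([f"sub_{i:05d}" for i in range(n)], name="subject_id")

    if config.amygdala_loadings is not None:
        A = np.asarray(config.amygdala_loadings, dtype=float)
    else:
        # mirrored by default: identical left/right half-loadings, so any
        # hemispheric difference comes only from the planted asymmetry
        half = _random_unit_rows(rng, K, p // 2)
        A = np.concatenate([half, half], axis=1)
    B = (
        np.asarray(config.brain_loadings, dtype=float)
        if config.brain_loadings is not None
        else _random_unit_rows(rng, K, q)
    )
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    asym = (
        np.asarray(config.asymmetry, dtype=float)
        if config.asymmetry is not None
        else np.zeros((K, p // 2))
    )
    A_eff = A.copy()
    A_eff[:, : p // 2] += asym  # left-half offsets define the lateralized truth

    s = np.asarray(config.mode_strengths, dtype=float)
    Z = rng.standard_normal((n, K))

    dX_clean = (Z * s) @ A_eff + config.noise_sd * rng.standard_normal((n, p))
    dY_clean = (Z * s) @ B + config.noise_sd * rng.standard_normal((n, q))

    # covariates
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n)
    sex = rng.integers(0, 2, size=n)
    site = rng.integers(0, config.n_sites, size=n)
    cov = pd.DataFrame(
        {
            "cov_age": age.astype(float),
            "cov_sex": sex.astype(float),
            "cov_site": site.astype(float),
            "cov_bmi": rng.normal(27.0, 4.0, n),
            "cov_head_size": rng.normal(1500.0, 120.0, n),
            "cov_motion_task": rng.gamma(2.0, 0.05, n),
            "cov_motion_rest": rng.gamma(2.0, 0.05, n),
            "cov_head_pos_x": rng.normal(0.0, 3.0, n),
            "cov_head_pos_y": rng.normal(0.0, 3.0, n),
            "cov_head_pos_z": rng.normal(0.0, 3.0, n),
            "cov_table_pos": rng.normal(0.0, 5.0, n),
            "cov_interval_years": np.clip(
                rng.normal(config.interval_years_mean, config.interval_years_sd, n),
                2.0,
                3.0,
            ),
        },
        index=subjects,
    )

    # linear confound contamination of both change matrices
    dX = dX_clean.copy()
    dY = dY_clean.copy()
    confound_coefs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, scale in config.confound_effects.items():
        if name not in CONFOUND_NAMES:
            raise ValueError(f"unknown confound {name!r}; known: {CONFOUND_NAMES}")
        col = cov[f"cov_{name}"].to_numpy()
        col = (col - col.mean()) / col.std()
        gx = rng.standard_normal(p) * scale
        gy = rng.standard_normal(q) * scale
        dX += np.outer(col, gx)
        dY += np.outer(col, gy)
        confound_coefs[name] = (gx, gy)

    # baselines: log-normal, region-specific means; t2 = t1 + delta
    am_mu = rng.uniform(np.log(150.0), np.log(800.0), p)
    br_mu = rng.uniform(np.log(2000.0), np.log(20000.0), q)
    t1_am = np.exp(am_mu + 0.10 * rng.standard_normal((n, p)))
    t1_br = np.exp(br_mu + 0.10 * rng.standard_normal((n, q)))

    data = {}
    for j, lab in enumerate(am_labels):
        data[f"{lab}_t1"] = t1_am[:, j]
        data[f"{lab}_t2"] = t1_am[:, j] + dX[:, j]
    for j, lab in enumerate(br_labels):
        data[f"{lab}_t1"] = t1_br[:, j]
        data[f"{lab}_t2"] = t1_br[:, j] + dY[:, j]
    cohort = pd.concat([pd.DataFrame(data, index=subjects), cov], axis=1)

    # phenotypes coupled to latent columns
    phen, phen_effects = _make_phenotypes(config, rng, Z, subjects)
    cohort = pd.concat([cohort, phen], axis=1)

    truth = GroundTruth(
        latent_scores=pd.DataFrame(
            Z, index=subjects, columns=[f"mode_{k + 1}" for k in range(K)]
        ),
        amygdala_loadings=A_eff,
        brain_loadings=B,
        mode_strengths=s,
        asymmetry=asym,
        delta_amygdala=pd.DataFrame(dX, index=subjects, columns=am_labels),
        delta_brain=pd.DataFrame(dY, index=subjects, columns=br_labels),
        delta_amygdala_clean=pd.DataFrame(dX_clean, index=subjects, columns=am_labels),
        delta_brain_clean=pd.DataFrame(dY_clean, index=subjects, columns=br_labels),
        confound_coefs=confound_coefs,
        phenotype_effects=phen_effects,
    )
    return cohort, truth


def _make_phenotypes(
    config: SynthConfig,
    rng: np.random.Generator,
    Z: np.ndarray,
    subjects: pd.Index,
) -> tuple[pd.DataFrame, dict[str, tuple[int | None, float]]]:
    n = len(subjects)
    cols: dict[str, np.ndarray] = {}
    effects: dict[str, tuple[int | None, float]] = {}
    for i, spec in enumerate(config.phenotype_spec):
        name = spec.name or f"phen_{i + 1:04d}"
        if not name.startswith("phen_"):
            name = "phen_" + name
        signal = Z[:, spec.mode] * spec.effect if spec.mode is not None else 0.0
        latent = signal + rng.standard_normal(n)
        if spec.datatype == "numerical":
            vals = latent
        elif spec.datatype == "binary":
            vals = (latent > np.median(latent)).astype(float)
        elif spec.datatype == "categorical-ordered":
            edges = np.quantile(latent, np.linspace(0, 1, spec.n_levels + 1)[1:-1])
            vals = np.digitize(latent, edges).astype(float)
        elif spec.datatype == "categorical-unordered":
            # unordered: levels carry no monotone relation to the latent signal
            shuffled_levels = rng.permutation(spec.n_levels)
            edges = np.quantile(latent, np.linspace(0, 1, spec.n_levels + 1)[1:-1])
            vals = shuffled_levels[np.digitize(latent, edges)].astype(float)
        else:
            raise ValueError(f"unknown phenotype datatype {spec.datatype!r}")
        if spec.missing_rate > 0:
            mask = rng.random(n) < spec.missing_rate
            vals = vals.astype(float)
            vals[mask] = np.nan
        cols[name] = vals
        effects[name] = (spec.mode, spec.effect)
    return pd.DataFrame(cols, index=subjects), effects


def make_phenotype_fixture(
    config: SynthConfig,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Phenotype table exercising every harmonization rule.

    Builds the configured phenotype columns and appends three trigger columns:
    one with fewer than 500 complete values, one duplicating the first column
    (correlation 1.0), and a 3-level unordered categorical. Returns the table
    plus datatype and category tag maps.
    """
    if not config.phenotype_spec:
        raise ValueError("phenotype_spec must be non-empty")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_subjects
    Z = rng.standard_normal((n, config.n_modes))
    subjects = pd.Index([f"sub_{i:05d}" for i in range(n)], name="subject_id")
    phen, _ = _make_phenotypes(config, rng, Z, subjects)
    dtypes = {
        c: s.datatype for c, s in zip(phen.columns, config.phenotype_spec)
    }
    cats = {c: s.category for c, s in zip(phen.columns, config.phenotype_spec)}

    sparse = rng.standard_normal(n)
    n_missing = max(0, n - 499)  # leaves 499 complete values -> dropped
    sparse[rng.choice(n, size=n_missing, replace=False)] = np.nan
    phen["phen_sparse"] = sparse
    dtypes["phen_sparse"] = "numerical"
    cats["phen_sparse"] = "early_life"

    first = phen.columns[0]
    phen["phen_duplicate"] = phen[first]
    dtypes["phen_duplicate"] = dtypes[first]
    cats["phen_duplicate"] = cats[first]

    phen["phen_unordered3"] = rng.integers(0, 3, n).astype(float)
    dtypes["phen_unordered3"] = "categorical-unordered"
    cats["phen_unordered3"] = "lifestyle"
    return phen, dtypes, cats
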