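"""Bootstrap hemisphere-contrast test for lateralized covariation.

Two PLSC models are fitted per bootstrap resample of subjects: one coupling
the left-hemisphere amygdala subnuclei to the whole brain, one coupling the
right-hemisphere subnuclei to the same brain regions. The two solutions carry
two non-identifiabilities — sign and mode order — so each is aligned to a
fixed full-sample reference via the brain-side canonical vectors (the only
variable space both fits share). The per-coefficient left-minus-right
differences of the aligned canonical vectors are aggregated over iterations
into a nonparametric distribution; a coefficient is called lateralized when
its [10th, 90th] percentile interval excludes zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconfound import ChangeMatrix
from .plsc import PLSCModel, fit_plsc


@dataclass
class Alignment:
    """Mode permutation + sign flips mapping one model onto a reference."""

    permutation: np.ndarray  # other mode index matched to each reference mode
    signs: np.ndarray  # +-1 per reference mode
    correlations: np.ndarray  # |r| of matched brain-side vector pairs

    @property
    def is_identity(self) -> bool:
        return bool(
            np.array_equal(self.permutation, np.arange(len(self.permutation)))
            and np.all(self.signs == 1)
        )


def _corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns of A with columns of B."""
    Az = A - A.mean(axis=0)
    Bz = B - B.mean(axis=0)
    na = np.linalg.norm(Az, axis=0)
    nb = np.linalg.norm(Bz, axis=0)
    tol = 1e-12 * np.sqrt(A.shape[0])
    if np.any(na < tol) or np.any(nb < tol):
        raise ValueError("degenerate (zero-variance) canonical vector")
    return (Az.T @ Bz) / np.outer(na, nb)


def match_modes(
    reference_U: np.ndarray, other_U: np.ndarray, method: str = "greedy"
) -> Alignment:
    """Solve the mode-matching assignment on brain-side canonical vectors.

    greedy: repeatedly take the largest remaining |r| pair (descending order);
    exhaustive: best total |r| over all permutations (tractable for small L).
    Each reference mode is matched exactly once; signs follow the sign of the
    matched correlation.
    """
    R = _corr_matrix(reference_U, other_U)
    L = R.shape[0]
    if method == "exhaustive":
        best, best_perm = -np.inf, None
        for perm in itertools.permutations(range(L)):
            total = sum(abs(R[i, perm[i]]) for i in range(L))
            if total > best:
                best, best_perm = total, perm
        perm = np.array(best_perm)
    elif method == "greedy":
        perm = np.full(L, -1)
        absR = np.abs(R.copy())
        for _ in range(L):
            i, j = np.unravel_index(np.argmax(absR), absR.shape)
            perm[i] = j
            absR[i, :] = -np.inf
            absR[:, j] = -np.inf
    else:
        raise ValueError(f"unknown matching method {method!r}")
    signs = np.sign(R[np.arange(L), perm])
    signs[signs == 0] = 1
    return Alignment(
        permutation=perm,
        signs=signs.astype(int),
        correlations=np.abs(R[np.arange(L), perm]),
    )


def align_modes(
    reference: PLSCModel, other: PLSCModel, method: str = "greedy"
) -> tuple[PLSCModel, Alignment]:
    """Return ``other`` with modes permuted/sign-flipped to match ``reference``.

    Flipped modes have V, U and both score columns negated together so the
    model stays internally consistent.
    """
    if reference.U.shape[0] != other.U.shape[0]:
        raise ValueError("models do not share the brain-side variable space")
    if reference.n_modes != other.n_modes:
        raise ValueError("mode counts differ")
    al = match_modes(reference.U.to_numpy(), other.U.to_numpy(), method=method)
    perm, signs = al.permutation, al.signs
    modes = list(reference.U.columns)

    def _remap(df: pd.DataFrame) -> pd.DataFrame:
        out = df.to_numpy()[:, perm] * signs
        return pd.DataFrame(out, index=df.index, columns=modes)

    aligned = PLSCModel(
        V=_remap(other.V),
        U=_remap(other.U),
        singular_values=other.singular_values[perm],
        LX=_remap(other.LX),
        LY=_remap(other.LY),
        mode_correlations=other.mode_correlations[perm],
        explained_covariance_fraction=other.explained_covariance_fraction[perm],
        n_subjects=other.n_subjects,
        perm_pvalues=None
        if other.perm_pvalues is None
        else other.perm_pvalues[perm],
    )
    return aligned, al


@dataclass
class BootstrapContrast:
    """Left-minus-right difference distributions and their percentile bounds."""

    amygdala_diffs: np.ndarray  # n_boot x 9 x L
    brain_diffs: np.ndarray  # n_boot x q x L
    amygdala_labels: list[str]  # nucleus names (hemisphere prefix stripped)
    brain_labels: list[str]
    mode_names: list[str]
    lower_pct: float
    upper_pct: float
    alignment_log: list[dict] = field(default_factory=list)
    retry_log: list[int] = field(default_factory=list)

    def _bounds(self, diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lo = np.percentile(diffs, self.lower_pct, axis=0)
        hi = np.percentile(diffs, self.upper_pct, axis=0)
        med = np.median(diffs, axis=0)
        return lo, med, hi

    def table(self, side: str = "amygdala") -> pd.DataFrame:
        """Per-coefficient summary: median, bounds, selection and direction."""
        diffs = self.amygdala_diffs if side == "amygdala" else self.brain_diffs
        labels = self.amygdala_labels if side == "amygdala" else self.brain_labels
        lo, med, hi = self._bounds(diffs)
        rows = []
        for l, mode in enumerate(self.mode_names):
            for j, lab in enumerate(labels):
                selected = bool(lo[j, l] > 0 or hi[j, l] < 0)
                direction = (
                    "left_dominant"
                    if selected and lo[j, l] > 0
                    else ("right_dominant" if selected else "none")
                )
                rows.append(
                    {
                        "signature": mode,
                        "label": lab,
                        "median_diff": med[j, l],
                        f"lo{self.lower_pct:g}": lo[j, l],
                        f"hi{self.upper_pct:g}": hi[j, l],
                        "selected": selected,
                        "direction": direction,
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_hemisphere_contrast(
    am_left: ChangeMatrix,
    am_right: ChangeMatrix,
    brain: ChangeMatrix,
    L: int,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    pairing: str = "reference",
    max_retries: int = 10,
) -> BootstrapContrast:
    """Bootstrap distribution of left-minus-right canonical coefficients.

    The same resampled subjects feed both hemisphere fits within an iteration
    (paired design). ``pairing='reference'`` aligns both per-iteration fits to
    the full-sample left-hemisphere solution; ``pairing='iteration'`` aligns
    the right fit to the left fit of the same iteration only.
    """
    if not (
        am_left.n_subjects == am_right.n_subjects == brain.n_subjects
    ):
        raise ValueError("matrices must share subjects")
    if len(am_left.region_labels) != len(am_right.region_labels):
        raise ValueError("hemisphere matrices must have equal column counts")
    if pairing not in ("reference", "iteration"):
        raise ValueError(f"unknown pairing {pairing!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = brain.n_subjects

    ref_left = fit_plsc(am_left, brain, L)
    ref_right_raw = fit_plsc(am_right, brain, L)
    ref_right, _ = align_modes(ref_left, ref_right_raw)

    nuclei = [l.replace("am_L_", "", 1) for l in am_left.region_labels]
    q = len(brain.region_labels)
    am_diffs = np.empty((n_boot, len(nuclei), L))
    br_diffs = np.empty((n_boot, q, L))
    alignment_log: list[dict] = []
    retry_log: list[int] = []

    def _resample_fit(idx: np.ndarray) -> tuple[PLSCModel, PLSCModel]:
        Xl = ChangeMatrix(am_left.values.iloc[idx].reset_index(drop=True), state=am_left.state)
        Xr = ChangeMatrix(am_right.values.iloc[idx].reset_index(drop=True), state=am_right.state)
        Yb = ChangeMatrix(brain.values.iloc[idx].reset_index(drop=True), state=brain.state)
        return fit_plsc(Xl, Yb, L), fit_plsc(Xr, Yb, L)

    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            zero_var = (
                np.any(am_left.to_numpy()[idx].std(axis=0) == 0)
                or np.any(am_right.to_numpy()[idx].std(axis=0) == 0)
                or np.any(brain.to_numpy()[idx].std(axis=0) == 0)
            )
            if not zero_var:
                break
            retry_log.append(b)
            warnings.warn(f"iteration {b}: zero-variance resample, redrawing", stacklevel=2)
        else:
            raise RuntimeError(f"iteration {b}: zero-variance resamples after {max_retries} retries")

        fit_l, fit_r = _resample_fit(idx)
        if pairing == "reference":
            fit_l, al_l = align_modes(ref_left, fit_l)
            fit_r, al_r = align_modes(ref_left, fit_r)
        else:
            al_l = Alignment(np.arange(L), np.ones(L, dtype=int), np.ones(L))
            fit_r, al_r = align_modes(fit_l, fit_r)
        alignment_log.append(
            {
                "iteration": b,
                "left_perm": al_l.permutation.tolist(),
                "left_signs": al_l.signs.tolist(),
                "right_perm": al_r.permutation.tolist(),
                "right_signs": al_r.signs.tolist(),
            }
        )
        am_diffs[b] = fit_l.V.to_numpy() - fit_r.V.to_numpy()
        br_diffs[b] = fit_l.U.to_numpy() - fit_r.U.to_numpy()

    return BootstrapContrast(
        amygdala_diffs=am_diffs,
        brain_diffs=br_diffs,
        amygdala_labels=nuclei,
        brain_labels=brain.region_labels,
        mode_names=list(ref_left.V.columns),
        lower_pct=lower_pct,
        upper_pct=upper_pct,
        alignment_log=alignment_log,
        retry_log=retry_log,
    )


def select_lateralized(contrast: BootstrapContrast) -> pd.DataFrame:
    """Coefficients whose percentile interval strictly excludes zero.

    Direction follows the left-minus-right convention: an interval entirely
    above zero is left-dominant, entirely below is right-dominant.
    """
    tables = [contrast.table("amygdala").assign(side="amygdala"),
              contrast.table("brain").assign(side="brain")]
    full = pd.concat(tables, ignore_index=True)
    return full[full["selected"]].reset_index(drop=True)
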