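"""Partial least squares canonical (PLSC) co-decomposition.

Two standardized change matrices X (n x p, amygdala subnuclei) and
Y (n x q, whole-brain regions) are co-decomposed by a single SVD of their
cross-covariance C = X^T Y / (n - 1). The left/right singular vectors are the
paired canonical vectors V (p x L) and U (q x L); projections L_X = XV and
L_Y = YU are the per-subject expressions of each covariation mode. Modes are
ordered by descending singular value, i.e. by the covariance
cov(l_X, l_Y) = s_l / (extra factor absorbed in the scaling) they capture.

Mode significance uses a permutation test: rows of Y are shuffled, the model
refitted, and each observed singular value is ranked against the permuted
singular values at the same mode index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .deconfound import ChangeMatrix


@dataclass
class PLSCModel:
    """Fitted co-decomposition: canonical vectors, scores and diagnostics."""

    V: pd.DataFrame  # p x L, unit-norm columns (amygdala side)
    U: pd.DataFrame  # q x L, unit-norm columns (brain side)
    singular_values: np.ndarray  # L, descending
    LX: pd.DataFrame  # n x L subject scores, X side
    LY: pd.DataFrame  # n x L subject scores, Y side
    mode_correlations: np.ndarray  # L, Pearson r of paired score columns
    explained_covariance_fraction: np.ndarray  # L, s_l^2 / sum all s^2
    n_subjects: int
    perm_pvalues: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return self.V.shape[1]

    def copy(self) -> "PLSCModel":
        return PLSCModel(
            V=self.V.copy(),
            U=self.U.copy(),
            singular_values=self.singular_values.copy(),
            LX=self.LX.copy(),
            LY=self.LY.copy(),
            mode_correlations=self.mode_correlations.copy(),
            explained_covariance_fraction=self.explained_covariance_fraction.copy(),
            n_subjects=self.n_subjects,
            perm_pvalues=None if self.perm_pvalues is None else self.perm_pvalues.copy(),
        )


def _check_inputs(X: ChangeMatrix, Y: ChangeMatrix, L: int) -> None:
    if X.state != "standardized" or Y.state != "standardized":
        raise ValueError(
            f"fit_plsc requires standardized matrices, got states "
            f"{X.state!r}/{Y.state!r}"
        )
    if X.n_subjects != Y.n_subjects:
        raise ValueError(
            f"row mismatch: X has {X.n_subjects} subjects, Y has {Y.n_subjects}"
        )
    if not X.values.index.equals(Y.values.index):
        raise ValueError("X and Y subject order differs")
    p, q = len(X.region_labels), len(Y.region_labels)
    if not 1 <= L <= min(p, q):
        raise ValueError(f"L must be in [1, {min(p, q)}], got {L}")


def _svd_cross_cov(Xa: np.ndarray, Ya: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    C = Xa.T @ Ya / (Xa.shape[0] - 1)
    V, s, Ut = linalg.svd(C, full_matrices=False)
    return V, s, Ut.T


def fit_plsc(X: ChangeMatrix, Y: ChangeMatrix, L: int) -> PLSCModel:
    """Fit the top-L covariance-maximizing mode pairs.

    Sign convention: the largest-magnitude entry of each amygdala-side
    canonical vector is made positive (U and the score columns flip with it),
    removing the SVD's sign non-identifiability deterministically.
    """
    _check_inputs(X, Y, L)
    Xa, Ya = X.to_numpy(), Y.to_numpy()
    Vfull, sfull, Ufull = _svd_cross_cov(Xa, Ya)
    V, s, U = Vfull[:, :L].copy(), sfull[:L].copy(), Ufull[:, :L].copy()

    for l in range(L):
        j = np.argmax(np.abs(V[:, l]))
        if V[j, l] < 0:
            V[:, l] *= -1
            U[:, l] *= -1

    LX = Xa @ V
    LY = Ya @ U
    r = np.array(
        [stats.pearsonr(LX[:, l], LY[:, l])[0] if LX[:, l].std() > 0 and LY[:, l].std() > 0 else 0.0 for l in range(L)]
    )
    modes = [f"mode_{l + 1}" for l in range(L)]
    return PLSCModel(
        V=pd.DataFrame(V, index=X.region_labels, columns=modes),
        U=pd.DataFrame(U, index=Y.region_labels, columns=modes),
        singular_values=s,
        LX=pd.DataFrame(LX, index=X.values.index, columns=modes),
        LY=pd.DataFrame(LY, index=Y.values.index, columns=modes),
        mode_correlations=r,
        explained_covariance_fraction=s**2 / np.sum(sfull**2),
        n_subjects=X.n_subjects,
    )


def permutation_test(
    X: ChangeMatrix,
    Y: ChangeMatrix,
    L: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-mode permutation p-values under row exchangeability.

    Rows of Y are permuted each iteration and the decomposition refitted; the
    p-value of mode l is (1 + #{permuted s_l >= observed s_l}) / (1 + n_perm),
    so the attainable minimum is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_inputs(X, Y, L)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xa, Ya = X.to_numpy(), Y.to_numpy()
    _, s_obs, _ = _svd_cross_cov(Xa, Ya)
    s_obs = s_obs[:L]
    exceed = np.zeros(L, dtype=int)
    n = Xa.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, s_perm, _ = _svd_cross_cov(Xa, Ya[perm])
        exceed += s_perm[:L] >= s_obs
    return (1 + exceed) / (1 + n_perm)


def fit_plsc_with_significance(
    X: ChangeMatrix,
    Y: ChangeMatrix,
    L: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PLSCModel:
    model = fit_plsc(X, Y, L)
    model.perm_pvalues = permutation_test(X, Y, L, n_perm=n_perm, seed=seed)
    return model


def project(
    model: PLSCModel, X: ChangeMatrix | None = None, Y: ChangeMatrix | None = None
) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Project (possibly new) subjects into the fitted embedding.

    Region labels must match the model's registries exactly; either side may
    be omitted.
    """
    LX = LY = None
    if X is not None:
        if X.region_labels != list(model.V.index):
            raise ValueError("X region labels do not match the model's amygdala registry")
        LX = pd.DataFrame(
            X.to_numpy() @ model.V.to_numpy(), index=X.values.index, columns=model.V.columns
        )
    if Y is not None:
        if Y.region_labels != list(model.U.index):
            raise ValueError("Y region labels do not match the model's brain registry")
        LY = pd.DataFrame(
            Y.to_numpy() @ model.U.to_numpy(), index=Y.values.index, columns=model.U.columns
        )
    return LX, LY
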