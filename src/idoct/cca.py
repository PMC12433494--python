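"""Canonical correlation analysis with permutation inference.

Quantifies the many-to-many association between per-task Cognitive
Indices and scalar imaging burden measures (stroke lesion volume,
white-matter hyperintensity volume).  The canonical weights solve the
standard generalized eigenproblem; the implementation whitens both blocks
with inverse symmetric square roots of their covariance and takes the SVD
of the cross-covariance, which is numerically equivalent.  Inference is by
permutation of the rows of one block: each mode's statistic is its
re-estimated canonical correlation, and p = (1 + #{perm >= obs}) /
(1 + n_perm).  Back-projected loadings are the Pearson correlations of
each original variable with the canonical variates of its own block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["CCA", "CCAResults", "permutation_test", "backproject"]

logger = logging.getLogger(__name__)


def _standardize(A: np.ndarray) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column: remove it before CCA")
    return (A - mu) / sd


def _inv_sqrt(S: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    vals, vecs = linalg.eigh(S)
    if vals.min() < rcond * vals.max():
        raise ValueError(
            "rank-deficient block covariance; remove collinear columns "
            "(no regularization is applied)")
    return (vecs / np.sqrt(vals)) @ vecs.T


def _fit_arrays(X: np.ndarray, Y: np.ndarray):
    n = X.shape[0]
    Xs, Ys = _standardize(X), _standardize(Y)
    Sxx = Xs.T @ Xs / (n - 1)
    Syy = Ys.T @ Ys / (n - 1)
    Sxy = Xs.T @ Ys / (n - 1)
    Kx, Ky = _inv_sqrt(Sxx), _inv_sqrt(Syy)
    U, svals, Vt = np.linalg.svd(Kx @ Sxy @ Ky)
    k = min(X.shape[1], Y.shape[1])
    corrs = np.clip(svals[:k], 0.0, 1.0)
    A = Kx @ U[:, :k]  # x weights: var(Xs @ a) = 1
    B = Ky @ Vt.T[:, :k]
    return corrs, A, B, Xs, Ys


class CCA:
    """Canonical correlation between two standardized variable blocks.

    Rows with any missing value in either block are dropped (listwise,
    logged).  Requires ``n > p + q`` complete rows.
    """

    def __init__(self, X, Y, phase: str = ""):
        Xd = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        Yd = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, float))
        if len(Xd) != len(Yd):
            raise ValueError("X and Y must have the same number of rows")
        complete = Xd.notna().all(axis=1).to_numpy() & Yd.notna().all(axis=1).to_numpy()
        dropped = int((~complete).sum())
        if dropped:
            logger.info("CCA: dropping %d incomplete rows (listwise deletion)", dropped)
        self.X = Xd.loc[complete].to_numpy(dtype=float)
        self.Y = Yd.loc[complete].to_numpy(dtype=float)
        self.x_names = list(Xd.columns)
        self.y_names = list(Yd.columns)
        self.phase = phase
        n, p, q = self.X.shape[0], self.X.shape[1], self.Y.shape[1]
        if n <= p + q:
            raise ValueError(f"need n > p + q complete rows (n={n}, p={p}, q={q})")

    def fit(self) -> "CCAResults":
        corrs, A, B, Xs, Ys = _fit_arrays(self.X, self.Y)
        xv = Xs @ A
        yv = Ys @ B
        # sign convention: the largest-|loading| variable of each x-variate
        # loads positively
        for m in range(corrs.size):
            lx = _colcorr(Xs, xv[:, m])
            j = int(np.argmax(np.abs(lx)))
            if lx[j] < 0:
                A[:, m] *= -1.0
                xv[:, m] *= -1.0
                B[:, m] *= -1.0
                yv[:, m] *= -1.0
        res = CCAResults(
            canonical_correlations=corrs,
            x_weights=pd.DataFrame(A, index=self.x_names,
                                   columns=_modes(corrs.size)),
            y_weights=pd.DataFrame(B, index=self.y_names,
                                   columns=_modes(corrs.size)),
            x_variates=xv, y_variates=yv,
            n_obs=self.X.shape[0], phase=self.phase,
        )
        res.x_backprojected = backproject(res, self.X, block="x")
        res.y_backprojected = backproject(res, self.Y, block="y")
        return res

    def permutation_test(self, n_perm: int = 9999, seed: int = 0) -> np.ndarray:
        """Per-mode permutation p-values (rows of Y shuffled)."""
        if n_perm < 1:
            raise ValueError("n_perm must be positive")
        rng = np.random.default_rng(seed)
        obs, *_ = _fit_arrays(self.X, self.Y)
        count = np.zeros_like(obs)
        Y = self.Y
        for _ in range(int(n_perm)):
            perm = rng.permutation(Y.shape[0])
            c, *_ = _fit_arrays(self.X, Y[perm])
            count += c >= obs
        return (1.0 + count) / (1.0 + n_perm)


def _modes(k: int) -> list[str]:
    return [f"mode{m + 1}" for m in range(k)]


def _colcorr(A: np.ndarray, v: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((Ac**2).sum(axis=0) * (vc**2).sum())
    return (Ac.T @ vc) / denom


@dataclass
class CCAResults:
    canonical_correlations: np.ndarray  # non-increasing, in [0, 1]
    x_weights: pd.DataFrame
    y_weights: pd.DataFrame
    x_variates: np.ndarray
    y_variates: np.ndarray
    n_obs: int
    phase: str = ""
    x_backprojected: pd.DataFrame | None = None
    y_backprojected: pd.DataFrame | None = None
    permutation_p: np.ndarray | None = None
    n_permutations: int = 0
    seed: int | None = None

    @property
    def r2(self) -> np.ndarray:
        """Squared canonical correlation per mode."""
        return self.canonical_correlations**2

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "mode": _modes(self.canonical_correlations.size),
            "canonical_r": self.canonical_correlations,
            "r2": self.r2,
        })
        if self.permutation_p is not None:
            out["perm_p"] = self.permutation_p
        return out


def permutation_test(X, Y, n_perm: int = 9999, seed: int = 0,
                     phase: str = "") -> CCAResults:
    """Fit the CCA and attach per-mode permutation p-values.

    For reportable inference use at least 999 permutations (the p-value
    floor is 1 / (1 + n_perm)).
    """
    if n_perm < 999:
        raise ValueError("use at least 999 permutations for inference")
    model = CCA(X, Y, phase=phase)
    res = model.fit()
    res.permutation_p = model.permutation_test(n_perm=n_perm, seed=seed)
    res.n_permutations = int(n_perm)
    res.seed = int(seed)
    return res


def backproject(result: CCAResults, data, block: str = "x") -> pd.DataFrame:
    """Correlate original variables with their own block's canonical variates."""
    arr = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else \
        np.asarray(data, dtype=float)
    variates = result.x_variates if block == "x" else result.y_variates
    names = result.x_weights.index if block == "x" else result.y_weights.index
    if arr.shape[0] != variates.shape[0]:
        raise ValueError("data rows do not match the fitted variates")
    if arr.shape[1] != len(names):
        raise ValueError("data columns do not match the fitted block")
    out = np.column_stack([_colcorr(arr, variates[:, m])
                           for m in range(variates.shape[1])])
    return pd.DataFrame(out, index=names, columns=_modes(variates.shape[1]))
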