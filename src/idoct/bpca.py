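"""Bayesian (EM) principal component analysis tolerating missing entries.

A probabilistic PCA model ``x = W z + mu + eps`` with isotropic noise is
fitted by expectation-maximisation directly on the incomplete participant
x task matrix: the E-step computes the posterior of the latent factor for
each row given its observed entries, the M-step updates ``W``, ``mu`` and
the noise variance feature-by-feature over the rows where that feature is
observed.  With the flat default priors the posterior mode coincides with
the maximum-likelihood principal axes, so on complete data the first
component agrees with classical PCA.

Initialisation is classical PCA on the mean-imputed matrix - deterministic,
so repeated fits are identical without any random seed.  The first
principal axis over task-level metrics is the global cognition factor G;
its sign is fixed so that the mean loading is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BayesianPCA", "BayesianPCAResults", "GlobalFactor", "extract_g"]

logger = logging.getLogger(__name__)


class BayesianPCA:
    """EM-PCA on a matrix with missing values.

    Parameters
    ----------
    data
        DataFrame (rows = participants, columns = tasks) or 2-D array;
        NaN marks missing entries.  Columns are standardised internally.
    n_components
        Number of principal axes to estimate.
    tol
        EM stopping rule: maximum absolute change of any weight entry.
    """

    def __init__(self, data, n_components: int = 1, tol: float = 1e-4,
                 max_iter: int = 500):
        X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else \
            np.asarray(data, dtype=float)
        self.columns = list(data.columns) if isinstance(data, pd.DataFrame) \
            else [f"x{j}" for j in range(X.shape[1])]
        self.index = list(data.index) if isinstance(data, pd.DataFrame) \
            else list(range(X.shape[0]))
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("need a 2-D matrix with at least 2 columns")
        n_obs = np.sum(np.isfinite(X), axis=0)
        if (n_obs == 0).any():
            bad = [self.columns[j] for j in np.where(n_obs == 0)[0]]
            raise ValueError(f"column(s) with no observed values: {bad}")
        if (n_obs < 2).any():
            bad = [self.columns[j] for j in np.where(n_obs < 2)[0]]
            raise ValueError(f"column(s) with fewer than 2 observed values: {bad}")
        self.X_raw = X
        self.n_components = int(n_components)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    def fit(self) -> "BayesianPCAResults":
        X = self.X_raw
        n, p = X.shape
        k = min(self.n_components, p)
        obs = np.isfinite(X)
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - mean) / sd
        Z0 = np.where(obs, Z, 0.0)

        # deterministic init: classical PCA of the mean-imputed matrix
        U, s, Vt = np.linalg.svd(Z0, full_matrices=False)
        W = (Vt[:k].T * (s[:k] / np.sqrt(max(n - 1, 1))))
        resid = max(np.sum(Z0**2) / max(obs.sum() - 1, 1) - np.sum(W**2) / p, 1e-6)
        sigma2 = resid
        mu = np.zeros(p)

        Ez = np.zeros((n, k))
        converged = False
        it = 0
        patterns: dict[bytes, np.ndarray] = {}
        for key, rows in pd.DataFrame(obs).groupby(list(range(p)), sort=False).groups.items():
            patterns[np.asarray(key, dtype=bool).tobytes()] = np.asarray(rows)

        for it in range(1, self.max_iter + 1):
            Ezz_sum_per_feature = np.zeros((p, k, k))
            Ez_x_per_feature = np.zeros((p, k))
            Covs = np.zeros((n, k, k))
            for key, rows in patterns.items():
                o = np.frombuffer(key, dtype=bool)
                if not o.any():
                    continue
                Wo = W[o]
                M = Wo.T @ Wo + sigma2 * np.eye(k)
                Minv = np.linalg.inv(M)
                Xo = Z[np.ix_(rows, np.where(o)[0])] - mu[o]
                Ez[rows] = Xo @ Wo @ Minv.T
                Covs[rows] = sigma2 * Minv
            Ezz = Covs + Ez[:, :, None] * Ez[:, None, :]

            W_new = np.zeros_like(W)
            mu_new = np.zeros(p)
            for j in range(p):
                r = obs[:, j]
                xj = Z[r, j]
                mu_new[j] = float(np.mean(xj - Ez[r] @ W[j]))
                A = Ezz[r].sum(axis=0)
                b = (xj - mu_new[j]) @ Ez[r]
                W_new[j] = np.linalg.solve(A + 1e-12 * np.eye(k), b)
            # noise update
            sse = 0.0
            for j in range(p):
                r = obs[:, j]
                pred = mu_new[j] + Ez[r] @ W_new[j]
                sse += float(np.sum((Z[r, j] - pred) ** 2))
                sse += float(np.einsum("i,nij,j->", W_new[j], Covs[r], W_new[j]))
            sigma2_new = max(sse / obs.sum(), 1e-10)

            delta = float(np.max(np.abs(W_new - W)))
            W, mu, sigma2 = W_new, mu_new, sigma2_new
            if delta < self.tol:
                converged = True
                break
        if not converged:
            logger.warning("EM-PCA did not converge in %d iterations", self.max_iter)

        # final E-step with converged parameters
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            if not o.any():
                continue
            Wo = W[o]
            M = Wo.T @ Wo + sigma2 * np.eye(k)
            Xo = Z[np.ix_(rows, np.where(o)[0])] - mu[o]
            Ez[rows] = Xo @ Wo @ np.linalg.inv(M).T

        # order components by weight norm, fix sign: mean loading positive
        norms = np.linalg.norm(W, axis=0)
        order = np.argsort(-norms)
        W, Ez = W[:, order], Ez[:, order]
        for m in range(k):
            if W[:, m].mean() < 0:
                W[:, m] *= -1.0
                Ez[:, m] *= -1.0

        S = pd.DataFrame(Z).where(pd.DataFrame(obs)).cov().to_numpy()
        tr = float(np.trace(S))
        ve = []
        for m in range(k):
            u = W[:, m] / max(np.linalg.norm(W[:, m]), 1e-300)
            ve.append(float(u @ S @ u / tr))
        imputed = mu + Ez @ W.T
        X_imputed = np.where(obs, Z, imputed) * sd + mean
        return BayesianPCAResults(
            columns=self.columns, index=self.index, weights=W, scores=Ez,
            mean=mean, sd=sd, mu=mu, sigma2=sigma2,
            variance_explained=np.array(ve), n_iter=it, converged=converged,
            imputed=X_imputed, tol=self.tol,
        )


@dataclass
class BayesianPCAResults:
    columns: list
    index: list
    weights: np.ndarray  # p x k principal axes (standardised scale)
    scores: np.ndarray  # n x k posterior-mean factor values
    mean: np.ndarray
    sd: np.ndarray
    mu: np.ndarray
    sigma2: float
    variance_explained: np.ndarray
    n_iter: int
    converged: bool
    imputed: np.ndarray
    tol: float

    @property
    def loadings(self) -> pd.DataFrame:
        u = self.weights / np.maximum(np.linalg.norm(self.weights, axis=0), 1e-300)
        return pd.DataFrame(u, index=self.columns,
                            columns=[f"pc{m + 1}" for m in range(u.shape[1])])

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.index,
                            columns=[f"pc{m + 1}" for m in range(self.scores.shape[1])])

    def summary(self) -> pd.DataFrame:
        out = self.loadings.copy()
        out.loc["variance_explained"] = self.variance_explained
        return out


@dataclass
class GlobalFactor:
    """First principal axis of task-level metrics in one recovery phase."""

    phase: str
    metric_family: str
    loadings: pd.Series  # per task
    scores: pd.Series  # per participant (G)
    variance_explained: float
    n_components_retained: int
    tol: float
    n_iter: int
    converged: bool
    n_participants: int = 0
    dropped_tasks: list = field(default_factory=list)


def assemble_phase_matrix(metrics: pd.DataFrame, participants: pd.DataFrame,
                          phase: str, value_col: str) -> pd.DataFrame:
    """Participant x task matrix for one recovery phase.

    Uses one session per participant: if several of a participant's sessions
    fall in the phase, the one closest to the phase's median day is taken.
    """
    meta = participants[["participant_id", "session_index", "phase",
                         "days_since_stroke"]]
    df = metrics.merge(meta, on=["participant_id", "session_index"], how="inner")
    df = df.loc[df["phase"] == phase]
    if len(df) == 0:
        return pd.DataFrame()
    med = df["days_since_stroke"].median()
    df = df.assign(_dist=(df["days_since_stroke"] - med).abs())
    best = (df.sort_values(["participant_id", "_dist", "session_index"])
              .drop_duplicates(["participant_id", "task_id"], keep="first"))
    return best.pivot(index="participant_id", columns="task_id", values=value_col)


def extract_g(metrics: pd.DataFrame, participants: pd.DataFrame, phase: str,
              value_col: str, metric_family: str | None = None,
              tol: float = 1e-4, min_rows: int = 10) -> GlobalFactor:
    """Global factor G for one metric family and recovery phase."""
    mat = assemble_phase_matrix(metrics, participants, phase, value_col)
    if len(mat) < min_rows:
        raise ValueError(
            f"phase {phase!r}: only {len(mat)} participants; "
            f"refusing to extract an unstable factor (need >= {min_rows})")
    dropped = [c for c in mat.columns if mat[c].notna().sum() < 2]
    if dropped:
        logger.info("phase %s: dropping task(s) with <2 observations: %s", phase, dropped)
        mat = mat.drop(columns=dropped)
    res = BayesianPCA(mat, n_components=1, tol=tol).fit()
    return GlobalFactor(
        phase=phase,
        metric_family=metric_family or value_col,
        loadings=res.loadings["pc1"],
        scores=res.scores_frame()["pc1"],
        variance_explained=float(res.variance_explained[0]),
        n_components_retained=1,
        tol=tol,
        n_iter=res.n_iter,
        converged=res.converged,
        n_participants=len(mat),
        dropped_tasks=dropped,
    )
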