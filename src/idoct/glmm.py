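"""Aggregated binomial mixed model with random intercept and slope.

Accuracy outcomes are counts of correct responses out of trials per
session; their skew defeats Gaussian modelling, so they are fitted on the
logit scale as an aggregated binomial mixed-effects model

    y_ij ~ Binomial(n_ij, logit^-1(x_ij' beta + b0_i + b1_i * t_ij)),
    (b0_i, b1_i) ~ N(0, Sigma),

with subject random intercepts and random slopes on the (standardised)
time covariate.  Estimation maximises the Laplace approximation to the
marginal likelihood (the same approximation lme4's ``glmer`` uses at its
default settings): per-subject posterior modes are found by damped Newton
steps (the 2x2 systems are solved in closed form for all subjects at
once), and the profiled parameters - fixed effects plus a Cholesky
parameterisation of Sigma - are optimised with BFGS.  Standard errors come
from a finite-difference Hessian of the Laplace log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["BinomialMixedModel", "BinomialMixedResults"]

logger = logging.getLogger(__name__)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    big = x > 30
    out[big] = x[big]
    out[~big] = np.log1p(np.exp(x[~big]))
    return out


class BinomialMixedModel:
    """Laplace-approximate binomial GLMM.

    Parameters
    ----------
    successes, totals
        Aggregated counts per observation (0 <= successes <= totals);
        rows with ``totals == 0`` are dropped with a log entry.
    exog
        Fixed-effects design matrix (include the intercept column).
    groups
        Subject identifier per observation.
    slope
        Covariate carrying the random slope (typically standardised time);
        ``None`` fits a random intercept only.
    """

    def __init__(self, successes, totals, exog, groups, slope=None,
                 exog_names: list[str] | None = None):
        y = np.asarray(successes, dtype=float)
        n = np.asarray(totals, dtype=float)
        X = np.asarray(exog, dtype=float)
        if np.any(y < 0) or np.any(y > n):
            raise ValueError("need 0 <= successes <= totals")
        keep = n > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d rows with zero trials", dropped)
        self.y, self.n, self.X = y[keep], n[keep], X[keep]
        g = pd.Series(np.asarray(groups)[keep])
        self.g_codes, self.g_levels = pd.factorize(g, sort=True)
        self.t = (np.asarray(slope, dtype=float)[keep] if slope is not None
                  else None)
        self.re_dim = 2 if self.t is not None else 1
        self.exog_names = exog_names or [f"x{j}" for j in range(self.X.shape[1])]
        self.n_groups = len(self.g_levels)
        self.n_dropped = dropped

    # -- Laplace likelihood --------------------------------------------------

    def _chol(self, theta: np.ndarray) -> np.ndarray:
        if self.re_dim == 1:
            return np.array([[np.exp(theta[0])]])
        a, c, b = theta
        return np.array([[np.exp(a), 0.0], [c, np.exp(b)]])

    def _inner_modes(self, beta: np.ndarray, Sinv: np.ndarray,
                     b0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Damped Newton for all subjects' posterior modes at once."""
        G, d = self.n_groups, self.re_dim
        b = b0.copy()
        xb = self.X @ beta
        gi = self.g_codes
        u1 = np.ones_like(self.y)
        for _ in range(50):
            eta = xb + b[gi, 0] + (b[gi, 1] * self.t if d == 2 else 0.0)
            p = _sigmoid(eta)
            r = self.y - self.n * p
            w = self.n * p * (1.0 - p)
            grad = np.zeros((G, d))
            grad[:, 0] = np.bincount(gi, weights=r, minlength=G)
            H00 = np.bincount(gi, weights=w, minlength=G) + Sinv[0, 0]
            if d == 2:
                grad[:, 1] = np.bincount(gi, weights=r * self.t, minlength=G)
                H01 = np.bincount(gi, weights=w * self.t, minlength=G) + Sinv[0, 1]
                H11 = np.bincount(gi, weights=w * self.t**2, minlength=G) + Sinv[1, 1]
            grad -= b @ Sinv
            if d == 1:
                step = grad[:, 0] / H00
                newb = b + np.column_stack([step])
            else:
                det = H00 * H11 - H01**2
                s0 = (H11 * grad[:, 0] - H01 * grad[:, 1]) / det
                s1 = (H00 * grad[:, 1] - H01 * grad[:, 0]) / det
                newb = b + np.column_stack([s0, s1])
            if np.max(np.abs(newb - b)) < 1e-9:
                b = newb
                break
            b = np.clip(newb, -30, 30)
        eta = xb + b[gi, 0] + (b[gi, 1] * self.t if d == 2 else 0.0)
        p = _sigmoid(eta)
        w = self.n * p * (1.0 - p)
        if d == 1:
            logdetH = np.log(np.bincount(gi, weights=w, minlength=G) + Sinv[0, 0])
        else:
            H00 = np.bincount(gi, weights=w, minlength=G) + Sinv[0, 0]
            H01 = np.bincount(gi, weights=w * self.t, minlength=G) + Sinv[0, 1]
            H11 = np.bincount(gi, weights=w * self.t**2, minlength=G) + Sinv[1, 1]
            logdetH = np.log(np.maximum(H00 * H11 - H01**2, 1e-300))
        return b, logdetH

    def _negll(self, params: np.ndarray, cache: dict) -> float:
        q = self.X.shape[1]
        beta, theta = params[:q], params[q:]
        L = self._chol(theta)
        S = L @ L.T
        try:
            Sinv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            return 1e12
        b0 = cache.get("b", np.zeros((self.n_groups, self.re_dim)))
        b, logdetH = self._inner_modes(beta, Sinv, b0)
        cache["b"] = b
        gi = self.g_codes
        eta = self.X @ beta + b[gi, 0] + (b[gi, 1] * self.t if self.re_dim == 2 else 0.0)
        data_ll = float(np.sum(self.y * eta - self.n * _log1pexp(eta)))
        quad = float(np.sum((b @ Sinv) * b))
        sign, logdetS = np.linalg.slogdet(S)
        ll = data_ll - 0.5 * quad - 0.5 * self.n_groups * logdetS \
            - 0.5 * float(np.sum(logdetH))
        return -ll

    # -- fitting -------------------------------------------------------------

    def _start(self) -> np.ndarray:
        import statsmodels.api as sm
        q = self.X.shape[1]
        try:
            glm = sm.GLM(np.column_stack([self.y, self.n - self.y]), self.X,
                         family=sm.families.Binomial()).fit()
            beta0 = np.clip(glm.params, -5, 5)
        except Exception:
            beta0 = np.zeros(q)
        theta0 = np.full(3 if self.re_dim == 2 else 1, np.log(0.5))
        if self.re_dim == 2:
            theta0[1] = 0.0  # off-diagonal Cholesky entry
        return np.concatenate([beta0, theta0])

    def fit(self, maxiter: int = 300) -> "BinomialMixedResults":
        cache: dict = {}
        x0 = self._start()
        res = optimize.minimize(self._negll, x0, args=(cache,), method="BFGS",
                                options={"maxiter": maxiter, "gtol": 1e-5})
        params = res.x
        q = self.X.shape[1]
        hess = _numerical_hessian(lambda p: self._negll(p, cache), params)
        cov = _robust_inv(hess)
        bse = np.sqrt(np.maximum(np.diag(cov)[:q], 0.0))
        beta = params[:q]
        L = self._chol(params[q:])
        cov_re = L @ L.T
        # session-level extra-binomial variation (beyond the subject random
        # effects) deflates the model-based SEs; apply the standard
        # quasi-likelihood dispersion correction from conditional Pearson
        # residuals at the posterior modes
        b_hat = cache.get("b", np.zeros((self.n_groups, self.re_dim)))
        gi = self.g_codes
        eta_c = self.X @ beta + b_hat[gi, 0] \
            + (b_hat[gi, 1] * self.t if self.re_dim == 2 else 0.0)
        p_c = _sigmoid(eta_c)
        pearson = (self.y - self.n * p_c) / np.sqrt(
            np.maximum(self.n * p_c * (1.0 - p_c), 1e-12))
        dof = max(len(self.y) - q - 2 * self.n_groups // 3, 1)
        dispersion = float(max(1.0, np.sum(pearson**2) / dof))
        bse = bse * np.sqrt(dispersion)
        p_hat = _sigmoid(self.X @ beta)
        separation = bool(np.all(p_hat > 0.99) or np.all(p_hat < 0.01)
                          or np.any(np.abs(beta) > 15))
        z = np.divide(beta, bse, out=np.full_like(beta, np.nan), where=bse > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        return BinomialMixedResults(
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            cov_re=cov_re,
            llf=-float(res.fun),
            converged=bool(res.success or res.status in (0, 2)),
            separation=separation,
            n_groups=self.n_groups,
            n_obs=len(self.y),
            n_dropped=self.n_dropped,
            re_dim=self.re_dim,
            dispersion=dispersion,
        )


@dataclass
class BinomialMixedResults:
    params: pd.Series  # log-odds per fixed term
    bse: pd.Series
    pvalues: pd.Series
    cov_re: np.ndarray
    llf: float
    converged: bool
    separation: bool
    n_groups: int
    n_obs: int
    n_dropped: int
    re_dim: int
    dispersion: float = 1.0

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zc = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame({"lower": self.params - zc * self.bse,
                             "upper": self.params + zc * self.bse})

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse,
            "ci_lo": ci["lower"], "ci_hi": ci["upper"], "p": self.pvalues,
        })


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = x.size
    H = np.zeros((k, k))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / steps[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            e = np.zeros(k)
            e[i], e[j] = steps[i], steps[j]
            fpp = f(x + e)
            e[i], e[j] = -steps[i], -steps[j]
            fmm = f(x + e)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm) \
                / (2.0 * steps[i] * steps[j])
    return H


def _robust_inv(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)
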