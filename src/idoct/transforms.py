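"""Yeo-Johnson power transformation for model outcomes.

Outcome distributions from bounded scores (Cognitive Index, accuracy-style
metrics) and latencies are typically skewed; the Yeo-Johnson transform maps
them closer to normality before Gaussian mixed modelling.  Forward
evaluation and maximum-likelihood lambda come from scipy; the analytic
inverse is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["yeo_johnson", "yeo_johnson_inverse", "TransformFit", "fit_transform"]


def yeo_johnson(x, lam: float) -> np.ndarray:
    """Four-branch Yeo-Johnson transform, defined for all real x.

    lam = 1 is the identity on the nonnegative branch; lam = 0 maps
    x >= 0 to log(1 + x); negative x uses the reflected power with
    exponent 2 - lam.  Branches are evaluated with expm1/log1p forms, so
    the transform is numerically continuous in lam through 0 and 2.
    """
    x = np.asarray(x, dtype=float)
    lam = float(lam)
    y = np.empty_like(x)
    pos = x >= 0
    if abs(lam) < 1e-289:  # denormal lam underflows the expm1 form
        y[pos] = np.log1p(x[pos])
    else:
        y[pos] = np.expm1(lam * np.log1p(x[pos])) / lam
    if abs(lam - 2.0) < 1e-289:
        y[~pos] = -np.log1p(-x[~pos])
    else:
        y[~pos] = -np.expm1((2.0 - lam) * np.log1p(-x[~pos])) / (2.0 - lam)
    return y


def yeo_johnson_inverse(y, lam: float) -> np.ndarray:
    """Exact inverse of :func:`yeo_johnson` (stable through lam = 0 and 2)."""
    y = np.asarray(y, dtype=float)
    lam = float(lam)
    x = np.empty_like(y)
    pos = y >= 0
    if abs(lam) < 1e-289:
        x[pos] = np.expm1(y[pos])
    else:
        x[pos] = np.expm1(np.log1p(y[pos] * lam) / lam)
    if abs(lam - 2.0) < 1e-289:
        x[~pos] = -np.expm1(-y[~pos])
    else:
        x[~pos] = -np.expm1(np.log1p(-(2.0 - lam) * y[~pos]) / (2.0 - lam))
    return x


@dataclass
class TransformFit:
    """Maximum-likelihood Yeo-Johnson fit with shape diagnostics."""

    lmbda: float
    skew_before: float
    skew_after: float
    kurtosis_before: float
    kurtosis_after: float

    def transform(self, x) -> np.ndarray:
        return yeo_johnson(x, self.lmbda)

    def inverse(self, y) -> np.ndarray:
        return yeo_johnson_inverse(y, self.lmbda)


def fit_transform(x) -> TransformFit:
    """Fit lambda by profile Gaussian maximum likelihood.

    Requires at least 10 finite values; refuses constant input (the
    likelihood carries no information about lambda).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite values to fit the transform")
    if np.ptp(x) == 0:
        raise ValueError("constant input: transform parameter is not identifiable")
    xt, lam = stats.yeojohnson(x)
    return TransformFit(
        lmbda=float(lam),
        skew_before=float(stats.skew(x)),
        skew_after=float(stats.skew(xt)),
        kurtosis_before=float(stats.kurtosis(x)),
        kurtosis_after=float(stats.kurtosis(xt)),
    )
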