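"""Mixed-effects regression machinery for task-level cognitive outcomes.

All patient-level models share one fixed-effects structure,

    outcome ~ Age + Age^2 + Gender + Education + EnglishProficiency
              + log(1 + NIHSS) + TimeSinceStroke [+ ImpairedHand]
              + (1 + TimeSinceStroke | Subject),

with subject random intercepts and random time slopes to absorb
heterogeneous recovery trajectories.  Gaussian outcomes (Cognitive Index,
Response Delay Time, median RT) are Yeo-Johnson transformed and
standardised, so estimates are standardised betas; accuracy counts are
fitted as an aggregated binomial mixed model, giving standardised
log-odds.  Continuous covariates are z-scored on the analysis table;
NIHSS is log(1 + x)-transformed and never standardised; time since stroke
enters as z-scored log(1 + days).

The impaired-hand confound analysis fits all four outcome families per
task and controls the false discovery rate both within each task (the
four metrics) and across tasks per metric; a task-metric pair is deemed
confounded when the across-task q-value falls below alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .glmm import BinomialMixedModel
from .transforms import fit_transform
from .bpca import GlobalFactor

__all__ = [
    "bh_fdr",
    "ModelSpec",
    "RegressionResult",
    "prepare_covariates",
    "fit_lmm",
    "fit_binomial_glmm",
    "hand_impairment_analysis",
    "criterion_validity",
    "GAUSSIAN_METRICS",
]

logger = logging.getLogger(__name__)

GAUSSIAN_METRICS = ("cognitive_index", "delay_time", "median_rt")
ALL_METRICS = ("cognitive_index", "delay_time", "median_rt", "accuracy")


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, rejection mask)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class ModelSpec:
    """Declarative description of one model in the family."""

    outcome: str
    family: str = "gaussian"  # or "binomial"
    include_impaired_hand: bool = False
    random_slope: bool = True


@dataclass
class RegressionResult:
    """Standardised fixed-effect estimates with CIs, p and diagnostics."""

    outcome: str
    family: str
    terms: pd.DataFrame  # term, estimate, se, ci_lo, ci_hi, p
    resid_normality_p: float
    converged: bool
    random_structure: str
    n_obs: int
    n_subjects: int
    transform_lambda: float | None = None
    notes: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return self.terms.set_index("term")


# ---------------------------------------------------------------------------
# covariate preparation


def prepare_covariates(meta: pd.DataFrame) -> pd.DataFrame:
    """Standardise the shared covariates once, on the analysis table.

    ``meta`` needs one row per patient-session with age, sex, education,
    english_second_language, nihss_baseline, days_since_stroke,
    impaired_hand.
    """
    df = meta.copy()
    age_z = _zscore(df["age"])
    df["age_z"] = age_z
    df["age2_z"] = _zscore(age_z**2)
    df["gender_male"] = (df["sex"] == "male").astype(float)
    for lvl in (2, 3, 4):
        df[f"edu_{lvl}"] = (df["education"] == lvl).astype(float)
    df["esl"] = df["english_second_language"].astype(float)
    df["log_nihss"] = np.log1p(df["nihss_baseline"].astype(float))
    df["time_z"] = _zscore(np.log1p(df["days_since_stroke"].astype(float)))
    df["impaired"] = df["impaired_hand"].astype(float)
    return df


def _zscore(x: pd.Series) -> pd.Series:
    x = pd.Series(np.asarray(x, dtype=float), index=x.index if hasattr(x, "index") else None)
    sd = x.std(ddof=1)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


_BASE_TERMS = ["age_z", "age2_z", "gender_male", "edu_2", "edu_3", "edu_4",
               "esl", "log_nihss", "time_z"]


def _design(df: pd.DataFrame, include_impaired: bool) -> tuple[np.ndarray, list[str]]:
    names = ["intercept"] + _BASE_TERMS + (["impaired"] if include_impaired else [])
    X = np.column_stack([np.ones(len(df))] +
                        [df[c].to_numpy(dtype=float) for c in names[1:]])
    return X, names


def _wald_terms(names, est, se) -> pd.DataFrame:
    zc = stats.norm.ppf(0.975)
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    return pd.DataFrame({
        "term": names, "estimate": est, "se": se,
        "ci_lo": est - zc * se, "ci_hi": est + zc * se,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
    })


# ---------------------------------------------------------------------------
# model fits


def fit_lmm(data: pd.DataFrame, outcome: str,
            include_impaired_hand: bool = False,
            transform: bool = True) -> RegressionResult:
    """Gaussian linear mixed model on a (transformed, standardised) outcome.

    Random intercept and time slope by subject; if the random-slope fit is
    singular or fails to converge, the model falls back to a random
    intercept only and records the fallback.
    """
    df = data.dropna(subset=[outcome]).copy()
    y = df[outcome].to_numpy(dtype=float)
    lam = None
    notes: list[str] = []
    if transform:
        tf = fit_transform(y)
        y = tf.transform(y)
        lam = tf.lmbda
    y = (y - y.mean()) / (y.std(ddof=1) or 1.0)
    X, names = _design(df, include_impaired_hand)
    groups = df["participant_id"].to_numpy()

    def _try(re_formula_cols):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exog_re = np.column_stack([np.ones(len(df))] +
                                      [df[c].to_numpy(dtype=float)
                                       for c in re_formula_cols])
            mod = MixedLM(y, X, groups=groups, exog_re=exog_re)
            try:
                res = mod.fit(reml=True, method="lbfgs", maxiter=200)
            except np.linalg.LinAlgError:
                # lbfgs can step into a singular random-effects covariance;
                # the default optimizer is slower but recovers
                res = mod.fit(reml=True, maxiter=200)
        return res

    random_structure = "intercept+slope"
    try:
        res = _try(["time_z"])
        ev = np.linalg.eigvalsh(res.cov_re)
        singular = ev.min() < 1e-8 * max(ev.max(), 1e-12) or not res.converged
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        res = None
    if singular:
        notes.append("random-slope fit singular; refitted with random intercept only")
        random_structure = "intercept"
        res = _try([])

    k = len(names)
    terms = _wald_terms(names, res.fe_params[:k], res.bse[:k])
    resid = res.resid
    if len(resid) >= 8:
        sample = resid if len(resid) <= 4500 else pd.Series(resid).sample(
            4500, random_state=0).to_numpy()
        norm_p = float(stats.shapiro(sample).pvalue)
    else:
        norm_p = float("nan")
    return RegressionResult(
        outcome=outcome, family="gaussian", terms=terms,
        resid_normality_p=norm_p, converged=bool(res.converged),
        random_structure=random_structure, n_obs=len(df),
        n_subjects=df["participant_id"].nunique(),
        transform_lambda=lam, notes=notes,
    )


def fit_binomial_glmm(data: pd.DataFrame, successes: str, totals: str,
                      include_impaired_hand: bool = False) -> RegressionResult:
    """Aggregated binomial mixed model (Laplace); standardised log-odds."""
    df = data.dropna(subset=[successes, totals]).copy()
    df = df.loc[df[totals] > 0]
    X, names = _design(df, include_impaired_hand)
    notes: list[str] = []
    random_structure = "intercept+slope"
    mod = BinomialMixedModel(df[successes], df[totals], X,
                             groups=df["participant_id"],
                             slope=df["time_z"].to_numpy(dtype=float),
                             exog_names=names)
    res = mod.fit()
    slope_var = res.cov_re[1, 1] if res.re_dim == 2 else 0.0
    if not res.converged or (res.re_dim == 2 and slope_var < 1e-8):
        notes.append("random-slope fit degenerate; refitted with random intercept only")
        random_structure = "intercept"
        mod = BinomialMixedModel(df[successes], df[totals], X,
                                 groups=df["participant_id"], slope=None,
                                 exog_names=names)
        res = mod.fit()
    if res.separation:
        notes.append("possible separation: extreme fitted probabilities")
    terms = _wald_terms(names, res.params.to_numpy(), res.bse.to_numpy())
    return RegressionResult(
        outcome=successes, family="binomial", terms=terms,
        resid_normality_p=float("nan"), converged=res.converged,
        random_structure=random_structure, n_obs=res.n_obs,
        n_subjects=res.n_groups, notes=notes,
    )


# ---------------------------------------------------------------------------
# confound analysis


def hand_impairment_analysis(
    decomposition: pd.DataFrame,
    std_metrics: pd.DataFrame,
    participants: pd.DataFrame,
    alpha: float = 0.05,
    metrics: tuple[str, ...] = ALL_METRICS,
) -> tuple[pd.DataFrame, dict]:
    """Per-task, per-metric test of the impaired-hand term.

    Fits the full covariate model with ImpairedHand added, for the modelled
    metrics (Cognitive Index, Response Delay Time) and the standard metrics
    (accuracy counts - binomial; median RT - Gaussian).  Returns a tidy
    table with the impaired-hand estimate, p, q within the task's four
    tests, q across tasks per metric, and the confounded verdict
    (q_across_tasks < alpha), plus the dict of full model results.
    """
    meta = participants.loc[participants["cohort"] == "patient"]
    meta = prepare_covariates(meta)
    merged = decomposition.merge(std_metrics, on=["participant_id", "task_id",
                                                  "session_index"], how="outer")
    data = merged.merge(meta, on=["participant_id", "session_index"], how="inner")

    rows = []
    models: dict[tuple[str, str], RegressionResult] = {}
    for task_id, df in data.groupby("task_id", sort=True):
        for metric in metrics:
            try:
                if metric == "accuracy":
                    res = fit_binomial_glmm(df, "accuracy_count", "trial_count",
                                            include_impaired_hand=True)
                else:
                    if df[metric].notna().sum() == 0:
                        raise ValueError("metric absent")
                    res = fit_lmm(df, metric, include_impaired_hand=True)
            except ValueError as exc:
                logger.info("task %s metric %s skipped: %s", task_id, metric, exc)
                continue
            models[(task_id, metric)] = res
            t = res.terms.set_index("term").loc["impaired"]
            rows.append({
                "task_id": task_id, "metric": metric, "family": res.family,
                "estimate": t["estimate"], "se": t["se"],
                "ci_lo": t["ci_lo"], "ci_hi": t["ci_hi"], "p": t["p"],
            })
    table = pd.DataFrame(rows)
    if len(table) == 0:
        return table, models
    table["q_within_task"] = np.nan
    for task_id, idx in table.groupby("task_id").groups.items():
        q, _ = bh_fdr(table.loc[idx, "p"], alpha)
        table.loc[idx, "q_within_task"] = q
    table["q_across_tasks"] = np.nan
    for metric, idx in table.groupby("metric").groups.items():
        q, _ = bh_fdr(table.loc[idx, "p"], alpha)
        table.loc[idx, "q_across_tasks"] = q
    table["confounded"] = table["q_across_tasks"] < alpha
    return table, models


# ---------------------------------------------------------------------------
# criterion validity


def criterion_validity(
    gfactors: list[GlobalFactor],
    participants: pd.DataFrame,
    criterion: str = "moca",
    min_pairs: int = 10,
) -> pd.DataFrame:
    """OLS of a clinical criterion on the global factor G, per phase/family.

    p-values are deliberately uncorrected.  The criterion per participant
    and phase is the mean over that participant's sessions in the phase.
    """
    pat = participants.loc[participants["cohort"] == "patient"]
    rows = []
    for gf in gfactors:
        crit = (pat.loc[pat["phase"] == gf.phase]
                .groupby("participant_id")[criterion].mean())
        joined = pd.concat([gf.scores.rename("G"), crit.rename("crit")],
                           axis=1, join="inner").dropna()
        if len(joined) < min_pairs:
            logger.info("phase %s family %s: only %d matched pairs; skipped",
                        gf.phase, gf.metric_family, len(joined))
            continue
        X = sm.add_constant(joined["G"].to_numpy())
        fit = sm.OLS(joined["crit"].to_numpy(), X).fit()
        rows.append({
            "phase": gf.phase, "metric_family": gf.metric_family,
            "criterion": criterion, "n": len(joined),
            "r2": float(fit.rsquared), "slope": float(fit.params[1]),
            "p": float(fit.pvalues[1]),
        })
    return pd.DataFrame(rows)
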