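"""Simulation studies validating the pipeline against known ground truth.

These routines power the packaged benchmark checks: parameter recovery of
the decomposition, the impaired-hand confound pattern and its null
calibration, criterion-validity ordering, and frequentist calibration of
the mixed models and the CCA permutation test.  They are consumed by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort, model, regression
from .cca import CCA
from .pipeline import PipelineConfig, run_pipeline

__all__ = [
    "benchmark_run",
    "dt_recovery",
    "difficulty_recovery",
    "null_confound_rate",
    "lmm_type1_error",
    "cca_null_pvalues",
]

logger = logging.getLogger(__name__)


def benchmark_run(seed: int = 1, n_normative: int = 400, n_patient: int = 200,
                  cca_n_perm: int = 999, **overrides):
    """The packaged synthetic benchmark, end to end."""
    cfg = PipelineConfig(seed=seed, n_normative=n_normative,
                         n_patient=n_patient, cca_n_perm=cca_n_perm,
                         **overrides)
    return run_pipeline(cfg)


def dt_recovery(outputs, tasks=None) -> tuple[float, int]:
    """Pearson r between estimated delay time and the true motor delay.

    Estimated delays are averaged over sessions within participant-task;
    the truth is the participant's effective delay for that task (baseline
    plus the impairment addition, boosted in high-motor-demand tasks).
    """
    registry = tasks or cohort.default_task_registry()
    truth_cols = ["participant_id", "latent_motor_delay", "impair_delay_extra"]
    truth = (outputs.participants.loc[outputs.participants["cohort"] == "patient",
                                      truth_cols]
             .drop_duplicates("participant_id").set_index("participant_id"))
    gen = outputs.config.generator_config()
    est = (outputs.decomposition.dropna(subset=["delay_time"])
           .groupby(["participant_id", "task_id"])["delay_time"].mean())
    rows = []
    for task in registry:
        sub = est.xs(task.task_id, level="task_id")
        t = truth.loc[truth.index.intersection(sub.index)]
        boost = 1.0 + gen.motor_boost * (task.motor_demand == "high")
        true_delay = t["latent_motor_delay"] + t["impair_delay_extra"] * boost
        rows.append(pd.DataFrame({"est": sub.loc[t.index], "true": true_delay}))
    joined = pd.concat(rows).dropna()
    r = float(np.corrcoef(joined["est"], joined["true"])[0, 1])
    return r, len(joined)


def difficulty_recovery(outputs, tasks=None) -> pd.DataFrame:
    """Per-task Spearman rho between scaled difficulty and the true
    condition difficulties of the generator."""
    registry = tasks or cohort.default_task_registry()
    rows = []
    for task in registry:
        table = outputs.calibration.tables.get(task.task_id)
        if table is None:
            continue
        est = [table.d_scaled[c] for c in task.condition_labels]
        rho = stats.spearmanr(est, task.condition_difficulties).statistic
        rows.append({"task_id": task.task_id, "spearman_rho": float(rho),
                     "n_conditions": task.n_conditions})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# null calibration of the confound analysis


def null_confound_rate(n_replicates: int = 50, seed: int = 1,
                       n_normative: int = 250, n_patient: int = 110,
                       task_ids: tuple[str, ...] = ("motor_control",
                                                    "trail_making",
                                                    "semantic_judgement"),
                       ) -> tuple[float, int]:
    """Fraction of confounded verdicts under the no-motor-effect generator.

    The normative calibration is computed once (the null switch only
    affects patients); each replicate draws a fresh patient cohort with no
    impairment-related delay or slips, so every impaired-hand test is null.
    Returns (verdict rate, number of verdicts).
    """
    registry = [t for t in cohort.default_task_registry() if t.task_id in task_ids]
    gen = cohort.GeneratorConfig().null_motor()
    windows = {t.task_id: t.response_window for t in registry}

    norm = cohort.generate_participants(n_normative, 0, seed, gen)
    norm_trials = cohort.generate_cohort_trials(norm, registry, seed, gen)
    norm_trials, _ = model.clean_trials(norm_trials, rt_max=windows)
    calib = model.IDoCTModel(norm_trials).fit()

    n_confounded = 0
    n_tests = 0
    for rep in range(n_replicates):
        rep_seed = (seed + 1000 * (rep + 1)) % (2**31)
        pats = cohort.generate_participants(0, n_patient, rep_seed, gen)
        trials = cohort.generate_cohort_trials(pats, registry, rep_seed, gen)
        trials, _ = model.clean_trials(trials, rt_max=windows)
        decomp = calib.decompose(trials)
        std = model.standard_metrics(trials)
        public = pats.drop(columns=list(cohort.LATENT_COLUMNS))
        table, _ = regression.hand_impairment_analysis(decomp, std, public)
        n_confounded += int(table["confounded"].sum())
        n_tests += len(table)
    return n_confounded / max(n_tests, 1), n_tests


# ---------------------------------------------------------------------------
# mixed-model type-I calibration


def lmm_type1_error(n_replicates: int = 150, seed: int = 11,
                    n_subjects: int = 250, n_sessions: int = 3,
                    alpha: float = 0.05) -> tuple[float, int]:
    """Rejection rate of null fixed effects in the Gaussian mixed model.

    Covariates are drawn with the cohort's structure but the outcome is
    pure noise plus subject random intercepts and slopes, so every
    non-intercept term is null; rejections are pooled over terms.
    """
    rng = np.random.default_rng(seed)
    n_reject = 0
    n_tests = 0
    for _ in range(n_replicates):
        df = _null_longitudinal(rng, n_subjects, n_sessions)
        res = regression.fit_lmm(df, "y", include_impaired_hand=True)
        pvals = res.terms.loc[res.terms["term"] != "intercept", "p"]
        n_reject += int((pvals < alpha).sum())
        n_tests += len(pvals)
    return n_reject / n_tests, n_tests


def _null_longitudinal(rng: np.random.Generator, n_subjects: int,
                       n_sessions: int) -> pd.DataFrame:
    age = rng.normal(63.0, 14.0, n_subjects)
    sex = np.where(rng.random(n_subjects) < 0.7, "male", "female")
    edu = rng.choice([1, 2, 3, 4], size=n_subjects, p=(0.1, 0.5, 0.22, 0.18))
    esl = (rng.random(n_subjects) < 0.35).astype(int)
    nihss = np.clip(np.round(rng.gamma(1.1, 4.4, n_subjects)), 0, 26)
    imp = (rng.random(n_subjects) < 0.275).astype(int)
    days = np.stack([np.clip(np.round(4 * np.exp(rng.normal(0, .6, n_subjects))), 1, 14),
                     np.clip(np.round(rng.normal(94, 9, n_subjects)), 15, 180),
                     np.clip(np.round(rng.normal(371, 110, n_subjects)), 181, 730)],
                    axis=1)[:, :n_sessions]
    u0 = rng.normal(0.0, 0.6, n_subjects)
    u1 = rng.normal(0.0, 0.15, n_subjects)
    rows = []
    for s in range(n_sessions):
        t = np.log1p(days[:, s])
        y = u0 + u1 * (t - t.mean()) + rng.normal(0.0, 1.0, n_subjects)
        rows.append(pd.DataFrame({
            "participant_id": [f"s{i}" for i in range(n_subjects)],
            "age": age, "sex": sex, "education": edu,
            "english_second_language": esl, "nihss_baseline": nihss,
            "days_since_stroke": days[:, s], "impaired_hand": imp, "y": y,
        }))
    df = pd.concat(rows, ignore_index=True)
    return regression.prepare_covariates(df)


# ---------------------------------------------------------------------------
# CCA permutation calibration


def cca_null_pvalues(n_replicates: int = 50, seed: int = 19, n: int = 120,
                     p: int = 6, q: int = 2, n_perm: int = 199) -> np.ndarray:
    """First-mode permutation p-values for independent Gaussian blocks."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_replicates)
    for i in range(n_replicates):
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, q))
        mod = CCA(X, Y)
        pv = mod.permutation_test(n_perm=n_perm, seed=int(rng.integers(2**31)))
        out[i] = pv[0]
    return out
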