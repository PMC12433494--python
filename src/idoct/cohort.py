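"""Synthetic normative and patient cohorts for trial-level cognitive task data.

This module simulates the kind of data produced by a self-administered
digital cognitive battery taken by a large neurologically-healthy
("normative") cohort and a smaller longitudinal stroke ("patient") cohort.
Each simulated participant carries a latent cognitive ability and a latent
motor response delay; trials are generated from an item-response accuracy
model plus an additive reaction-time decomposition

    rt = motor_delay + answer_time(condition, ability) + positive noise,

so that every downstream estimation stage can be validated against known
ground truth.  Latent columns live in a separate ``truth`` table and are
never consumed by estimation code.

Key generative assumptions (all parameters in :class:`GeneratorConfig`):

* accuracy ~ Bernoulli(sigmoid(alpha * (ability + caution - difficulty)));
  a latent response-caution trait trades accuracy against answer speed
  (the speed-accuracy trade-off that makes accuracy alone overstate
  ability in cautious responders);
* answer time splits into an encoding component and a
  difficulty-dependent operation component; ability speeds up, and
  caution slows down, the operation component only (person-mean RT spread
  of cognitive origin stays modest relative to motor-delay spread);
* hand-motor impairment adds delay (larger in high-motor-demand tasks) and
  can flip correct responses ("slips", mis-taps) only in high-motor tasks;
* reaction times exceeding the response window are recorded as timeouts
  (accuracy 0, rt clamped to the window);
* cognitive recovery follows a subject-specific random slope on
  log(1 + days since stroke);
* criterion scores (MoCA-like, IADL-like) are noisy increasing functions of
  latent ability; imaging burden (lesion volume, white-matter
  hyperintensity volume) are noisy decreasing functions of it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskSpec",
    "GeneratorConfig",
    "default_task_registry",
    "derive_phase",
    "generate_participants",
    "generate_trials",
    "generate_cohort_trials",
    "effective_motor_delay",
    "write_cohort",
    "read_cohort",
    "benchmark_cohort",
    "PHASES",
    "LATENT_COLUMNS",
]

PHASES = ("acute", "subacute", "chronic")

#: columns that hold simulation ground truth and must never reach estimators
LATENT_COLUMNS = (
    "latent_ability",
    "latent_motor_delay",
    "latent_caution",
    "impair_delay_extra",
    "wmh_domain_deficit",
)

# cognitive domains whose chronic-phase performance is additionally coupled
# to white-matter burden in the generator
WMH_SENSITIVE_DOMAINS = frozenset({"attention", "speed", "memory"})


@dataclass(frozen=True)
class TaskSpec:
    """Design parameters of one task in the battery."""

    task_id: str
    domain: str
    motor_demand: str  # {"low", "high"}
    cognitive_demand: str  # {"low", "high"}
    condition_difficulties: tuple[float, ...]
    trials_per_condition: int = 5
    response_window: float = 2000.0  # ms
    base_answer_time: float = 700.0  # ms
    difficulty_rt_slope: float = 0.3
    slip_rate_impaired: float = 0.0  # mis-tap recorded as a wrong answer
    fumble_rate_impaired: float = 0.0  # mis-tap registering no response (timeout)
    early_stop_failures: int | None = None  # task ends after this many consecutive failures

    def __post_init__(self) -> None:
        b = np.asarray(self.condition_difficulties, dtype=float)
        if b.size < 1:
            raise ValueError(f"task {self.task_id}: needs at least one condition")
        if b.size > 1 and not np.all(np.diff(b) > 0):
            raise ValueError(
                f"task {self.task_id}: condition difficulties must be strictly increasing"
            )
        if self.motor_demand not in ("low", "high"):
            raise ValueError(f"task {self.task_id}: bad motor_demand")
        if self.cognitive_demand not in ("low", "high"):
            raise ValueError(f"task {self.task_id}: bad cognitive_demand")
        for rate in (self.slip_rate_impaired, self.fumble_rate_impaired):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"task {self.task_id}: slip/fumble rate not a probability")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_difficulties)

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.trials_per_condition

    @property
    def condition_labels(self) -> list[str]:
        return [f"c{i + 1:02d}" for i in range(self.n_conditions)]


def _ceiling_difficulties() -> tuple[float, ...]:
    return tuple(np.round(np.linspace(-3.8, -1.6, 8), 4))


def _graded_difficulties() -> tuple[float, ...]:
    return tuple(np.round(np.linspace(-1.6, 1.9, 8), 4))


def default_task_registry() -> list[TaskSpec]:
    """The 18-task battery used throughout the package.

    Tasks are tagged by motor and cognitive demand; ``motor_control`` is the
    designated pure-motor task (tap-precision is what it scores, so impaired
    hand function legitimately lowers its accuracy).
    """

    hi = _graded_difficulties()
    lo = _ceiling_difficulties()
    # visuomotor tasks: cognitively demanding (long, graded operation times)
    # but with near-ceiling accuracy, as in real trail/cancellation/copying
    # designs where failures are slow or missed responses, not wrong ones
    vm = tuple(np.round(np.linspace(-3.0, -0.4, 8), 4))
    t = TaskSpec
    return [
        # task_id, domain, motor, cognitive
        t("motor_control", "motor", "high", "low", tuple(np.round(np.linspace(-4.2, -2.4, 8), 4)),
          base_answer_time=500.0, difficulty_rt_slope=0.08, response_window=2300.0,
          slip_rate_impaired=0.18, fumble_rate_impaired=0.22),
        t("simple_reaction", "speed", "low", "low", lo,
          base_answer_time=380.0, difficulty_rt_slope=0.08, response_window=1800.0),
        t("choice_reaction", "speed", "high", "low", lo,
          base_answer_time=450.0, difficulty_rt_slope=0.08, response_window=2300.0,
          fumble_rate_impaired=0.22),
        t("symbol_matching", "speed", "high", "low", lo,
          base_answer_time=500.0, difficulty_rt_slope=0.08, response_window=2300.0,
          fumble_rate_impaired=0.22),
        t("number_comparison", "numeracy", "low", "low", lo,
          base_answer_time=450.0, difficulty_rt_slope=0.08, response_window=1900.0),
        t("orientation", "memory", "low", "low", lo,
          base_answer_time=500.0, difficulty_rt_slope=0.08, response_window=1900.0),
        t("trail_making", "executive", "high", "high", vm,
          base_answer_time=800.0, response_window=2800.0, fumble_rate_impaired=0.22),
        t("spatial_span", "memory", "high", "high", vm,
          base_answer_time=750.0, response_window=2700.0, fumble_rate_impaired=0.22),
        t("target_cancellation", "attention", "high", "high", vm,
          base_answer_time=650.0, response_window=2600.0, fumble_rate_impaired=0.22),
        t("figure_copying", "praxis", "high", "high", vm,
          base_answer_time=800.0, response_window=2800.0, fumble_rate_impaired=0.22),
        t("semantic_judgement", "language", "low", "high", hi,
          base_answer_time=850.0, response_window=2400.0),
        t("word_recognition", "memory", "low", "high", hi,
          base_answer_time=700.0, response_window=2300.0),
        t("digit_span", "memory", "low", "high", hi,
          base_answer_time=700.0, response_window=2300.0),
        t("paired_associates", "memory", "low", "high", hi,
          base_answer_time=750.0, response_window=2300.0),
        t("sustained_attention", "attention", "low", "high", hi,
          base_answer_time=600.0, response_window=2200.0),
        t("mental_rotation", "executive", "low", "high", hi,
          base_answer_time=900.0, response_window=2500.0),
        t("arithmetic", "numeracy", "low", "high", hi,
          base_answer_time=850.0, response_window=2400.0),
        t("verbal_analogy", "language", "low", "high", hi,
          base_answer_time=800.0, response_window=2400.0),
    ]


@dataclass
class GeneratorConfig:
    """All distributional parameters of the cohort simulator.

    Demographic and clinical marginals are anchored to a large normative
    cohort (N ~ 6.4k, age 60.8 +/- 10.1) and a stroke cohort (N = 171, age
    63.01 +/- 14.1, NIHSS 4.93 +/- 4.66 range 0-26, impaired responding
    hand in 47/171) assessed at ~4, ~94 and ~371 days post-stroke.
    """

    # demographics: (mean, sd, low, high)
    age_normative: tuple[float, float, float, float] = (60.8, 10.1, 40.0, 95.0)
    age_patient: tuple[float, float, float, float] = (63.01, 14.1, 24.0, 97.0)
    male_prob_normative: float = 0.427
    male_prob_patient: float = 0.696
    education_probs_normative: tuple[float, ...] = (0.155, 0.372, 0.288, 0.185)
    education_probs_patient: tuple[float, ...] = (0.082, 0.503, 0.228, 0.187)
    esl_prob_normative: float = 0.036
    esl_prob_patient: float = 0.345

    # stroke-specific
    nihss_mean: float = 4.93
    nihss_sd: float = 4.66
    nihss_max: int = 26
    impairment_rate: float = 47.0 / 171.0
    session_attendance: tuple[float, float, float] = (132 / 171, 72 / 171, 131 / 171)
    imaging_rate: float = 78.0 / 171.0

    # latent cognitive ability (unitless, ~N(0,1) scale)
    beta_age: float = -0.35
    beta_age2: float = -0.05
    beta_education: float = 0.22  # per ordinal step, centred at 2.5
    beta_esl: float = -0.18
    beta_nihss: float = -0.28  # on log(1 + NIHSS)
    ability_sd: float = 0.55
    recovery_slope: float = 0.10  # per unit log(1 + days), shared
    recovery_slope_sd: float = 0.04  # subject-specific random slope

    # latent motor delay (ms)
    delay_median: float = 300.0
    delay_sigma: float = 0.5  # lognormal shape of the baseline delay
    impair_delay_mean: float = 200.0  # added by impairment (low-motor task)
    impair_delay_sigma: float = 0.45  # lognormal spread of impairment severity
    motor_boost: float = 1.2  # extra fraction in high-motor-demand tasks

    # trial model
    accuracy_discrimination: float = 1.5  # alpha in the item-response model
    caution_sd: float = 1.0  # latent response-caution trait
    caution_accuracy_weight: float = 0.1  # logit boost per caution SD
    caution_rt_slope: float = 0.05  # operation time scales with exp(+slope*caution)
    rt_ability_slope_high_cog: float = 0.12  # operation time ~ exp(-eta*ability)
    rt_ability_slope_low_cog: float = 0.05
    rt_encoding_fraction: float = 0.45  # share of base AT that is fixed encoding time
    session_jitter_sd: float = 0.15  # task-session level ability fluctuation
    rt_noise_median: float = 180.0  # ms, lognormal additive noise
    rt_noise_sigma: float = 0.75
    disable_slips: bool = False  # null-generator switch (with impair_delay_mean=0)

    # criterion and imaging variables
    moca_intercept: float = 23.0
    moca_slope: float = 2.0
    moca_noise_sd: float = 0.6
    iadl_intercept: float = 6.0
    iadl_slope: float = 0.8
    iadl_noise_sd: float = 0.9
    lesion_intercept: float = 2.2  # on log mL
    lesion_ability_slope: float = -0.8
    lesion_noise_sd: float = 0.5
    wmh_intercept: float = 1.8
    wmh_ability_slope: float = -0.6
    wmh_noise_sd: float = 0.45
    wmh_domain_effect: float = 0.30  # chronic extra deficit on wmh-sensitive domains

    # session structure
    days_acute: tuple[float, float] = (4.0, 0.6)  # lognormal (median, sigma)
    days_subacute: tuple[float, float] = (94.0, 9.0)  # normal (mean, sd)
    days_chronic: tuple[float, float] = (371.0, 110.0)  # normal (mean, sd)
    task_missing_rate: float = 0.08

    def validate(self) -> None:
        probs = [
            self.male_prob_normative, self.male_prob_patient,
            self.esl_prob_normative, self.esl_prob_patient,
            self.impairment_rate, self.imaging_rate, self.task_missing_rate,
            *self.session_attendance,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("generator config: probabilities must lie in [0, 1]")
        for probs_edu in (self.education_probs_normative, self.education_probs_patient):
            if abs(sum(probs_edu) - 1.0) > 1e-6:
                raise ValueError("generator config: education probabilities must sum to 1")

    def null_motor(self) -> "GeneratorConfig":
        """A copy with no motor-impairment effect (null generator)."""
        return replace(self, impair_delay_mean=0.0, disable_slips=True)


def derive_phase(days: float) -> str:
    """Map days since stroke to recovery phase (acute <= 14 < subacute <= 180 < chronic)."""
    if pd.isna(days):
        return ""
    if days <= 14:
        return "acute"
    if days <= 180:
        return "subacute"
    return "chronic"


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, size: int) -> np.ndarray:
    x = rng.normal(mean, sd, size)
    bad = (x < low) | (x > high)
    while bad.any():
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (x < low) | (x > high)
    return x


def _nihss(rng: np.random.Generator, cfg: GeneratorConfig, size: int) -> np.ndarray:
    # gamma matched to the target mean/sd, rounded and clipped to [0, max]
    shape = (cfg.nihss_mean / cfg.nihss_sd) ** 2
    scale = cfg.nihss_sd**2 / cfg.nihss_mean
    return np.clip(np.round(rng.gamma(shape, scale, size)), 0, cfg.nihss_max).astype(int)


def generate_participants(
    n_normative: int,
    n_patient: int,
    seed: int,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Draw participant metadata and latent ground truth.

    Returns a long-format frame with one row per participant-session
    (normative participants have a single session with no stroke fields).
    Latent columns (``latent_*``, ``impair_delay_extra``,
    ``wmh_domain_deficit``) are ground truth for validation only;
    :func:`write_cohort` splits them into a separate ``truth.csv``.
    """

    cfg = config or GeneratorConfig()
    cfg.validate()
    if n_normative < 0 or n_patient < 0:
        raise ValueError("participant counts must be non-negative")
    rng = np.random.default_rng([int(seed), 101])
    frames = []

    if n_normative > 0:
        frames.append(_generate_normative(rng, cfg, n_normative))
    if n_patient > 0:
        frames.append(_generate_patients(rng, cfg, n_patient))
    if not frames:
        return _empty_participants()
    out = pd.concat(frames, ignore_index=True)
    return out


def _ability_demographics(cfg: GeneratorConfig, age_z: np.ndarray,
                          education: np.ndarray, esl: np.ndarray) -> np.ndarray:
    return (
        cfg.beta_age * age_z
        + cfg.beta_age2 * (age_z**2 - 1.0)
        + cfg.beta_education * (education - 2.5)
        + cfg.beta_esl * esl
    )


def _criteria_and_imaging(rng: np.random.Generator, cfg: GeneratorConfig,
                          theta: np.ndarray) -> dict[str, np.ndarray]:
    n = theta.shape[0]
    moca = cfg.moca_intercept + cfg.moca_slope * theta
    if cfg.moca_noise_sd > 0:
        moca = moca + rng.normal(0.0, cfg.moca_noise_sd, n)
    iadl = cfg.iadl_intercept + cfg.iadl_slope * theta
    if cfg.iadl_noise_sd > 0:
        iadl = iadl + rng.normal(0.0, cfg.iadl_noise_sd, n)
    lesion = np.exp(cfg.lesion_intercept + cfg.lesion_ability_slope * theta
                    + rng.normal(0.0, cfg.lesion_noise_sd, n))
    wmh = np.exp(cfg.wmh_intercept + cfg.wmh_ability_slope * theta
                 + rng.normal(0.0, cfg.wmh_noise_sd, n))
    return {
        "moca": np.clip(moca, 0.0, 30.0),
        "iadl": np.clip(iadl, 0.0, 8.0),
        "lesion_volume": lesion,
        "wmh_volume": wmh,
    }


def _generate_normative(rng: np.random.Generator, cfg: GeneratorConfig,
                        n: int) -> pd.DataFrame:
    mean, sd, lo, hi = cfg.age_normative
    age = _truncated_normal(rng, mean, sd, lo, hi, n)
    sex = np.where(rng.random(n) < cfg.male_prob_normative, "male", "female")
    education = rng.choice([1, 2, 3, 4], size=n, p=cfg.education_probs_normative)
    esl = (rng.random(n) < cfg.esl_prob_normative).astype(int)
    age_z = (age - mean) / sd
    theta = _ability_demographics(cfg, age_z, education, esl) \
        + rng.normal(0.0, cfg.ability_sd, n)
    caution = rng.normal(0.0, cfg.caution_sd, n)
    delay = cfg.delay_median * np.exp(rng.normal(0.0, cfg.delay_sigma, n))
    extra = _criteria_and_imaging(rng, cfg, theta)
    return pd.DataFrame({
        "participant_id": [f"n{i + 1:05d}" for i in range(n)],
        "cohort": "normative",
        "session_index": 0,
        "age": np.round(age, 1),
        "sex": sex,
        "education": education,
        "english_second_language": esl,
        "nihss_baseline": np.nan,
        "impaired_hand": 0,
        "days_since_stroke": np.nan,
        "phase": "",
        "moca": extra["moca"],
        "iadl": extra["iadl"],
        "lesion_volume": 0.0,
        "wmh_volume": extra["wmh_volume"],
        "has_imaging": 0,
        "latent_ability": theta,
        "latent_motor_delay": delay,
        "latent_caution": caution,
        "impair_delay_extra": 0.0,
        "wmh_domain_deficit": 0.0,
    })


def _generate_patients(rng: np.random.Generator, cfg: GeneratorConfig,
                       n: int) -> pd.DataFrame:
    mean, sd, lo, hi = cfg.age_patient
    age = _truncated_normal(rng, mean, sd, lo, hi, n)
    sex = np.where(rng.random(n) < cfg.male_prob_patient, "male", "female")
    education = rng.choice([1, 2, 3, 4], size=n, p=cfg.education_probs_patient)
    esl = (rng.random(n) < cfg.esl_prob_patient).astype(int)
    nihss = _nihss(rng, cfg, n)
    impaired = (rng.random(n) < cfg.impairment_rate).astype(int)
    has_imaging = (rng.random(n) < cfg.imaging_rate).astype(int)

    age_z = (age - mean) / sd
    theta0 = (
        _ability_demographics(cfg, age_z, education, esl)
        + cfg.beta_nihss * np.log1p(nihss)
        + rng.normal(0.0, cfg.ability_sd, n)
    )
    slope = cfg.recovery_slope + rng.normal(0.0, cfg.recovery_slope_sd, n)
    caution = rng.normal(0.0, cfg.caution_sd, n)

    delay = cfg.delay_median * np.exp(rng.normal(0.0, cfg.delay_sigma, n))
    if cfg.impair_delay_mean > 0:
        extra_delay = impaired * cfg.impair_delay_mean * np.exp(
            rng.normal(0.0, cfg.impair_delay_sigma, n))
    else:
        extra_delay = np.zeros(n)

    # session days
    med, sig = cfg.days_acute
    d_acute = np.clip(np.round(med * np.exp(rng.normal(0.0, sig, n))), 1, 14)
    m2, s2 = cfg.days_subacute
    d_sub = np.clip(np.round(rng.normal(m2, s2, n)), 15, 180)
    m3, s3 = cfg.days_chronic
    d_chr = np.clip(np.round(rng.normal(m3, s3, n)), 181, 730)
    days = np.stack([d_acute, d_sub, d_chr], axis=1)

    attend = rng.random((n, 3)) < np.asarray(cfg.session_attendance)
    none = ~attend.any(axis=1)
    attend[none, 0] = True  # everyone is assessed at least once

    # log-wmh z-score drives the chronic-phase domain-specific deficit
    rows = []
    wmh_draw = rng.normal(0.0, cfg.wmh_noise_sd, n)
    log_wmh = cfg.wmh_intercept + cfg.wmh_ability_slope * theta0 + wmh_draw
    wmh_z = (log_wmh - np.mean(log_wmh)) / max(np.std(log_wmh), 1e-12)
    for s in range(3):
        idx = np.where(attend[:, s])[0]
        if idx.size == 0:
            continue
        d = days[idx, s]
        theta_it = theta0[idx] + slope[idx] * (np.log1p(d) - np.log1p(4.0))
        crit = _criteria_and_imaging(rng, cfg, theta_it)
        phase = np.array([derive_phase(v) for v in d])
        deficit = np.where(
            phase == "chronic",
            cfg.wmh_domain_effect * np.maximum(wmh_z[idx], 0.0),
            0.0,
        )
        rows.append(pd.DataFrame({
            "participant_id": np.array([f"p{i + 1:04d}" for i in idx]),
            "cohort": "patient",
            "session_index": s,
            "age": np.round(age[idx], 1),
            "sex": sex[idx],
            "education": education[idx],
            "english_second_language": esl[idx],
            "nihss_baseline": nihss[idx].astype(float),
            "impaired_hand": impaired[idx],
            "days_since_stroke": d,
            "phase": phase,
            "moca": crit["moca"],
            "iadl": crit["iadl"],
            "lesion_volume": np.exp(cfg.lesion_intercept
                                    + cfg.lesion_ability_slope * theta_it
                                    + rng.normal(0.0, cfg.lesion_noise_sd, idx.size)),
            "wmh_volume": np.exp(log_wmh[idx]),
            "has_imaging": has_imaging[idx],
            "latent_ability": theta_it,
            "latent_motor_delay": delay[idx],
            "latent_caution": caution[idx],
            "impair_delay_extra": extra_delay[idx],
            "wmh_domain_deficit": deficit,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["participant_id", "session_index"], ignore_index=True)


def _empty_participants() -> pd.DataFrame:
    cols = ["participant_id", "cohort", "session_index", "age", "sex", "education",
            "english_second_language", "nihss_baseline", "impaired_hand",
            "days_since_stroke", "phase", "moca", "iadl", "lesion_volume",
            "wmh_volume", "has_imaging", *LATENT_COLUMNS]
    return pd.DataFrame({c: [] for c in cols})


def effective_motor_delay(participants: pd.DataFrame, task: TaskSpec,
                          config: GeneratorConfig | None = None) -> pd.Series:
    """True per-row motor delay (ms) for this task, from latent truth columns."""
    cfg = config or GeneratorConfig()
    boost = 1.0 + cfg.motor_boost * (task.motor_demand == "high")
    return participants["latent_motor_delay"] + participants["impair_delay_extra"] * boost


def generate_trials(
    participants: pd.DataFrame,
    task: TaskSpec,
    seed: int,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Simulate every trial of ``task`` for each participant-session row.

    Requires the latent columns produced by :func:`generate_participants`.
    A participant-session skips the whole task with probability
    ``task_missing_rate`` (engagement / technical failures).
    """

    cfg = config or GeneratorConfig()
    if task.n_conditions == 0:
        raise ValueError(f"task {task.task_id}: no conditions configured")
    for col in ("latent_ability", "latent_motor_delay"):
        if col not in participants.columns:
            raise ValueError(f"participants table lacks latent column {col!r}")
    if len(participants) == 0:
        return _empty_trials()

    rng = np.random.default_rng([int(seed), zlib.crc32(task.task_id.encode()) % (2**31)])
    n_rows = len(participants)
    keep = rng.random(n_rows) >= cfg.task_missing_rate

    b = np.asarray(task.condition_difficulties, dtype=float)
    labels = np.repeat(task.condition_labels, task.trials_per_condition)
    b_trial = np.repeat(b, task.trials_per_condition)
    nt = task.n_trials

    theta = participants["latent_ability"].to_numpy(dtype=float)
    if "wmh_domain_deficit" in participants.columns and task.domain in WMH_SENSITIVE_DOMAINS:
        theta = theta - participants["wmh_domain_deficit"].to_numpy(dtype=float)
    delay = effective_motor_delay(participants, task, cfg).to_numpy(dtype=float)
    impaired = participants["impaired_hand"].to_numpy(dtype=float)

    eta = (cfg.rt_ability_slope_high_cog if task.cognitive_demand == "high"
           else cfg.rt_ability_slope_low_cog)
    alpha = cfg.accuracy_discrimination

    idx = np.where(keep)[0]
    if idx.size == 0:
        return _empty_trials()
    m = idx.size
    caution = participants["latent_caution"].to_numpy(dtype=float)[idx] \
        if "latent_caution" in participants.columns else np.zeros(m)
    th = theta[idx][:, None]  # (m, 1)
    if cfg.session_jitter_sd > 0:
        th = th + rng.normal(0.0, cfg.session_jitter_sd, (m, 1))
    kappa = cfg.caution_accuracy_weight
    p_correct = 1.0 / (1.0 + np.exp(-alpha * (th + kappa * caution[:, None]
                                              - b_trial[None, :])))
    acc = (rng.random((m, nt)) < p_correct).astype(int)
    # mis-tap rates scale with each patient's impairment severity (the same
    # severity that lengthens their response delay)
    if cfg.impair_delay_mean > 0 and "impair_delay_extra" in participants.columns:
        severity = participants["impair_delay_extra"].to_numpy(dtype=float)[idx] \
            / cfg.impair_delay_mean
    else:
        severity = impaired[idx]
    severity = severity[:, None]
    if (task.slip_rate_impaired > 0 and not cfg.disable_slips
            and task.motor_demand == "high"):
        slip_p = np.clip(task.slip_rate_impaired * severity, 0.0, 0.6)
        slip_mask = (rng.random((m, nt)) < slip_p) & (impaired[idx][:, None] > 0)
        acc = np.where(slip_mask, 0, acc)
    # answer time: fixed encoding share plus a difficulty-graded operation
    # share that ability speeds up and caution slows down
    b_rel = b_trial - b_trial.min()
    encode = cfg.rt_encoding_fraction * task.base_answer_time
    operation = (1.0 - cfg.rt_encoding_fraction) * task.base_answer_time \
        * (1.0 + task.difficulty_rt_slope * b_rel[None, :])
    at_det = encode + operation * np.exp(-eta * th
                                         + cfg.caution_rt_slope * caution[:, None])
    noise = cfg.rt_noise_median * np.exp(rng.normal(0.0, cfg.rt_noise_sigma, (m, nt)))
    rt = delay[idx][:, None] + at_det + noise
    timed_out = rt > task.response_window
    if (task.fumble_rate_impaired > 0 and not cfg.disable_slips
            and task.motor_demand == "high"):
        # mis-taps that register no valid response: recorded like a timeout
        fumble_p = np.clip(task.fumble_rate_impaired * severity, 0.0, 0.6)
        fumble = (rng.random((m, nt)) < fumble_p) & (impaired[idx][:, None] > 0)
        timed_out = timed_out | fumble
    rt = np.where(timed_out, task.response_window, rt)
    acc = np.where(timed_out, 0, acc)

    # progressive designs terminate after a run of consecutive failures, so
    # weaker (or motor-impaired) participants never reach the hardest trials
    administered = np.ones((m, nt), dtype=bool)
    if task.early_stop_failures is not None:
        failure = (acc == 0) | timed_out
        run = np.zeros(m, dtype=int)
        alive = np.ones(m, dtype=bool)
        for j in range(nt):
            administered[:, j] = alive
            run = np.where(failure[:, j], run + 1, 0)
            alive = alive & (run < task.early_stop_failures)

    pid = participants["participant_id"].to_numpy()[idx]
    sess = participants["session_index"].to_numpy()[idx].astype(int)
    out = pd.DataFrame({
        "participant_id": np.repeat(pid, nt),
        "task_id": task.task_id,
        "session_index": np.repeat(sess, nt),
        "trial_index": np.tile(np.arange(nt), m),
        "condition_label": np.tile(labels, m),
        "accuracy": acc.ravel(),
        "rt": rt.ravel(),
        "timed_out": timed_out.astype(int).ravel(),
    })
    if task.early_stop_failures is not None:
        out = out.loc[administered.ravel()].reset_index(drop=True)
    return out


def _empty_trials() -> pd.DataFrame:
    cols = ["participant_id", "task_id", "session_index", "trial_index",
            "condition_label", "accuracy", "rt", "timed_out"]
    return pd.DataFrame({c: [] for c in cols})


def generate_cohort_trials(
    participants: pd.DataFrame,
    tasks: Sequence[TaskSpec],
    seed: int,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Trials for a whole battery, one long table with all task_ids."""
    frames = [generate_trials(participants, task, seed, config) for task in tasks]
    frames = [f for f in frames if len(f)]
    if not frames:
        return _empty_trials()
    return pd.concat(frames, ignore_index=True)


def write_cohort(participants: pd.DataFrame, trials: pd.DataFrame,
                 out_dir: str | Path) -> dict[str, Path]:
    """Write participants.csv / trials.csv / truth.csv.

    Latent ground-truth columns go to truth.csv only, so the file set read
    by estimation commands never contains them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    latent = [c for c in LATENT_COLUMNS if c in participants.columns]
    public = participants.drop(columns=latent)
    truth = participants[["participant_id", "session_index", *latent]]
    paths = {
        "participants": out / "participants.csv",
        "trials": out / "trials.csv",
        "truth": out / "truth.csv",
    }
    try:
        public.to_csv(paths["participants"], index=False)
        truth.to_csv(paths["truth"], index=False)
        trials.to_csv(paths["trials"], index=False)
    except OSError as exc:
        raise OSError(f"failed writing cohort files under {out}: {exc}") from exc
    return paths


def read_cohort(in_dir: str | Path, with_truth: bool = False
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read (participants, trials); with_truth merges truth.csv back in."""
    d = Path(in_dir)
    participants = pd.read_csv(d / "participants.csv",
                               dtype={"participant_id": str},
                               keep_default_na=True)
    participants["phase"] = participants["phase"].fillna("")
    trials = pd.read_csv(d / "trials.csv", dtype={"participant_id": str})
    if with_truth:
        truth = pd.read_csv(d / "truth.csv", dtype={"participant_id": str})
        participants = participants.merge(truth, on=["participant_id", "session_index"],
                                          how="left")
    return participants, trials


def benchmark_cohort(
    seed: int = 1,
    n_normative: int = 400,
    n_patient: int = 200,
    tasks: Sequence[TaskSpec] | None = None,
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[TaskSpec]]:
    """The packaged synthetic benchmark: participants, trials, registry."""
    registry = list(tasks) if tasks is not None else default_task_registry()
    cfg = config or GeneratorConfig()
    participants = generate_participants(n_normative, n_patient, seed, cfg)
    trials = generate_cohort_trials(participants, registry, seed, cfg)
    return participants, trials, registry
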