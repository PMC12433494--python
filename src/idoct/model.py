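"""Iterative decomposition of trial-level task data (IDoCT).

The model separates each reaction time into a cognitive Answer Time (AT)
and a participant-level Response Delay Time (DT), and summarises each
participant-task-session as a Cognitive Index (AS) in [0, 1] that
triangulates accuracy, answer speed and trial difficulty.

Calibration runs on a large normative cohort and proceeds as a fixed
point:

1. speed score ``s = clip((rt_ceiling - rt) / (rt_ceiling - rt_floor), 0, 1)``
   with floor/ceiling the 5th/95th normative RT percentiles;
2. trial performance ``p = accuracy * (w + (1 - w) * s)`` with ``w = 0.5``;
3. raw condition difficulty ``D_raw(c) = 1 - mean p`` over trials of ``c``;
4. difficulty-weighted provisional ability
   ``A_i = sum(p * D_scaled) / sum(D_scaled)`` over participant i's trials;
5. ability-corrected scaled difficulty
   ``D_scaled(c) = clip(D_raw(c) + mean(A | attempted c) - mean(A), 0, 1)``,
   iterating 4-5 to convergence.  The correction removes the bias that
   arises when only stronger participants reach the harder conditions.

A second alternation on the normative cohort estimates a monotone
(in ``D_scaled``) condition-level answer-time curve ``AT_c`` and per-person
delays ``DT_i = max(0, mean(rt - AT_c))``; the curve, RT percentiles and the
normative mean DT are frozen into the difficulty table.  Applying the model
to new data then computes, per participant-task-session,

* ``delay_time = max(0, mean(rt - AT_c))`` against the frozen curve,
* per-trial ``answer_time = rt - delay_time``,
* ``AS = sum(acc * D_scaled * (w + (1 - w) * s*)) / sum(D_scaled)``
  with ``s*`` the speed score of the answer times against the frozen
  percentiles shifted by the normative mean DT.

Trials without a registered response (timeouts, dropped taps) are censored
observations: the recorded RT is the response window, not AT + DT, and the
intended response is unknown.  They are excluded from delay estimation and
from the Cognitive Index sums.  The standard accuracy metric, by contrast,
counts them as errors; this is precisely how motor impairment confounds
conventional scores while leaving the modelled index clean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "clean_trials",
    "standard_metrics",
    "DifficultyTable",
    "Decomposition",
    "IDoCTModel",
    "IDoCTResults",
    "decompose_session",
]

logger = logging.getLogger(__name__)

_SESSION_KEY = ["participant_id", "task_id", "session_index"]


# ---------------------------------------------------------------------------
# pre-processing


def clean_trials(
    trials: pd.DataFrame,
    rt_min: float = 200.0,
    rt_max: float | Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop physiologically implausible reaction times.

    Non-timeout trials with ``rt < rt_min`` or ``rt > rt_max`` are removed;
    timeouts are kept (their RT is the response window by construction).
    ``rt_max`` may be a scalar, a mapping ``task_id -> bound``, or None
    (no upper bound).  Returns ``(kept, report)`` where the report lists the
    excluded fraction per task; row order of kept trials is preserved.
    """
    if len(trials) == 0:
        report = pd.DataFrame(columns=["task_id", "n_total", "n_removed", "fraction_removed"])
        return trials.copy(), report

    rt = trials["rt"].to_numpy(dtype=float)
    if rt_max is None:
        upper = np.full(len(trials), np.inf)
    elif isinstance(rt_max, Mapping):
        upper = trials["task_id"].map(rt_max).to_numpy(dtype=float)
        if np.isnan(upper).any():
            missing = sorted(set(trials.loc[np.isnan(upper), "task_id"]))
            raise KeyError(f"rt_max mapping lacks task(s): {missing}")
    else:
        upper = np.full(len(trials), float(rt_max))
    if rt_min >= np.min(upper):
        raise ValueError("rt_min must be below rt_max")

    timed_out = trials["timed_out"].to_numpy() > 0
    bad = (~timed_out) & ((rt < rt_min) | (rt > upper))
    kept = trials.loc[~bad]
    grp = trials.assign(_bad=bad).groupby("task_id")["_bad"]
    report = grp.agg(n_total="size", n_removed="sum").reset_index()
    report["fraction_removed"] = report["n_removed"] / report["n_total"]
    return kept, report


def standard_metrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Conventional outcome measures per participant-task-session.

    ``accuracy_count`` is the number of correct responses (timeouts count
    as errors) and ``median_rt`` the median RT over all trials.
    """
    if len(trials) == 0:
        return pd.DataFrame(columns=_SESSION_KEY + ["accuracy_count", "trial_count", "median_rt"])
    g = trials.groupby(_SESSION_KEY, sort=True)
    out = g.agg(accuracy_count=("accuracy", "sum"),
                trial_count=("accuracy", "size"),
                median_rt=("rt", "median")).reset_index()
    return out


# ---------------------------------------------------------------------------
# difficulty table


@dataclass
class DifficultyTable:
    """Frozen per-task calibration: difficulties, AT curve, RT percentiles."""

    task_id: str
    labels: list[str]
    d_raw: dict[str, float]
    d_scaled: dict[str, float]
    n_trials_observed: dict[str, int]
    rt_floor: float
    rt_ceiling: float
    at_curve: dict[str, float]
    dt_reference_mean: float
    w: float
    converged: bool
    n_iterations: int
    group_performance_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rt_floor < self.rt_ceiling:
            raise ValueError(f"{self.task_id}: rt_floor must be below rt_ceiling")
        for lab in self.labels:
            for d in (self.d_raw[lab], self.d_scaled[lab]):
                if not -1e-12 <= d <= 1 + 1e-12:
                    raise ValueError(f"{self.task_id}/{lab}: difficulty outside [0, 1]")
        # AT curve must be non-decreasing in scaled difficulty
        order = sorted(self.labels, key=lambda c: self.d_scaled[c])
        ats = [self.at_curve[c] for c in order]
        if any(b < a - 1e-9 for a, b in zip(ats, ats[1:])):
            raise ValueError(f"{self.task_id}: AT curve not monotone in scaled difficulty")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DifficultyTable":
        return cls(**d)


# ---------------------------------------------------------------------------
# calibration


def _speed_score(rt: np.ndarray, floor: float, ceiling: float) -> np.ndarray:
    return np.clip((ceiling - rt) / (ceiling - floor), 0.0, 1.0)


def _fit_difficulties(task_trials: pd.DataFrame, w: float, tol: float,
                      max_iter: int) -> tuple[pd.DataFrame, dict]:
    """The difficulty <-> ability fixed point for one task. Deterministic."""
    rt = task_trials["rt"].to_numpy(dtype=float)
    acc = task_trials["accuracy"].to_numpy(dtype=float)
    ok = task_trials["timed_out"].to_numpy() == 0
    floor, ceiling = np.percentile(rt[ok], [5.0, 95.0])
    if not floor < ceiling:
        raise ValueError("degenerate RT distribution: rt_floor == rt_ceiling")
    s = _speed_score(rt, floor, ceiling)
    p = acc * (w + (1.0 - w) * s)

    labels = np.sort(task_trials["condition_label"].unique())
    lab_idx = pd.Categorical(task_trials["condition_label"], categories=labels).codes
    pid_codes, pids = pd.factorize(task_trials["participant_id"], sort=True)

    n_lab = np.bincount(lab_idx, minlength=len(labels)).astype(float)
    d_raw = 1.0 - np.bincount(lab_idx, weights=p, minlength=len(labels)) / n_lab
    d_raw = np.clip(d_raw, 0.0, 1.0)

    # participant x condition attendance (for the ability correction)
    att = pd.DataFrame({"pid": pid_codes, "lab": lab_idx}).drop_duplicates()

    d_scaled = d_raw.copy()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d_trial = d_scaled[lab_idx]
        denom = np.bincount(pid_codes, weights=d_trial, minlength=len(pids))
        numer = np.bincount(pid_codes, weights=p * d_trial, minlength=len(pids))
        with np.errstate(invalid="ignore"):
            ability = np.where(denom > 0, numer / np.maximum(denom, 1e-300), np.nan)
        fallback = np.bincount(pid_codes, weights=p, minlength=len(pids)) \
            / np.bincount(pid_codes, minlength=len(pids))
        ability = np.where(np.isnan(ability), fallback, ability)
        grand = float(np.mean(ability))
        att_ab = ability[att["pid"].to_numpy()]
        mean_att = np.full(len(labels), grand)
        cnt = np.bincount(att["lab"].to_numpy(), minlength=len(labels)).astype(float)
        s_ab = np.bincount(att["lab"].to_numpy(), weights=att_ab, minlength=len(labels))
        nz = cnt > 0
        mean_att[nz] = s_ab[nz] / cnt[nz]
        new = np.clip(d_raw + (mean_att - grand), 0.0, 1.0)
        delta = float(np.max(np.abs(new - d_scaled)))
        d_scaled = new
        trace.append(float(np.mean(p)))
        if delta < tol:
            converged = True
            break

    per_label = pd.DataFrame({
        "condition_label": labels,
        "d_raw": d_raw,
        "d_scaled": d_scaled,
        "n_trials_observed": n_lab.astype(int),
    })
    info = {
        "rt_floor": float(floor),
        "rt_ceiling": float(ceiling),
        "converged": converged,
        "n_iterations": it,
        "trace": trace,
    }
    return per_label, info


def _fit_at_curve(task_trials: pd.DataFrame, d_scaled: Mapping[str, float],
                  tol: float, max_iter: int) -> tuple[dict[str, float], np.ndarray, bool]:
    """Alternation between the monotone condition AT curve and per-person DT.

    Runs on non-timed-out trials.  Returns (at_curve, per-person DT,
    converged).
    """
    ok = task_trials.loc[task_trials["timed_out"] == 0]
    if len(ok) == 0:
        raise ValueError("no non-timeout trials to fit the AT curve")
    rt = ok["rt"].to_numpy(dtype=float)
    labels = np.sort(ok["condition_label"].unique())
    lab_idx = pd.Categorical(ok["condition_label"], categories=labels).codes
    pid_codes, pids = pd.factorize(ok["participant_id"], sort=True)
    x = np.array([d_scaled[c] for c in labels], dtype=float)
    weights = np.bincount(lab_idx, minlength=len(labels)).astype(float)

    dt = np.zeros(len(pids))
    at = np.zeros(len(labels))
    converged = False
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    for _ in range(max_iter):
        resid = rt - dt[pid_codes]
        med = pd.Series(resid).groupby(lab_idx).median().reindex(
            range(len(labels))).to_numpy()
        seen = np.isfinite(med)
        if not seen.any():
            raise ValueError("no condition has usable trials for the AT curve")
        at_new = iso.fit(x[seen], med[seen], sample_weight=weights[seen]).predict(x)
        dt_new = np.bincount(pid_codes, weights=rt - at_new[lab_idx],
                             minlength=len(pids))
        dt_new = dt_new / np.bincount(pid_codes, minlength=len(pids))
        # AT level and DT are only jointly identified (rt = AT + DT admits a
        # constant shift); anchor the gauge so the fastest normative
        # responders have zero delay, then floor the remainder at zero.
        anchor = float(np.percentile(dt_new, 1.0))
        at_new = at_new + anchor
        dt_new = np.maximum(0.0, dt_new - anchor)
        rel = max(
            float(np.max(np.abs(at_new - at) / np.maximum(np.abs(at), 1.0))),
            float(np.max(np.abs(dt_new - dt) / np.maximum(np.abs(dt), 1.0))),
        )
        at, dt = at_new, dt_new
        if rel < tol:
            converged = True
            break
    return {c: float(a) for c, a in zip(labels, at)}, dt, converged


class IDoCTModel:
    """Calibrates the decomposition on a normative cohort.

    Parameters
    ----------
    normative_trials
        Long trial table (cleaned) for the normative cohort; must contain
        participant_id, task_id, session_index, condition_label, accuracy,
        rt, timed_out.
    w
        Weight of accuracy relative to speed in trial performance
        ``p = a * (w + (1 - w) * s)``.
    tol, max_iter
        Convergence tolerance (applied to both fixed points) and iteration cap.
    min_obs
        Minimum number of normative observations required per condition label.
    """

    def __init__(self, normative_trials: pd.DataFrame, w: float = 0.5,
                 tol: float = 1e-4, max_iter: int = 200, min_obs: int = 10):
        if not 0.0 <= w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        self.trials = normative_trials
        self.w = float(w)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.min_obs = int(min_obs)

    def fit(self) -> "IDoCTResults":
        tables: dict[str, DifficultyTable] = {}
        for task_id, df in self.trials.groupby("task_id", sort=True):
            if df["participant_id"].nunique() < 2:
                raise ValueError(f"task {task_id}: need at least 2 normative participants")
            counts = df["condition_label"].value_counts()
            thin = counts[counts < self.min_obs]
            if len(thin):
                raise ValueError(
                    f"task {task_id}: condition(s) observed fewer than "
                    f"{self.min_obs} times: {sorted(thin.index)}")
            per_label, info = _fit_difficulties(df, self.w, self.tol, self.max_iter)
            d_scaled = dict(zip(per_label["condition_label"], per_label["d_scaled"]))
            at_curve, dt, at_conv = _fit_at_curve(df, d_scaled, self.tol, self.max_iter)
            converged = info["converged"] and at_conv
            if not converged:
                logger.warning("task %s: calibration did not converge in %d iterations",
                               task_id, self.max_iter)
            tables[task_id] = DifficultyTable(
                task_id=task_id,
                labels=list(per_label["condition_label"]),
                d_raw=dict(zip(per_label["condition_label"],
                               per_label["d_raw"].astype(float))),
                d_scaled={k: float(v) for k, v in d_scaled.items()},
                n_trials_observed=dict(zip(per_label["condition_label"],
                                           per_label["n_trials_observed"].astype(int))),
                rt_floor=info["rt_floor"],
                rt_ceiling=info["rt_ceiling"],
                at_curve=at_curve,
                dt_reference_mean=float(np.mean(dt)),
                w=self.w,
                converged=bool(converged),
                n_iterations=int(info["n_iterations"]),
                group_performance_trace=info["trace"],
            )
        return IDoCTResults(tables, w=self.w, tol=self.tol, max_iter=self.max_iter)


@dataclass
class Decomposition:
    """One participant-task-session decomposition."""

    participant_id: str
    task_id: str
    session_index: int
    cognitive_index: float
    delay_time: float
    answer_times: np.ndarray
    n_trials_used: int
    converged: bool
    n_iterations: int
    low_confidence: bool


class IDoCTResults:
    """Frozen calibration; applies the decomposition to new trial data."""

    def __init__(self, tables: dict[str, DifficultyTable], w: float,
                 tol: float, max_iter: int):
        self.tables = tables
        self.w = w
        self.tol = tol
        self.max_iter = max_iter

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "w": self.w, "tol": self.tol, "max_iter": self.max_iter,
            "tables": {k: t.to_dict() for k, t in self.tables.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "IDoCTResults":
        payload = json.loads(Path(path).read_text())
        tables = {k: DifficultyTable.from_dict(d) for k, d in payload["tables"].items()}
        return cls(tables, w=payload["w"], tol=payload["tol"],
                   max_iter=payload["max_iter"])

    # -- reporting ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        rows = []
        for task_id, t in sorted(self.tables.items()):
            for lab in t.labels:
                rows.append({
                    "task_id": task_id, "condition_label": lab,
                    "d_raw": t.d_raw[lab], "d_scaled": t.d_scaled[lab],
                    "at_ms": t.at_curve[lab],
                    "n_obs": t.n_trials_observed[lab],
                    "rt_floor": t.rt_floor, "rt_ceiling": t.rt_ceiling,
                    "dt_reference_mean": t.dt_reference_mean,
                    "converged": t.converged,
                })
        return pd.DataFrame(rows)

    # -- application --------------------------------------------------------

    def _check_labels(self, trials: pd.DataFrame) -> None:
        for task_id, df in trials.groupby("task_id"):
            if task_id not in self.tables:
                raise KeyError(f"no calibration for task {task_id!r}")
            known = set(self.tables[task_id].labels)
            seen = set(df["condition_label"].unique())
            unknown = seen - known
            if unknown:
                raise KeyError(
                    f"task {task_id}: unseen condition label(s) {sorted(unknown)}; "
                    "refusing to impute difficulties")

    def decompose(self, trials: pd.DataFrame,
                  min_usable_fraction: float = 0.5) -> pd.DataFrame:
        """Bulk decomposition -> one row per participant-task-session.

        Timed-out trials are censored: excluded from both the delay estimate
        and the Cognitive Index sums.  Sessions where fewer than
        ``min_usable_fraction`` of trials yielded a genuine response are
        treated as failed administrations and dropped (logged); sessions
        with fewer than 3 usable trials are flagged ``low_confidence``.
        """
        if len(trials) == 0:
            return pd.DataFrame(columns=_SESSION_KEY + [
                "cognitive_index", "delay_time", "n_trials_used",
                "converged", "low_confidence"])
        self._check_labels(trials)

        t = trials.copy()
        key = t["task_id"]
        t["_d"] = [self.tables[k].d_scaled[c] for k, c in zip(key, t["condition_label"])]
        t["_at_c"] = [self.tables[k].at_curve[c] for k, c in zip(key, t["condition_label"])]
        t["_floor"] = key.map({k: tb.rt_floor for k, tb in self.tables.items()})
        t["_ceiling"] = key.map({k: tb.rt_ceiling for k, tb in self.tables.items()})
        t["_dtref"] = key.map({k: tb.dt_reference_mean for k, tb in self.tables.items()})

        usable = t.loc[t["timed_out"] == 0].copy()
        g_all = t.groupby(_SESSION_KEY, sort=True)
        sessions = g_all.size().rename("n_trials_total").reset_index()

        if len(usable):
            usable["_resid"] = usable["rt"] - usable["_at_c"]
            g = usable.groupby(_SESSION_KEY, sort=True)
            dt = np.maximum(0.0, g["_resid"].mean()).rename("delay_time")
            usable = usable.merge(dt.reset_index(), on=_SESSION_KEY, how="left")
            at = usable["rt"] - usable["delay_time"]
            shift = usable["_dtref"]
            s_star = np.clip(((usable["_ceiling"] - shift) - at)
                             / (usable["_ceiling"] - usable["_floor"]), 0.0, 1.0)
            usable["_num"] = usable["accuracy"] * usable["_d"] \
                * (self.w + (1.0 - self.w) * s_star)
            g = usable.groupby(_SESSION_KEY, sort=True)
            agg = g.agg(_num=("_num", "sum"), _den=("_d", "sum"),
                        n_trials_used=("_d", "size"),
                        delay_time=("delay_time", "first")).reset_index()
            with np.errstate(invalid="ignore"):
                agg["cognitive_index"] = np.where(
                    agg["_den"] > 0, agg["_num"] / agg["_den"].clip(lower=1e-300), 0.0)
            agg = agg.drop(columns=["_num", "_den"])
        else:
            agg = pd.DataFrame(columns=_SESSION_KEY + [
                "n_trials_used", "delay_time", "cognitive_index"])

        out = sessions.merge(agg, on=_SESSION_KEY, how="left")
        frac_usable = out["n_trials_used"].fillna(0) / out["n_trials_total"]
        failed = frac_usable < min_usable_fraction
        if failed.any():
            # a mostly/fully timed-out session is a failed administration:
            # emit nothing rather than a score dominated by censoring (the
            # standard metrics still count those trials as errors)
            logger.info("%d session(s) below %.0f%% usable trials; no decomposition emitted",
                        int(failed.sum()), 100 * min_usable_fraction)
            out = out.loc[~failed]
        out = out.copy()
        out["n_trials_used"] = out["n_trials_used"].astype(int)
        out["low_confidence"] = out["n_trials_used"] < 3
        out["converged"] = True
        return out.drop(columns=["n_trials_total"])


def decompose_session(trials: pd.DataFrame, table: DifficultyTable,
                      w: float | None = None) -> Decomposition:
    """Decompose a single participant-task-session; returns per-trial ATs."""
    if trials["task_id"].nunique() != 1 or trials["participant_id"].nunique() != 1:
        raise ValueError("decompose_session expects one participant and one task")
    unknown = set(trials["condition_label"]) - set(table.labels)
    if unknown:
        raise KeyError(f"unseen condition label(s) {sorted(unknown)}")
    w = table.w if w is None else w
    usable = trials.loc[trials["timed_out"] == 0]
    pid = str(trials["participant_id"].iat[0])
    sess = int(trials["session_index"].iat[0])
    if len(usable) == 0:
        # all trials censored at the response window: no usable responses
        return Decomposition(pid, table.task_id, sess, float("nan"), float("nan"),
                             np.array([]), 0, True, 1, True)
    rt = usable["rt"].to_numpy(dtype=float)
    at_c = usable["condition_label"].map(table.at_curve).to_numpy(dtype=float)
    d = usable["condition_label"].map(table.d_scaled).to_numpy(dtype=float)
    acc = usable["accuracy"].to_numpy(dtype=float)
    delay = max(0.0, float(np.mean(rt - at_c)))
    answer_times = rt - delay
    s_star = np.clip(((table.rt_ceiling - table.dt_reference_mean) - answer_times)
                     / (table.rt_ceiling - table.rt_floor), 0.0, 1.0)
    den = float(np.sum(d))
    num = float(np.sum(acc * d * (w + (1.0 - w) * s_star)))
    asc = num / den if den > 0 else 0.0
    return Decomposition(pid, table.task_id, sess, asc, delay, answer_times,
                         int(len(usable)), True, 1, len(usable) < 3)
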