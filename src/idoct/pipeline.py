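"""End-to-end analysis pipeline behind a single configuration object.

Stages: simulate (or load) -> validate -> clean -> calibrate on the
normative cohort -> decompose patient sessions -> standard metrics ->
per-phase global factors (both metric families) -> impaired-hand confound
regressions -> criterion validity -> canonical correlation against imaging
burden -> report.  Identical config and seed give byte-identical numeric
outputs; the configuration hash is recorded in the run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bpca, cca, cohort, model, regression

__all__ = ["PipelineConfig", "PipelineOutputs", "validate_inputs", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 1
    n_normative: int = 400
    n_patient: int = 200
    input_dir: str | None = None  # read an existing cohort instead of simulating
    rt_min: float = 200.0
    idoct_w: float = 0.5
    idoct_tol: float = 1e-4
    idoct_max_iter: int = 200
    idoct_min_obs: int = 10
    fdr_alpha: float = 0.05
    cca_n_perm: int = 9999
    cca_phases: tuple[str, ...] = ("subacute", "chronic")
    gfactor_min_rows: int = 10
    null_motor: bool = False  # null generator: no motor-impairment effect
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides

    def generator_config(self) -> cohort.GeneratorConfig:
        cfg = cohort.GeneratorConfig(**self.generator)
        if self.null_motor:
            cfg = cfg.null_motor()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cca_phases"] = list(self.cca_phases)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "cca_phases" in raw:
            raw["cca_phases"] = tuple(raw["cca_phases"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


REQUIRED_TRIAL_COLUMNS = ("participant_id", "task_id", "session_index",
                          "trial_index", "condition_label", "accuracy", "rt",
                          "timed_out")
REQUIRED_PARTICIPANT_COLUMNS = ("participant_id", "cohort", "session_index",
                                "age", "sex", "education",
                                "english_second_language", "impaired_hand")


def validate_inputs(participants: pd.DataFrame,
                    trials: pd.DataFrame) -> pd.DataFrame:
    """Schema / domain / referential-integrity checks; returns findings."""
    findings = []

    def add(kind, message):
        findings.append({"kind": kind, "message": message})

    for col in REQUIRED_PARTICIPANT_COLUMNS:
        if col not in participants.columns:
            add("schema", f"participants: missing column {col!r}")
    for col in REQUIRED_TRIAL_COLUMNS:
        if col not in trials.columns:
            add("schema", f"trials: missing column {col!r}")
    if findings:
        return pd.DataFrame(findings)

    bad_acc = ~trials["accuracy"].isin([0, 1])
    for i in np.where(bad_acc)[0][:20]:
        add("domain", f"trials row {i}: accuracy outside {{0,1}}")
    bad_rt = trials["rt"] <= 0
    for i in np.where(bad_rt)[0][:20]:
        add("domain", f"trials row {i}: rt <= 0")
    known = set(participants["participant_id"])
    orphan = ~trials["participant_id"].isin(known)
    for pid in sorted(set(trials.loc[orphan, "participant_id"]))[:20]:
        add("integrity", f"trial references unknown participant {pid!r}")
    pat = participants.loc[participants["cohort"] == "patient"]
    if len(pat) and pat["days_since_stroke"].isna().any():
        add("domain", "patient rows with missing days_since_stroke (phase underivable)")
    norm = participants.loc[participants["cohort"] == "normative"]
    if len(norm) and (norm["impaired_hand"].astype(float) != 0).any():
        add("domain", "normative participants flagged with impaired hand")
    return pd.DataFrame(findings)


@dataclass
class PipelineOutputs:
    config: PipelineConfig
    participants: pd.DataFrame
    trials: pd.DataFrame
    cleaning_report: pd.DataFrame
    calibration: "model.IDoCTResults"
    decomposition: pd.DataFrame
    std_metrics: pd.DataFrame
    gfactors: list
    impairment_table: pd.DataFrame
    criterion_results: pd.DataFrame
    cca_results: dict
    report: dict


def _task_windows(tasks) -> dict[str, float]:
    return {t.task_id: t.response_window for t in tasks}


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 force: bool = False, tasks=None) -> PipelineOutputs:
    """Execute every stage; optionally write the artifact set to ``out_dir``."""
    registry = list(tasks) if tasks is not None else cohort.default_task_registry()
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        stale = [p for p in out.iterdir() if p.name != "run.log"] \
            if out.exists() else []
        if stale and not force:
            raise FileExistsError(
                f"output directory {out} is not empty; pass force=True to overwrite")
        out.mkdir(parents=True, exist_ok=True)

    from . import __version__
    report: dict = {"config_hash": config.hash(), "version": __version__,
                    "stages": {}}

    # -- stage: simulate / load --------------------------------------------
    if config.input_dir:
        participants, trials = cohort.read_cohort(config.input_dir)
    else:
        gen = config.generator_config()
        participants = cohort.generate_participants(
            config.n_normative, config.n_patient, config.seed, gen)
        trials = cohort.generate_cohort_trials(participants, registry,
                                               config.seed, gen)
    public = participants.drop(columns=[c for c in cohort.LATENT_COLUMNS
                                        if c in participants.columns])
    report["stages"]["simulate"] = {
        "participant_sessions": int(len(public)),
        "trials": int(len(trials)),
    }

    # -- stage: validate ----------------------------------------------------
    findings = validate_inputs(public, trials)
    if len(findings):
        raise ValueError("input validation failed:\n"
                         + "\n".join(findings["message"].tolist()))
    report["stages"]["validate"] = {"findings": 0}

    # -- stage: clean -------------------------------------------------------
    windows = _task_windows(registry)
    kept, cleaning_report = model.clean_trials(trials, rt_min=config.rt_min,
                                               rt_max=windows)
    report["stages"]["clean"] = {
        "kept": int(len(kept)),
        "removed": int(len(trials) - len(kept)),
        "fraction_removed": float(1.0 - len(kept) / max(len(trials), 1)),
    }

    # -- stage: calibrate + decompose --------------------------------------
    norm_ids = set(public.loc[public["cohort"] == "normative", "participant_id"])
    norm_trials = kept.loc[kept["participant_id"].isin(norm_ids)]
    pat_trials = kept.loc[~kept["participant_id"].isin(norm_ids)]
    calib = model.IDoCTModel(norm_trials, w=config.idoct_w, tol=config.idoct_tol,
                             max_iter=config.idoct_max_iter,
                             min_obs=config.idoct_min_obs).fit()
    decomposition = calib.decompose(pat_trials)
    std = model.standard_metrics(pat_trials)
    report["stages"]["decompose"] = {
        "tasks_calibrated": len(calib.tables),
        "all_converged": bool(all(t.converged for t in calib.tables.values())),
        "patient_sessions": int(len(decomposition)),
    }

    # -- stage: global factors ---------------------------------------------
    gfactors = []
    for value_col, family in (("cognitive_index", "cognitive_index"),
                              ("accuracy_count", "standard_accuracy")):
        metrics = decomposition if value_col == "cognitive_index" else std
        for phase in cohort.PHASES:
            try:
                gf = bpca.extract_g(metrics, public, phase, value_col,
                                    metric_family=family,
                                    min_rows=config.gfactor_min_rows)
            except ValueError as exc:
                logger.info("global factor skipped (%s, %s): %s", family, phase, exc)
                continue
            gfactors.append(gf)
    report["stages"]["pca"] = {
        "factors": [
            {"phase": g.phase, "family": g.metric_family,
             "variance_explained": g.variance_explained,
             "n": g.n_participants, "all_loadings_positive":
                 bool((g.loadings > 0).all())}
            for g in gfactors],
    }

    # -- stage: impaired-hand confound analysis -----------------------------
    impairment_table, _models = regression.hand_impairment_analysis(
        decomposition, std, public, alpha=config.fdr_alpha)
    confounded = (impairment_table.pivot(index="task_id", columns="metric",
                                         values="confounded")
                  if len(impairment_table) else pd.DataFrame())
    report["stages"]["regress"] = {
        "models": int(len(impairment_table)),
        "confounded_matrix": confounded.astype(bool).to_dict()
        if len(confounded) else {},
    }

    # -- stage: criterion validity ------------------------------------------
    crit_frames = []
    for criterion in ("moca", "iadl"):
        crit_frames.append(regression.criterion_validity(gfactors, public,
                                                         criterion=criterion))
    criterion_results = pd.concat(crit_frames, ignore_index=True)
    report["stages"]["criterion"] = {
        "rows": int(len(criterion_results)),
        "r2": criterion_results[["criterion", "phase", "metric_family",
                                 "r2"]].to_dict("records"),
    }

    # -- stage: CCA ----------------------------------------------------------
    cca_results: dict = {}
    imaging = public.loc[(public["cohort"] == "patient")
                         & (public["has_imaging"] == 1)]
    for phase in config.cca_phases:
        mat = bpca.assemble_phase_matrix(decomposition, public, phase,
                                         "cognitive_index")
        if len(mat) == 0:
            logger.info("CCA skipped for phase %s: no data", phase)
            continue
        # at 18 task columns even mild task-level missingness leaves almost
        # no complete rows; keep participants with at least half the tasks
        # and impute the rest with the EM-PCA posterior means
        mat = mat.loc[mat.notna().mean(axis=1) >= 0.5]
        img = (imaging.loc[imaging["phase"] == phase]
               .groupby("participant_id")[["lesion_volume", "wmh_volume"]]
               .mean().apply(np.log1p))
        common = mat.index.intersection(img.index)
        try:
            fit = bpca.BayesianPCA(mat.loc[common], n_components=2).fit()
            x_block = pd.DataFrame(fit.imputed, index=common, columns=mat.columns)
            res = cca.permutation_test(x_block, img.loc[common],
                                       n_perm=config.cca_n_perm,
                                       seed=config.seed, phase=phase)
            cca_results[phase] = res
        except ValueError as exc:
            logger.info("CCA skipped for phase %s: %s", phase, exc)
    report["stages"]["cca"] = {
        phase: {"canonical_r": res.canonical_correlations.tolist(),
                "r2": res.r2.tolist(),
                "perm_p": res.permutation_p.tolist(),
                "n": res.n_obs}
        for phase, res in cca_results.items()
    }

    outputs = PipelineOutputs(
        config=config, participants=participants, trials=trials,
        cleaning_report=cleaning_report, calibration=calib,
        decomposition=decomposition, std_metrics=std, gfactors=gfactors,
        impairment_table=impairment_table, criterion_results=criterion_results,
        cca_results=cca_results, report=report,
    )
    if out is not None:
        _write_outputs(outputs, out)
    return outputs


def _write_outputs(o: PipelineOutputs, out: Path) -> None:
    cohort.write_cohort(o.participants, o.trials, out)
    o.cleaning_report.to_csv(out / "cleaning_report.csv", index=False)
    o.calibration.to_json(out / "difficulty_table.json")
    o.decomposition.to_csv(out / "decomposition.csv", index=False)
    o.std_metrics.to_csv(out / "standard_metrics.csv", index=False)
    if o.gfactors:
        loads = []
        for g in o.gfactors:
            s = g.loadings.rename("loading").reset_index()
            s.insert(0, "metric_family", g.metric_family)
            s.insert(0, "phase", g.phase)
            loads.append(s)
            g.scores.rename("G").reset_index().to_csv(
                out / f"gfactor_{g.metric_family}_{g.phase}.csv", index=False)
        pd.concat(loads, ignore_index=True).to_csv(
            out / "gfactor_loadings.csv", index=False)
    o.impairment_table.to_csv(out / "regression_results.csv", index=False)
    o.criterion_results.to_csv(out / "criterion_validity.csv", index=False)
    cca_payload = {}
    for phase, res in o.cca_results.items():
        cca_payload[phase] = {
            "canonical_correlations": res.canonical_correlations.tolist(),
            "r2": res.r2.tolist(),
            "permutation_p": res.permutation_p.tolist(),
            "n_permutations": res.n_permutations,
            "n_obs": res.n_obs,
        }
        bp = pd.concat([res.x_backprojected.assign(block="cognitive"),
                        res.y_backprojected.assign(block="imaging")])
        bp.index.name = "variable"
        bp.reset_index().to_csv(out / f"backprojection_{phase}.csv", index=False)
    (out / "cca_results.json").write_text(json.dumps(cca_payload, indent=1))
    (out / "run_report.json").write_text(json.dumps(o.report, indent=1, default=str))
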