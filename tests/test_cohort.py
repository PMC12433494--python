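"""Synthetic cohort generator: marginals, ground-truth structure, I/O."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from idoct import cohort
from idoct.cohort import (
    GeneratorConfig,
    TaskSpec,
    default_task_registry,
    derive_phase,
    effective_motor_delay,
    generate_participants,
    generate_trials,
    generate_cohort_trials,
    read_cohort,
    write_cohort,
    LATENT_COLUMNS,
)


def _patients(df):
    return df.loc[df["cohort"] == "patient"]


class TestParticipants:
    def test_empty_patient_list(self):
        df = generate_participants(25, 0, seed=3)
        assert (df["cohort"] == "normative").all()
        assert len(df) == 25

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_participants(-1, 10, seed=0)

    def test_invalid_probability_rejected(self):
        cfg = GeneratorConfig(impairment_rate=1.5)
        with pytest.raises(ValueError):
            generate_participants(10, 10, seed=0, config=cfg)

    def test_demographic_marginals_match_configuration(self):
        """Patient age, NIHSS and impairment prevalence sit within 3 SE of
        the configured cohort parameters at n = 600."""
        n = 600
        df = generate_participants(0, n, seed=11)
        per = df.drop_duplicates("participant_id")
        cfg = GeneratorConfig()
        age_se = cfg.age_patient[1] / np.sqrt(len(per))
        assert abs(per["age"].mean() - cfg.age_patient[0]) < 3 * age_se
        assert per["age"].between(*cfg.age_patient[2:]).all()
        nihss_se = cfg.nihss_sd / np.sqrt(len(per))
        assert abs(per["nihss_baseline"].mean() - cfg.nihss_mean) < 4 * nihss_se
        assert per["nihss_baseline"].between(0, cfg.nihss_max).all()
        rate_se = np.sqrt(cfg.impairment_rate * (1 - cfg.impairment_rate) / len(per))
        assert abs(per["impaired_hand"].mean() - cfg.impairment_rate) < 3 * rate_se

    def test_normative_participants_have_no_stroke_fields(self):
        df = generate_participants(50, 0, seed=2)
        assert (df["impaired_hand"] == 0).all()
        assert df["nihss_baseline"].isna().all()
        assert df["days_since_stroke"].isna().all()

    def test_phase_mapping_is_deterministic(self):
        assert derive_phase(14) == "acute"
        assert derive_phase(15) == "subacute"
        assert derive_phase(180) == "subacute"
        assert derive_phase(181) == "chronic"
        per = _patients(generate_participants(0, 80, seed=5))
        assert (per["phase"] == per["days_since_stroke"].map(derive_phase)).all()

    def test_zero_noise_criterion_tracks_ability_exactly(self):
        """With all criterion noise switched off, the MoCA-like score is an
        exact monotone (affine) function of latent ability."""
        cfg = GeneratorConfig(moca_noise_sd=0.0, iadl_noise_sd=0.0)
        df = generate_participants(0, 500, seed=1, config=cfg)
        clipped = (df["moca"] <= 0) | (df["moca"] >= 30)
        sub = df.loc[~clipped]
        r = np.corrcoef(sub["moca"], sub["latent_ability"])[0, 1]
        assert r > 1 - 1e-12

    def test_imaging_burden_decreases_with_ability(self):
        df = _patients(generate_participants(0, 500, seed=9))
        for col in ("lesion_volume", "wmh_volume"):
            r = stats.spearmanr(df[col], df["latent_ability"]).statistic
            assert r < -0.3, col


class TestTrials:
    def test_zero_conditions_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            TaskSpec("bad", "memory", "low", "low", ())

    def test_unordered_difficulties_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec("bad", "memory", "low", "low", (0.5, 0.1))

    def test_saturated_ability_means_all_correct(self):
        """alpha*(theta - b) >= 10 for every condition forces accuracy 1 on
        every non-censored trial."""
        task = TaskSpec("easy", "memory", "low", "low", (-8.0, -7.5),
                        response_window=1e9, base_answer_time=400.0)
        cfg = GeneratorConfig(session_jitter_sd=0.0, caution_accuracy_weight=0.0)
        parts = generate_participants(0, 30, seed=4, config=cfg)
        parts["latent_ability"] = 1.0
        trials = generate_trials(parts, task, seed=4, config=cfg)
        assert (trials["accuracy"] == 1).all()

    def test_noise_free_rt_has_closed_form(self):
        cfg = GeneratorConfig(rt_noise_median=0.0, session_jitter_sd=0.0,
                              caution_sd=0.0, task_missing_rate=0.0)
        task = TaskSpec("one", "memory", "low", "high", (0.5,),
                        trials_per_condition=4, response_window=1e9,
                        base_answer_time=700.0, difficulty_rt_slope=0.3)
        parts = generate_participants(0, 1, seed=8, config=cfg).iloc[[0]].copy()
        theta = float(parts["latent_ability"].iloc[0])
        delay = float(parts["latent_motor_delay"].iloc[0])
        trials = generate_trials(parts, task, seed=8, config=cfg)
        eta = cfg.rt_ability_slope_high_cog
        encode = cfg.rt_encoding_fraction * 700.0
        operation = (1 - cfg.rt_encoding_fraction) * 700.0 * (1 + 0.3 * 0.0)
        expected = delay + encode + operation * np.exp(-eta * theta)
        assert np.allclose(trials["rt"], expected, atol=1e-9)

    def test_timeouts_are_censored_consistently(self):
        reg = default_task_registry()
        parts = generate_participants(60, 60, seed=6)
        trials = generate_cohort_trials(parts, reg[:6], seed=6)
        to = trials.loc[trials["timed_out"] == 1]
        windows = {t.task_id: t.response_window for t in reg[:6]}
        assert (to["accuracy"] == 0).all()
        assert np.allclose(to["rt"], to["task_id"].map(windows))
        assert (trials["rt"] <= trials["task_id"].map(windows) + 1e-9).all()

    def test_null_motor_generator_removes_group_differences(self):
        """With no impairment delay, no slips and an unbounded window, the
        impaired and unimpaired groups differ only by sampling error."""
        cfg = GeneratorConfig().null_motor()
        task = replace(default_task_registry()[2], response_window=1e9)
        parts = generate_participants(0, 400, seed=7, config=cfg)
        trials = generate_trials(parts, task, seed=7, config=cfg)
        merged = trials.merge(parts[["participant_id", "session_index",
                                     "impaired_hand"]],
                              on=["participant_id", "session_index"])
        acc = merged.groupby(["participant_id", "impaired_hand"])["accuracy"].mean()
        acc = acc.reset_index()
        a = acc.loc[acc["impaired_hand"] == 1, "accuracy"]
        b = acc.loc[acc["impaired_hand"] == 0, "accuracy"]
        assert stats.ttest_ind(a, b).pvalue > 0.01

    def test_impairment_confound_present_by_construction(self):
        """Default slips/fumbles/timeouts make impaired participants' raw
        accuracy lower and their median RT higher in high-motor tasks."""
        reg = [t for t in default_task_registry() if t.motor_demand == "high"]
        parts = generate_participants(0, 400, seed=13)
        trials = generate_cohort_trials(parts, reg[:3], seed=13)
        merged = trials.merge(parts[["participant_id", "session_index",
                                     "impaired_hand"]],
                              on=["participant_id", "session_index"])
        g = merged.groupby("impaired_hand")
        assert g["accuracy"].mean()[1] < g["accuracy"].mean()[0] - 0.05
        assert g["rt"].median()[1] > g["rt"].median()[0] + 50

    def test_early_stopping_truncates_after_consecutive_failures(self):
        task = TaskSpec("stop", "memory", "low", "high",
                        tuple(np.linspace(2.0, 4.0, 4)), trials_per_condition=5,
                        response_window=1e9, early_stop_failures=3)
        cfg = GeneratorConfig(session_jitter_sd=0.0, caution_accuracy_weight=0.0)
        parts = generate_participants(0, 50, seed=3, config=cfg)
        parts["latent_ability"] = -3.0  # fails essentially every trial
        trials = generate_trials(parts, task, seed=3, config=cfg)
        assert trials.groupby(["participant_id", "session_index"]).size().max() <= 4

    def test_effective_delay_boosted_in_high_motor_tasks(self):
        reg = default_task_registry()
        high = next(t for t in reg if t.motor_demand == "high")
        low = next(t for t in reg if t.motor_demand == "low")
        parts = generate_participants(0, 100, seed=5)
        imp = parts.loc[parts["impaired_hand"] == 1]
        d_high = effective_motor_delay(imp, high)
        d_low = effective_motor_delay(imp, low)
        assert (d_high > d_low).all()


class TestIO:
    def test_registry_has_18_unique_tasks(self):
        reg = default_task_registry()
        assert len(reg) == 18
        assert len({t.task_id for t in reg}) == 18
        assert sum(t.motor_demand == "high" for t in reg) >= 4
        assert sum(t.cognitive_demand == "high" for t in reg) >= 4

    def test_cohort_round_trip_is_lossless(self, tmp_path):
        parts = generate_participants(20, 15, seed=21)
        trials = generate_cohort_trials(parts, default_task_registry()[:2], seed=21)
        write_cohort(parts, trials, tmp_path)
        back_p, back_t = read_cohort(tmp_path, with_truth=True)
        pd.testing.assert_frame_equal(
            back_p[parts.columns].reset_index(drop=True), parts,
            check_dtype=False)
        pd.testing.assert_frame_equal(back_t, trials, check_dtype=False)

    def test_truth_is_separated_from_public_tables(self, tmp_path):
        parts = generate_participants(10, 10, seed=22)
        trials = generate_cohort_trials(parts, default_task_registry()[:1], seed=22)
        write_cohort(parts, trials, tmp_path)
        public, _ = read_cohort(tmp_path)
        assert not set(LATENT_COLUMNS) & set(public.columns)
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert set(LATENT_COLUMNS) <= set(truth.columns)

    def test_fixed_seed_gives_byte_identical_files(self, tmp_path):
        for d in ("a", "b"):
            parts = generate_participants(15, 15, seed=33)
            trials = generate_cohort_trials(parts, default_task_registry()[:3], seed=33)
            write_cohort(parts, trials, tmp_path / d)
        for name in ("participants.csv", "trials.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
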