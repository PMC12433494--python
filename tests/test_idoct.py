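"""Trial cleaning, calibration and decomposition of the IDoCT model."""

import numpy as np
import pandas as pd
import pytest

from idoct.model import (
    IDoCTModel,
    IDoCTResults,
    clean_trials,
    decompose_session,
    standard_metrics,
)


def _trials(rows):
    return pd.DataFrame(rows, columns=["participant_id", "task_id",
                                       "session_index", "trial_index",
                                       "condition_label", "accuracy", "rt",
                                       "timed_out"])


def _noise_free_normative(n_participants=6, at=(600.0, 800.0, 1000.0, 1200.0)):
    """Normative cohort with rt exactly equal to a monotone AT curve.

    Accuracy degrades with condition so difficulty is strictly graded.
    """
    rows = []
    acc_by_cond = [1, 1, 1, 0]
    for i in range(n_participants):
        for c, (a_ms, acc) in enumerate(zip(at, acc_by_cond)):
            for k in range(3):
                rows.append((f"n{i}", "t", 0, c * 3 + k, f"c{c + 1:02d}",
                             acc, a_ms, 0))
    return _trials(rows)


class TestCleanTrials:
    def test_all_within_bounds_is_identity(self):
        t = _trials([("p", "t", 0, i, "c01", 1, 400 + i, 0) for i in range(5)])
        kept, report = clean_trials(t, rt_min=200, rt_max=2000)
        pd.testing.assert_frame_equal(kept, t)
        assert report["fraction_removed"].iloc[0] == 0.0

    def test_fraction_removed_counts_fast_trials(self):
        rows = [("p", "t", 0, i, "c01", 1, 50 if i < 3 else 500, 0)
                for i in range(10)]
        kept, report = clean_trials(_trials(rows), rt_min=200, rt_max=2000)
        assert len(kept) == 7
        assert report["fraction_removed"].iloc[0] == pytest.approx(0.3)
        # original order preserved
        assert list(kept["trial_index"]) == sorted(kept["trial_index"])

    def test_timeouts_survive_the_upper_bound(self):
        rows = [("p", "t", 0, 0, "c01", 0, 2000, 1),
                ("p", "t", 0, 1, "c01", 1, 2500, 0)]
        kept, _ = clean_trials(_trials(rows), rt_min=200, rt_max=2000)
        assert list(kept["trial_index"]) == [0]

    def test_empty_input_is_not_an_error(self):
        kept, report = clean_trials(_trials([]), rt_min=200, rt_max=2000)
        assert len(kept) == 0 and len(report) == 0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            clean_trials(_trials([("p", "t", 0, 0, "c01", 1, 400, 0)]),
                         rt_min=2000, rt_max=200)

    def test_default_bounds_exclude_almost_nothing_on_synthetic_data(self):
        from idoct import cohort
        reg = cohort.default_task_registry()[:4]
        parts = cohort.generate_participants(80, 40, seed=17)
        trials = cohort.generate_cohort_trials(parts, reg, seed=17)
        windows = {t.task_id: t.response_window for t in reg}
        _, report = clean_trials(trials, rt_min=200.0, rt_max=windows)
        assert (report["fraction_removed"] < 0.01).all()


class TestStandardMetrics:
    def test_counts_and_median(self):
        rows = [("p", "t", 0, i, "c01", a, rt, 0)
                for i, (a, rt) in enumerate(zip([1, 1, 1, 0, 0],
                                                [400, 500, 600, 700, 800]))]
        out = standard_metrics(_trials(rows))
        assert out["accuracy_count"].iloc[0] == 3
        assert out["trial_count"].iloc[0] == 5
        assert out["median_rt"].iloc[0] == 600

    def test_empty_input_yields_no_rows(self):
        assert len(standard_metrics(_trials([]))) == 0

    def test_timeouts_count_as_errors(self):
        rows = [("p", "t", 0, 0, "c01", 0, 2000, 1),
                ("p", "t", 0, 1, "c01", 1, 600, 0)]
        out = standard_metrics(_trials(rows))
        assert out["accuracy_count"].iloc[0] == 1
        assert out["trial_count"].iloc[0] == 2


class TestCalibration:
    def test_requires_two_participants(self):
        t = _trials([("p", "t", 0, i, "c01", 1, 400 + 10 * i, 0) for i in range(12)])
        with pytest.raises(ValueError, match="2 normative participants"):
            IDoCTModel(t, min_obs=2).fit()

    def test_thin_condition_rejected(self):
        t = _noise_free_normative()
        with pytest.raises(ValueError, match="fewer than"):
            IDoCTModel(t, min_obs=100).fit()

    def test_extreme_conditions_hit_difficulty_bounds(self):
        """All-correct-at-top-speed conditions get D_raw 0; all-incorrect
        conditions get D_raw 1."""
        rows = []
        for i in range(4):
            for k in range(6):
                rows.append((f"p{i}", "t", 0, k, "c01", 1, 100.0, 0))
                rows.append((f"p{i}", "t", 0, 6 + k, "c02", 0, 2000.0, 0))
        res = IDoCTModel(_trials(rows), min_obs=2).fit()
        tb = res.tables["t"]
        assert tb.d_raw["c01"] == pytest.approx(0.0, abs=1e-12)
        assert tb.d_raw["c02"] == pytest.approx(1.0, abs=1e-12)

    def test_ability_correction_raises_selectively_attempted_difficulty(self):
        """Two conditions with identical raw pass rates, but the second is
        attempted only by stronger participants: its scaled difficulty must
        come out higher."""
        rows = []
        # weak pair: label A only, mixed outcomes, slow
        for i, pid in enumerate(["w1", "w2"]):
            for k in range(6):
                rows.append((pid, "t", 0, k, "c01", int(k < 2), 1500.0, 0))
        # strong pair: label A (fast, correct) and label B with the same raw
        # pass rate as A overall
        for pid in ["s1", "s2"]:
            for k in range(6):
                rows.append((pid, "t", 0, k, "c01", 1, 420.0, 0))
            for k in range(6):
                rows.append((pid, "t", 0, 6 + k, "c02", int(k < 4), 700.0, 0))
        res = IDoCTModel(_trials(rows), min_obs=2).fit()
        tb = res.tables["t"]
        attempt_adjustment = tb.d_scaled["c02"] - tb.d_raw["c02"]
        assert attempt_adjustment > 0
        baseline_adjustment = tb.d_scaled["c01"] - tb.d_raw["c01"]
        assert attempt_adjustment > baseline_adjustment

    def test_at_curve_monotone_and_deterministic(self):
        from idoct import cohort
        reg = cohort.default_task_registry()[:2]
        parts = cohort.generate_participants(120, 0, seed=19)
        trials = cohort.generate_cohort_trials(parts, reg, seed=19)
        res1 = IDoCTModel(trials).fit()
        res2 = IDoCTModel(trials).fit()
        for tid, tb in res1.tables.items():
            order = sorted(tb.labels, key=lambda c: tb.d_scaled[c])
            ats = [tb.at_curve[c] for c in order]
            assert all(b >= a - 1e-9 for a, b in zip(ats, ats[1:]))
            assert tb.converged
            tb2 = res2.tables[tid]
            assert tb.at_curve == tb2.at_curve
            assert tb.d_scaled == tb2.d_scaled

    def test_round_trip_through_json(self, tmp_path):
        res = IDoCTModel(_noise_free_normative(), min_obs=2).fit()
        res.to_json(tmp_path / "tables.json")
        back = IDoCTResults.from_json(tmp_path / "tables.json")
        tb, tb2 = res.tables["t"], back.tables["t"]
        assert tb.d_scaled == tb2.d_scaled
        assert tb.at_curve == tb2.at_curve
        assert tb.dt_reference_mean == tb2.dt_reference_mean


class TestDecomposition:
    def test_noise_free_delay_recovered_exactly(self):
        """A patient whose rt is a constant 350 ms above the frozen AT curve
        decomposes to delay_time 350 within tolerance."""
        res = IDoCTModel(_noise_free_normative(), min_obs=2).fit()
        tb = res.tables["t"]
        rows = [("pat", "t", 0, k, f"c{c + 1:02d}", 1, tb.at_curve[f"c{c + 1:02d}"] + 350.0, 0)
                for k, c in enumerate([0, 1, 2, 3] * 3)]
        d = decompose_session(_trials(rows), tb)
        assert d.delay_time == pytest.approx(350.0, abs=1e-6)
        # reconstruction: rt - answer_time is the constant delay per trial
        rts = np.array([r[6] for r in rows])
        assert np.allclose(rts - d.answer_times, d.delay_time, atol=1e-6)

    def test_all_incorrect_session_scores_zero(self):
        res = IDoCTModel(_noise_free_normative(), min_obs=2).fit()
        tb = res.tables["t"]
        rows = [("pat", "t", 0, k, "c02", 0, 900.0, 0) for k in range(6)]
        d = decompose_session(_trials(rows), tb)
        assert d.cognitive_index == 0.0

    def test_slower_answer_times_score_strictly_lower(self):
        """Identical accuracy pattern; the participant with uniformly slower
        answer times gets the lower Cognitive Index."""
        res = IDoCTModel(_noise_free_normative(), min_obs=2).fit()
        tb = res.tables["t"]
        acc = [1, 1, 0, 1, 1, 0]
        conds = ["c01", "c02", "c03", "c01", "c02", "c03"]
        fast = [("fast", "t", 0, k, c, a, tb.at_curve[c] - 250.0, 0)
                for k, (c, a) in enumerate(zip(conds, acc))]
        slow = [("slow", "t", 0, k, c, a, tb.at_curve[c], 0)
                for k, (c, a) in enumerate(zip(conds, acc))]
        d_fast = decompose_session(_trials(fast), tb)
        d_slow = decompose_session(_trials(slow), tb)
        assert np.mean(d_slow.answer_times) > np.mean(d_fast.answer_times)
        assert d_slow.cognitive_index < d_fast.cognitive_index

    def test_unseen_label_is_a_hard_error(self):
        res = IDoCTModel(_noise_free_normative(), min_obs=2).fit()
        rows = [("pat", "t", 0, 0, "c99", 1, 700.0, 0)]
        with pytest.raises(KeyError, match="c99"):
            decompose_session(_trials(rows), res.tables["t"])
        with pytest.raises(KeyError, match="c99"):
            res.decompose(_trials(rows))

    def test_single_trial_session_flagged_low_confidence(self):
        res = IDoCTModel(_noise_free_normative(), min_obs=2).fit()
        rows = [("pat", "t", 0, 0, "c01", 1, 700.0, 0)]
        d = decompose_session(_trials(rows), res.tables["t"])
        assert d.low_confidence
        bulk = res.decompose(_trials(rows), min_usable_fraction=0.0)
        assert bool(bulk["low_confidence"].iloc[0])

    def test_mostly_censored_session_emits_nothing(self):
        res = IDoCTModel(_noise_free_normative(), min_obs=2).fit()
        rows = [("pat", "t", 0, k, "c01", 0, 1200.0, 1) for k in range(5)]
        rows += [("pat", "t", 0, 5, "c01", 1, 700.0, 0)]
        out = res.decompose(_trials(rows))
        assert len(out) == 0

    def test_bulk_matches_single_session_path(self):
        from idoct import cohort
        reg = cohort.default_task_registry()[:1]
        parts = cohort.generate_participants(60, 20, seed=23)
        trials = cohort.generate_cohort_trials(parts, reg, seed=23)
        norm = trials.loc[trials["participant_id"].str.startswith("n")]
        pat = trials.loc[trials["participant_id"].str.startswith("p")]
        res = IDoCTModel(norm).fit()
        bulk = res.decompose(pat, min_usable_fraction=0.0)
        key = bulk.iloc[0]
        sub = pat.loc[(pat["participant_id"] == key["participant_id"])
                      & (pat["session_index"] == key["session_index"])]
        single = decompose_session(sub, res.tables[reg[0].task_id])
        assert single.cognitive_index == pytest.approx(key["cognitive_index"], abs=1e-12)
        assert single.delay_time == pytest.approx(key["delay_time"], abs=1e-9)


class TestHandOracle:
    """Every intermediate on the committed toy table matches independently
    hand-executed formulas to 1e-12 (values frozen in the fixture)."""

    def test_calibration_intermediates(self, toy_fixture):
        trials = pd.DataFrame(toy_fixture["trials"])
        res = IDoCTModel(trials, w=toy_fixture["w"], min_obs=2).fit()
        tb = res.tables["toy"]
        exp = toy_fixture["expected"]
        assert tb.rt_floor == pytest.approx(exp["rt_floor"], abs=1e-12)
        assert tb.rt_ceiling == pytest.approx(exp["rt_ceiling"], abs=1e-12)
        for c in tb.labels:
            assert tb.d_raw[c] == pytest.approx(exp["d_raw"][c], abs=1e-12)
            assert tb.d_scaled[c] == pytest.approx(exp["d_scaled"][c], abs=1e-12)
            assert tb.at_curve[c] == pytest.approx(exp["at_curve"][c], abs=1e-12)
        assert tb.dt_reference_mean == pytest.approx(exp["dt_reference_mean"], abs=1e-12)

    def test_decomposition_intermediates(self, toy_fixture):
        trials = pd.DataFrame(toy_fixture["trials"])
        res = IDoCTModel(trials, w=toy_fixture["w"], min_obs=2).fit()
        tb = res.tables["toy"]
        exp = toy_fixture["expected"]["decomposition"]
        for pid, e in exp.items():
            sub = trials.loc[trials["participant_id"] == pid]
            d = decompose_session(sub, tb)
            assert d.cognitive_index == pytest.approx(e["cognitive_index"], abs=1e-12)
            assert d.delay_time == pytest.approx(e["delay_time"], abs=1e-12)
            assert np.allclose(d.answer_times, e["answer_times"], atol=1e-12)
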