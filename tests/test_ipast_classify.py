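"""Saccade-timing windows, trial categories, and session statistics."""

import numpy as np
import pandas as pd
import pytest

from oculopipe import (CATEGORIES, GeneratorConfig, analyze_session,
                       classify_timing, classify_trial, first_viable_saccade,
                       session_stats, simulate_session)
from oculopipe.io_session import SampleTrace, TrialRecord
from oculopipe.ipast_classify import TrialClassification


@pytest.mark.parametrize("srt, label", [
    (-111, "fixation_break"),
    (-110, "anticipatory"), (89, "anticipatory"),
    (90, "express"), (139, "express"),
    (140, "regular"), (800, "regular"),
    (801, "late"), (1000, "late"),
])
def test_timing_window_boundaries_exact(srt, label):
    assert classify_timing(float(srt)).label == label


def _sacc_row(onset, amp=10.0, start=(0.0, 0.0), dx=10.0, dy=0.0, blincade=False):
    return {"trial_id": 0, "onset_ms": float(onset), "offset_ms": onset + 50.0,
            "start_x": start[0], "start_y": start[1],
            "end_x": start[0] + dx, "end_y": start[1] + dy,
            "amplitude": amp, "angle": float(np.degrees(np.arctan2(dy, dx))),
            "duration_ms": 50.0, "peak_velocity": 300.0,
            "peak_acceleration": 1e4, "blincade": blincade}


def _table(rows):
    return pd.DataFrame(rows)


class TestFirstViable:
    def test_earliest_qualifying_record_wins(self):
        v = first_viable_saccade(_table([_sacc_row(300), _sacc_row(120)]))
        assert v["onset_ms"] == 120

    def test_small_jitter_skipped(self):
        assert first_viable_saccade(
            _table([_sacc_row(150, amp=1.0, dx=1.0)])) is None

    def test_eccentric_launch_skipped(self):
        v = first_viable_saccade(_table([
            _sacc_row(150, start=(6.0, 0.0)), _sacc_row(400)]))
        assert v["onset_ms"] == 400

    def test_blincades_participate(self):
        v = first_viable_saccade(_table([_sacc_row(150, blincade=True)]))
        assert v is not None


def _trial(geometry, condition="PRO", side="right", gaze=None, area=None,
           n=1600):
    T = -2200.0 + np.arange(n) * 2.0
    X = np.zeros(n) if gaze is None else gaze[0]
    Y = np.zeros(n) if gaze is None else gaze[1]
    A = np.full(n, 500.0) if area is None else area
    tr = SampleTrace(T, X, Y, A, np.ones(n, bool), 500.0, units="deg")
    return TrialRecord(trial_id=0, condition=condition, stim_side=side,
                       trace=tr, events={"stim_on": 0.0}, geometry=geometry)


class TestClassifyTrial:
    def test_pro_toward_stim_in_window_is_correct(self, geometry):
        c = classify_trial(_trial(geometry, "PRO", "right"),
                           _table([_sacc_row(120, dx=10.0)]), [])
        assert c.category == "Correct Pro-Saccade"

    def test_anti_toward_stim_is_direction_error(self, geometry):
        c = classify_trial(_trial(geometry, "ANTI", "right"),
                           _table([_sacc_row(150, dx=10.0)]), [])
        assert c.category == "Anti-Saccade Direction Error"

    def test_anticipatory_away_is_anticipatory_correct_anti(self, geometry):
        c = classify_trial(_trial(geometry, "ANTI", "right"),
                           _table([_sacc_row(-50, dx=-10.0)]), [])
        assert c.category == "Anticipatory Correct Anti-Saccade"

    def test_boundary_89_is_anticipatory_90_is_not(self, geometry):
        c89 = classify_trial(_trial(geometry, "PRO", "right"),
                             _table([_sacc_row(89, dx=10.0)]), [])
        c90 = classify_trial(_trial(geometry, "PRO", "right"),
                             _table([_sacc_row(90, dx=10.0)]), [])
        assert c89.category == "Anticipatory Correct Pro-Saccade"
        assert c90.category == "Correct Pro-Saccade"

    def test_late_saccade_still_classifies_up_to_1000(self, geometry):
        c = classify_trial(_trial(geometry, "PRO", "right"),
                           _table([_sacc_row(950, dx=10.0)]), [])
        assert c.category == "Correct Pro-Saccade"

    def test_fixation_held_no_saccade(self, geometry):
        c = classify_trial(_trial(geometry), _table([]), [])
        assert c.category == "No Saccade"

    def test_vertical_saccade_is_random(self, geometry):
        c = classify_trial(_trial(geometry),
                           _table([_sacc_row(200, dx=0.0, dy=8.0, amp=8.0)]), [])
        assert c.category == "Random Saccade"

    def test_gaze_never_near_fix(self, geometry):
        n = 1600
        gaze = (np.full(n, 6.0), np.full(n, 4.0))
        c = classify_trial(_trial(geometry, gaze=gaze), _table([]), [])
        assert c.category == "Never Fixated"

    def test_eye_loss_dominates(self, geometry):
        n = 1600
        area = np.full(n, 500.0)
        T = -2200.0 + np.arange(n) * 2.0
        area[(T >= -1200) & (T <= 800)] = 0.0
        c = classify_trial(_trial(geometry, area=area), _table([]), [])
        assert c.category == "Eye Loss"

    def test_unmarked_trial_reserved_category(self, geometry):
        rec = _trial(geometry)
        rec.not_marked = True
        c = classify_trial(rec, _table([]), [])
        assert c.category == "Not marked"

    def test_transient_break_sets_lapse_and_defers(self, geometry):
        n = 1600
        X = np.zeros(n)
        T = -2200.0 + np.arange(n) * 2.0
        X[(T >= -700) & (T <= -500)] = 5.0  # breaks, returns before FIX off
        c = classify_trial(_trial(geometry, gaze=(X, np.zeros(n))),
                           _table([_sacc_row(120, dx=10.0)]), [])
        assert c.lapse_flag
        assert c.category == "Correct Pro-Saccade"

    def test_unreturned_break_is_fixation_break(self, geometry):
        n = 1600
        X = np.zeros(n)
        T = -2200.0 + np.arange(n) * 2.0
        X[T >= -600] = 10.0
        c = classify_trial(_trial(geometry, gaze=(X, np.zeros(n))),
                           _table([]), [])
        assert c.category == "Fixation Break"


def _cls(cond, cat, n):
    return [TrialClassification(i, cond, cat, None, False) for i in range(n)]


class TestSessionStats:
    def test_hand_worked_error_rate_and_ratio(self):
        cls = (_cls("ANTI", "Correct Anti-Saccade", 40)
               + _cls("ANTI", "Anti-Saccade Direction Error", 10)
               + _cls("ANTI", "Fixation Break", 10))
        s = session_stats(cls)
        assert s.error_ratio == pytest.approx(10 / 50)
        assert s.error_rate == pytest.approx(10 / 60)
        assert s.error_ratio >= s.error_rate

    def test_zero_errors(self):
        s = session_stats(_cls("ANTI", "Correct Anti-Saccade", 30))
        assert s.error_rate == 0.0 and s.error_ratio == 0.0

    def test_all_correct_no_non_compliance(self):
        s = session_stats(_cls("PRO", "Correct Pro-Saccade", 25))
        assert s.non_compliance_rate == 0.0

    def test_zero_denominator_reported_missing(self):
        s = session_stats(_cls("PRO", "Correct Pro-Saccade", 5))
        assert s.error_rate is None and s.error_ratio is None

    def test_counts_partition_trials(self):
        cls = (_cls("PRO", "Correct Pro-Saccade", 7)
               + _cls("ANTI", "Never Fixated", 3)
               + _cls("ANTI", "No Saccade", 2))
        s = session_stats(cls)
        total = sum(sum(v.values()) for v in s.counts.values())
        assert total == s.n_trials == 12
        assert s.non_compliance_rate == pytest.approx(5 / 12)


def test_generative_labels_recovered(small_session):
    trials, truth = small_session
    res = analyze_session(trials)
    agree = sum(1 for c, t in zip(res.classifications, truth.trials)
                if c.category == t.category)
    assert agree >= 0.95 * len(trials)
    # exactly one category per trial, all from the published taxonomy
    assert len(res.classifications) == len(trials)
    assert all(c.category in CATEGORIES for c in res.classifications)
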