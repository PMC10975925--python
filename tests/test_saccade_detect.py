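"""Dynamic thresholds, candidate events, PSO merging, boomerangs, blincades,
and main-sequence Z-scores."""

import numpy as np
import pandas as pd
import pytest

from oculopipe import (GeneratorConfig, SampleTrace, analyze_session,
                       compute_velocity, detect_candidates, dynamic_threshold,
                       filter_by_masez, main_sequence_zscores, merge_pso,
                       saccade_table, simulate_session, split_boomerang)
from oculopipe.saccade_detect import measure_event
from oculopipe.synthgen import simulate_blincade_trial


class TestDynamicThreshold:
    def _thr(self, values):
        speed = np.array(values, dtype=float)
        T = np.arange(len(speed)) * 2.0 - 700.0
        return dynamic_threshold(speed, T, (-700.0, -200.0))

    def test_low_noise_hits_floor(self):
        # mean 5, SD 4 -> 5 + 2.5*4 = 15 -> floored at 20
        thr = self._thr([1.0, 9.0] * 60)
        assert thr.value == 20.0
        assert thr.noise_mean == pytest.approx(5.0)
        assert thr.noise_sd == pytest.approx(4.0)

    def test_noisy_trial_raises_threshold(self):
        # mean 10, SD 8 -> 30
        thr = self._thr([2.0, 18.0] * 60)
        assert thr.value == pytest.approx(30.0)

    def test_empty_qualifying_set_falls_back(self):
        speed = np.full(120, 80.0)  # all above the 50 deg/s ceiling
        T = np.arange(120) * 2.0 - 700.0
        with pytest.warns(UserWarning):
            thr = dynamic_threshold(speed, T, (-700.0, -200.0))
        assert thr.value == 20.0


class TestDetectCandidates:
    def test_single_lobe_spanned(self):
        speed = np.zeros(200)
        speed[50:70] = 100.0  # 40 ms
        (ev,) = detect_candidates(speed, 20.0, 500.0)
        assert ev == (50, 70)

    def test_short_spike_discarded(self):
        speed = np.zeros(200)
        speed[50:54] = 100.0  # 8 ms < 10 ms
        assert detect_candidates(speed, 20.0, 500.0) == []

    def test_two_lobes_two_events(self):
        speed = np.zeros(300)
        speed[50:70] = 100.0
        speed[100:130] = 150.0
        assert len(detect_candidates(speed, 20.0, 500.0)) == 2


def _single_saccade_vel(amp=8.0, noise=0.0, seed=0, slosh=0.0):
    cfg = GeneratorConfig(n_trials=1, seed=seed, noise_sd_deg=noise,
                          slosh_gain=slosh, blink_rate_per_trial=0.0,
                          p_fixation_break=0, p_no_saccade=0, p_random_saccade=0,
                          p_never_fixated=0, p_eye_loss=0, p_anticipatory=0,
                          p_direction_error_pro=0, p_direction_error_anti=0,
                          drift_offset_sd_deg=0.0)
    trials, truth = simulate_session(cfg)
    from oculopipe import pixels_to_degrees
    rec = trials[0]
    tr = pixels_to_degrees(rec.trace, rec.geometry)
    vel = compute_velocity(tr, 3)
    return tr, vel, truth.trials[0]


def test_noise_free_onsets_match_brute_force_scan():
    """Equivalence oracle: detected bounds equal a literal threshold scan."""
    tr, vel, _ = _single_saccade_vel(noise=0.0)
    thr = 20.0
    events = detect_candidates(vel.speed, thr, 500.0)
    # brute force: walk the speed vector sample by sample
    runs, start = [], None
    for i, s in enumerate(vel.speed):
        if s > thr and start is None:
            start = i
        elif s <= thr and start is not None:
            if i - start >= 5:
                runs.append((start, i))
            start = None
    assert events == runs


class TestMergePso:
    def _events(self, speed_segments, xs):
        """Build records from an artificial speed/position layout."""
        n = 600
        T = np.arange(n) * 2.0
        speed = np.zeros(n)
        x = np.zeros(n)
        for (i0, i1, v), (xa, xb) in zip(speed_segments, xs):
            speed[i0:i1] = v
            x[i0:i1] = np.linspace(xa, xb, i1 - i0)
            x[i1:] = xb
        from oculopipe.kinematics import VelocityTrace
        vel = VelocityTrace(velX=speed, velY=np.zeros(n), speed=speed,
                            smoothing_w=1, xs=x, ys=np.zeros(n))
        evs = [measure_event(0, i0, i1, T, vel, 0.002)
               for i0, i1, _ in speed_segments]
        return evs, T, vel

    def test_small_close_follower_absorbed(self):
        evs, T, vel = self._events([(50, 90, 300.0), (100, 110, 60.0)],
                                   [(0.0, 10.0), (10.0, 11.0)])
        out = merge_pso(evs, T, vel, 0.002)
        assert len(out) == 1
        assert out[0].pso_merged
        assert out[0].end_x == pytest.approx(11.0)
        assert out[0].pso_end_ms == out[0].offset_ms

    def test_distant_follower_kept(self):
        evs, T, vel = self._events([(50, 90, 300.0), (120, 135, 60.0)],
                                   [(0.0, 10.0), (10.0, 11.0)])
        assert len(merge_pso(evs, T, vel, 0.002)) == 2  # 60 ms gap

    def test_large_follower_kept(self):
        evs, T, vel = self._events([(50, 90, 300.0), (100, 130, 200.0)],
                                   [(0.0, 10.0), (10.0, 16.0)])
        assert len(merge_pso(evs, T, vel, 0.002)) == 2  # 6 deg follower

    def test_merged_amplitude_is_start_to_pso_end(self):
        evs, T, vel = self._events([(50, 90, 300.0), (100, 110, 60.0)],
                                   [(0.0, 10.0), (10.0, 9.0)])
        out = merge_pso(evs, T, vel, 0.002)
        assert out[0].amplitude == pytest.approx(9.0)


class TestBoomerang:
    def test_fused_opposed_pair_split(self):
        cfg = GeneratorConfig(n_trials=30, seed=21, blink_rate_per_trial=0.0,
                              slosh_gain=0.4, boomerang_prob=1.0,
                              p_direction_error_anti=1.0,
                              p_fixation_break=0, p_no_saccade=0,
                              p_random_saccade=0, p_never_fixated=0,
                              p_eye_loss=0, p_anticipatory=0)
        trials, truth = simulate_session(cfg)
        res = analyze_session(trials)
        n_pairs = n_true = 0
        for t in truth.trials:
            if not t.boomerang:
                continue
            n_true += 1
            d = res.saccades[(res.saccades.trial_id == t.trial_id)
                             & (res.saccades.amplitude >= 2)].sort_values("onset_ms")
            d = d[(d.onset_ms > t.srt_ms - 30) & (d.onset_ms < t.srt_ms + 250)]
            if len(d) >= 2:
                dx = (d.end_x - d.start_x).to_numpy()
                if dx[0] * dx[1] < 0:
                    n_pairs += 1
        assert n_true >= 10
        assert n_pairs / n_true >= 0.9

    def test_ordinary_saccade_not_split(self):
        tr, vel, _ = _single_saccade_vel(noise=0.05, seed=5, slosh=0.5)
        events = detect_candidates(vel.speed, 20.0, 500.0)
        for i0, i1 in events:
            ev = measure_event(0, i0, i1, tr.T, vel, 0.002)
            if ev.amplitude < 2:
                continue
            out = split_boomerang(ev, tr.T, vel, 0.002, 500.0)
            assert len(out) == 1 and out[0].boomerang_half == "none"

    def test_moderate_direction_change_not_split(self):
        # a curved oblique movement (40 deg direction change) stays single
        n = 400
        T = np.arange(n) * 2.0
        th = np.linspace(0, np.radians(40), 30)
        x = np.zeros(n)
        y = np.zeros(n)
        x[100:130] = np.cumsum(0.4 * np.cos(th))
        y[100:130] = np.cumsum(0.4 * np.sin(th))
        x[130:] = x[129]
        y[130:] = y[129]
        tr = SampleTrace(T, x, y, np.full(n, 500.0), np.ones(n, bool), 500.0,
                         units="deg")
        vel = compute_velocity(tr, 3)
        events = detect_candidates(vel.speed, 20.0, 500.0)
        assert len(events) == 1
        ev = measure_event(0, *events[0], T, vel, 0.002)
        out = split_boomerang(ev, T, vel, 0.002, 500.0)
        assert len(out) == 1 and out[0].boomerang_half == "none"


class TestBlincades:
    def test_near_zero_net_artifact_becomes_blink(self):
        cfg = GeneratorConfig(seed=5)
        for k in range(5):
            trial = simulate_blincade_trial(cfg, 0, net_dx_deg=0.3, seed=300 + k)
            res = analyze_session([trial], do_classify=False, do_pupil=False)
            assert res.saccades.blincade.sum() == 0
            assert (res.blinks.category == "blink").any()

    def test_large_net_artifact_becomes_one_blincade(self):
        cfg = GeneratorConfig(seed=5)
        for k in range(5):
            trial = simulate_blincade_trial(cfg, 0, net_dx_deg=8.0, seed=400 + k)
            res = analyze_session([trial], do_classify=False, do_pupil=False)
            b = res.saccades[res.saccades.blincade]
            assert len(b) == 1
            assert b.iloc[0].amplitude == pytest.approx(8.0, abs=0.8)

    def test_loss_free_saccade_untouched(self):
        tr, vel, _ = _single_saccade_vel(noise=0.05, seed=9)
        from oculopipe.saccade_detect import detect_saccades_trial
        _, events, reclassified = detect_saccades_trial(
            0, tr.T, vel, 500.0, (-700.0, -200.0), blinks=[])
        assert reclassified == []
        assert not any(e.blincade for e in events)


def _masez_table(n=200, seed=0, sd=10.0):
    rng = np.random.default_rng(seed)
    amp = rng.uniform(2, 15, n)
    pv = 500 * (1 - np.exp(-amp / 12))
    dur = 2.4 * amp + 47
    rows = pd.DataFrame({
        "trial_id": np.arange(n), "onset_ms": 0.0, "offset_ms": 50.0,
        "start_x": 0.0, "start_y": 0.0, "end_x": amp, "end_y": 0.0,
        "amplitude": amp, "angle": 0.0, "duration_ms": dur,
        "peak_velocity": pv + rng.normal(0, sd, n),
        "peak_acceleration": 0.0, "pso_merged": False, "pso_end_ms": np.nan,
        "boomerang_half": "none", "boomerang_unsplit": False,
        "blincade": False, "interpolated": False, "lapse_flag": False,
        "masez_amp": np.nan, "masez_dur": np.nan,
    })
    return rows


class TestMainSequenceZscores:
    def test_on_curve_record_scores_near_zero(self):
        table = _masez_table(sd=10.0)
        scored, meta = main_sequence_zscores(table)
        assert meta["fitted"]
        # residual SD should be close to the injected noise SD
        assert meta["resid_sd_amp"] == pytest.approx(10.0, rel=0.2)
        assert np.abs(scored["masez_amp"]).mean() < 1.0

    def test_constructed_outlier_scores_five_sigma(self):
        table = _masez_table(sd=10.0, seed=1)
        scored, meta = main_sequence_zscores(table)
        sd = meta["resid_sd_amp"]
        # construct an outlier exactly 5 fitted-residual SDs above the fit,
        # flagged so it cannot perturb the refit
        probe = scored.iloc[[100]].copy()
        fit_at_probe = probe["peak_velocity"].iloc[0] - probe["masez_amp"].iloc[0] * sd
        probe["peak_velocity"] = fit_at_probe + 5 * sd
        probe["blincade"] = True
        table2 = pd.concat([table, probe], ignore_index=True)
        scored2, _ = main_sequence_zscores(table2)
        assert scored2["masez_amp"].iloc[-1] == pytest.approx(5.0, abs=0.2)

    def test_flagged_records_excluded_from_fit_but_scored(self):
        table = _masez_table(sd=10.0, seed=2)
        table.loc[:4, "blincade"] = True
        scored, meta = main_sequence_zscores(table)
        assert meta["n_clean"] == len(table) - 5
        assert np.isfinite(scored.loc[:4, "masez_amp"]).all()

    def test_too_few_clean_saccades_gives_missing_scores(self):
        table = _masez_table(n=20, seed=3)
        scored, meta = main_sequence_zscores(table)
        assert not meta["fitted"]
        assert scored["masez_amp"].isna().all()


class TestFilterByMasez:
    def test_retention_and_exclusion(self):
        table = _masez_table(n=40, seed=4)
        table["masez_amp"] = 0.5
        table["masez_dur"] = 1.0
        table.loc[0, "masez_amp"] = 4.0
        out = filter_by_masez(table, zcrit=3.29)
        assert len(out) == 39
        assert 0 not in out.index

    def test_infinite_cut_is_identity(self):
        table = _masez_table(n=10, seed=5)
        table["masez_amp"] = table["masez_dur"] = 100.0
        assert len(filter_by_masez(table, zcrit=np.inf)) == 10


def test_saccade_table_columns_roundtrip():
    tr, vel, _ = _single_saccade_vel(noise=0.05, seed=2)
    events = detect_candidates(vel.speed, 20.0, 500.0)
    recs = [measure_event(0, i0, i1, tr.T, vel, 0.002) for i0, i1 in events]
    df = saccade_table(recs)
    assert {"trial_id", "amplitude", "angle", "peak_velocity",
            "duration_ms", "blincade"} <= set(df.columns)
    assert (df["offset_ms"] > df["onset_ms"]).all()
    assert (df["amplitude"] >= 0).all()
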