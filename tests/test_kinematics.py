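"""Unit conversion, zero-phase smoothing, velocity, and drift re-referencing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculopipe import (SampleTrace, central_velocity, compute_velocity,
                       degrees_to_pixels, drift_reference, euclidean_speed,
                       pixels_to_degrees, zero_phase_boxcar)
from oculopipe.io_session import TrialRecord


def _trace_px(X, Y, geometry, rate=500.0):
    n = len(X)
    return SampleTrace(np.arange(n) * 1000.0 / rate, np.asarray(X, float),
                       np.asarray(Y, float), np.full(n, 500.0),
                       np.ones(n, bool), rate, units="px")


class TestPixelsToDegrees:
    def test_screen_center_maps_to_origin(self, geometry):
        tr = _trace_px([640.0], [512.0], geometry)
        out = pixels_to_degrees(tr, geometry)
        assert out.X[0] == pytest.approx(0.0)
        assert out.Y[0] == pytest.approx(0.0)

    def test_known_offset_gives_ten_degrees(self, geometry):
        # 10.58 cm right of center at 60 cm viewing distance -> atan = 10.0 deg
        px = 640.0 + 10.58 / geometry.cm_per_px_x
        out = pixels_to_degrees(_trace_px([px], [512.0], geometry), geometry)
        assert out.X[0] == pytest.approx(np.degrees(np.arctan(10.58 / 60)), abs=1e-9)
        assert out.X[0] == pytest.approx(10.0, abs=0.01)

    def test_left_right_symmetry(self, geometry):
        out = pixels_to_degrees(_trace_px([640 - 100, 640 + 100],
                                          [512.0, 512.0], geometry), geometry)
        assert out.X[0] == pytest.approx(-out.X[1])

    def test_round_trip_inversion(self, geometry, rng):
        xd = rng.uniform(-15, 15, 50)
        yd = rng.uniform(-12, 12, 50)
        px, py = degrees_to_pixels(xd, yd, geometry)
        out = pixels_to_degrees(_trace_px(px, py, geometry), geometry)
        bx, by = degrees_to_pixels(out.X, out.Y, geometry)
        assert np.max(np.abs(bx - px)) < 1e-9
        assert np.max(np.abs(by - py)) < 1e-9

    def test_zero_distance_rejected(self, geometry):
        import dataclasses
        with pytest.raises(ValueError):
            dataclasses.replace(geometry, distance_cm=0.0)


def _brute_force_filtfilt_boxcar(x, w):
    """Oracle: explicit forward-then-backward moving average on the
    odd-reflection-padded signal, trimmed back."""
    pad = 3 * (w - 1)
    left = 2 * x[0] - x[pad:0:-1]
    right = 2 * x[-1] - x[-2:-pad - 2:-1]
    ext = np.concatenate([left, x, right])
    b = np.ones(w) / w

    def causal(sig):
        out = np.zeros_like(sig)
        for i in range(len(sig)):
            acc = 0.0
            for k in range(w):
                if i - k >= 0:
                    acc += b[k] * sig[i - k]
            out[i] = acc
        return out

    fwd = causal(ext)
    bwd = causal(fwd[::-1])[::-1]
    return bwd[pad:len(ext) - pad] if pad else bwd


class TestZeroPhaseBoxcar:
    def test_constant_preserved(self):
        x = np.full(50, 7.25)
        assert np.allclose(zero_phase_boxcar(x, 5), x)

    def test_impulse_response_symmetric(self):
        x = np.zeros(101)
        x[50] = 1.0
        y = zero_phase_boxcar(x, 3)
        assert np.allclose(y, y[::-1])
        assert np.argmax(y) == 50  # zero phase: no lag

    @pytest.mark.parametrize("w", [2, 3, 5])
    def test_matches_brute_force_oracle(self, w, rng):
        x = np.cumsum(rng.normal(size=60))  # smooth-ish random walk
        assert np.allclose(zero_phase_boxcar(x, w),
                           _brute_force_filtfilt_boxcar(x, w), atol=1e-9)

    def test_linear_ramp_interior_unchanged(self):
        x = np.arange(40.0)
        y = zero_phase_boxcar(x, 3)
        assert np.allclose(y[5:-5], x[5:-5], atol=1e-9)

    def test_too_short_input_names_minimum(self):
        with pytest.raises(ValueError, match="13"):
            zero_phase_boxcar(np.zeros(12), 5)

    def test_no_lag_on_band_limited_signal(self):
        # a pulse (band-limited by its Gaussian envelope) must not shift
        t = np.arange(400) * 0.002
        x = np.exp(-((t - 0.4) / 0.05) ** 2) * np.sin(2 * np.pi * 8 * t)
        y = zero_phase_boxcar(x, 5)
        xc = np.correlate(y, x, mode="full")
        assert np.argmax(xc) == len(x) - 1  # peak at lag 0


class TestCentralVelocity:
    def test_linear_ramp_exact(self):
        v = central_velocity(np.array([0.0, 2.0, 4.0, 6.0]), dt=0.002)
        assert np.allclose(v, 1000.0)

    def test_constant_is_zero(self):
        assert np.allclose(central_velocity(np.full(10, 3.3), 0.002), 0.0)

    def test_two_point_endpoint_rule(self):
        assert np.allclose(central_velocity(np.array([0.0, 1.0]), 0.002),
                           [500.0, 500.0])

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            central_velocity(np.array([1.0]), 0.002)

    def test_recovers_analytic_sinusoid_to_second_order(self):
        dt = 0.002
        t = np.arange(0, 1, dt)
        x = np.sin(2 * np.pi * 2 * t)
        v_true = 2 * np.pi * 2 * np.cos(2 * np.pi * 2 * t)
        v = central_velocity(x, dt)
        interior = slice(1, -1)
        assert np.max(np.abs(v[interior] - v_true[interior])) < \
            (2 * np.pi * 2) ** 3 * dt ** 2  # O(dt^2) bound


@given(vx=st.floats(-1e3, 1e3), vy=st.floats(-1e3, 1e3))
@settings(deadline=None, max_examples=50)
def test_speed_is_euclidean_norm(vx, vy):
    s = euclidean_speed(np.array([vx]), np.array([vy]))[0]
    assert s == pytest.approx(np.hypot(vx, vy))
    assert s <= abs(vx) + abs(vy) + 1e-12


def test_speed_345():
    assert euclidean_speed(np.array([300.0]), np.array([400.0]))[0] == 500.0


def _fix_trial(geometry, x_deg, y_deg, n=600, sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    T = -1400.0 + np.arange(n) * 2.0  # spans the fixation epoch
    X = np.full(n, float(x_deg)) + rng.normal(0, sd, n)
    Y = np.full(n, float(y_deg)) + rng.normal(0, sd, n)
    tr = SampleTrace(T, X, Y, np.full(n, 500.0), np.ones(n, bool), 500.0,
                     units="deg")
    return TrialRecord(trial_id=0, condition="PRO", stim_side="left", trace=tr,
                       events={}, geometry=geometry)


class TestDriftReference:
    def test_constant_fixation_recovered_exactly(self, geometry):
        rec = _fix_trial(geometry, 1.2, -0.4)
        vel = compute_velocity(rec.trace, 3)
        off = drift_reference([rec], [vel])
        assert off.dx == pytest.approx(1.2, abs=1e-9)
        assert off.dy == pytest.approx(-0.4, abs=1e-9)

    def test_bimodal_tie_broken_toward_zero(self, geometry):
        recs = [_fix_trial(geometry, -1.02, 0.0), _fix_trial(geometry, 1.02, 0.0)]
        vels = [compute_velocity(r.trace, 3) for r in recs]
        off1 = drift_reference(recs, vels)
        off2 = drift_reference(recs, vels)
        assert off1.dx == off2.dx  # deterministic
        assert abs(off1.dx) == pytest.approx(1.02)  # mass sits at +-1.02
        assert off1.dx < 0  # the negative bin center lies nearer zero

    def test_noisy_fixation_mode_within_tolerance(self, geometry):
        recs = [_fix_trial(geometry, 0.5, 0.5, sd=0.1, seed=s) for s in range(4)]
        vels = [compute_velocity(r.trace, 3) for r in recs]
        off = drift_reference(recs, vels)
        assert off.dx == pytest.approx(0.5, abs=0.1)
        assert off.n_samples_used > 900

    def test_too_few_samples_warns_and_zeroes(self, geometry):
        rec = _fix_trial(geometry, 2.0, 2.0, n=40)
        vel = compute_velocity(rec.trace, 3)
        with pytest.warns(UserWarning, match="qualifying"):
            off = drift_reference([rec], [vel], min_samples=100)
        assert (off.dx, off.dy) == (0.0, 0.0)
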