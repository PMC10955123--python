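"""Dynamometer preprocessing: filtering, segmentation, phase extraction,
fixed-grid interpolation."""

import numpy as np
import pytest

from ecctrain.isokin import (
    DynamometerTrial,
    IsokineticPhase,
    RepetitionSegment,
    extract_isokinetic_phase,
    filter_trial,
    filter_zero_lag,
    normalize_to_body_mass,
    segment_repetitions,
    to_normalized_curve,
)
from ecctrain.synth import TrialSpec, simulate_active_trial, simulate_passive_trial

FS = 200.0


def _trial_from_arrays(angle, torque, velocity, fs=FS, **meta):
    n = len(angle)
    meta.setdefault("sampling_rate", fs)
    return DynamometerTrial(
        time=np.arange(n) / fs, angle=np.asarray(angle, float),
        torque=np.asarray(torque, float),
        velocity=np.asarray(velocity, float), meta=meta,
    )


class TestFilter:
    def test_dc_gain_is_one(self):
        x = np.ones(400)
        assert np.allclose(filter_zero_lag(x, FS), 1.0, atol=1e-9)

    def test_50hz_sine_strongly_attenuated(self):
        t = np.arange(0, 10, 1 / FS)
        y = filter_zero_lag(np.sin(2 * np.pi * 50 * t), FS)
        # squared Butterworth magnitude at 50 Hz: (6/50)^10 ~ 6e-10;
        # discard the filter's edge transients, keep the steady state
        assert np.abs(y[600:-600]).max() <= 1e-6

    def test_1hz_sine_passes_unchanged(self):
        t = np.arange(0, 10, 1 / FS)
        y = filter_zero_lag(np.sin(2 * np.pi * 1.0 * t), FS)
        assert np.abs(y[400:-400]).max() == pytest.approx(1.0, rel=0.01)

    def test_zero_lag_property(self):
        # cross-correlation of band-limited input and output peaks at lag 0
        rng = np.random.default_rng(0)
        x = filter_zero_lag(rng.standard_normal(2000), FS, cutoff=20)
        y = filter_zero_lag(x, FS)
        lags = np.arange(-50, 51)
        xc = [np.dot(x[50:-50], y[50 + k:len(y) - 50 + k]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_short_series_error_names_minimum(self):
        with pytest.raises(ValueError, match="need more than"):
            filter_zero_lag(np.ones(10), FS)


class TestSegmentation:
    def test_three_rep_alternating_trial_gives_six_directional_segments(self):
        spec = TrialSpec(mode="eccentric", noise_sd_torque=0.0, seed=0)
        trial, _ = simulate_active_trial(spec, 40.0, 20.0, n_reps=3)
        segs = segment_repetitions(trial)
        assert len(segs) == 6
        assert sum(s.direction == "external" for s in segs) == 3
        assert sum(s.direction == "internal" for s in segs) == 3
        # segments are disjoint and ordered
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.stop <= b.start

    def test_monotone_ramp_is_single_segment(self):
        n = 400
        trial = _trial_from_arrays(
            np.linspace(0, 60, n), np.zeros(n), np.full(n, 30.0)
        )
        segs = segment_repetitions(trial)
        assert len(segs) == 1
        assert segs[0].direction == "external"
        assert (segs[0].start, segs[0].stop) == (0, n)

    def test_passive_ten_cycle_trial_gives_twenty_segments(self):
        spec = TrialSpec(mode="passive", target_speed=10.0, rom_start=0.0,
                         rom_end=140.0, noise_sd_torque=0.0, seed=0)
        trial, _ = simulate_passive_trial(spec, (0.5, 0.05, 0.0), 10)
        assert len(segment_repetitions(trial)) == 20

    def test_zero_velocity_warns_single_segment(self):
        n = 400
        trial = _trial_from_arrays(np.zeros(n), np.zeros(n), np.zeros(n))
        with pytest.warns(UserWarning):
            segs = segment_repetitions(trial)
        assert len(segs) == 1


class TestIsokineticPhase:
    def test_generator_plateau_recovered_exactly(self, active_trial):
        trial, truth = active_trial
        segs = segment_repetitions(trial)
        phase = extract_isokinetic_phase(segs[0], 30.0)
        a, b = truth["plateau_ranges"][0]
        # the plateau holds |v| = target exactly; the band adds the ramp
        # samples within 10% of target (a fixed kinematic margin)
        ramp_margin = int(round(0.10 * 0.2 * FS))  # 10% of the 0.2 s ramp
        assert abs(phase.start - a) <= ramp_margin
        assert abs(phase.stop - b) <= ramp_margin + 1
        assert phase.achieved_speed == pytest.approx(30.0, rel=0.01)

    def test_constant_velocity_keeps_whole_segment(self):
        n = 300
        trial = _trial_from_arrays(
            np.linspace(0, 50, n), np.ones(n), np.full(n, 30.0)
        )
        seg = segment_repetitions(trial)[0]
        phase = extract_isokinetic_phase(seg, 30.0)
        assert (phase.start, phase.stop) == (0, n)

    def test_velocity_below_band_raises(self):
        n = 300
        trial = _trial_from_arrays(
            np.linspace(0, 50, n), np.ones(n), np.full(n, 15.0)
        )
        seg = segment_repetitions(trial)[0]
        with pytest.raises(ValueError, match="no isokinetic phase"):
            extract_isokinetic_phase(seg, 30.0)

    def test_idempotence_on_extracted_output(self):
        n = 300
        trial = _trial_from_arrays(
            np.linspace(0, 50, n), np.ones(n), np.full(n, 30.0)
        )
        seg = segment_repetitions(trial)[0]
        p1 = extract_isokinetic_phase(seg, 30.0)
        sub = RepetitionSegment(p1.start, p1.stop, seg.direction, trial)
        p2 = extract_isokinetic_phase(sub, 30.0)
        assert (p2.start, p2.stop) == (p1.start, p1.stop)


class TestNormalization:
    def test_body_mass_division(self):
        out = normalize_to_body_mass([45.63], 89.2)
        assert out[0] == pytest.approx(0.5116, abs=1e-4)

    def test_unit_mass_identity_and_zeros(self):
        x = np.array([0.0, 1.5, 3.0])
        assert np.array_equal(normalize_to_body_mass(x, 1.0), x)
        assert np.all(normalize_to_body_mass(np.zeros(3), 70.0) == 0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_body_mass([1.0], 0.0)


class TestNormalizedCurve:
    def _phase(self, angle, torque):
        n = len(angle)
        v = np.gradient(np.asarray(angle, float)) * FS
        trial = _trial_from_arrays(angle, torque, v, body_mass=1.0)
        seg = RepetitionSegment(0, n, "external", trial)
        return IsokineticPhase(0, n, seg, 30.0)

    def test_linear_torque_reproduced_exactly(self):
        ang = np.linspace(10, 70, 240)
        trq = 2.0 * ang + 5.0
        curve = to_normalized_curve(self._phase(ang, trq))
        assert curve.n_nodes == 101
        assert np.allclose(curve.torque, 2.0 * curve.angle_grid + 5.0, atol=1e-9)

    def test_endpoints_preserved(self):
        ang = np.linspace(0, 50, 150)
        trq = np.sin(ang / 10.0) + 2
        curve = to_normalized_curve(self._phase(ang, trq))
        assert curve.torque[0] == pytest.approx(trq[0])
        assert curve.torque[-1] == pytest.approx(trq[-1])

    def test_smooth_bell_interpolation_error_small(self):
        ang = np.linspace(-50, 80, 1000)
        peak, opt, width = 40.0, 20.0, 35.0
        bell = lambda a: peak * np.exp(-((a - opt) ** 2) / (2 * width**2))
        curve = to_normalized_curve(self._phase(ang, bell(ang)))
        assert np.abs(curve.torque - bell(curve.angle_grid)).max() < 1e-3 * peak

    def test_reversed_movement_keeps_movement_order(self):
        ang = np.linspace(70, 10, 240)
        trq = 2.0 * ang
        curve = to_normalized_curve(self._phase(ang, trq))
        assert curve.angle_start == pytest.approx(70.0)
        assert curve.angle_end == pytest.approx(10.0)
        assert curve.torque[0] == pytest.approx(140.0)

    def test_degenerate_span_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            to_normalized_curve(self._phase(np.full(50, 5.0), np.ones(50)))

    def test_scaling_equivariance(self):
        ang = np.linspace(0, 60, 200)
        trq = np.cos(ang / 20.0) + 2.0
        c1 = to_normalized_curve(self._phase(ang, trq))
        c2 = to_normalized_curve(self._phase(ang, 3.0 * trq))
        assert np.allclose(c2.torque, 3.0 * c1.torque)
        # normalization cancels a joint (torque, mass) scaling
        c3 = to_normalized_curve(self._phase(ang, 3.0 * trq), body_mass=3.0)
        assert np.allclose(c3.torque, c1.torque)


class TestFilterTrial:
    def test_pipeline_on_generated_trial_preserves_plateau_speed(self):
        spec = TrialSpec(mode="eccentric", noise_sd_torque=0.5, seed=2)
        trial, truth = simulate_active_trial(spec, 40.0, 20.0, 3)
        filt = filter_trial(trial)
        segs = [s for s in segment_repetitions(filt) if s.direction == "external"]
        phase = extract_isokinetic_phase(segs[0], 30.0)
        assert phase.achieved_speed == pytest.approx(30.0, rel=0.02)
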