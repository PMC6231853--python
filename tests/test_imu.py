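"""Orientation estimation and ROM extraction against analytic oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from siteless.imu import (G, IMUTrace, ROMResult, RomSettings,
                          TraceFormatError, TraceTooShortError,
                          estimate_orientation, extract_rom, measure_wrist,
                          quat_conjugate, quat_multiply)
from siteless.simulate import TraceConfig, generate_rom_trace

NOISELESS = dict(gyro_noise_sd=0.0, accel_noise_sd=0.0, off_axis_fraction=0.0)


def still_trace(duration=4.0, rate=100.0):
    n = int(duration * rate)
    t = np.arange(n) / rate
    return IMUTrace(t=t, gyro=np.zeros((n, 3)),
                    accel=np.tile([0.0, 0.0, -G], (n, 1)), nominal_rate=rate)


def matrix_integration_angles(trace):
    """Brute-force oracle: orientation by cumulative rotation-matrix
    products of per-step gyro increments (trapezoidal); returns the
    per-sample total rotation angle relative to the start, degrees."""
    R = np.eye(3)
    mats = [R]
    for k in range(trace.t.size - 1):
        dt = trace.t[k + 1] - trace.t[k]
        w = 0.5 * (trace.gyro[k] + trace.gyro[k + 1])
        R = R @ Rotation.from_rotvec(w * dt).as_matrix()
        mats.append(R)
    return np.array([np.degrees(np.linalg.norm(
        Rotation.from_matrix(M).as_rotvec())) for M in mats])


def quaternion_angles(series):
    """Per-sample rotation angle of quats relative to the first sample."""
    q0c = quat_conjugate(series.quats[0])
    out = []
    for q in series.quats:
        rel = quat_multiply(q0c, q)
        out.append(np.degrees(2 * np.arctan2(np.linalg.norm(rel[1:]),
                                             abs(rel[0]))))
    return np.array(out)


class TestEstimateOrientation:
    def test_still_trace_gives_identity_relative_orientation(self):
        series = estimate_orientation(still_trace())
        angles = quaternion_angles(series)
        assert np.max(np.abs(angles)) < 1e-9
        assert series.quality_flags == set()

    def test_gyro_only_matches_analytic_angle_profile(self):
        """Noiseless rotation about x: the estimated per-sample rotation
        angle equals the analytic wrist angle within 0.5 degrees."""
        tc = TraceConfig(seed=0, **NOISELESS)
        trace, truth = generate_rom_trace(70.0, 70.0, tc)
        series = estimate_orientation(trace, RomSettings(filter_gain=0.0))
        est = quaternion_angles(series)
        assert np.max(np.abs(est - np.abs(truth["angle_deg"]))) < 0.5

    def test_quaternion_equals_matrix_oracle(self):
        """Gyro-only quaternion propagation agrees with brute-force
        rotation-matrix integration to < 1e-3 degrees per sample."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(10):
            f, e = rng.uniform(20, 90, 2)
            tc = TraceConfig(seed=int(rng.integers(2**31)),
                             gyro_noise_sd=0.0, accel_noise_sd=0.0,
                             off_axis_fraction=0.08)
            trace, _ = generate_rom_trace(f, e, tc)
            series = estimate_orientation(trace, RomSettings(filter_gain=0.0))
            worst = max(worst, np.max(np.abs(
                quaternion_angles(series) - matrix_integration_angles(trace))))
        assert worst < 1e-3

    def test_accel_correction_reduces_bias_drift(self):
        """With a constant 0.01 rad/s gyro bias, the complementary filter
        (gain 0.02) ends with a smaller tilt error than gyro-only."""
        tc = TraceConfig(seed=0, **NOISELESS)
        trace, _ = generate_rom_trace(60.0, 60.0, tc)
        biased = IMUTrace(t=trace.t, gyro=trace.gyro + [0.01, 0.01, 0.0],
                          accel=trace.accel, nominal_rate=trace.nominal_rate)

        def endpoint_tilt_error(gain):
            series = estimate_orientation(biased, RomSettings(filter_gain=gain))
            q = series.quats[-1]
            # true endpoint orientation is identity (profile returns to 0)
            v_pred = Rotation.from_quat(np.r_[q[1:], q[0]]).inv().apply(
                [0.0, 0.0, -1.0])
            v_true = trace.accel[-1] / np.linalg.norm(trace.accel[-1])
            return np.degrees(np.arccos(np.clip(v_pred @ v_true, -1, 1)))

        assert endpoint_tilt_error(0.02) <= endpoint_tilt_error(0.0)

    def test_too_short_and_bad_timestamps(self):
        with pytest.raises(TraceTooShortError):
            estimate_orientation(still_trace(duration=1.0))
        t = np.array([0.0, 0.02, 0.01, 0.03])
        with pytest.raises(TraceFormatError):
            IMUTrace(t=t, gyro=np.zeros((4, 3)), accel=np.zeros((4, 3)),
                     nominal_rate=100)

    def test_irregular_sampling_is_resampled_and_flagged(self, rng):
        base = still_trace()
        jitter = rng.uniform(-0.004, 0.004, base.t.size)
        t = np.sort(base.t + jitter)
        t[0] = base.t[0]
        trace = IMUTrace(t=t, gyro=base.gyro, accel=base.accel,
                         nominal_rate=100)
        series = estimate_orientation(trace)
        assert "irregular_sampling" in series.quality_flags
        assert np.allclose(np.diff(series.t), 0.01)

    def test_freefall_and_no_still_start_flags(self):
        tr = still_trace()
        accel = tr.accel.copy()
        accel[50:60] = 0.0    # free fall
        series = estimate_orientation(
            IMUTrace(t=tr.t, gyro=tr.gyro, accel=accel, nominal_rate=100))
        assert "freefall_samples" in series.quality_flags

        gyro = tr.gyro.copy()
        gyro[:120, 0] = 0.5   # moving during the calibration window
        series = estimate_orientation(
            IMUTrace(t=tr.t, gyro=gyro, accel=tr.accel, nominal_rate=100))
        assert "no_still_start" in series.quality_flags


class TestExtractRom:
    def test_identity_orientations_give_zero_rom(self):
        result = measure_wrist(still_trace())
        assert result.rom == 0.0
        assert result.flexion == 0.0 and result.extension == 0.0

    def test_noiseless_trace_recovers_rom_within_1_degree(self):
        trace, _ = generate_rom_trace(70.0, 70.0, TraceConfig(seed=0, **NOISELESS))
        result = measure_wrist(trace, RomSettings(filter_gain=0.0))
        assert result.rom == pytest.approx(140.0, abs=1.0)
        assert result.extension == pytest.approx(70.0, abs=1.0)
        assert result.flexion == pytest.approx(70.0, abs=1.0)

    def test_default_noise_recovers_rom_within_5_degrees(self):
        """Truth 50/60 deg with default sensor noise, 20 seeds."""
        for seed in range(20):
            trace, _ = generate_rom_trace(50.0, 60.0, TraceConfig(seed=seed))
            result = measure_wrist(trace)
            assert result.rom == pytest.approx(110.0, abs=5.0)

    def test_rom_invariants(self):
        trace, _ = generate_rom_trace(45.0, 80.0, TraceConfig(seed=5))
        r = measure_wrist(trace)
        assert r.rom == pytest.approx(r.flexion + r.extension, abs=1e-9)
        assert r.rom == pytest.approx(
            np.max(r.angle_series) - np.min(r.angle_series), abs=1e-6)
        assert np.linalg.norm(r.flexion_axis) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_frame_invariance(self):
        """Re-expressing the whole trace in a rotated device frame leaves
        the measured ROM unchanged (< 0.1 deg)."""
        trace, _ = generate_rom_trace(55.0, 65.0, TraceConfig(seed=2))
        C = Rotation.from_rotvec([0.4, -0.7, 1.1]).as_matrix()
        rotated = IMUTrace(t=trace.t, gyro=trace.gyro @ C.T,
                           accel=trace.accel @ C.T,
                           nominal_rate=trace.nominal_rate)
        r0 = measure_wrist(trace)
        r1 = measure_wrist(rotated)
        assert abs(r0.rom - r1.rom) < 0.1

    def test_error_degrades_monotonically_with_gyro_noise(self):
        """Mean |ROM error| is non-decreasing in gyro noise sd."""
        mean_errors = []
        for sd in (0.0, 0.02, 0.1):
            errs = []
            for seed in range(10):
                tc = TraceConfig(seed=seed, gyro_noise_sd=sd)
                trace, truth = generate_rom_trace(50.0, 60.0, tc)
                errs.append(abs(measure_wrist(trace).rom - truth["rom"]))
            mean_errors.append(np.mean(errs))
        assert mean_errors[0] <= mean_errors[1] <= mean_errors[2]

    def test_no_movement_returns_zero_rom_without_off_axis_flag(self):
        result = measure_wrist(still_trace())
        assert isinstance(result, ROMResult)
        assert "off_axis_motion" not in result.quality_flags
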