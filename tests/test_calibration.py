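import math

import numpy as np
import pytest

from gaitscore.calibration import (
    CalibrationAngles,
    CycleDisplacement,
    apply_calibration,
    calibrate_trial,
    dynamic_roll,
    integrate_cycle_displacement,
    static_misalignment,
)
from gaitscore.core import (
    AcquisitionConfig,
    DegenerateCycleError,
    NotStaticError,
    OrientationError,
)
from gaitscore.synthetic import MisalignmentTruth, forward_misalign_matrix, generate_subject

G = 9.81


def _static(vec, n=100):
    return np.tile(np.asarray(vec, dtype=float), (n, 1))


class TestStaticMisalignment:
    def test_aligned_sensor(self):
        assert static_misalignment(_static([G, 0, 0])) == pytest.approx((0, 0))

    def test_forty_five_degree_pitch(self):
        e_pitch, e_yaw = static_misalignment(_static([G / math.sqrt(2), 0,
                                                      -G / math.sqrt(2)]))
        assert e_pitch == pytest.approx(math.pi / 4)
        assert e_yaw == pytest.approx(0)

    def test_rotation_matrix_oracle(self):
        """Gravity rotated forward by (pitch 10°, yaw 5°) is recovered exactly."""
        mis = MisalignmentTruth(math.radians(10), math.radians(5), 0.0)
        g_sensor = forward_misalign_matrix(mis) @ np.array([G, 0, 0])
        e_pitch, e_yaw = static_misalignment(_static(g_sensor))
        assert e_pitch == pytest.approx(math.radians(10), abs=1e-9)
        assert e_yaw == pytest.approx(math.radians(5), abs=1e-9)

    def test_not_static_rejected(self):
        with pytest.raises(NotStaticError):
            static_misalignment(_static([3.0, 0, 0]))

    def test_upside_down_rejected(self):
        with pytest.raises(OrientationError):
            static_misalignment(_static([-G, 0, 0.1]))


class TestDynamicRoll:
    def test_forward_only_cycle(self):
        assert dynamic_roll(CycleDisplacement(1.2, 0.0)) == 0.0

    def test_forty_five_degrees(self):
        assert dynamic_roll(CycleDisplacement(1.0, 1.0)) == pytest.approx(math.pi / 4)

    def test_median_over_cycles(self):
        cycles = [CycleDisplacement(1.0, 0.1), CycleDisplacement(1.0, 0.2),
                  CycleDisplacement(1.0, 0.9)]
        assert dynamic_roll(cycles) == pytest.approx(math.atan(0.2))

    def test_degenerate_cycle(self):
        with pytest.raises(DegenerateCycleError):
            dynamic_roll(CycleDisplacement(0.05, 0.0))


class TestApplyCalibration:
    def test_zero_angles_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 6))
        np.testing.assert_array_equal(apply_calibration(x, CalibrationAngles()), x)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_with_forward_rotation(self, seed):
        """Correction inverts the generator's forward misalignment rotation."""
        rng = np.random.default_rng(seed)
        ang = rng.uniform(-math.radians(30), math.radians(30), 3)
        mis = MisalignmentTruth(*ang)
        R = forward_misalign_matrix(mis)
        x = rng.standard_normal((40, 3))
        rotated = x @ R.T
        back = apply_calibration(rotated, CalibrationAngles(
            e_pitch=ang[0], e_yaw=ang[1], e_roll=ang[2]))
        np.testing.assert_allclose(back, x, atol=1e-12)

    def test_norm_preservation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((100, 3))
        y = apply_calibration(x, CalibrationAngles(0.3, -0.2, 0.4))
        np.testing.assert_allclose(np.linalg.norm(y, axis=1),
                                   np.linalg.norm(x, axis=1), atol=1e-12)

    def test_static_mean_maps_to_x_axis(self):
        mis = MisalignmentTruth(0.2, -0.1, 0.15)
        g_sensor = forward_misalign_matrix(mis) @ np.array([G, 0, 0])
        e_pitch, e_yaw = static_misalignment(_static(g_sensor))
        # pitch/yaw zero the y and z static components; roll leaves x fixed
        cal = apply_calibration(_static(g_sensor),
                                CalibrationAngles(e_pitch, e_yaw, 0.0))
        np.testing.assert_allclose(cal.mean(axis=0), [G, 0, 0], atol=1e-9)


class TestIntegration:
    def test_gravity_only_gives_zero_displacement(self):
        cfg = AcquisitionConfig()
        acc = np.zeros((121, 6))
        acc[:, 0] = cfg.gravity_g
        disp, traj = integrate_cycle_displacement(acc, (0, 60, 120), cfg)
        assert disp.xy_cycle == 0.0 and disp.xz_cycle == 0.0
        np.testing.assert_array_equal(traj, np.zeros((121, 3)))

    def test_constant_bias_removed_by_drift_correction(self):
        """A 0.1 m/s² bias leaves < 2 cm residual over a 1.1 s cycle.

        Closed form: velocity ramp v = b·t minus the linear drift correction
        leaves v ≡ 0, so displacement is exactly zero up to quadrature error.
        """
        cfg = AcquisitionConfig()
        acc = np.zeros((111, 6))
        acc[:, 0] = cfg.gravity_g
        acc[:, 1] = 0.1
        disp, _ = integrate_cycle_displacement(acc, (0, 55, 110), cfg)
        assert abs(disp.xy_cycle) < 0.02

    def test_implausible_cycle_duration(self):
        cfg = AcquisitionConfig()
        acc = np.zeros((500, 6))
        acc[:, 0] = cfg.gravity_g
        with pytest.raises(DegenerateCycleError):
            integrate_cycle_displacement(acc, (0, 10, 20), cfg)  # 0.2 s
        with pytest.raises(DegenerateCycleError):
            integrate_cycle_displacement(acc, (0, 200, 400), cfg)  # 4.0 s


class TestCalibrateTrial:
    def test_injected_angles_recovered_noise_free(self, misaligned_subject):
        trial, truth = misaligned_subject
        _, angles = calibrate_trial(trial)
        for side in ("left", "right"):
            t = truth.misalignment[side]
            a = angles[side]
            assert a.e_pitch == pytest.approx(t.e_pitch_true, abs=math.radians(1))
            assert a.e_yaw == pytest.approx(t.e_yaw_true, abs=math.radians(1))
            assert a.e_roll == pytest.approx(t.e_roll_true, abs=math.radians(1))

    def test_zero_misalignment_angles_near_zero(self, clean_subject):
        trial, _ = clean_subject
        cal, angles = calibrate_trial(trial)
        for side in ("left", "right"):
            a = angles[side]
            assert max(abs(a.e_pitch), abs(a.e_yaw), abs(a.e_roll)) < math.radians(0.5)
        np.testing.assert_allclose(cal.imu_left, trial.imu_left, atol=0.05)

    def test_idempotence(self, misaligned_subject):
        """Calibrating an already calibrated trial finds ~zero residuals."""
        trial, _ = misaligned_subject
        cal, _ = calibrate_trial(trial)
        _, residual = calibrate_trial(cal)
        for side in ("left", "right"):
            a = residual[side]
            assert max(abs(a.e_pitch), abs(a.e_yaw), abs(a.e_roll)) < math.radians(0.5)
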