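"""Static–dynamic IMU mounting-misalignment calibration.

Mounting errors are estimated in two steps.  *Static*: during quiet standing
the shank accelerometer should read ``[g, 0, 0]``; the tilt of the measured
mean gravity vector gives the pitch (about y) and yaw (about z) errors,

    e_pitch = atan(-ā_z / sqrt(ā_x² + ā_y²)),   e_yaw = atan(ā_y / ā_x).

*Dynamic*: a residual roll about the shank's long (x) axis leaves gravity
unchanged, but leaks forward walking displacement into the mediolateral
axis; over one straight-line gait cycle the ideal displacement is purely
forward, so

    e_roll = atan(xz_cycle / xy_cycle).

Correction applies the elementary rotations Rx(-e_roll)·Ry(-e_pitch)·
Rz(-e_yaw) to every accelerometer and gyroscope sample — the unique
elementary sequence under which the static formulas exactly zero the y and z
components of the static mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import (
    AcquisitionConfig,
    DegenerateCycleError,
    NotStaticError,
    OrientationError,
    RawTrial,
    SchemaError,
)
from . import events as _events


@dataclass(frozen=True)
class CalibrationAngles:
    """Mounting-error angles (rad) of one IMU."""

    e_pitch: float = 0.0
    e_yaw: float = 0.0
    e_roll: float = 0.0

    def __post_init__(self) -> None:
        for name in ("e_pitch", "e_yaw", "e_roll"):
            if not -math.pi / 2 < getattr(self, name) < math.pi / 2:
                raise SchemaError(f"{name} outside (-pi/2, pi/2)")


@dataclass(frozen=True)
class CycleDisplacement:
    """Net displacement (m) of one gait cycle along the sensor y and z axes."""

    xy_cycle: float
    xz_cycle: float


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def correction_matrix(angles: CalibrationAngles) -> np.ndarray:
    """Sensor→anatomical rotation Rx(-roll)·Ry(-pitch)·Rz(-yaw)."""
    return (_rot_x(-angles.e_roll) @ _rot_y(-angles.e_pitch)
            @ _rot_z(-angles.e_yaw))


def static_misalignment(static_samples: np.ndarray,
                        gravity_g: float = 9.81) -> Tuple[float, float]:
    """Pitch/yaw mounting error from static accelerometer samples ``(n, 3)``.

    Multiple static windows (pre and post trial) should be concatenated or
    averaged into one sample block before calling.
    """
    a = np.asarray(static_samples, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise SchemaError("static_samples must have shape (n, 3)")
    if a.shape[0] < 10:
        raise NotStaticError(f"static window has {a.shape[0]} samples, need >= 10")
    mean = a.mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if not 0.8 * gravity_g <= norm <= 1.2 * gravity_g:
        raise NotStaticError(
            f"static mean norm {norm:.3f} m/s² outside [0.8g, 1.2g] — "
            "window is not stationary")
    if mean[0] <= 0:
        raise OrientationError("static x-acceleration <= 0: sensor upside-down?")
    e_pitch = math.atan2(-mean[2], math.hypot(mean[0], mean[1]))
    e_yaw = math.atan2(mean[1], mean[0])
    return e_pitch, e_yaw


def dynamic_roll(displacement: CycleDisplacement | Sequence[CycleDisplacement]
                 ) -> float:
    """Roll mounting error from per-cycle displacements (median over cycles)."""
    if isinstance(displacement, CycleDisplacement):
        displacement = [displacement]
    if len(displacement) == 0:
        raise DegenerateCycleError("no cycles supplied")
    rolls = []
    for d in displacement:
        if d.xy_cycle <= 0.1:
            raise DegenerateCycleError(
                f"forward displacement {d.xy_cycle:.3f} m <= 0.1 m: degenerate cycle")
        rolls.append(math.atan2(d.xz_cycle, d.xy_cycle))
    return float(np.median(rolls))


def apply_calibration(samples: np.ndarray, angles: CalibrationAngles) -> np.ndarray:
    """Rotate IMU samples into the anatomical frame.

    ``samples`` is ``(n, 3)`` (accel or gyro) or ``(n, 6)`` (accel + gyro);
    both 3-vector groups are rotated by the same correction matrix.
    """
    x = np.asarray(samples, dtype=float)
    R = correction_matrix(angles)
    if x.ndim == 2 and x.shape[1] == 3:
        return x @ R.T
    if x.ndim == 2 and x.shape[1] == 6:
        return np.hstack([x[:, :3] @ R.T, x[:, 3:] @ R.T])
    raise SchemaError("samples must have shape (n, 3) or (n, 6)")


def integrate_cycle_displacement(
    accel: np.ndarray,
    cycle: Tuple[int, int, int],
    config: AcquisitionConfig | None = None,
) -> Tuple[CycleDisplacement, np.ndarray]:
    """Double-integrate calibrated acceleration over one gait cycle.

    Gravity ``[g, 0, 0]`` is subtracted; velocity comes from trapezoidal
    integration with zero-velocity anchoring at both bounding heel strikes
    (linear drift removal across the cycle); displacement from trapezoidal
    integration of the corrected velocity.  Returns the net (y, z)
    displacement plus the full 3-D trajectory ``(n, 3)``.
    """
    cfg = config or AcquisitionConfig()
    hs0, _, hs1 = cycle
    dur = (hs1 - hs0) / cfg.fs_imu
    if not 0.4 <= dur <= 2.5:
        raise DegenerateCycleError(f"cycle duration {dur:.2f} s outside [0.4, 2.5] s")
    a = np.asarray(accel[hs0:hs1 + 1, :3], dtype=float).copy()
    a[:, 0] -= cfg.gravity_g
    dt = 1.0 / cfg.fs_imu
    # trapezoidal velocity, ZUPT: v = 0 at the starting heel strike
    v = np.vstack([np.zeros(3), np.cumsum((a[1:] + a[:-1]) / 2 * dt, axis=0)])
    # linear drift removal so v = 0 again at the closing heel strike
    ramp = np.linspace(0.0, 1.0, v.shape[0])[:, None]
    v = v - ramp * v[-1]
    p = np.vstack([np.zeros(3), np.cumsum((v[1:] + v[:-1]) / 2 * dt, axis=0)])
    return CycleDisplacement(float(p[-1, 1]), float(p[-1, 2])), p


def _pooled_static_accel(trial: RawTrial, side: str) -> np.ndarray:
    # pre- and post-trial windows have equal length, so concatenating them
    # pools the two window means with equal weight
    imu = trial.imu(side)
    return np.vstack([imu[slice(*trial.static_pre), :3],
                      imu[slice(*trial.static_post), :3]])


def calibrate_trial(trial: RawTrial
                    ) -> Tuple[RawTrial, Dict[str, CalibrationAngles]]:
    """Full static–dynamic calibration of both IMUs of a trial.

    Pipeline per side: pooled static windows → pitch/yaw → apply → detect
    gait cycles → per-cycle double integration → roll (median over cycles) →
    apply roll.  Returns the calibrated trial and the angle triple per IMU.
    """
    cfg = trial.config
    out = trial
    angles: Dict[str, CalibrationAngles] = {}
    for side in ("left", "right"):
        static = _pooled_static_accel(trial, side)
        e_pitch, e_yaw = static_misalignment(static, cfg.gravity_g)
        partial = CalibrationAngles(e_pitch=e_pitch, e_yaw=e_yaw)
        imu_py = apply_calibration(trial.imu(side), partial)

        evs = _events.detect_events(
            imu_py[:, 5], cfg.fs_imu,
            static_windows=(trial.static_pre, trial.static_post))
        cycles = _events.segment_cycles(evs, cfg.fs_imu)
        disps: List[CycleDisplacement] = []
        for cyc in cycles:
            try:
                d, _ = integrate_cycle_displacement(imu_py, cyc, cfg)
                if d.xy_cycle > 0.1:
                    disps.append(d)
            except DegenerateCycleError:
                continue
        e_roll = dynamic_roll(disps) if disps else 0.0
        full = CalibrationAngles(e_pitch=e_pitch, e_yaw=e_yaw, e_roll=e_roll)
        out = out.with_imu(side, apply_calibration(trial.imu(side), full))
        angles[side] = full
    return out, angles
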