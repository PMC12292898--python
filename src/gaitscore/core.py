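"""Domain types shared by every pipeline stage.

Coordinate convention (all modules): the shank anatomical frame has
x = vertical (gravity-aligned, so a static accelerometer reads ``[g, 0, 0]``),
y = anterior walking direction, z = mediolateral.  Accelerations are in m/s²,
angular velocities in rad/s, EMG in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

IMU_COLUMNS = ("ax", "ay", "az", "gx", "gy", "gz")
EMG_CHANNELS = ("ta_l", "ta_r", "ga_l", "ga_r")  # TA-L, TA-R, GA-L, GA-R
N_CYCLE_POINTS = 97
N_SCALES = 100


class GaitScoreError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(GaitScoreError):
    """A trial file or in-memory trial violates the schema."""


class NotStaticError(GaitScoreError):
    """A nominally static window does not look stationary."""


class OrientationError(GaitScoreError):
    """Static gravity direction is inconsistent with an upright sensor."""


class DegenerateCycleError(GaitScoreError):
    """A gait cycle is too short/implausible for the requested computation."""


class NoGaitError(GaitScoreError):
    """No walking activity could be found in the signal."""


class InsufficientCyclesError(GaitScoreError):
    """Fewer valid gait cycles than the operation requires."""


class DegenerateLabelsError(GaitScoreError):
    """A training set contains a single class."""


class PlanningError(GaitScoreError):
    """A cross-validation plan satisfying the constraints could not be built."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition constants: sampling rates, static-window length, tensor sizes."""

    fs_imu: float = 100.0
    fs_emg: float = 1000.0
    static_duration_s: float = 5.0
    n_cycle_points: int = N_CYCLE_POINTS
    n_scales: int = N_SCALES
    gravity_g: float = 9.81

    def __post_init__(self) -> None:
        if self.fs_imu <= 0 or self.fs_emg <= 0:
            raise SchemaError("sampling rates (fs_imu, fs_emg) must be > 0")
        if self.static_duration_s * self.fs_imu < 10:
            raise SchemaError(
                "static_duration_s too short: static_duration_s * fs_imu must "
                "be >= 10 samples"
            )
        if self.gravity_g <= 0:
            raise SchemaError("gravity_g must be > 0")

    @property
    def emg_per_imu(self) -> float:
        """EMG samples per IMU sample (shared wall clock)."""
        return self.fs_emg / self.fs_imu


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    height_m: float
    group: str  # "HC" or "PD"
    updrs_level: int  # 0, 1 or 2

    def __post_init__(self) -> None:
        if self.group not in ("HC", "PD"):
            raise SchemaError(f"group must be HC or PD, got {self.group!r}")
        if self.updrs_level not in (0, 1, 2):
            raise SchemaError(
                f"updrs_level must be 0, 1 or 2, got {self.updrs_level!r}"
            )
        if (self.group == "HC") != (self.updrs_level == 0):
            raise SchemaError(
                "group/updrs_level inconsistent: group == HC iff updrs_level == 0"
            )
        if not 1.2 < self.height_m < 2.2:
            raise SchemaError(f"height_m out of range (1.2, 2.2): {self.height_m}")


@dataclass
class RawTrial:
    """One walking trial: two shank IMUs, four EMG channels, subject metadata.

    ``imu_left``/``imu_right`` are ``(n, 6)`` arrays with columns
    (ax, ay, az, gx, gy, gz); ``emg`` is ``(m, 4)`` with channel order
    TA-left, TA-right, GA-left, GA-right.  ``static_pre``/``static_post`` are
    half-open ``[start, end)`` index ranges into the IMU stream during which
    the subject stood still.
    """

    imu_left: np.ndarray
    imu_right: np.ndarray
    emg: np.ndarray
    static_pre: Tuple[int, int]
    static_post: Tuple[int, int]
    subject: SubjectRecord
    trial_id: str
    config: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def validate(self) -> "RawTrial":
        for name, arr, ncol in (
            ("imu_left", self.imu_left, 6),
            ("imu_right", self.imu_right, 6),
            ("emg", self.emg, 4),
        ):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != ncol:
                raise SchemaError(f"{name} must be 2-D with {ncol} columns")
            if arr.shape[0] == 0:
                raise SchemaError(f"{name} is empty")
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"{name} contains NaN or infinite values")
        if self.imu_left.shape[0] != self.imu_right.shape[0]:
            raise SchemaError("imu_left/imu_right lengths differ")
        n = self.imu_left.shape[0]
        min_static = int(round(self.config.static_duration_s * self.config.fs_imu))
        for name, (a, b) in (
            ("static_pre", self.static_pre),
            ("static_post", self.static_post),
        ):
            if not (0 <= a < b <= n):
                raise SchemaError(f"{name} range [{a}, {b}) outside IMU stream")
            if b - a < min_static:
                raise SchemaError(
                    f"{name} spans {b - a} samples, "
                    f"< static_duration_s * fs_imu = {min_static}"
                )
        if n < 2 * min_static:
            raise SchemaError(
                f"IMU stream too short ({n} samples) for two static windows"
            )
        # IMU and EMG must cover the same wall-clock interval (5% tolerance).
        t_imu = n / self.config.fs_imu
        t_emg = self.emg.shape[0] / self.config.fs_emg
        if abs(t_imu - t_emg) > 0.05 * t_imu:
            raise SchemaError(
                f"emg duration {t_emg:.3f}s does not match imu duration {t_imu:.3f}s"
            )
        return self

    @property
    def n_imu(self) -> int:
        return self.imu_left.shape[0]

    def imu(self, side: str) -> np.ndarray:
        if side == "left":
            return self.imu_left
        if side == "right":
            return self.imu_right
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def with_imu(self, side: str, data: np.ndarray) -> "RawTrial":
        if side == "left":
            return replace(self, imu_left=data)
        if side == "right":
            return replace(self, imu_right=data)
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def imu_to_emg_index(self, imu_index: int) -> int:
        """Map an IMU sample index onto the EMG stream via the shared clock."""
        return int(round(imu_index * self.config.emg_per_imu))
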