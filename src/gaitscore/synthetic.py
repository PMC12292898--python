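"""Synthetic severity-labelled gait cohorts with known ground truth.

The generator emulates the walking protocol the pipeline expects: a 10 m
straight-line walk bracketed by 5 s of quiet standing, recorded by two
shank-mounted IMUs (100 Hz) and four lower-limb sEMG channels (1 kHz).
Severity (UPDRS gait level 0/1/2) moves the kinematic and myoelectric
profiles in the directions reported for Parkinsonian gait: shorter strides,
longer cycles, reduced swing ratio and shank excursion, and increasingly
asymmetric, temporally dispersed muscle bursts.

Every trial carries exact ground truth (mounting misalignment, gait events,
per-cycle kinematics) so calibration and feature extraction can be tested as
parameter-recovery problems.

Signal model, per leg and gait cycle of duration ``T`` (phase ``u ∈ [0,1)``,
heel strike at 0, toe-off at ``u_to = 1 - swing_ratio``):

* forward position ``y(u) = SL·(u - sin(2πu)/2π)`` — monotone advance of one
  stride length per cycle with zero velocity at each heel strike (the
  zero-velocity-update anchor the integrator assumes);
* vertical position ``x(u) = MFC·sin⁴(π·(u-u_to)/(1-u_to))`` during swing —
  a single foot-lift bump peaking at MFC, with continuous acceleration at
  toe-off and heel strike;
* sagittal angular velocity: a raised-cosine template with one dominant
  mid-swing positive peak flanked by negative troughs at toe-off and heel
  strike (standard shank-gyro morphology), scaled so the shank angular
  excursion per cycle equals ``shank_rom_rad``;
* accelerometer output = second derivative of position + gravity ``[g,0,0]``,
  expressed in a sensor frame rotated by the misalignment truth;
* EMG = band-limited Gaussian carriers (default 60–160 Hz, energy near
  100 Hz) amplitude-modulated by cycle-locked burst envelopes (TA around
  heel strike, GA at push-off); severity widens bursts (dispersion) and
  attenuates/delays the right side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import AcquisitionConfig, RawTrial, SchemaError, SubjectRecord
from .io import save_trial, write_manifest


@dataclass(frozen=True)
class GaitProfile:
    stride_length_m: float
    cycle_duration_s: float
    swing_ratio: float
    foot_clearance_m: float
    shank_rom_rad: float
    lr_asymmetry: float = 0.0
    cycle_jitter_cv: float = 0.03

    def __post_init__(self) -> None:
        if not 0.2 < self.swing_ratio < 0.6:
            raise SchemaError(f"swing_ratio out of (0.2, 0.6): {self.swing_ratio}")
        for name in ("stride_length_m", "cycle_duration_s", "foot_clearance_m",
                     "shank_rom_rad"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be > 0")
        if not 0 <= self.cycle_jitter_cv <= 0.3:
            raise SchemaError("cycle_jitter_cv out of [0, 0.3]")


@dataclass(frozen=True)
class EmgProfile:
    """Cycle-locked burst structure of the four EMG channels.

    Per-channel tuples follow the fixed channel order TA-L, TA-R, GA-L, GA-R.
    ``dispersion`` widens bursts multiplicatively (Parkinsonian temporal
    dispersion); ``lr_amplitude_ratio`` scales the right-side channels;
    ``lr_timing_offset_pct`` delays right-side bursts within their own cycle.
    """

    burst_center_pct: Tuple[float, float, float, float] = (2.0, 2.0, 45.0, 45.0)
    burst_width_pct: Tuple[float, float, float, float] = (26.0, 26.0, 30.0, 30.0)
    burst_amplitude: Tuple[float, float, float, float] = (1.0, 1.0, 0.9, 0.9)
    dispersion: float = 1.0
    carrier_band_hz: Tuple[float, float] = (60.0, 160.0)
    lr_amplitude_ratio: float = 1.0
    lr_timing_offset_pct: float = 0.0

    def __post_init__(self) -> None:
        for c in self.burst_center_pct:
            if not 0 <= c <= 100:
                raise SchemaError("burst_center_pct outside [0, 100]%")
        lo, hi = self.carrier_band_hz
        if not (20.0 < lo < hi < 450.0):
            raise SchemaError("carrier_band_hz must be inside (20, 450) Hz")
        if self.dispersion <= 0 or self.lr_amplitude_ratio <= 0:
            raise SchemaError("dispersion and lr_amplitude_ratio must be > 0")


@dataclass(frozen=True)
class MisalignmentTruth:
    """Ground-truth mounting error angles (rad) for one IMU."""

    e_pitch_true: float = 0.0
    e_yaw_true: float = 0.0
    e_roll_true: float = 0.0

    def __post_init__(self) -> None:
        for name in ("e_pitch_true", "e_yaw_true", "e_roll_true"):
            if abs(getattr(self, name)) > math.radians(30):
                raise SchemaError(f"{name} exceeds 30 degrees")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.e_pitch_true, self.e_yaw_true, self.e_roll_true)


@dataclass
class SubjectTruth:
    """Everything the generator knows that the pipeline must recover."""

    subject: SubjectRecord
    gait: Dict[str, GaitProfile]                 # per side
    emg: EmgProfile
    misalignment: Dict[str, MisalignmentTruth]   # per side
    events: List[Dict[str, Dict[str, np.ndarray]]] = field(default_factory=list)
    cycle_truth: List[Dict[str, List[dict]]] = field(default_factory=list)


# severity defaults, calibrated to the reported direction and coarse magnitude
# of group separations: SL, SR, SPR decrease and GC increases with severity;
# EMG dispersion and left-right asymmetry increase with severity.
_GAIT_DEFAULTS = {
    0: dict(stride_length_m=1.30, cycle_duration_s=1.02, swing_ratio=0.40,
            foot_clearance_m=0.130, shank_rom_rad=1.10, lr_asymmetry=0.02,
            cycle_jitter_cv=0.02),
    1: dict(stride_length_m=1.12, cycle_duration_s=1.08, swing_ratio=0.38,
            foot_clearance_m=0.115, shank_rom_rad=0.92, lr_asymmetry=0.06,
            cycle_jitter_cv=0.04),
    2: dict(stride_length_m=0.88, cycle_duration_s=1.18, swing_ratio=0.33,
            foot_clearance_m=0.095, shank_rom_rad=0.70, lr_asymmetry=0.12,
            cycle_jitter_cv=0.06),
}
_EMG_DEFAULTS = {
    0: dict(dispersion=1.0, lr_amplitude_ratio=1.00, lr_timing_offset_pct=0.0),
    1: dict(dispersion=1.4, lr_amplitude_ratio=0.85, lr_timing_offset_pct=3.0),
    2: dict(dispersion=1.9, lr_amplitude_ratio=0.70, lr_timing_offset_pct=7.0),
}

IMU_NOISE_ACC = 0.05   # m/s², white
IMU_NOISE_GYR = 0.01   # rad/s, white
EMG_NOISE_FLOOR = 0.02  # fraction of burst amplitude

_BETWEEN_SUBJECT_CV = {"HC": 0.08, "PD": 0.12}


def severity_defaults(level: int) -> Tuple[GaitProfile, EmgProfile]:
    """Default gait/EMG profiles for UPDRS gait level 0, 1 or 2."""
    if level not in (0, 1, 2):
        raise SchemaError(f"level must be 0, 1 or 2, got {level!r}")
    return GaitProfile(**_GAIT_DEFAULTS[level]), EmgProfile(**_EMG_DEFAULTS[level])


def _raised_cosine(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """Circular raised-cosine bump on cycle phase (period 1)."""
    d = np.abs(((u - center) + 0.5) % 1.0 - 0.5)
    out = np.zeros_like(u)
    inside = d < width / 2
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * d[inside] / width))
    return out


def _gyro_template(u: np.ndarray, u_to: float) -> np.ndarray:
    """Unscaled sagittal shank angular-velocity waveform over cycle phase."""
    u_ms = (u_to + 1.0) / 2.0  # mid-swing
    w = (_raised_cosine(u, u_ms, 0.8 * (1 - u_to))
         - 0.55 * _raised_cosine(u, u_to, 0.25)
         - 0.50 * _raised_cosine(u, 0.0, 0.20))
    return w


def _template_excursion(u_to: float) -> float:
    """Angular excursion (max-min of the integral) of the zero-mean template."""
    u = np.linspace(0, 1, 2001, endpoint=False)
    w = _gyro_template(u, u_to)
    w = w - w.mean()
    theta = np.cumsum(w) / len(u)
    return float(theta.max() - theta.min())


def _leg_truth(gait: GaitProfile, n_cycles: int, t_start: float,
               rng: np.random.Generator) -> List[dict]:
    """Per-cycle truth records: start time, duration, toe-off phase, targets."""
    out = []
    t = t_start
    for _ in range(n_cycles):
        T = gait.cycle_duration_s * (1 + gait.cycle_jitter_cv * rng.standard_normal())
        T = float(np.clip(T, 0.5 * gait.cycle_duration_s, 1.8 * gait.cycle_duration_s))
        out.append(dict(
            t_start=t, duration=T, u_to=1.0 - gait.swing_ratio,
            stride_length=gait.stride_length_m,
            foot_clearance=gait.foot_clearance_m,
            shank_rom=gait.shank_rom_rad,
        ))
        t += T
    return out


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def forward_misalign_matrix(mis: MisalignmentTruth) -> np.ndarray:
    """Anatomical→sensor rotation: Rz(yaw) · Ry(pitch) · Rx(roll)."""
    return _rot_z(mis.e_yaw_true) @ _rot_y(mis.e_pitch_true) @ _rot_x(mis.e_roll_true)


def _leg_signals(cycles: List[dict], t: np.ndarray, g: float
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Anatomical-frame accel (n,3), gyro (n,3) and event sample masks."""
    n = len(t)
    acc = np.zeros((n, 3))
    acc[:, 0] = g
    gyr = np.zeros((n, 3))
    hs_times = [c["t_start"] for c in cycles] + [
        cycles[-1]["t_start"] + cycles[-1]["duration"]]
    to_times = [c["t_start"] + c["u_to"] * c["duration"] for c in cycles]
    for c in cycles:
        T, u_to = c["duration"], c["u_to"]
        sl, mfc, rom = c["stride_length"], c["foot_clearance"], c["shank_rom"]
        sel = (t >= c["t_start"]) & (t < c["t_start"] + T)
        u = (t[sel] - c["t_start"]) / T
        # forward: y(u) = SL (u - sin(2πu)/2π) → ÿ = SL/T² · 2π sin(2πu)
        acc[sel, 1] += sl / T ** 2 * 2 * np.pi * np.sin(2 * np.pi * u)
        # vertical foot-lift bump during swing: x = MFC·sin⁴(πv); its second
        # derivative vanishes at toe-off and heel strike (no accel jumps)
        swing = u >= u_to
        v = (u[swing] - u_to) / (1 - u_to)
        t_sw = T * (1 - u_to)
        s2 = np.sin(np.pi * v) ** 2
        acc[np.flatnonzero(sel)[swing], 0] += (
            4 * np.pi ** 2 * mfc / t_sw ** 2 * (3 * s2 * (1 - s2) - s2 ** 2))
        # sagittal gyro: zero-mean template scaled to the programmed excursion
        w = _gyro_template(u, u_to)
        u_fine = np.linspace(0, 1, 2001, endpoint=False)
        w_mean = _gyro_template(u_fine, u_to).mean()
        amp = rom / (T * _template_excursion(u_to))
        gyr[sel, 2] += amp * (w - w_mean)
    return acc, gyr, np.asarray(hs_times), np.asarray(to_times)


def _emg_envelope(phase: np.ndarray, valid: np.ndarray, emg: EmgProfile,
                  ch: int) -> np.ndarray:
    """Cycle-locked burst envelope for one channel over EMG samples."""
    right = ch in (1, 3)
    center = emg.burst_center_pct[ch] / 100.0
    if right:
        center = (center + emg.lr_timing_offset_pct / 100.0) % 1.0
    width = min(0.95, emg.burst_width_pct[ch] / 100.0 * emg.dispersion)
    amp = emg.burst_amplitude[ch] * (emg.lr_amplitude_ratio if right else 1.0)
    env = np.full(phase.shape, 0.05 * amp)
    env[valid] += amp * _raised_cosine(phase[valid], center, width)
    return env


def generate_subject(
    level: int,
    seed: int,
    profiles: Optional[Tuple[GaitProfile, EmgProfile]] = None,
    misalignment: Optional[Dict[str, MisalignmentTruth]] = None,
    config: Optional[AcquisitionConfig] = None,
    subject_id: Optional[str] = None,
    height_m: float = 1.70,
    n_trials: int = 3,
    noise: bool = True,
) -> Tuple[List[RawTrial], SubjectTruth]:
    """Generate ``n_trials`` walking trials for one subject, with ground truth.

    Fixed ``seed`` (and arguments) gives bit-identical output.
    """
    cfg = config or AcquisitionConfig()
    rng = np.random.default_rng(seed)
    gait, emg = profiles if profiles is not None else severity_defaults(level)
    if misalignment is None:
        misalignment = {"left": MisalignmentTruth(), "right": MisalignmentTruth()}
    subject = SubjectRecord(
        subject_id=subject_id or f"L{level}S{seed}",
        height_m=height_m,
        group="HC" if level == 0 else "PD",
        updrs_level=level,
    )
    # right-leg profile: attenuated by the left-right asymmetry fraction
    a = gait.lr_asymmetry
    gait_right = replace(
        gait,
        shank_rom_rad=gait.shank_rom_rad * (1 - a),
        foot_clearance_m=gait.foot_clearance_m * (1 - a),
    )
    truth = SubjectTruth(subject=subject,
                         gait={"left": gait, "right": gait_right},
                         emg=emg, misalignment=misalignment)

    n_cycles = max(8, math.ceil(10.0 / gait.stride_length_m))
    trials: List[RawTrial] = []
    for k in range(n_trials):
        t_walk = cfg.static_duration_s
        cyc = {"left": _leg_truth(gait, n_cycles, t_walk, rng),
               "right": _leg_truth(gait_right, n_cycles,
                                   t_walk + gait.cycle_duration_s / 2, rng)}
        walk_end = max(c[-1]["t_start"] + c[-1]["duration"] for c in cyc.values())
        total = walk_end + cfg.static_duration_s
        n_imu = int(math.ceil(total * cfg.fs_imu)) + 1
        t_imu = np.arange(n_imu) / cfg.fs_imu

        imu_data = {}
        ev: Dict[str, Dict[str, np.ndarray]] = {}
        for side in ("left", "right"):
            acc, gyr, hs_t, to_t = _leg_signals(cyc[side], t_imu, cfg.gravity_g)
            R = forward_misalign_matrix(misalignment[side])
            acc = acc @ R.T
            gyr = gyr @ R.T
            if noise:
                acc = acc + IMU_NOISE_ACC * rng.standard_normal(acc.shape)
                gyr = gyr + IMU_NOISE_GYR * rng.standard_normal(gyr.shape)
            imu_data[side] = np.hstack([acc, gyr])
            ev[side] = {
                "hs": np.round(hs_t * cfg.fs_imu).astype(int),
                "to": np.round(to_t * cfg.fs_imu).astype(int),
            }

        n_emg = int(math.ceil(total * cfg.fs_emg)) + 1
        t_emg = np.arange(n_emg) / cfg.fs_emg
        sos = butter(4, emg.carrier_band_hz, btype="bandpass",
                     fs=cfg.fs_emg, output="sos")
        emg_out = np.zeros((n_emg, 4))
        phase = {}
        valid = {}
        for side in ("left", "right"):
            ph = np.zeros(n_emg)
            ok = np.zeros(n_emg, dtype=bool)
            for c in cyc[side]:
                sel = (t_emg >= c["t_start"]) & (t_emg < c["t_start"] + c["duration"])
                ph[sel] = (t_emg[sel] - c["t_start"]) / c["duration"]
                ok |= sel
            phase[side], valid[side] = ph, ok
        for ch, side in enumerate(("left", "right", "left", "right")):
            carrier = rng.standard_normal(n_emg)
            carrier = sosfiltfilt(sos, carrier)
            carrier /= np.sqrt(np.mean(carrier ** 2))
            env = _emg_envelope(phase[side], valid[side], emg, ch)
            sig = env * carrier
            if noise:
                sig = sig + EMG_NOISE_FLOOR * rng.standard_normal(n_emg)
            emg_out[:, ch] = sig

        n_static = int(round(cfg.static_duration_s * cfg.fs_imu))
        trial = RawTrial(
            imu_left=imu_data["left"],
            imu_right=imu_data["right"],
            emg=emg_out,
            static_pre=(0, n_static),
            static_post=(n_imu - n_static, n_imu),
            subject=subject,
            trial_id=f"{subject.subject_id}_t{k}",
            config=cfg,
        ).validate()
        trials.append(trial)
        truth.events.append(ev)
        truth.cycle_truth.append(cyc)
    return trials, truth


def _vary_profiles(level: int, group: str, rng: np.random.Generator
                   ) -> Tuple[GaitProfile, EmgProfile]:
    """Draw subject profiles around severity defaults (lognormal factors)."""
    gait, emg = severity_defaults(level)
    cv = _BETWEEN_SUBJECT_CV[group]
    sigma = math.sqrt(math.log(1 + cv ** 2))

    def f() -> float:
        return float(np.exp(sigma * rng.standard_normal() - sigma ** 2 / 2))

    gait = replace(
        gait,
        stride_length_m=gait.stride_length_m * f(),
        cycle_duration_s=gait.cycle_duration_s * f(),
        swing_ratio=float(np.clip(gait.swing_ratio * f(), 0.25, 0.55)),
        foot_clearance_m=gait.foot_clearance_m * f(),
        shank_rom_rad=gait.shank_rom_rad * f(),
    )
    emg = replace(
        emg,
        dispersion=emg.dispersion * f(),
        lr_amplitude_ratio=float(np.clip(emg.lr_amplitude_ratio * f(), 0.3, 1.2)),
    )
    return gait, emg


def generate_cohort(
    n_hc: int = 10,
    n_pd1: int = 5,
    n_pd2: int = 6,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    config: Optional[AcquisitionConfig] = None,
    noise: bool = True,
    misalign_max_deg: float = 10.0,
    n_trials: int = 3,
) -> Tuple[List[Tuple[List[RawTrial], SubjectTruth]], List[dict]]:
    """Generate a labelled cohort (default 10 HC / 5 PD-1 / 6 PD-2 subjects,
    three trials each). Returns per-subject (trials, truth) plus manifest rows;
    if ``out_dir`` is given, trials and ``manifest.csv`` are written there.
    """
    if min(n_hc, n_pd1, n_pd2) < 1:
        raise SchemaError("each group needs at least one subject")
    cfg = config or AcquisitionConfig()
    master = np.random.default_rng(seed)
    cohort = []
    manifest_rows = []
    levels = [0] * n_hc + [1] * n_pd1 + [2] * n_pd2
    for i, level in enumerate(levels):
        sid = f"S{i:02d}"
        group = "HC" if level == 0 else "PD"
        sub_seed = int(master.integers(0, 2 ** 31 - 1))
        rng = np.random.default_rng(sub_seed)
        profiles = _vary_profiles(level, group, rng)
        lim = math.radians(misalign_max_deg)
        mis = {
            side: MisalignmentTruth(*(rng.uniform(-lim, lim, 3)))
            for side in ("left", "right")
        }
        height = float(np.clip(rng.normal(1.70 if group == "HC" else 1.625,
                                          0.07 if group == "HC" else 0.05),
                               1.45, 2.05))
        trials, truth = generate_subject(
            level, seed=int(rng.integers(0, 2 ** 31 - 1)), profiles=profiles,
            misalignment=mis, config=cfg, subject_id=sid, height_m=height,
            n_trials=n_trials, noise=noise,
        )
        cohort.append((trials, truth))
        paths = [f"{t.trial_id}.csv" for t in trials]
        manifest_rows.append(dict(
            subject_id=sid, group=group, updrs_level=level,
            height_m=height, trial_paths=";".join(paths),
        ))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for trials, _ in cohort:
            for t in trials:
                save_trial(t, out_dir / f"{t.trial_id}.csv")
        write_manifest(manifest_rows, out_dir / "manifest.csv")
    return cohort, manifest_rows
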