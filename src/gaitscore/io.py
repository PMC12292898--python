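"""Trial file I/O.

One CSV per trial: a ``key = value`` header block (subject metadata,
sampling rates, static-window index ranges) followed by two numeric
sections, ``[imu]`` and ``[emg]``, each with its own time column because the
two modalities are sampled at different rates.  A cohort is a directory of
trial CSVs plus a ``manifest.csv`` listing subjects, labels and trial paths.
Feature tensors are persisted in one HDF5 container per cohort, keyed by
subject/trial/feature-name.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, List, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import (
    EMG_CHANNELS,
    IMU_COLUMNS,
    AcquisitionConfig,
    RawTrial,
    SchemaError,
    SubjectRecord,
)

_MAGIC = "# gaitscore-trial v1"

_IMU_HEADER = ["t"] + [f"{c}_l" for c in IMU_COLUMNS] + [f"{c}_r" for c in IMU_COLUMNS]
_EMG_HEADER = ["t"] + list(EMG_CHANNELS)


def save_trial(trial: RawTrial, path: str | Path) -> Path:
    """Write a validated trial to ``path`` in the trial-CSV dialect."""
    trial.validate()
    path = Path(path)
    cfg = trial.config
    buf = _io.StringIO()
    buf.write(_MAGIC + "\n")
    for key, val in (
        ("subject_id", trial.subject.subject_id),
        ("height_m", repr(trial.subject.height_m)),
        ("group", trial.subject.group),
        ("updrs_level", trial.subject.updrs_level),
        ("trial_id", trial.trial_id),
        ("fs_imu", repr(cfg.fs_imu)),
        ("fs_emg", repr(cfg.fs_emg)),
        ("static_duration_s", repr(cfg.static_duration_s)),
        ("gravity_g", repr(cfg.gravity_g)),
        ("static_pre", f"{trial.static_pre[0]},{trial.static_pre[1]}"),
        ("static_post", f"{trial.static_post[0]},{trial.static_post[1]}"),
    ):
        buf.write(f"{key} = {val}\n")

    n = trial.n_imu
    t_imu = np.arange(n) / cfg.fs_imu
    imu = np.column_stack([t_imu, trial.imu_left, trial.imu_right])
    buf.write("[imu]\n" + ",".join(_IMU_HEADER) + "\n")
    pd.DataFrame(imu).to_csv(buf, header=False, index=False, float_format="%.9g")

    t_emg = np.arange(trial.emg.shape[0]) / cfg.fs_emg
    emg = np.column_stack([t_emg, trial.emg])
    buf.write("[emg]\n" + ",".join(_EMG_HEADER) + "\n")
    pd.DataFrame(emg).to_csv(buf, header=False, index=False, float_format="%.9g")

    path.write_text(buf.getvalue())
    return path


def load_trial(path: str | Path) -> RawTrial:
    """Read a trial CSV written by :func:`save_trial` and validate it."""
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise SchemaError(f"{path}: not a gaitscore trial file")

    header: Dict[str, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("["):
        line = lines[i].strip()
        if line and "=" in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
        i += 1

    sections: Dict[str, str] = {}
    current = None
    start = i
    for j in range(i, len(lines) + 1):
        if j == len(lines) or lines[j].startswith("["):
            if current is not None:
                sections[current] = "\n".join(lines[start:j])
            if j < len(lines):
                current = lines[j].strip().strip("[]")
                start = j + 1
    for sec in ("imu", "emg"):
        if sec not in sections:
            raise SchemaError(f"{path}: missing [{sec}] section")

    def _parse_section(name: str, expected: Sequence[str]) -> np.ndarray:
        df = pd.read_csv(_io.StringIO(sections[name]))
        for col in expected:
            if col not in df.columns:
                raise SchemaError(f"{path}: [{name}] missing column {col!r}")
        if df.shape[0] == 0:
            raise SchemaError(f"{path}: [{name}] section is empty")
        return df[list(expected)].to_numpy(dtype=float)

    imu = _parse_section("imu", _IMU_HEADER)
    emg = _parse_section("emg", _EMG_HEADER)

    try:
        cfg = AcquisitionConfig(
            fs_imu=float(header["fs_imu"]),
            fs_emg=float(header["fs_emg"]),
            static_duration_s=float(header.get("static_duration_s", 5.0)),
            gravity_g=float(header.get("gravity_g", 9.81)),
        )
        subject = SubjectRecord(
            subject_id=header["subject_id"],
            height_m=float(header["height_m"]),
            group=header["group"],
            updrs_level=int(header["updrs_level"]),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing header key {exc}") from exc

    n = imu.shape[0]
    n_static = int(round(cfg.static_duration_s * cfg.fs_imu))
    if n < 2 * n_static:
        raise SchemaError(
            f"{path}: stream length {n} shorter than two static windows"
        )

    def _parse_range(key: str, default: tuple) -> tuple:
        if key not in header:
            return default
        a, _, b = header[key].partition(",")
        return (int(a), int(b))

    static_pre = _parse_range("static_pre", (0, n_static))
    static_post = _parse_range("static_post", (n - n_static, n))

    trial = RawTrial(
        imu_left=imu[:, 1:7],
        imu_right=imu[:, 7:13],
        emg=emg[:, 1:5],
        static_pre=static_pre,
        static_post=static_post,
        subject=subject,
        trial_id=header.get("trial_id", path.stem),
        config=cfg,
    )
    return trial.validate()


def write_config(config: AcquisitionConfig, path: str | Path) -> Path:
    """Write an acquisition config as a ``key = value`` text file."""
    path = Path(path)
    lines = [f"{k} = {getattr(config, k)!r}" for k in
             ("fs_imu", "fs_emg", "static_duration_s", "n_cycle_points",
              "n_scales", "gravity_g")]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_config(path: str | Path) -> AcquisitionConfig:
    """Read a ``key = value`` config file back into an AcquisitionConfig."""
    kw = {}
    casts = dict(fs_imu=float, fs_emg=float, static_duration_s=float,
                 n_cycle_points=int, n_scales=int, gravity_g=float)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        if key in casts:
            kw[key] = casts[key](val.strip())
        else:
            raise SchemaError(f"unknown config key {key!r}")
    return AcquisitionConfig(**kw)


def write_manifest(rows: List[dict], path: str | Path) -> Path:
    """Write a cohort manifest: one row per subject with labels + trial paths."""
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "updrs_level", "height_m", "trial_paths"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"manifest missing columns: {sorted(missing)}")
    return df


def trial_paths(manifest_row: pd.Series, base: str | Path) -> List[Path]:
    base = Path(base)
    return [base / p for p in str(manifest_row["trial_paths"]).split(";")]


class FeatureStore:
    """HDF5 container for per-trial feature tensors, keyed subject/trial/name."""

    def __init__(self, path: str | Path, mode: str = "a"):
        self._h5 = h5py.File(path, mode)

    def put(self, subject_id: str, trial_id: str, name: str, arr: np.ndarray) -> None:
        key = f"{subject_id}/{trial_id}/{name}"
        if key in self._h5:
            del self._h5[key]
        self._h5.create_dataset(key, data=np.asarray(arr))

    def get(self, subject_id: str, trial_id: str, name: str) -> np.ndarray:
        return np.asarray(self._h5[f"{subject_id}/{trial_id}/{name}"])

    def trials(self, subject_id: str) -> List[str]:
        return sorted(self._h5[subject_id].keys())

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "FeatureStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
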