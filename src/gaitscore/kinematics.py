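"""Per-cycle gait kinematics and the 4×6 MF summary matrix.

Six parameters are computed per gait cycle from the calibrated shank IMU:

* **SL** — stride length: net anterior (y) displacement over the cycle;
* **GC** — gait-cycle duration (s);
* **SPR** — swing-phase ratio: (hs_end − toe_off) / (hs_end − hs_start);
* **MGS** — mean gait speed: SL / GC;
* **MFC** — maximum foot clearance: peak vertical (x) displacement above the
  cycle-start position;
* **SR** — shank range of motion: max − min of the drift-corrected integral
  of the sagittal angular velocity (rad).

SL and MFC are normalized by subject height before summarization.  Pooled
per-cycle 6-vectors from both sides are condensed into a fixed 4×6 matrix
(MF) by k-means with k = 4 on z-scored features; the de-standardized
centroids are sorted ascending by SL/H so the row order is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .core import AcquisitionConfig, InsufficientCyclesError, SchemaError
from .calibration import integrate_cycle_displacement

MF_COLUMNS = ("SL_H", "GC", "SPR", "MGS", "MFC_H", "SR")


@dataclass(frozen=True)
class CycleKinematics:
    SL: float
    GC: float
    SPR: float
    MGS: float
    MFC: float
    SR: float
    side: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.SPR < 1:
            raise SchemaError(f"SPR out of (0, 1): {self.SPR}")
        if abs(self.MGS - self.SL / self.GC) > 1e-9:
            raise SchemaError("MGS must equal SL / GC")

    def as_vector(self, height_m: float | None = None) -> np.ndarray:
        """(SL/H, GC, SPR, MGS, MFC/H, SR); raw SL/MFC if height is None."""
        h = height_m if height_m is not None else 1.0
        return np.array([self.SL / h, self.GC, self.SPR, self.MGS,
                         self.MFC / h, self.SR])


def cycle_kinematics(
    imu_calibrated: np.ndarray,
    cycle: Tuple[int, int, int],
    config: AcquisitionConfig | None = None,
    side: str = "",
) -> CycleKinematics:
    """Six gait parameters for one ``(hs_start, toe_off, hs_end)`` cycle."""
    cfg = config or AcquisitionConfig()
    hs0, to, hs1 = cycle
    disp, traj = integrate_cycle_displacement(imu_calibrated, cycle, cfg)
    gc = (hs1 - hs0) / cfg.fs_imu
    spr = (hs1 - to) / (hs1 - hs0)
    sl = disp.xy_cycle
    mfc = float(np.max(traj[:, 0] - traj[0, 0]))
    # shank excursion: drift-corrected integral of the sagittal gyro
    gz = np.asarray(imu_calibrated[hs0:hs1 + 1, 5], dtype=float)
    theta = np.concatenate([[0.0], np.cumsum((gz[1:] + gz[:-1]) / 2)]) / cfg.fs_imu
    theta = theta - np.linspace(0.0, 1.0, theta.size) * theta[-1]
    sr = float(theta.max() - theta.min())
    return CycleKinematics(SL=sl, GC=gc, SPR=spr, MGS=sl / gc, MFC=mfc,
                           SR=sr, side=side)


def normalize_by_height(features: CycleKinematics, height_m: float
                        ) -> np.ndarray:
    """Height-normalized feature 6-vector (SL/H, GC, SPR, MGS, MFC/H, SR).

    Only SL and MFC are divided by subject height; the other four
    parameters are passed through unchanged.
    """
    if height_m <= 0:
        raise SchemaError("height_m must be > 0")
    return features.as_vector(height_m)


def summarize_mf(
    per_cycle: Sequence[CycleKinematics],
    height_m: float,
    seed: int = 0,
) -> np.ndarray:
    """Condense pooled per-cycle kinematics (both sides) into the 4×6 MF matrix.

    K-means (k = 4, 10 restarts, fixed seed) on per-feature z-scored,
    height-normalized cycle vectors; rows are the de-standardized centroids
    sorted ascending by SL/H.
    """
    if len(per_cycle) < 4:
        raise InsufficientCyclesError(
            f"need >= 4 cycles to build the MF matrix, got {len(per_cycle)}")
    X = np.vstack([c.as_vector(height_m) for c in per_cycle])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=4, n_init=10, random_state=seed).fit(Z)
    centroids = km.cluster_centers_ * sd + mu
    order = np.argsort(centroids[:, 0], kind="stable")
    mf = centroids[order]
    if mf.shape != (4, 6) or not np.all(np.isfinite(mf)):
        raise SchemaError("MF matrix must be finite with shape 4x6")
    return mf
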