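"""EMG feature tensors: cycle-normalized envelopes (FTF) and Morlet
scalograms (ETFF).

Preprocessing band-passes each channel at 20–450 Hz (4th-order Butterworth,
zero-phase) and normalizes its amplitude by the 99th percentile of |signal|
over the trial.  The linear envelope is the magnitude of the analytic
signal, ``env(t) = sqrt(ε(t)² + H(ε(t))²)`` with ``H`` the Hilbert
transform, smoothed by a zero-phase 10 Hz low-pass.  Each within-cycle
segment is time-warped onto 97 equally spaced points of the gait cycle;
cycle-wise representations are averaged into per-trial feature maps:

* FTF — 4 channels × 97 points, per-channel max-normalized to [0, 1];
* ETFF — 100 wavelet scales × 97 points × 4 channels, magnitudes of a
  complex-Morlet continuous wavelet transform with scales log-spaced so
  center frequencies span 10–500 Hz.

Left-side channels (TA-L, GA-L) are warped on left-leg cycles and
right-side channels on right-leg cycles; cycle boundaries are mapped from
IMU to EMG sample indices through the shared wall clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pywt
from scipy.signal import butter, hilbert, sosfiltfilt

from .core import (
    EMG_CHANNELS,
    InsufficientCyclesError,
    RawTrial,
    SchemaError,
)

_CHANNEL_SIDE = ("left", "right", "left", "right")
_WAVELET = "cmor1.5-1.0"
FREQ_RANGE_HZ = (10.0, 500.0)


@dataclass(frozen=True)
class FTFTensor:
    """4×97 cycle-averaged envelope map, channel order TA-L, TA-R, GA-L, GA-R."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != 4 or v.ndim != 2:
            raise SchemaError("FTF must have shape (4, n_cycle_points)")
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise SchemaError("FTF values must lie in [0, 1]")


@dataclass(frozen=True)
class ETFFTensor:
    """100×97×4 cycle-averaged scalogram magnitudes + scale center freqs (Hz)."""

    values: np.ndarray
    scale_freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != 4:
            raise SchemaError("ETFF must have shape (n_scales, n_points, 4)")
        if np.nanmin(self.values) < 0:
            raise SchemaError("ETFF magnitudes must be nonnegative")
        if np.any(np.diff(self.scale_freqs) > 0):
            raise SchemaError("scale_freqs must be descending")


def preprocess_emg(raw_channel: np.ndarray, fs_emg: float,
                   band_hz: Tuple[float, float] = (20.0, 450.0)) -> np.ndarray:
    """Zero-phase 20–450 Hz band-pass + robust amplitude normalization."""
    if fs_emg <= 900:
        raise SchemaError(
            f"fs_emg = {fs_emg} Hz too low: need > 900 Hz for a 450 Hz band edge")
    x = np.asarray(raw_channel, dtype=float).ravel()
    sos = butter(4, band_hz, btype="bandpass", fs=fs_emg, output="sos")
    y = sosfiltfilt(sos, x)
    scale = np.percentile(np.abs(y), 99)
    return y / scale if scale > 0 else y


def envelope(eps: np.ndarray, fs_emg: float,
             smooth_hz: float = 10.0) -> np.ndarray:
    """Hilbert linear envelope: |analytic signal|, low-pass smoothed."""
    env = np.abs(hilbert(np.asarray(eps, dtype=float).ravel()))
    if smooth_hz is not None and smooth_hz > 0:
        sos = butter(4, smooth_hz, btype="lowpass", fs=fs_emg, output="sos")
        env = sosfiltfilt(sos, env)
    return np.clip(env, 0.0, None)


def warp_to_cycle(series: np.ndarray, start: int, end: int,
                  n_points: int = 97) -> np.ndarray:
    """Resample ``series[start:end+1]`` onto ``n_points`` points of [0, 100]%."""
    series = np.asarray(series, dtype=float)
    if start < 0 or end >= series.shape[0] or end <= start:
        raise SchemaError(
            f"cycle [{start}, {end}] outside series of length {series.shape[0]}")
    seg = series[start:end + 1]
    xp = np.linspace(0.0, 1.0, seg.size)
    return np.interp(np.linspace(0.0, 1.0, n_points), xp, seg)


def _emg_cycles(trial: RawTrial, cycles_by_side: Dict[str, Sequence[Tuple[int, int, int]]]
                ) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    m = trial.emg.shape[0]
    for side, cycles in cycles_by_side.items():
        lst = []
        for hs0, _, hs1 in cycles:
            a = trial.imu_to_emg_index(hs0)
            b = min(trial.imu_to_emg_index(hs1), m - 1)
            if b > a:
                lst.append((a, b))
        out[side] = lst
    return out


def build_ftf(trial: RawTrial,
              cycles_by_side: Dict[str, Sequence[Tuple[int, int, int]]],
              n_points: int | None = None) -> FTFTensor:
    """Cycle-averaged, per-channel max-normalized envelope map (4×97)."""
    cfg = trial.config
    n_points = n_points or cfg.n_cycle_points
    spans = _emg_cycles(trial, cycles_by_side)
    if not any(spans.values()):
        raise InsufficientCyclesError("no valid gait cycles for FTF")
    rows = np.zeros((4, n_points))
    for ch in range(4):
        eps = preprocess_emg(trial.emg[:, ch], cfg.fs_emg)
        env = envelope(eps, cfg.fs_emg)
        ch_spans = spans[_CHANNEL_SIDE[ch]]
        if not ch_spans:
            raise InsufficientCyclesError(
                f"no cycles on the {_CHANNEL_SIDE[ch]} side for {EMG_CHANNELS[ch]}")
        warped = np.vstack([warp_to_cycle(env, a, b, n_points) for a, b in ch_spans])
        row = warped.mean(axis=0)
        peak = row.max()
        rows[ch] = row / peak if peak > 0 else row
    return FTFTensor(values=rows)


def scale_frequencies(fs_emg: float, n_scales: int = 100,
                      freq_range: Tuple[float, float] = FREQ_RANGE_HZ
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Log-spaced CWT center frequencies (descending) and matching scales."""
    freqs = np.logspace(np.log10(freq_range[1]), np.log10(freq_range[0]), n_scales)
    fc = pywt.central_frequency(_WAVELET)
    scales = fc * fs_emg / freqs
    return freqs, scales


def build_etff(trial: RawTrial,
               cycles_by_side: Dict[str, Sequence[Tuple[int, int, int]]],
               n_points: int | None = None,
               n_scales: int | None = None) -> ETFFTensor:
    """Cycle-averaged complex-Morlet scalogram map (100×97×4)."""
    cfg = trial.config
    n_points = n_points or cfg.n_cycle_points
    n_scales = n_scales or cfg.n_scales
    spans = _emg_cycles(trial, cycles_by_side)
    if not any(spans.values()):
        raise InsufficientCyclesError("no valid gait cycles for ETFF")
    freqs, scales = scale_frequencies(cfg.fs_emg, n_scales)
    out = np.zeros((n_scales, n_points, 4))
    margin = int(0.25 * cfg.fs_emg)
    for ch in range(4):
        ch_spans = spans[_CHANNEL_SIDE[ch]]
        if not ch_spans:
            raise InsufficientCyclesError(
                f"no cycles on the {_CHANNEL_SIDE[ch]} side for {EMG_CHANNELS[ch]}")
        eps = preprocess_emg(trial.emg[:, ch], cfg.fs_emg)
        lo = max(0, min(a for a, _ in ch_spans) - margin)
        hi = min(eps.size, max(b for _, b in ch_spans) + margin)
        coefs, _ = pywt.cwt(eps[lo:hi], scales, _WAVELET,
                            sampling_period=1.0 / cfg.fs_emg, method="fft")
        mag = np.abs(coefs)
        acc = np.zeros((n_scales, n_points))
        for a, b in ch_spans:
            for s in range(n_scales):
                acc[s] += warp_to_cycle(mag[s], a - lo, b - lo, n_points)
        out[:, :, ch] = acc / len(ch_spans)
    return ETFFTensor(values=out, scale_freqs=freqs)


def stance_energy_spread(etff: ETFFTensor, channel: int = 2) -> float:
    """Temporal dispersion of scalogram energy along the gait cycle.

    Circular standard deviation (in cycle fraction) of the column-energy
    distribution of one channel; larger values mean energy spread over more
    of the cycle rather than a tight stance-phase bundle.  Only scale rows
    carrying at least half the peak row energy contribute, so broadband
    background does not dilute the burst timing.
    """
    v = etff.values[:, :, channel]
    row_e = v.sum(axis=1)
    e = (v[row_e >= 0.5 * row_e.max()] ** 2).sum(axis=0)
    p = e / e.sum()
    ang = 2 * np.pi * np.linspace(0, 1, e.size, endpoint=False)
    r = np.abs(np.sum(p * np.exp(1j * ang)))
    r = min(max(r, 1e-12), 1.0)
    return float(np.sqrt(-2 * np.log(r)) / (2 * np.pi))
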