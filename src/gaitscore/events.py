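"""Gait-event detection from sagittal shank angular velocity.

The shank gyroscope's sagittal component shows one dominant positive peak
per gait cycle at mid-swing, flanked by negative troughs near toe-off
(before) and heel strike (after).  Detection proceeds in three steps:

1. mid-swing candidates: positive peaks with adaptive prominence
   (``prominence_factor`` × the 90th-percentile amplitude, default 0.4) and a
   minimum separation of 0.5 s;
2. toe-off = most negative sample in the window (default 0.35 s) *before*
   each mid-swing peak; heel strike = most negative sample in the window
   *after* it;
3. events falling inside the static standing windows are discarded.

The detector is invariant to positive amplitude scaling, and the sign of the
sagittal axis is auto-detected (a correctly signed signal is positively
skewed by the dominant swing peak).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import skew

from .core import NoGaitError

#: plausible single-cycle duration bounds (s); covers slow Parkinsonian gait
CYCLE_DURATION_BOUNDS = (0.4, 2.5)


@dataclass(frozen=True)
class GaitEvent:
    index: int
    kind: str  # "heel_strike" or "toe_off"
    side: str = ""


def detect_events(
    sagittal_gyro: np.ndarray,
    fs: float,
    static_windows: Sequence[Tuple[int, int]] = (),
    prominence_factor: float = 0.4,
    trough_window_s: float = 0.35,
    min_separation_s: float = 0.5,
    sign_convention: str = "auto",
    side: str = "",
) -> List[GaitEvent]:
    """Detect alternating heel-strike/toe-off events in one gyro channel."""
    w = np.asarray(sagittal_gyro, dtype=float).ravel()
    if w.size < 2 * fs:
        raise NoGaitError("signal shorter than 2 s")
    if np.ptp(w) == 0:
        raise NoGaitError("constant signal: no gait activity")
    if sign_convention == "flip" or (
            sign_convention == "auto" and skew(w) < 0):
        w = -w

    amp = np.percentile(np.abs(w), 90)
    peaks, _ = find_peaks(
        w, height=0.0, prominence=prominence_factor * amp,
        distance=max(1, int(round(min_separation_s * fs))))
    half = max(1, int(round(trough_window_s * fs)))

    def in_static(idx: int) -> bool:
        return any(a <= idx < b for a, b in static_windows)

    peaks = [p for p in peaks if not in_static(p)]
    if len(peaks) < 2:
        raise NoGaitError(f"only {len(peaks)} mid-swing peaks found")

    events: List[GaitEvent] = []
    for p in peaks:
        lo = max(0, p - half)
        to_idx = lo + int(np.argmin(w[lo:p])) if p > lo else p
        hi = min(len(w), p + half + 1)
        hs_idx = p + 1 + int(np.argmin(w[p + 1:hi])) if hi > p + 1 else p
        for idx, kind in ((to_idx, "toe_off"), (hs_idx, "heel_strike")):
            if not in_static(idx):
                events.append(GaitEvent(index=int(idx), kind=kind, side=side))

    events.sort(key=lambda e: e.index)
    # enforce alternation HS, TO, HS, ... keeping the first of any run
    cleaned: List[GaitEvent] = []
    for e in events:
        if cleaned and cleaned[-1].kind == e.kind:
            continue
        cleaned.append(e)
    return cleaned


def segment_cycles(
    events: Sequence[GaitEvent],
    fs: float,
    bounds_s: Tuple[float, float] = CYCLE_DURATION_BOUNDS,
    trim_cycles: int = 0,
) -> List[Tuple[int, int, int]]:
    """Pair consecutive heel strikes (with the enclosed toe-off) into cycles.

    Cycles whose duration falls outside ``bounds_s`` are dropped.
    ``trim_cycles`` additionally discards that many cycles at each end of
    the walk (acceleration/deceleration strides).  Returns
    ``(hs_start, toe_off, hs_end)`` index triples.
    """
    hs = [e.index for e in events if e.kind == "heel_strike"]
    to = [e.index for e in events if e.kind == "toe_off"]
    cycles: List[Tuple[int, int, int]] = []
    for a, b in zip(hs[:-1], hs[1:]):
        dur = (b - a) / fs
        if not bounds_s[0] <= dur <= bounds_s[1]:
            continue
        enclosed = [t for t in to if a < t < b]
        if not enclosed:
            continue
        cycles.append((int(a), int(enclosed[0]), int(b)))
    if trim_cycles > 0:
        cycles = cycles[trim_cycles:len(cycles) - trim_cycles]
    return cycles
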