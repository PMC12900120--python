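"""Beat segmentation and derivative-based fiducial point detection.

Landmarks are localized by zero-crossing analysis of the first, second and
third derivatives of the conditioned waveform:

* foot - the last minimum before the systolic peak, found as the last
  negative-to-positive sign change of the first derivative (argmin fallback);
* rising steep - maximum upslope, the first-derivative maximum between foot
  and peak (equivalently the second-derivative zero crossing);
* systolic peak - the local maximum anchoring each beat window;
* falling steep - the first local minimum of the first derivative after the
  maximum upslope (steepest descent);
* dicrotic notch - the first positive-to-negative third-derivative zero
  crossing after the peak, reported only when a dicrotic lobe is actually
  present; absent otherwise.

Beats whose landmarks violate the ordering foot < rising < peak < falling are
flagged invalid and excluded from aggregation rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "FiducialSet",
    "DetectionReport",
    "derivatives",
    "segment_beats",
    "detect_fiducials",
    "detection_rate",
    "delineate",
    "foot_times",
]

LANDMARKS = ("foot", "rising_steep", "systolic_peak", "falling_steep", "dicrotic_notch")

# minimum dicrotic-lobe prominence, as a fraction of the beat range, for a
# notch to be reported
_NOTCH_PROMINENCE = 0.01


@dataclass(frozen=True)
class FiducialSet:
    """Per-beat landmark sample indices (global, into the full record)."""

    foot: int
    rising_steep: int
    systolic_peak: int
    falling_steep: int
    dicrotic_notch: Optional[int] = None
    beat_index: int = 0

    def __post_init__(self) -> None:
        if not self.foot < self.rising_steep < self.systolic_peak < self.falling_steep:
            raise ValueError("fiducial ordering violated")
        if self.dicrotic_notch is not None and self.dicrotic_notch <= self.systolic_peak:
            raise ValueError("dicrotic notch must follow the systolic peak")

    def shifted(self, k: int) -> "FiducialSet":
        return FiducialSet(
            self.foot + k, self.rising_steep + k, self.systolic_peak + k,
            self.falling_steep + k,
            None if self.dicrotic_notch is None else self.dicrotic_notch + k,
            self.beat_index,
        )


@dataclass
class DetectionReport:
    expected_beats: int
    detected: Dict[str, int]
    success_rate: Dict[str, float]


def derivatives(x: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First three central-difference derivatives, same length as the input.

    Meaningful only on band-limited (low-pass filtered) signals; the
    derivative of raw wide-band noise is dominated by the noise.
    """
    x = np.asarray(x, float)
    if len(x) < 5:
        raise ValueError("need at least 5 samples to form third derivatives")
    dt = 1.0 / fs
    d1 = np.gradient(x, dt, edge_order=2)
    d2 = np.gradient(d1, dt, edge_order=2)
    d3 = np.gradient(d2, dt, edge_order=2)
    return d1, d2, d3


def segment_beats(
    x: np.ndarray, fs: float, hr_hint: float
) -> List[Tuple[slice, int]]:
    """Split a record into beat windows around detected systolic peaks.

    Peaks are local maxima with a refractory period of 0.6 nominal cycles and
    a prominence of 30 % of the signal range; windows run midpoint-to-midpoint
    between adjacent peaks (clipped at the record edges).  Returns
    ``(window_slice, global_peak_index)`` pairs; empty on a flat signal.
    """
    if hr_hint <= 0:
        raise ValueError("heart-rate hint must be strictly positive")
    x = np.asarray(x, float)
    rng = np.ptp(x)
    if rng == 0:
        return []
    distance = max(1, int(round(0.6 * (60.0 / hr_hint) * fs)))
    peaks, _ = find_peaks(x, distance=distance, prominence=0.3 * rng)
    if len(peaks) == 0:
        return []
    mids = ((peaks[:-1] + peaks[1:]) // 2).tolist()
    half = int(round(0.5 * (60.0 / hr_hint) * fs))
    starts = [max(0, peaks[0] - half)] + mids
    stops = mids + [min(len(x), peaks[-1] + half)]
    return [(slice(a, b), int(p)) for a, b, p in zip(starts, stops, peaks)]


def detect_fiducials(
    beat: np.ndarray,
    d1: np.ndarray,
    d2: np.ndarray,
    d3: np.ndarray,
    fs: float,
    peak: Optional[int] = None,
    beat_index: int = 0,
) -> Optional[FiducialSet]:
    """Locate the landmark set inside one beat window.

    ``beat`` and the derivative arrays are the window slices; ``peak`` is the
    systolic peak index within the window (detected if omitted).  Returns
    ``None`` for invalid beats (no peak structure or ordering violation).
    Indices are window-relative; use :meth:`FiducialSet.shifted` to globalize.
    """
    beat = np.asarray(beat, float)
    n = len(beat)
    if n < 5:
        return None
    if peak is None:
        interior = np.argmax(beat[1:-1]) + 1
        peak = int(interior)
    if peak <= 1 or peak >= n - 1 or not (
        beat[peak] >= beat[peak - 1] and beat[peak] >= beat[peak + 1]
    ):
        return None  # no interior peak: monotone or degenerate window

    # foot: last -/+ sign change of d1 before the peak; argmin fallback
    foot = None
    for i in range(peak - 1, 0, -1):
        if d1[i] <= 0.0 < d1[i + 1]:
            foot = i + 1 if abs(d1[i + 1]) < abs(d1[i]) else i
            break
    if foot is None:
        foot = int(np.argmin(beat[:peak]))
    if foot >= peak:
        return None

    rising = foot + int(np.argmax(d1[foot:peak + 1]))
    fall = peak
    while fall + 1 < n and d1[fall + 1] < d1[fall]:
        fall += 1
    try:
        fs_set = FiducialSet(foot, rising, peak, fall, None, beat_index)
    except ValueError:
        return None

    # dicrotic notch: only when a dicrotic lobe exists after the descent
    notch = None
    tail = beat[fall:]
    if len(tail) > 2:
        lobes, _ = find_peaks(tail, prominence=_NOTCH_PROMINENCE * np.ptp(beat))
        if len(lobes):
            j = peak + 1
            while j + 1 < n and d3[j] <= 0.0:      # skip the zero at the peak
                j += 1
            while j + 1 < n and d3[j + 1] > 0.0:   # first +/- crossing after it
                j += 1
            if j + 1 < n and d3[j] > 0.0 >= d3[j + 1]:
                notch = j + 1
    if notch is not None:
        try:
            fs_set = FiducialSet(foot, rising, peak, fall, notch, beat_index)
        except ValueError:
            pass  # keep the four-landmark set
    return fs_set


def delineate(x: np.ndarray, fs: float, hr_hint: float) -> List[FiducialSet]:
    """Segment a conditioned record and detect fiducials in every beat.

    Returns valid landmark sets with record-global indices; invalid beats are
    dropped.
    """
    x = np.asarray(x, float)
    d1, d2, d3 = derivatives(x, fs)
    out: List[FiducialSet] = []
    for k, (win, peak) in enumerate(segment_beats(x, fs, hr_hint)):
        s = detect_fiducials(x[win], d1[win], d2[win], d3[win], fs,
                             peak=peak - win.start, beat_index=k)
        if s is not None:
            out.append(s.shifted(win.start))
    return out


def foot_times(x: np.ndarray, fs: float, hr_hint: float) -> np.ndarray:
    """Per-beat foot times in seconds (convenience for transit-time work)."""
    return np.array([s.foot / fs for s in delineate(x, fs, hr_hint)])


def detection_rate(
    fiducial_sets: Sequence[FiducialSet], expected_beats: int
) -> DetectionReport:
    """Per-landmark detection percentage against the expected beat count."""
    if expected_beats <= 0:
        raise ValueError("expected_beats must be strictly positive")
    detected = {name: 0 for name in LANDMARKS}
    for s in fiducial_sets:
        for name in LANDMARKS:
            if getattr(s, name) is not None:
                detected[name] += 1
    rate = {name: 100.0 * detected[name] / expected_beats for name in LANDMARKS}
    return DetectionReport(expected_beats=expected_beats, detected=detected,
                           success_rate=rate)
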