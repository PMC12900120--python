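"""Signal conditioning: baseline removal, adaptive low-pass, normalization.

The chain mirrors the acquisition pipeline of the phantom measurements: a
zero-phase high-pass at 0.2 Hz strips the maintained 30 mmHg baseline and any
slow drift, a zero-phase low-pass with a heart-rate-dependent cutoff (3, 6 or
8 Hz for the 30/60/80 bpm pump settings, keeping at least four harmonics)
suppresses wide-band noise, and an affine normalization maps each trial to
[0, 1] while retaining the scale so pulse pressure can still be read from the
pre-normalization amplitude.

Both filters are 4th-order Butterworth applied forward-backward
(zero phase), so fiducial timings are not shifted by filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "SpectrumEstimate",
    "NormalizedSignal",
    "remove_baseline",
    "estimate_fundamental",
    "select_cutoff",
    "lowpass_zero_phase",
    "normalize_amplitude",
]

#: nominal pump rate (bpm) -> low-pass cutoff (Hz); cutoff >= 4 harmonics
CUTOFF_BY_RATE = {30.0: 3.0, 60.0: 6.0, 80.0: 8.0}

_F0_BAND = (0.2, 3.0)  # fundamental search band, Hz


@dataclass(frozen=True)
class FilterSpec:
    hp_cutoff: float = 0.2
    lp_cutoff: float = 6.0
    filter_order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.hp_cutoff < self.lp_cutoff:
            raise ValueError("require 0 < hp_cutoff < lp_cutoff")


@dataclass(frozen=True)
class SpectrumEstimate:
    frequencies: np.ndarray
    power: np.ndarray
    f0: float
    low_confidence: bool = False


class NormalizedSignal(NamedTuple):
    values: np.ndarray  # in [0, 1]
    offset: float       # original minimum
    scale: float        # original range (max - min)


def _sos(order: int, cutoff: float, fs: float, btype: str) -> np.ndarray:
    return sps.butter(order, cutoff, btype=btype, fs=fs, output="sos")


def _filtfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= 3 * padlen:
        raise ValueError(
            f"signal of {len(x)} samples is too short for zero-phase filtering "
            f"(need > {3 * padlen})"
        )
    return sps.sosfiltfilt(sos, x)


def remove_baseline(x: np.ndarray, fs: float, hp_cutoff: float = 0.2,
                    order: int = 4) -> np.ndarray:
    """Zero-phase high-pass removing the constant offset and sub-cutoff drift."""
    if fs <= 2.0 * hp_cutoff:
        raise ValueError("sampling rate must exceed twice the high-pass cutoff")
    return _filtfilt(_sos(order, hp_cutoff, fs, "highpass"), np.asarray(x, float))


def estimate_fundamental(x: np.ndarray, fs: float) -> SpectrumEstimate:
    """Fundamental frequency from a Welch periodogram.

    Welch settings: 8 s Hann segments with 50 % overlap; the fundamental is
    the power maximum inside the [0.2, 3] Hz band plausible for pump rates.
    A peak below 3x the median band power is flagged low-confidence.
    """
    x = np.asarray(x, float)
    nperseg = int(8 * fs)
    if len(x) < 1.5 * nperseg:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than two Welch segments "
            f"({int(1.5 * nperseg)} samples)"
        )
    freqs, power = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=nperseg // 2)
    band = (freqs >= _F0_BAND[0]) & (freqs <= _F0_BAND[1])
    bp = power[band]
    bf = freqs[band]
    i = int(np.argmax(bp))
    low_conf = bool(bp[i] < 3.0 * np.median(bp))
    return SpectrumEstimate(frequencies=freqs, power=power, f0=float(bf[i]),
                            low_confidence=low_conf)


def select_cutoff(heart_rate_nominal: float) -> float:
    """Low-pass cutoff for a pump rate: nearest of the three nominal settings.

    The mapping {30 -> 3 Hz, 60 -> 6 Hz, 80 -> 8 Hz} keeps at least the first
    four harmonics of the fundamental; rates above 120 bpm would push the 4th
    harmonic past the largest available cutoff and are rejected.
    """
    hr = float(heart_rate_nominal)
    if hr <= 0:
        raise ValueError("heart rate must be strictly positive")
    if 4.0 * hr / 60.0 > max(CUTOFF_BY_RATE.values()):
        raise ValueError(
            f"heart rate {hr:g} bpm unsupported: 4th harmonic exceeds 8 Hz"
        )
    nominal = min(CUTOFF_BY_RATE, key=lambda r: abs(r - hr))
    return CUTOFF_BY_RATE[nominal]


def lowpass_zero_phase(x: np.ndarray, fs: float, lp_cutoff: float,
                       order: int = 4) -> np.ndarray:
    """Zero-phase low-pass; cutoff must stay below Nyquist."""
    if lp_cutoff >= fs / 2.0:
        raise ValueError("low-pass cutoff must be below the Nyquist frequency")
    return _filtfilt(_sos(order, lp_cutoff, fs, "lowpass"), np.asarray(x, float))


def normalize_amplitude(x: np.ndarray) -> NormalizedSignal:
    """Affine map of a whole trial onto [0, 1], returning offset and scale.

    The returned scale/offset let pulse pressure be computed from the
    pre-normalization amplitude: ``raw = values * scale + offset``.
    """
    x = np.asarray(x, float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("cannot normalize a constant signal (degenerate range)")
    return NormalizedSignal((x - lo) / (hi - lo), offset=lo, scale=hi - lo)
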