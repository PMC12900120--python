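"""Synthetic two-site pulse waveform generator with known ground truth.

Emulates a pulsatile-pump vascular phantom: silicone vessel segments of
varying Shore A hardness and wall thickness, driven at set stroke volumes and
heart rates, with two pressure sensors 30 cm apart and two capacitive sensors
5 cm inboard of them.  Each beat is a two-lobe pressure pulse riding on a
maintained 30 mmHg baseline: a Gaussian systolic lobe plus an asymmetric
dicrotic lobe whose broad right tail decays through diastole into a sharp
foot.  Morphology follows the qualitative trends of the physical setup:
pulse pressure and systole fraction grow with hardness while the dicrotic
lobe shrinks (degenerating into a shoulder for the stiffest walls).

The downstream channels are the upstream waveform delayed by the ground-truth
transit time ``distance / PWV`` where PWV comes from the Moens-Korteweg
relation applied to the configured Shore-A-to-elasticity conversion, so every
downstream stage (fiducial detection, transit-time estimation, hardness
regression) can be validated against exact truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .elasticity import PwvConstants, moens_korteweg, shore_to_elasticity

__all__ = [
    "SetupConfig",
    "GeneratorParams",
    "TruthBundle",
    "WaveformRecord",
    "BeatTemplate",
    "make_config_grid",
    "beat_template",
    "generate_record",
    "generate_dataset",
    "FULL_SV", "FULL_HR", "FULL_W", "FULL_SHA", "LOW_SHA",
]

# factorial grid of the study: 2 SV x 3 HR x 3 W x 5 ShA = 90 setups
FULL_SV = (10.0, 20.0)
FULL_HR = (30.0, 60.0, 80.0)
FULL_W = (1.0, 1.5, 2.0)
FULL_SHA = (10.0, 20.0, 30.0, 40.0, 50.0)
LOW_SHA = (10.0, 20.0, 30.0)

# channel geometry along the segment, metres from the upstream pressure site
CHANNEL_POSITIONS = {"p1": 0.0, "c1": 0.05, "c2": 0.25, "p2": 0.30}

# oversampled template resolution (samples per cardiac cycle)
_DENSE = 8192


@dataclass(frozen=True)
class SetupConfig:
    """One experimental condition of the phantom.

    stroke_volume in mL, heart_rate in bpm, wall_thickness in mm, shore_a on
    the (dimensionless) Shore A scale.
    """

    stroke_volume: float
    heart_rate: float
    wall_thickness: float
    shore_a: float

    def __post_init__(self) -> None:
        for name in ("stroke_volume", "heart_rate", "wall_thickness", "shore_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable knobs of the waveform generator.

    noise_sd is the white-noise standard deviation as a fraction of the pulse
    pressure; drift is a slow sinusoid below the 0.2 Hz baseline-removal
    cutoff; mean_offset is the maintained baseline pressure (30 mmHg).
    """

    fs: float = 200.0
    duration: float = 30.0
    noise_sd: float = 0.02
    drift_amp: float = 1.0
    drift_freq: float = 0.05
    mean_offset: float = 30.0
    # morphology maps (affine in the setup condition)
    pp_base: float = 8.0
    pp_sv: float = 0.4
    pp_sha: float = 0.25
    zeta_base: float = 0.28
    zeta_sha: float = 0.002
    dicrotic_base: float = 0.25
    dicrotic_sha: float = -0.004
    # right-tail width of the dicrotic lobe as a fraction of the cycle: the
    # lobe is asymmetric, narrow on the left (distinct notch) and broad on
    # the right so pressure decays through diastole into a well-defined foot
    # instead of a flat inter-beat gap
    dicrotic_tail: float = 0.22
    conversion_model: str = "Ruess"
    distance: float = 0.30
    attenuation: float = 0.95
    rho: float = 1000.0
    inner_diameter: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift_freq >= 0.2:
            raise ValueError("drift_freq must stay below the 0.2 Hz baseline cutoff")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be strictly positive")

    @property
    def constants(self) -> PwvConstants:
        return PwvConstants(rho=self.rho, d=self.inner_diameter, distance=self.distance)


@dataclass
class TruthBundle:
    """Ground truth attached to a generated record."""

    elasticity: float          # MPa
    pwv_true: float            # m/s
    delay_true: float          # s between the two pressure sites
    foot_times: np.ndarray     # true per-beat onset times, upstream channel, s
    pp_true: float             # signal units (mmHg)
    zeta_true: float           # realized systole fraction of the cycle
    landmarks: Dict[str, float] = field(default_factory=dict)  # within-beat times, s


@dataclass
class WaveformRecord:
    """Multi-channel time series plus the condition that produced it."""

    time: np.ndarray
    channels: Dict[str, np.ndarray]
    fs: float
    config: SetupConfig
    truth: TruthBundle | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if any(len(v) != n for v in self.channels.values()):
            raise ValueError("all channels must have the same length as time")
        if len(self.channels) < 2:
            raise ValueError("at least two channels are required for PTT estimation")


def make_config_grid(
    sv_list: Sequence[float] = FULL_SV,
    hr_list: Sequence[float] = FULL_HR,
    w_list: Sequence[float] = FULL_W,
    sha_list: Sequence[float] = FULL_SHA,
) -> List[SetupConfig]:
    """Cartesian product of setup levels, stroke-volume-major, hardness-minor."""
    for name, lst in (("sv_list", sv_list), ("hr_list", hr_list),
                      ("w_list", w_list), ("sha_list", sha_list)):
        if len(lst) == 0:
            raise ValueError(f"{name} must be non-empty")
    return [
        SetupConfig(sv, hr, w, sha)
        for sv, hr, w, sha in itertools.product(sv_list, hr_list, w_list, sha_list)
    ]


@dataclass
class BeatTemplate:
    """One noise-free cardiac cycle with analytic landmark truth.

    ``phase``/``values`` form a dense lookup table over one period (periodic);
    ``sampled`` is the cycle at the requested sampling rate.  Landmark times
    are in seconds from the start of the cycle; the template is phased so the
    pulse foot sits at 0.15 T.
    """

    period: float
    phase: np.ndarray
    values: np.ndarray
    sampled: np.ndarray
    fs: float
    landmarks: Dict[str, float]
    pp_true: float
    zeta_true: float
    dicrotic_amp: float
    # closed-form shape parameters for exact evaluation at arbitrary times
    mu_s: float = 0.0
    sigma_s: float = 1.0
    mu_d: float = 0.0
    sigma_d_l: float = 1.0
    sigma_d_r: float = 1.0
    dic: float = 0.0
    amp: float = 1.0
    offset: float = 0.0
    phase_shift: float = 0.0

    def eval(self, t: np.ndarray) -> np.ndarray:
        """Exact closed-form periodic evaluation at arbitrary times.

        Evaluating the lobes analytically (rather than resampling a lookup
        table) keeps sub-sample delays free of interpolation noise, which
        matters for foot detection near the diastolic minimum.
        """
        ph = np.mod(np.asarray(t, float) + self.phase_shift, self.period)
        base = _lobe_sum(ph, self.period, self.mu_s, self.sigma_s) \
            + self.dic * _lobe_sum(ph, self.period, self.mu_d,
                                   self.sigma_d_l, self.sigma_d_r)
        return self.offset + self.amp * base


def _lobe_sum(x: np.ndarray, period: float, mu: float, sigma_l: float,
              sigma_r: float | None = None) -> np.ndarray:
    """Periodically wrapped (optionally asymmetric) Gaussian lobe.

    With ``sigma_r`` given, the lobe uses ``sigma_l`` left of the centre and
    ``sigma_r`` right of it (continuous, C1 at the centre).  Three
    neighbouring periods suffice for the wrap.
    """
    out = np.zeros_like(np.asarray(x, float))
    for k in (-1, 0, 1):
        d = x - mu - k * period
        if sigma_r is None:
            s = sigma_l
        else:
            s = np.where(d < 0, sigma_l, sigma_r)
        out += np.exp(-(d**2) / (2.0 * s**2))
    return out


def beat_template(config: SetupConfig, params: GeneratorParams = GeneratorParams()) -> BeatTemplate:
    """Construct the single-cycle waveform for one setup condition.

    The cycle is ``mean_offset + A_s G(t; mu_s, s_s) + A_d G'(t; mu_d,
    s_dl, s_dr)`` where ``G'`` is an asymmetric Gaussian (narrow left flank,
    broad diastolic right tail).  The amplitude is scaled so max - min equals
    the target pulse pressure, the systolic width follows the target systole
    fraction, and the dicrotic amplitude decreases with hardness.  Landmarks
    (foot, rising steep, systolic peak, falling steep, dicrotic notch) are
    located on a dense oversampled evaluation of the closed-form template.
    """
    period = 60.0 / config.heart_rate
    n = int(round(period * params.fs))
    if n < 20:
        raise ValueError(
            f"cycle of {period:.3f} s is not representable at fs={params.fs} "
            "(need at least 20 samples per beat)"
        )
    pp_target = params.pp_base + params.pp_sv * config.stroke_volume \
        + params.pp_sha * config.shore_a
    zeta_target = params.zeta_base + params.zeta_sha * config.shore_a
    if not 0.15 < zeta_target < 0.6:
        raise ValueError("systole fraction target outside the plausible (0.15, 0.6) band")
    dic = max(0.0, params.dicrotic_base + params.dicrotic_sha * config.shore_a)

    sigma_s = zeta_target * period / 3.0
    mu_s = 0.15 * period + 2.2 * sigma_s
    mu_d = mu_s + 3.2 * sigma_s
    sigma_d_l = 0.75 * sigma_s
    sigma_d_r = params.dicrotic_tail * period

    dense_t = np.arange(_DENSE) * (period / _DENSE)
    raw = _lobe_sum(dense_t, period, mu_s, sigma_s) \
        + dic * _lobe_sum(dense_t, period, mu_d, sigma_d_l, sigma_d_r)
    # phase the cycle so the foot (global minimum of the periodic signal,
    # where the diastolic decay meets the next upstroke) sits at 0.15 T and
    # the whole beat fits inside one period without wrapping
    phase_shift = (int(np.argmin(raw)) - int(round(0.15 * _DENSE))) * (period / _DENSE)
    amp = pp_target / (raw.max() - raw.min())
    temp = BeatTemplate(
        period=period, phase=dense_t, values=np.empty(0), sampled=np.empty(0),
        fs=params.fs, landmarks={}, pp_true=pp_target, zeta_true=0.0,
        dicrotic_amp=dic * amp, mu_s=mu_s, sigma_s=sigma_s, mu_d=mu_d,
        sigma_d_l=sigma_d_l, sigma_d_r=sigma_d_r, dic=dic, amp=amp,
        offset=params.mean_offset, phase_shift=phase_shift,
    )
    values = temp.eval(dense_t)

    # landmark truth from the dense template and its derivatives
    dt = period / _DENSE
    d1 = np.gradient(values, dt, edge_order=2)
    d3 = np.gradient(np.gradient(d1, dt, edge_order=2), dt, edge_order=2)
    i_peak = int(np.argmax(values))
    i_foot = int(np.argmin(values))  # unique global minimum in the diastolic gap
    i_rise = i_foot + int(np.argmax(d1[i_foot:i_peak + 1]))
    i_fall = i_peak
    while i_fall + 1 < _DENSE and d1[i_fall + 1] < d1[i_fall]:
        i_fall += 1
    landmarks = {
        "foot": i_foot * dt,
        "rising_steep": i_rise * dt,
        "systolic_peak": i_peak * dt,
        "falling_steep": i_fall * dt,
    }
    # a notch exists only when the dicrotic lobe forms a distinct local
    # maximum after the descent (same 1 %-prominence rule as the detector);
    # in stiff configurations the lobe degenerates into a shoulder
    from scipy.signal import find_peaks
    lobes, _ = find_peaks(values[i_fall:], prominence=0.01 * np.ptp(values))
    if dic > 0.0 and len(lobes):
        j = i_peak + 1
        while j + 1 < _DENSE and d3[j] <= 0.0:     # skip the zero at the peak
            j += 1
        while j + 1 < _DENSE and d3[j + 1] > 0.0:  # first +/- crossing after it
            j += 1
        if j + 1 < _DENSE:
            landmarks["dicrotic_notch"] = (j + 1) * dt
    temp.values = values
    temp.landmarks = landmarks
    temp.zeta_true = (landmarks["falling_steep"] - landmarks["foot"]) / period
    temp.sampled = temp.eval(np.arange(n) / params.fs)
    return temp


def _record_rng(seed: int, index: int) -> np.random.Generator:
    # stable per-record substream: same (seed, position) -> same realization
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def generate_record(
    config: SetupConfig,
    params: GeneratorParams = GeneratorParams(),
    index: int = 0,
) -> WaveformRecord:
    """Generate one multi-channel record with ground truth.

    The upstream pressure channel tiles the beat template over the requested
    duration; each downstream channel is the same periodic waveform evaluated
    at ``t - position/PWV`` (fractional-sample delay by linear interpolation
    into the dense template) and attenuated with distance.  Baseline drift and
    white noise are added per channel.
    """
    temp = beat_template(config, params)
    e_mpa = shore_to_elasticity(config.shore_a, params.conversion_model)
    pwv = moens_korteweg(e_mpa, config.wall_thickness, params.constants)
    delay = params.distance / pwv
    if delay >= temp.period:
        raise ValueError(
            f"transit time {delay:.3f} s exceeds one cardiac cycle; unphysical setup"
        )

    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs
    rng = _record_rng(params.seed, index)
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    channels: Dict[str, np.ndarray] = {}
    for name, pos in CHANNEL_POSITIONS.items():
        ch_delay = pos / pwv
        gain = params.attenuation ** (pos / params.distance)
        clean = params.mean_offset + gain * (temp.eval(t - ch_delay) - params.mean_offset)
        drift = params.drift_amp * np.sin(2.0 * np.pi * params.drift_freq * t + drift_phase)
        noise = rng.normal(0.0, params.noise_sd * temp.pp_true, size=n) \
            if params.noise_sd > 0 else 0.0
        channels[name] = clean + drift + noise

    n_beats = int(np.floor((params.duration - temp.landmarks["foot"]) / temp.period))
    foot_times = temp.landmarks["foot"] + temp.period * np.arange(n_beats)
    truth = TruthBundle(
        elasticity=e_mpa, pwv_true=pwv, delay_true=delay,
        foot_times=foot_times, pp_true=temp.pp_true, zeta_true=temp.zeta_true,
        landmarks=dict(temp.landmarks),
    )
    return WaveformRecord(time=t, channels=channels, fs=params.fs,
                          config=config, truth=truth)


def generate_dataset(
    grid: Sequence[SetupConfig],
    params: GeneratorParams = GeneratorParams(),
) -> tuple[List[WaveformRecord], pd.DataFrame]:
    """One record per grid entry plus the ground-truth label table."""
    if len(grid) == 0:
        raise ValueError("configuration grid must be non-empty")
    records = []
    rows = []
    for i, cfg in enumerate(grid):
        rec = generate_record(cfg, params, index=i)
        records.append(rec)
        tr = rec.truth
        rows.append({
            "sv": cfg.stroke_volume, "hr": cfg.heart_rate,
            "w": cfg.wall_thickness, "sha": cfg.shore_a,
            "elasticity_mpa": tr.elasticity, "pwv_true": tr.pwv_true,
            "delay_true": tr.delay_true, "pp_true": tr.pp_true,
            "zeta_true": tr.zeta_true,
        })
    return records, pd.DataFrame(rows)
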