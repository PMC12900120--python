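"""Per-beat waveform features and per-trial aggregation.

From each beat's fiducial set we compute crest time (foot to systolic peak),
systole time (foot to falling steepest point), pulse pressure (foot-to-peak
amplitude on the pre-normalization signal) and the pulse-to-pulse interval
(consecutive feet).  Time features are normalized to a percentage of the
cardiac cycle, which compensates the unavoidable pump-rate variability across
trials, and everything is aggregated to one vector per trial by the median.

The engineered feature set (FE) adds nine physiologically motivated
transforms: the RR interval 60/HR, timing ratios against RR, the
compliance/stiffness proxies SV/PP and PP/SV, wall-thickness interactions
PP/W and W*PP, and the variance-stabilizing logs log(1+PP), log(1+SV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .fiducials import FiducialSet
from .synthgen import SetupConfig

__all__ = [
    "BeatFeatures",
    "FeatureVector",
    "beat_features",
    "normalize_time",
    "aggregate_trial",
    "engineer_features",
    "FE_KEYS",
    "feature_table",
]

FE_KEYS = (
    "rr", "systole_over_rr", "crest_over_rr", "sv_over_pp", "pp_over_sv",
    "pp_over_w", "w_times_pp", "log1p_pp", "log1p_sv",
)

#: column order of the per-trial feature table
TABLE_COLUMNS = (
    "sv", "hr", "w", "sha", "crest_pct", "systole_pct", "pp", "pp_interval",
) + FE_KEYS


@dataclass(frozen=True)
class BeatFeatures:
    pp_interval: float     # s, foot to next foot
    crest_time: float      # s, foot to systolic peak
    systole_time: float    # s, foot to falling steepest point
    pulse_pressure: float  # raw (pre-normalization) signal units

    def __post_init__(self) -> None:
        if not 0 < self.crest_time < self.systole_time < self.pp_interval:
            raise ValueError("beat timing invariant violated")
        if self.pulse_pressure <= 0:
            raise ValueError("pulse pressure must be strictly positive")


@dataclass
class FeatureVector:
    """One aggregated feature vector per trial."""

    crest_time_pct: float
    systole_time_pct: float
    pulse_pressure: float
    pp_interval: float
    sv: float
    hr: float
    w: float
    sha: float
    fe: Dict[str, float] = field(default_factory=dict)


def beat_features(
    fiducials: FiducialSet,
    raw_beat: np.ndarray,
    fs: float,
    next_foot: Optional[int] = None,
) -> Optional[BeatFeatures]:
    """Features of one beat from its landmarks and the pre-normalization signal.

    ``raw_beat`` is indexed by the same (global) sample indices as the
    fiducial set.  ``next_foot`` is the following beat's foot index, needed
    for the pulse-to-pulse interval; beats without a successor are skipped
    (return ``None``), as are beats whose landmarks are missing.
    """
    if next_foot is None:
        return None
    f, p, d = fiducials.foot, fiducials.systolic_peak, fiducials.falling_steep
    crest = (p - f) / fs
    systole = (d - f) / fs
    interval = (next_foot - f) / fs
    pp = float(raw_beat[p] - raw_beat[f])
    try:
        return BeatFeatures(pp_interval=interval, crest_time=crest,
                            systole_time=systole, pulse_pressure=pp)
    except ValueError:
        return None


def normalize_time(value_s: float, cycle_s: float) -> float:
    """A duration as a percentage of the cardiac cycle."""
    if not 0 < value_s < cycle_s:
        raise ValueError("duration must lie strictly inside one cycle")
    return 100.0 * value_s / cycle_s


def aggregate_trial(
    beats: Sequence[BeatFeatures], config: SetupConfig
) -> FeatureVector:
    """Median-aggregate per-beat features into one trial vector.

    The cycle length used for time normalization is the median pulse-to-pulse
    interval of the trial.  The median is robust to the occasional corrupted
    beat; fewer than 5 valid beats is tolerated but low-confidence.
    """
    if len(beats) == 0:
        raise ValueError("cannot aggregate a trial with zero valid beats")
    cycle = float(np.median([b.pp_interval for b in beats]))
    crest = float(np.median([b.crest_time for b in beats]))
    systole = float(np.median([b.systole_time for b in beats]))
    pp = float(np.median([b.pulse_pressure for b in beats]))
    return FeatureVector(
        crest_time_pct=normalize_time(crest, cycle),
        systole_time_pct=normalize_time(systole, cycle),
        pulse_pressure=pp,
        pp_interval=cycle,
        sv=config.stroke_volume, hr=config.heart_rate,
        w=config.wall_thickness, sha=config.shore_a,
    )


def engineer_features(fv: FeatureVector, config: SetupConfig | None = None) -> FeatureVector:
    """Populate the nine-entry engineered (FE) map on a trial vector."""
    if config is None:
        sv, hr, w = fv.sv, fv.hr, fv.w
    else:
        sv, hr, w = config.stroke_volume, config.heart_rate, config.wall_thickness
    pp = fv.pulse_pressure
    if sv <= 0:
        raise ValueError("stroke volume must be strictly positive")
    rr = 60.0 / hr
    fe = {
        "rr": rr,
        "systole_over_rr": (fv.systole_time_pct / 100.0 * fv.pp_interval) / rr,
        "crest_over_rr": (fv.crest_time_pct / 100.0 * fv.pp_interval) / rr,
        "pp_over_sv": pp / sv,
        "pp_over_w": pp / w,
        "w_times_pp": w * pp,
        "log1p_pp": math.log1p(pp),
        "log1p_sv": math.log1p(sv),
    }
    if pp <= 0:
        raise ValueError("sv_over_pp undefined at zero pulse pressure")
    fe["sv_over_pp"] = sv / pp
    fv.fe = {k: fe[k] for k in FE_KEYS}
    return fv


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Per-trial feature table in the canonical column order."""
    rows = []
    for fv in vectors:
        row = {
            "sv": fv.sv, "hr": fv.hr, "w": fv.w, "sha": fv.sha,
            "crest_pct": fv.crest_time_pct, "systole_pct": fv.systole_time_pct,
            "pp": fv.pulse_pressure, "pp_interval": fv.pp_interval,
        }
        row.update(fv.fe)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
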