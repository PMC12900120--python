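"""File formats, configuration and end-to-end pipeline orchestration.

A waveform record travels as a CSV with ``#key=value`` metadata header lines
(sampling rate and setup condition) followed by ``time_s,p1,c1,c2,p2``
columns; ground truth goes to a JSON sidecar.  :func:`run_pipeline` wires the
stages together: simulate -> condition -> delineate -> featurize -> estimate
hardness (OLS + ANFIS) -> convert to elasticity -> Moens-Korteweg PWV ->
compare against the transit-time reference and run the error statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .elasticity import (ErrorStats, PwvConstants, error_analysis,
                         estimate_pwv_from_hardness, reference_ptt, reference_pwv,
                         shore_to_elasticity, moens_korteweg)
from .features import (FeatureVector, aggregate_trial, beat_features,
                       engineer_features, feature_table)
from .fiducials import delineate
from .preprocess import (lowpass_zero_phase, normalize_amplitude, remove_baseline,
                         select_cutoff)
from .stiffness import (anfis_init, anfis_predict, anfis_train, cooks_filter,
                        fit_regression, predict_regression)
from .synthgen import (FULL_HR, FULL_SHA, FULL_SV, FULL_W, LOW_SHA, GeneratorParams,
                       SetupConfig, TruthBundle, WaveformRecord, generate_dataset,
                       make_config_grid)

__all__ = [
    "PipelineConfig", "RunReport",
    "write_record_csv", "read_record_csv",
    "process_record", "run_pipeline",
]

_HEADER_KEYS = {
    "fs": "fs", "sv_ml": "stroke_volume", "hr_bpm": "heart_rate",
    "wall_mm": "wall_thickness", "shore_a": "shore_a", "distance_m": "distance",
}
_CHANNELS = ("p1", "c1", "c2", "p2")


# ---------------------------------------------------------------- file I/O

def write_record_csv(record: WaveformRecord, path: str | Path,
                     distance_m: float = 0.30) -> Path:
    """Write a record as headered CSV; truth (if any) to a ``.truth.json`` sidecar."""
    path = Path(path)
    cfg = record.config
    lines = [
        f"#fs={record.fs:g}", f"#sv_ml={cfg.stroke_volume:g}",
        f"#hr_bpm={cfg.heart_rate:g}", f"#wall_mm={cfg.wall_thickness:g}",
        f"#shore_a={cfg.shore_a:g}", f"#distance_m={distance_m:g}",
    ]
    df = pd.DataFrame({"time_s": record.time,
                       **{c: record.channels[c] for c in _CHANNELS}})
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    if record.truth is not None:
        tr = record.truth
        sidecar = {
            "elasticity": tr.elasticity, "pwv_true": tr.pwv_true,
            "delay_true": tr.delay_true, "foot_times": tr.foot_times.tolist(),
            "pp_true": tr.pp_true, "zeta_true": tr.zeta_true,
            "landmarks": tr.landmarks,
        }
        path.with_suffix(".truth.json").write_text(json.dumps(sidecar))
    return path


def read_record_csv(path: str | Path) -> WaveformRecord:
    """Read a headered record CSV (and truth sidecar, when present)."""
    path = Path(path)
    meta: Dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key] = float(val)
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise ValueError(f"record header missing metadata key(s): {missing}")
    try:
        df = pd.read_csv(path, skiprows=n_header)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed record CSV {path.name}: {exc}") from exc
    expected = ["time_s", *_CHANNELS]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, found {list(df.columns)}")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + n_header + 2
        raise ValueError(f"truncated or non-numeric row near line {bad} of {path.name}")
    t = df["time_s"].to_numpy(float)
    fs = meta["fs"]
    if len(t) > 1 and not np.allclose(np.diff(t), 1.0 / fs, rtol=1e-6, atol=1e-9):
        raise ValueError("time column is not uniformly spaced at 1/fs")
    cfg = SetupConfig(meta["sv_ml"], meta["hr_bpm"], meta["wall_mm"], meta["shore_a"])
    truth = None
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        truth = TruthBundle(
            elasticity=d["elasticity"], pwv_true=d["pwv_true"],
            delay_true=d["delay_true"], foot_times=np.array(d["foot_times"]),
            pp_true=d["pp_true"], zeta_true=d["zeta_true"],
            landmarks=d.get("landmarks", {}),
        )
    return WaveformRecord(time=t, channels={c: df[c].to_numpy(float) for c in _CHANNELS},
                          fs=fs, config=cfg, truth=truth)


# ---------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run needs."""

    scenario: str = "full"          # 'full' (90 setups) or 'low' (54 setups)
    fs: float = 200.0
    duration: float = 30.0
    seed: int = 0
    epochs: int = 30
    filter_order: int = 4
    hp_cutoff: float = 0.2
    noise_sd: float = 0.02
    drift_amp: float = 1.0
    conversion_model: str = "Ruess"
    rho: float = 1000.0
    inner_diameter: float = 0.010
    distance: float = 0.30
    reference: bool = True          # run the 2000 sps transit-time validation
    reference_fs: float = 2000.0
    reference_duration: float = 30.0
    outdir: Optional[str] = None
    # explicit level overrides (None -> scenario defaults)
    sv_levels: Optional[List[float]] = None
    hr_levels: Optional[List[float]] = None
    w_levels: Optional[List[float]] = None
    sha_levels: Optional[List[float]] = None

    def grid_levels(self) -> Tuple[list, list, list, list]:
        sha_default = list(FULL_SHA if self.scenario == "full" else LOW_SHA)
        return (
            list(self.sv_levels or FULL_SV), list(self.hr_levels or FULL_HR),
            list(self.w_levels or FULL_W), list(self.sha_levels or sha_default),
        )

    def generator_params(self, fs: float | None = None,
                         duration: float | None = None) -> GeneratorParams:
        return GeneratorParams(
            fs=fs or self.fs, duration=duration or self.duration,
            noise_sd=self.noise_sd, drift_amp=self.drift_amp,
            conversion_model=self.conversion_model, distance=self.distance,
            rho=self.rho, inner_diameter=self.inner_diameter, seed=self.seed,
        )

    @property
    def constants(self) -> PwvConstants:
        return PwvConstants(rho=self.rho, d=self.inner_diameter,
                            distance=self.distance)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict()))
        path.write_text(text)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


# ------------------------------------------------------------- processing

def process_record(record: WaveformRecord, channel: str = "p1",
                   filter_order: int = 4, hp_cutoff: float = 0.2
                   ) -> Tuple[Optional[FeatureVector], dict]:
    """Condition one record and extract its aggregated trial features.

    Conditioning: baseline removal, heart-rate-adaptive low-pass,
    normalization for detection; pulse pressure is read from the filtered
    signal *before* normalization.  Returns ``(feature_vector | None,
    diagnostics)`` with per-stage beat counts.
    """
    cfg = record.config
    x = record.channels[channel]
    x0 = remove_baseline(x, record.fs, hp_cutoff, order=filter_order)
    lp = lowpass_zero_phase(x0, record.fs, select_cutoff(cfg.heart_rate),
                            order=filter_order)
    norm = normalize_amplitude(lp)
    sets = delineate(norm.values, record.fs, cfg.heart_rate)
    beats = []
    for cur, nxt in zip(sets, sets[1:]):
        bf = beat_features(cur, lp, record.fs, next_foot=nxt.foot)
        if bf is not None:
            beats.append(bf)
    diag = {"beats_detected": len(sets), "beats_used": len(beats),
            "beats_dropped": max(0, len(sets) - 1 - len(beats))}
    if not beats:
        return None, diag
    fv = engineer_features(aggregate_trial(beats, cfg))
    return fv, diag


# ------------------------------------------------------------- run report

@dataclass
class RunReport:
    n_trials: int
    n_trials_featurized: int
    beats_detected: int
    beats_used: int
    beats_dropped: int
    features: pd.DataFrame
    regression: dict
    anfis_holdout_rmse: Optional[float]
    pwv: pd.DataFrame
    error_stats: Dict[str, dict]
    config_digest: str
    version: str = __version__

    def digest(self) -> str:
        payload = json.dumps({
            "features": self.features.round(10).to_dict("records"),
            "regression": self.regression,
            "pwv": self.pwv.round(10).to_dict("records"),
            "error_stats": self.error_stats,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self) -> str:
        return json.dumps({
            "n_trials": self.n_trials,
            "n_trials_featurized": self.n_trials_featurized,
            "beats_detected": self.beats_detected,
            "beats_used": self.beats_used,
            "beats_dropped": self.beats_dropped,
            "features": self.features.to_dict("records"),
            "regression": self.regression,
            "anfis_holdout_rmse": self.anfis_holdout_rmse,
            "pwv": self.pwv.to_dict("records"),
            "error_stats": self.error_stats,
            "config_digest": self.config_digest,
            "version": self.version,
        })


def _stats_dict(s: ErrorStats) -> dict:
    return {"test_used": s.test_used, "shapiro_p": None if np.isnan(s.shapiro_p)
            else s.shapiro_p, "statistic": s.statistic, "p_value": s.p_value,
            "median": s.median, "iqr": s.iqr, "mean": s.mean}


ANFIS_INPUTS = ("sv", "hr", "w", "crest_pct", "pp", "systole_pct")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full synthetic-study pipeline and summarize it.

    Stage order is fixed: simulate the configuration grid, condition and
    delineate every record, aggregate trial features, fit the hardness
    estimators (Cook's-filtered OLS and ANFIS), convert estimated and true
    hardness to PWV through the configured conversion model, measure the
    reference PWV from 2000 sps two-site records, and run the paired error
    statistics for every method comparison.
    """
    sv, hr, w, sha = config.grid_levels()
    grid = make_config_grid(sv, hr, w, sha)
    stage = "simulate"
    try:
        records, labels = generate_dataset(grid, config.generator_params())
        stage = "features"
        fvs, diags, kept_cfgs = [], [], []
        for rec in records:
            fv, diag = process_record(rec, filter_order=config.filter_order,
                                      hp_cutoff=config.hp_cutoff)
            diags.append(diag)
            if fv is not None:
                fvs.append(fv)
                kept_cfgs.append(rec.config)
        if not fvs:
            raise RuntimeError("no trial produced valid features")
        feats = feature_table(fvs)

        stage = "hardness"
        Xreg = pd.DataFrame({
            "ST": feats["systole_pct"] / 100.0, "PP": feats["pp"],
            "SV": feats["sv"], "HR": feats["hr"], "W": feats["w"]})
        y = feats["sha"].to_numpy()
        mask = cooks_filter(Xreg, y)
        reg = fit_regression(Xreg, y, outlier_mask=mask)
        sha_r = np.array([predict_regression(reg, **row)
                          for row in Xreg.to_dict("records")])
        Xanf = feats[list(ANFIS_INPUTS)].to_numpy(float)
        model = anfis_init(Xanf, y)
        model, hist = anfis_train(model, Xanf, y, epochs=config.epochs,
                                  seed=config.seed)
        sha_f = anfis_predict(model, Xanf)

        stage = "pwv"
        rows = []
        for i, cfg in enumerate(kept_cfgs):
            pwv_t = estimate_pwv_from_hardness(cfg.shore_a, cfg.wall_thickness,
                                               config.conversion_model,
                                               config.constants, "T").value
            pwv_r = estimate_pwv_from_hardness(max(sha_r[i], 1.0),
                                               cfg.wall_thickness,
                                               config.conversion_model,
                                               config.constants, "R").value
            pwv_f = estimate_pwv_from_hardness(max(sha_f[i], 1.0),
                                               cfg.wall_thickness,
                                               config.conversion_model,
                                               config.constants, "F").value
            rows.append({"sv": cfg.stroke_volume, "hr": cfg.heart_rate,
                         "w": cfg.wall_thickness, "sha": cfg.shore_a,
                         "pwv_T": pwv_t, "pwv_R": pwv_r, "pwv_F": pwv_f})
        pwv = pd.DataFrame(rows)

        if config.reference:
            stage = "reference"
            ref_params = config.generator_params(fs=config.reference_fs,
                                                 duration=config.reference_duration)
            ref_records, _ = generate_dataset(
                [SetupConfig(r["sv"], r["hr"], r["w"], r["sha"])
                 for r in rows], ref_params)
            pwv_m = []
            for rec in ref_records:
                pwv_m.append(_measured_pwv(rec, config))
            pwv["pwv_M"] = pwv_m

        stage = "stats"
        stats: Dict[str, dict] = {
            "R_minus_T": _stats_dict(error_analysis(pwv["pwv_R"], pwv["pwv_T"])),
            "F_minus_T": _stats_dict(error_analysis(pwv["pwv_F"], pwv["pwv_T"])),
        }
        if config.reference:
            for a, b in (("T", "M"), ("R", "M"), ("F", "M")):
                stats[f"{a}_minus_{b}"] = _stats_dict(
                    error_analysis(pwv[f"pwv_{a}"], pwv[f"pwv_{b}"]))
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted in stage '{stage}': {exc}") from exc

    report = RunReport(
        n_trials=len(grid), n_trials_featurized=len(fvs),
        beats_detected=sum(d["beats_detected"] for d in diags),
        beats_used=sum(d["beats_used"] for d in diags),
        beats_dropped=sum(d["beats_dropped"] for d in diags),
        features=feats,
        regression=json.loads(reg.to_json()),
        anfis_holdout_rmse=(hist.holdout_rmse[-1] if hist.holdout_rmse else None),
        pwv=pwv, error_stats=stats, config_digest=config.digest(),
    )
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        feats.to_csv(out / "features.csv", index=False)
        pwv.to_csv(out / "pwv.csv", index=False)
        (out / "report.json").write_text(report.to_json())
    return report


def _measured_pwv(rec: WaveformRecord, config: PipelineConfig) -> float:
    """Reference PWV from foot-to-foot transit time between p1 and p2."""
    from .fiducials import foot_times

    cutoff = select_cutoff(rec.config.heart_rate)
    feet = {}
    for ch in ("p1", "p2"):
        x0 = remove_baseline(rec.channels[ch], rec.fs, config.hp_cutoff,
                             order=config.filter_order)
        lp = lowpass_zero_phase(x0, rec.fs, cutoff, order=config.filter_order)
        feet[ch] = foot_times(lp, rec.fs, rec.config.heart_rate)
    ptt = reference_ptt(feet["p1"], feet["p2"])
    return reference_pwv(ptt, config.constants).value
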