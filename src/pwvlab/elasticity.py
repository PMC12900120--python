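"""Shore A hardness -> Young's modulus conversion and Moens-Korteweg PWV.

Five empirical conversion models for silicone elastomers map the Shore A
indentation hardness ``S`` of an artificial vessel wall to a Young's modulus
``E`` in MPa.  The Moens-Korteweg relation

    PWV = sqrt(E * W / (rho * d))

then gives the pulse wave velocity of a thin-walled elastic tube of wall
thickness ``W`` and inner diameter ``d`` filled with an incompressible fluid
of density ``rho``.  The module also provides the reference transit-time
estimate between two measurement sites (``PWV = D / PTT``) and the paired
error statistics used to compare estimated against reference velocities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONVERSION_MODELS",
    "PwvConstants",
    "PwvEstimate",
    "ErrorStats",
    "shore_to_elasticity",
    "moens_korteweg",
    "theoretical_pwv_table",
    "reference_ptt",
    "reference_pwv",
    "estimate_pwv_from_hardness",
    "error_analysis",
]


def _gent(s: float) -> float:
    # Gent relation for Shore A -> MPa; singular at S = 100 (denominator zero).
    denom = 0.137505 * (254.0 - 2.54 * s)
    if denom == 0.0:
        raise ValueError("Gent conversion is singular at Shore A = 100")
    return 0.0981 * (56.0 + 7.62336 * s) / denom


#: name -> callable(S) returning Young's modulus in MPa (unrounded)
CONVERSION_MODELS: Dict[str, Callable[[float], float]] = {
    "DMA": lambda s: 0.2354 * math.exp(0.0657 * s),
    "Gent": _gent,
    "RDA": lambda s: 0.1611 * math.exp(0.058 * s),
    "Ruess": lambda s: math.exp(0.0235 * s - 0.6403),
    "Secant": lambda s: 0.1614 * math.exp(0.0541 * s),
}

#: canonical model ordering used in output tables
MODEL_ORDER = ("DMA", "Gent", "RDA", "Ruess", "Secant")


def _canonical_model_name(model: str) -> str:
    for name in CONVERSION_MODELS:
        if name.lower() == model.lower():
            return name
    raise KeyError(
        f"unknown conversion model {model!r}; choose one of {sorted(CONVERSION_MODELS)}"
    )


@dataclass(frozen=True)
class PwvConstants:
    """Physical constants of the phantom for Moens-Korteweg evaluation.

    rho
        Fluid density in kg/m^3 (water in the phantom loop).
    d
        Inner diameter of the vessel in metres.
    distance
        Separation of the two pressure measurement sites in metres.
    """

    rho: float = 1000.0
    d: float = 0.010
    distance: float = 0.30

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.d <= 0 or self.distance <= 0:
            raise ValueError("all PwvConstants must be strictly positive")


@dataclass(frozen=True)
class PwvEstimate:
    """A pulse wave velocity tagged by the method that produced it.

    method is one of ``R`` (regression-estimated hardness), ``F`` (fuzzy /
    ANFIS-estimated hardness), ``T`` (theoretical, from the true hardness) or
    ``M`` (measured, from the two-site transit time).
    """

    value: float
    method: str
    conversion: str | None = None
    config: object | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("PWV must be strictly positive")
        if self.method not in {"R", "F", "T", "M"}:
            raise ValueError(f"unknown method tag {self.method!r}")


def shore_to_elasticity(sha: float, model: str = "Ruess") -> float:
    """Convert Shore A hardness to Young's modulus in MPa (unrounded).

    Values outside the validated range [10, 50] are accepted (the models are
    smooth) but should be treated with caution.
    """
    if sha < 0:
        raise ValueError("Shore A hardness must be non-negative")
    return CONVERSION_MODELS[_canonical_model_name(model)](float(sha))


def moens_korteweg(
    e_mpa: float, wall_mm: float, constants: PwvConstants = PwvConstants()
) -> float:
    """Moens-Korteweg PWV in m/s from modulus (MPa) and wall thickness (mm)."""
    if e_mpa <= 0 or wall_mm <= 0:
        raise ValueError("modulus and wall thickness must be strictly positive")
    e_pa = e_mpa * 1e6
    w_m = wall_mm * 1e-3
    return math.sqrt(e_pa * w_m / (constants.rho * constants.d))


def theoretical_pwv_table(
    wall_mm_levels: Sequence[float] = (1.0, 1.5, 2.0),
    sha_levels: Sequence[float] = (10, 20, 30, 40, 50),
    models: Sequence[str] = MODEL_ORDER,
    constants: PwvConstants = PwvConstants(),
) -> pd.DataFrame:
    """Theoretical PWV over a (wall thickness, hardness, model) grid.

    Returns a long-format frame with columns ``wall_mm``, ``sha``, ``model``,
    ``pwv`` (unrounded) and ``pwv_2dp`` (display rounding).  Unrounded
    elasticity feeds the Moens-Korteweg step throughout.
    """
    rows = []
    for w in wall_mm_levels:
        for s in sha_levels:
            for m in models:
                name = _canonical_model_name(m)
                pwv = moens_korteweg(shore_to_elasticity(s, name), w, constants)
                rows.append(
                    {"wall_mm": w, "sha": s, "model": name,
                     "pwv": pwv, "pwv_2dp": round(pwv, 2)}
                )
    return pd.DataFrame(rows)


def elasticity_table(
    sha_levels: Sequence[float] = (10, 20, 30, 40, 50),
    models: Sequence[str] = MODEL_ORDER,
) -> pd.DataFrame:
    """Young's modulus (MPa) per hardness level and conversion model."""
    rows = []
    for s in sha_levels:
        for m in models:
            name = _canonical_model_name(m)
            e = shore_to_elasticity(s, name)
            rows.append({"sha": s, "model": name, "e_mpa": e, "e_2dp": round(e, 2)})
    return pd.DataFrame(rows)


def reference_ptt(
    foot_times_upstream: Sequence[float],
    foot_times_downstream: Sequence[float],
) -> float:
    """Median beat-to-beat transit time between two foot-time sequences.

    Each upstream foot is paired with the nearest downstream foot within half
    a cardiac cycle; the per-beat differences (downstream minus upstream) are
    aggregated by the median so an occasional mis-detection does not bias the
    trial value.
    """
    up = np.asarray(foot_times_upstream, dtype=float)
    down = np.asarray(foot_times_downstream, dtype=float)
    if up.size == 0 or down.size == 0:
        raise ValueError("both foot-time lists must be non-empty")
    if up.size > 1:
        cycle = float(np.median(np.diff(np.sort(up))))
    else:
        cycle = np.inf
    window = 0.5 * cycle
    diffs = []
    for t in up:
        j = int(np.argmin(np.abs(down - t)))
        if abs(down[j] - t) < window:
            diffs.append(down[j] - t)
    if not diffs:
        raise ValueError("no pairable beats between the two channels")
    ptt = float(np.median(diffs))
    if ptt <= 0:
        raise ValueError(
            "negative transit time: downstream channel appears to lead upstream "
            "(channels swapped?)"
        )
    return ptt


def reference_pwv(
    ptt: float, constants: PwvConstants = PwvConstants(), config: object | None = None
) -> PwvEstimate:
    """Measured PWV = sensor separation / transit time, tagged method ``M``."""
    if ptt <= 0:
        raise ValueError("transit time must be strictly positive")
    return PwvEstimate(constants.distance / ptt, method="M", config=config)


def estimate_pwv_from_hardness(
    sha_estimate: float,
    wall_mm: float,
    model: str = "Ruess",
    constants: PwvConstants = PwvConstants(),
    method_tag: str = "R",
    config: object | None = None,
) -> PwvEstimate:
    """Hardness estimate -> elasticity -> Moens-Korteweg PWV (method R or F)."""
    name = _canonical_model_name(model)
    e = shore_to_elasticity(sha_estimate, name)
    pwv = moens_korteweg(e, wall_mm, constants)
    return PwvEstimate(pwv, method=method_tag, conversion=name, config=config)


@dataclass
class ErrorStats:
    """Paired-error summary with a normality-gated location test.

    The Shapiro-Wilk test at alpha = 0.05 decides the location test for the
    paired differences: normality not rejected -> one-sample two-sided
    Student's t-test against zero; rejected -> two-sided Wilcoxon signed-rank
    (zero differences dropped, normal approximation for n > 25).
    """

    differences: np.ndarray
    shapiro_p: float
    test_used: str
    statistic: float
    p_value: float
    median: float
    iqr: float
    mean: float
    degenerate: bool = False
    alpha: float = field(default=0.05, repr=False)


def error_analysis(
    estimates: Sequence[float], references: Sequence[float], alpha: float = 0.05
) -> ErrorStats:
    """Analyse paired errors ``estimate - reference`` against a zero location."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimates and references must be paired (equal length)")
    if est.size < 3:
        raise ValueError("need at least 3 pairs for the location test")
    d = est - ref
    median = float(np.median(d))
    iqr = float(np.subtract(*np.percentile(d, [75, 25])))
    mean = float(np.mean(d))
    if np.allclose(d, 0.0):
        return ErrorStats(d, shapiro_p=float("nan"), test_used="degenerate",
                          statistic=0.0, p_value=1.0, median=median, iqr=iqr,
                          mean=mean, degenerate=True, alpha=alpha)
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p >= alpha:
        res = stats.ttest_1samp(d, 0.0)
        test_used = "t_test"
    else:
        nz = d[d != 0.0]
        method = "approx" if nz.size > 25 else "exact"
        res = stats.wilcoxon(nz, alternative="two-sided", method=method)
        test_used = "wilcoxon"
    return ErrorStats(d, shapiro_p=shapiro_p, test_used=test_used,
                      statistic=float(res.statistic), p_value=float(res.pvalue),
                      median=median, iqr=iqr, mean=mean, alpha=alpha)
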