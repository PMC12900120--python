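"""Hardness estimation from waveform features.

Three estimator families recover the Shore A hardness of the vessel wall
from the per-trial features (systole time ST, pulse pressure PP) and the
known pump/tube settings (stroke volume SV, heart rate HR, wall thickness W):

* ordinary least squares with Cook's-distance outlier screening,
* a first-order Sugeno ANFIS (see :mod:`pwvlab.anfis`),
* a benchmark of ML/DL classifiers and snap-to-class regressors evaluated by
  stratified 5-fold cross-validation with macro-averaged F1 / sensitivity /
  specificity and MAE/RMSE on the numeric Shore A scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import (GradientBoostingRegressor, HistGradientBoostingClassifier,
                              RandomForestClassifier, RandomForestRegressor)
from sklearn.linear_model import Lasso, LogisticRegression, Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVC, SVR

from ._nnet import TinyNet, coral_head
from .anfis import AnfisModel, anfis_forward, anfis_init, anfis_predict, anfis_train

__all__ = [
    "REGRESSORS", "RegressionModel", "BenchmarkResult",
    "cooks_filter", "fit_regression", "predict_regression",
    "snap_to_class", "classification_metrics", "run_benchmark",
    "coral_head",
    "AnfisModel", "anfis_init", "anfis_forward", "anfis_predict", "anfis_train",
]

#: predictor order of the hardness regression
REGRESSORS = ("ST", "PP", "SV", "HR", "W")

FULL_CLASSES = (10.0, 20.0, 30.0, 40.0, 50.0)
LOW_CLASSES = (10.0, 20.0, 30.0)


@dataclass
class RegressionModel:
    """OLS hardness model: ShA ~ intercept + ST + PP + SV + HR + W."""

    coefficients: Dict[str, float]
    standard_errors: Dict[str, float]
    t_values: Dict[str, float]
    p_values: Dict[str, float]
    r_squared: float
    n_used: int
    outlier_mask: np.ndarray | None = None

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("coefficients", "standard_errors", "t_values", "p_values",
              "r_squared", "n_used")}
        d["outlier_mask"] = (None if self.outlier_mask is None
                             else self.outlier_mask.astype(int).tolist())
        return json.dumps(d)


@dataclass
class BenchmarkResult:
    scenario: str
    model_name: str
    f1_macro: float
    sens_macro: float
    spec_macro: float
    mae_sha: float
    rmse_sha: float
    fold_seeds: Tuple[int, ...] = ()


def _design(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in REGRESSORS if c not in X.columns]
        if missing:
            raise KeyError(f"missing predictor column(s): {missing}")
        return X[list(REGRESSORS)].to_numpy(float)
    X = np.asarray(X, float)
    if X.shape[1] != len(REGRESSORS):
        raise ValueError(f"expected {len(REGRESSORS)} predictor columns")
    return X


def cooks_filter(X: pd.DataFrame | np.ndarray, y: Sequence[float],
                 threshold: float | None = None) -> np.ndarray:
    """Flag influential observations by Cook's distance from a full-data fit.

    A single OLS pass computes ``D_i = r_i^2 h_ii / (p s^2 (1 - h_ii)^2)``;
    observations with ``D_i > 4/n`` (the conventional threshold) are flagged.
    Returns a boolean mask, True = outlier.
    """
    Xd = _design(X)
    y = np.asarray(y, float)
    n, p = Xd.shape
    if n <= p + 1:
        raise ValueError(f"need more than p + 1 = {p + 1} observations, got {n}")
    model = sm.OLS(y, sm.add_constant(Xd)).fit()
    d = model.get_influence().cooks_distance[0]
    thr = 4.0 / n if threshold is None else threshold
    return d > thr


def fit_regression(X: pd.DataFrame | np.ndarray, y: Sequence[float],
                   outlier_mask: np.ndarray | None = None) -> RegressionModel:
    """OLS fit of Shore A hardness on (ST, PP, SV, HR, W).

    ``outlier_mask`` (True = drop) is typically the :func:`cooks_filter`
    output; coefficient tests are two-sided t-tests with n_used - 6 degrees
    of freedom.
    """
    Xd = _design(X)
    y = np.asarray(y, float)
    if outlier_mask is not None:
        keep = ~np.asarray(outlier_mask, bool)
        Xd, y = Xd[keep], y[keep]
    if len(y) <= len(REGRESSORS) + 1:
        raise ValueError("too few observations after outlier removal")
    Xc = sm.add_constant(Xd)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(
            f"rank-deficient design matrix in columns {('intercept',) + REGRESSORS}")
    res = sm.OLS(y, Xc).fit()
    names = ("intercept",) + REGRESSORS
    # constant target: zero total variance, define R^2 = 0
    r2 = float(res.rsquared) if res.centered_tss > 0 else 0.0
    return RegressionModel(
        coefficients=dict(zip(names, res.params)),
        standard_errors=dict(zip(names, res.bse)),
        t_values=dict(zip(names, res.tvalues)),
        p_values=dict(zip(names, res.pvalues)),
        r_squared=r2,
        n_used=int(res.nobs),
        outlier_mask=None if outlier_mask is None else np.asarray(outlier_mask, bool),
    )


def predict_regression(model: RegressionModel | Dict[str, float],
                       ST: float, PP: float, SV: float, HR: float, W: float) -> float:
    """Affine evaluation of the hardness regression."""
    coefs = model.coefficients if isinstance(model, RegressionModel) else model
    vals = {"ST": ST, "PP": PP, "SV": SV, "HR": HR, "W": W}
    return float(coefs["intercept"]
                 + sum(coefs[k] * vals[k] for k in REGRESSORS))


def snap_to_class(value: float | np.ndarray,
                  grid: Sequence[float] = FULL_CLASSES) -> float | np.ndarray:
    """Nearest discrete class on an ordered grid.

    Exact midpoints round up to the higher class; values beyond the grid
    clamp to the nearest endpoint.
    """
    g = np.asarray(grid, float)
    if g.size == 0:
        raise ValueError("class grid must be non-empty")
    if np.any(np.diff(g) <= 0):
        raise ValueError("class grid must be sorted ascending")
    v = np.atleast_1d(np.asarray(value, float))
    # distance ties broken toward the higher class: search on midpoints
    mids = (g[:-1] + g[1:]) / 2.0
    idx = np.searchsorted(mids, v, side="right")
    out = g[idx]
    return float(out[0]) if np.ndim(value) == 0 else out


def classification_metrics(
    y_true: Sequence[float], y_pred: Sequence[float], classes: Sequence[float]
) -> Tuple[float, float, float, float, float]:
    """Macro F1 / sensitivity / specificity and numeric-label MAE / RMSE.

    Per-class one-vs-rest precision and recall are macro-averaged with the
    zero-division -> 0 convention; specificity is TN / (TN + FP) per class,
    macro-averaged.  Predicted class labels are treated as numeric Shore A
    values for MAE and RMSE.
    """
    yt = np.asarray(y_true, float)
    yp = np.asarray(y_pred, float)
    cls = np.asarray(classes, float)
    if yt.shape != yp.shape:
        raise ValueError("label vectors must be aligned")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if not np.all(np.isin(arr, cls)):
            raise ValueError(f"{name} contains labels outside the class set")
    f1s, senss, specs = [], [], []
    for c in cls:
        tp = np.sum((yt == c) & (yp == c))
        fp = np.sum((yt != c) & (yp == c))
        fn = np.sum((yt == c) & (yp != c))
        tn = np.sum((yt != c) & (yp != c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        senss.append(rec)
        specs.append(tn / (tn + fp) if tn + fp else 0.0)
    err = yp - yt
    return (float(np.mean(f1s)), float(np.mean(senss)), float(np.mean(specs)),
            float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2))))


def _model_zoo(seed: int, n_classes: int) -> Dict[str, Tuple[str, object]]:
    """(kind, estimator) per benchmark entry; kind is 'clf', 'reg' or 'dl'."""
    return {
        "ML_Logistic": ("clf", LogisticRegression(max_iter=5000)),
        "ML_SVC_RBF": ("clf", SVC(kernel="rbf")),
        "ML_KNN": ("clf", KNeighborsClassifier(n_neighbors=5)),
        "ML_RF": ("clf", RandomForestClassifier(n_estimators=200, random_state=seed)),
        # leaf size reduced from the default 20: training folds here hold
        # only a few dozen samples
        "ML_HistGB": ("clf", HistGradientBoostingClassifier(
            min_samples_leaf=5, random_state=seed)),
        "ML_RidgeSnap": ("reg", Ridge()),
        "ML_Poly_RidgeSnap": ("reg", make_pipeline(
            PolynomialFeatures(degree=2, include_bias=False), Ridge())),
        "ML_Poly_LassoSnap": ("reg", make_pipeline(
            PolynomialFeatures(degree=2, include_bias=False),
            Lasso(alpha=0.01, max_iter=50000))),
        "ML_SVR_RBF_Snap": ("reg", SVR(kernel="rbf")),
        "ML_RF_Reg_Snap": ("reg", RandomForestRegressor(n_estimators=200,
                                                        random_state=seed)),
        "ML_GB_Reg_Snap": ("reg", GradientBoostingRegressor(random_state=seed)),
        "DL_MLP_softmax": ("dl", TinyNet(n_classes, head="softmax", seed=seed)),
        "DL_Ordinal_CORAL": ("dl", TinyNet(n_classes, head="coral", seed=seed)),
        "DL_MC_Dropout_MLP": ("dl", TinyNet(n_classes, head="softmax", dropout=0.2,
                                            mc_passes=100, seed=seed)),
    }


def run_benchmark(feature_table: pd.DataFrame, scenario: str = "FULL_10_50",
                  seed: int = 0,
                  feature_cols: Sequence[str] | None = None) -> List[BenchmarkResult]:
    """Stratified 5-fold out-of-fold benchmark of all model families.

    ``feature_table`` must carry a ``sha`` label column; ``scenario`` selects
    the class grid (``FULL_10_50`` -> {10..50}, ``LOW_10_30`` -> {10, 20, 30},
    rows outside the grid are dropped).  Features are standardized inside each
    training fold; out-of-fold predictions are pooled before computing the
    metrics.  Identical seeds reproduce identical results.
    """
    if scenario == "FULL_10_50":
        classes = np.asarray(FULL_CLASSES)
    elif scenario == "LOW_10_30":
        classes = np.asarray(LOW_CLASSES)
    else:
        raise ValueError("scenario must be FULL_10_50 or LOW_10_30")
    df = feature_table[feature_table["sha"].isin(classes)].reset_index(drop=True)
    if feature_cols is None:
        feature_cols = [c for c in df.columns if c != "sha"]
    X = df[list(feature_cols)].to_numpy(float)
    y = df["sha"].to_numpy(float)
    _, counts = np.unique(y, return_counts=True)
    n_splits = 5
    if counts.min() < n_splits:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot build "
            f"{n_splits} stratified folds with every class present")
    y_idx = np.searchsorted(classes, y)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    results: List[BenchmarkResult] = []
    for name, (kind, proto) in _model_zoo(seed, len(classes)).items():
        oof = np.empty_like(y)
        for tr, te in folds:
            scaler = StandardScaler().fit(X[tr])
            Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
            est = clone_estimator(proto)
            if kind == "clf":
                est.fit(Xtr, y[tr])
                oof[te] = est.predict(Xte)
            elif kind == "reg":
                est.fit(Xtr, y[tr])
                oof[te] = snap_to_class(est.predict(Xte), classes)
            else:  # dl: integer class indices
                est.fit(Xtr, y_idx[tr])
                oof[te] = classes[np.clip(est.predict(Xte), 0, len(classes) - 1)]
        f1, sens, spec, mae, rmse = classification_metrics(y, oof, classes)
        results.append(BenchmarkResult(scenario=scenario, model_name=name,
                                       f1_macro=f1, sens_macro=sens,
                                       spec_macro=spec, mae_sha=mae,
                                       rmse_sha=rmse, fold_seeds=(seed,)))
    return results


def clone_estimator(proto):
    """Fresh copy of a zoo prototype (sklearn clone or TinyNet re-init)."""
    if isinstance(proto, TinyNet):
        return TinyNet(proto.n_classes, head=proto.head, hidden=proto.hidden,
                       dropout=proto.dropout, mc_passes=proto.mc_passes,
                       lr=proto.lr, max_epochs=proto.max_epochs,
                       patience=proto.patience, seed=proto.seed)
    from sklearn.base import clone
    return clone(proto)


def benchmark_table(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "scenario": r.scenario, "model": r.model_name, "f1_macro": r.f1_macro,
        "sens_macro": r.sens_macro, "spec_macro": r.spec_macro,
        "mae_sha": r.mae_sha, "rmse_sha": r.rmse_sha,
    } for r in results]).sort_values(["scenario", "f1_macro"],
                                     ascending=[True, False]).reset_index(drop=True)
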