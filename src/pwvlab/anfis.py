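"""First-order Sugeno ANFIS with hybrid least-squares / gradient learning.

The network is the classical five-layer adaptive neuro-fuzzy inference
system: Gaussian membership functions fuzzify each input, rules fire with the
product t-norm, firing strengths are normalized, each rule contributes an
affine (first-order) consequent, and the output is the firing-weighted
average of the rule outputs.

Training is the standard hybrid scheme: per epoch, all consequent
coefficients are re-estimated jointly by (lightly ridge-regularized) linear
least squares given the current memberships, then one batch gradient step
with an adaptive learning rate updates the membership centers and widths.
With the default grid partition of 2 membership functions on each of 6
inputs the rule base has 2^6 = 64 rules and 64 x 7 = 448 consequent
coefficients plus 24 premise parameters.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = ["AnfisModel", "TrainHistory", "anfis_init", "anfis_forward",
           "anfis_predict", "anfis_train"]

_RIDGE = 1e-8       # LSE regularization for near-degenerate firing patterns
_SIGMA_FLOOR = 1e-4
_FIRING_GUARD = 1e-300


@dataclass
class AnfisModel:
    """Gaussian membership parameters, rule table and affine consequents.

    centers/sigmas have shape (n_inputs, n_mfs); rules is an integer array
    (n_rules, n_inputs) giving the membership index each rule uses per input;
    consequents has shape (n_rules, n_inputs + 1) with the bias last.  Inputs
    are standardized by (x - x_mean) / x_scale before entering the network.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    rules: np.ndarray
    consequents: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[0]

    @property
    def n_rules(self) -> int:
        return self.rules.shape[0]

    @property
    def n_consequent_params(self) -> int:
        return int(self.consequents.size)

    @property
    def n_premise_params(self) -> int:
        return int(self.centers.size + self.sigmas.size)

    def to_json(self) -> str:
        return json.dumps({
            "centers": self.centers.tolist(), "sigmas": self.sigmas.tolist(),
            "rules": self.rules.tolist(), "consequents": self.consequents.tolist(),
            "x_mean": self.x_mean.tolist(), "x_scale": self.x_scale.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "AnfisModel":
        d = json.loads(text)
        return cls(
            centers=np.array(d["centers"]), sigmas=np.array(d["sigmas"]),
            rules=np.array(d["rules"], dtype=int),
            consequents=np.array(d["consequents"]),
            x_mean=np.array(d["x_mean"]), x_scale=np.array(d["x_scale"]),
        )


@dataclass
class TrainHistory:
    train_rmse: List[float] = field(default_factory=list)
    holdout_rmse: List[float] = field(default_factory=list)
    sse_before_lse: List[float] = field(default_factory=list)
    sse_after_lse: List[float] = field(default_factory=list)


def anfis_init(X: np.ndarray, y: np.ndarray | None = None,
               mfs_per_input: int = 2, spread: float = 1.0) -> AnfisModel:
    """Grid-partition initialization on standardized inputs.

    Membership centers sit at empirical quantiles of each (standardized)
    column - min and max for two functions - with widths
    ``range / (2 (m - 1)) * spread``; the rule base is the full Cartesian
    product of membership choices and consequents start at zero.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_inputs)")
    if mfs_per_input < 2:
        raise ValueError("need at least 2 membership functions per input")
    n, p = X.shape
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    if np.any(x_scale == 0):
        bad = [int(j) for j in np.flatnonzero(x_scale == 0)]
        raise ValueError(f"constant input column(s) {bad}: zero membership width")
    Z = (X - x_mean) / x_scale
    qs = np.linspace(0.0, 1.0, mfs_per_input)
    centers = np.quantile(Z, qs, axis=0).T          # (p, m)
    rng_col = Z.max(axis=0) - Z.min(axis=0)         # (p,)
    sigma = rng_col / (2.0 * (mfs_per_input - 1)) * spread
    sigmas = np.repeat(sigma[:, None], mfs_per_input, axis=1)
    rules = np.array(list(itertools.product(range(mfs_per_input), repeat=p)),
                     dtype=int)
    consequents = np.zeros((rules.shape[0], p + 1))
    return AnfisModel(centers=centers, sigmas=sigmas, rules=rules,
                      consequents=consequents, x_mean=x_mean, x_scale=x_scale)


def _memberships(model: AnfisModel, Z: np.ndarray) -> np.ndarray:
    # (n, p, m) Gaussian membership grades on standardized inputs
    diff = Z[:, :, None] - model.centers[None, :, :]
    return np.exp(-(diff**2) / (2.0 * model.sigmas[None, :, :] ** 2))


def _firing(model: AnfisModel, Z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Raw and normalized rule firing strengths, shapes (n, n_rules)."""
    mu = _memberships(model, Z)                       # (n, p, m)
    cols = np.arange(model.n_inputs)[None, :]
    mu_r = mu[:, cols, model.rules]                   # (n, n_rules, p)
    w = np.prod(mu_r, axis=2)
    tot = w.sum(axis=1, keepdims=True)
    wn = np.where(tot < _FIRING_GUARD, 1.0 / model.n_rules, w / np.maximum(tot, _FIRING_GUARD))
    return w, wn


def _rule_outputs(model: AnfisModel, Z: np.ndarray) -> np.ndarray:
    # affine consequents on standardized inputs: (n, n_rules)
    return Z @ model.consequents[:, :-1].T + model.consequents[:, -1]


def anfis_forward(model: AnfisModel, x: np.ndarray) -> float | np.ndarray:
    """Five-layer forward pass on already-standardized input(s).

    Accepts a single vector or an (n, n_inputs) matrix in the model's
    standardized coordinates (use :func:`anfis_predict` for raw inputs).
    """
    Z = np.atleast_2d(np.asarray(x, float))
    _, wn = _firing(model, Z)
    f = _rule_outputs(model, Z)
    y = np.sum(wn * f, axis=1)
    return float(y[0]) if np.ndim(x) == 1 else y


def anfis_predict(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Forward pass on raw (unstandardized) inputs."""
    X = np.atleast_2d(np.asarray(X, float))
    Z = (X - model.x_mean) / model.x_scale
    return np.asarray(anfis_forward(model, Z))


def _lse_consequents(model: AnfisModel, Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Jointly re-estimate all consequents by ridge-regularized least squares.

    Design matrix rows are the rule-blocks [wn_i * z, wn_i] so the normal
    equations solve all n_rules x (p + 1) coefficients at once.
    """
    _, wn = _firing(model, Z)
    n, p = Z.shape
    Z1 = np.hstack([Z, np.ones((n, 1))])              # (n, p+1)
    A = (wn[:, :, None] * Z1[:, None, :]).reshape(n, -1)
    ata = A.T @ A + _RIDGE * np.eye(A.shape[1])
    coef = np.linalg.solve(ata, A.T @ y)
    return coef.reshape(model.n_rules, p + 1)


def _sse(model: AnfisModel, Z: np.ndarray, y: np.ndarray) -> float:
    r = anfis_forward(model, Z) - y
    return float(r @ r)


def _premise_gradients(model: AnfisModel, Z: np.ndarray, y: np.ndarray
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """d SSE / d centers and d SSE / d sigmas (batch, exact)."""
    n, p = Z.shape
    w, wn = _firing(model, Z)
    f = _rule_outputs(model, Z)
    yhat = np.sum(wn * f, axis=1)
    e = yhat - y
    tot = np.maximum(w.sum(axis=1), _FIRING_GUARD)
    # d yhat / d w_k = (f_k - yhat) / sum(w)
    dy_dw = (f - yhat[:, None]) / tot[:, None]        # (n, r)
    common = 2.0 * e[:, None] * dy_dw * w             # (n, r); includes w_k factor
    gc = np.zeros_like(model.centers)
    gs = np.zeros_like(model.sigmas)
    for j in range(p):
        zj = Z[:, j][:, None]
        for m in range(model.centers.shape[1]):
            mask = model.rules[:, j] == m             # rules using MF (j, m)
            if not mask.any():
                continue
            c, s = model.centers[j, m], model.sigmas[j, m]
            # d ln(mu) / dc and / dsigma; w_k includes mu as a factor
            dln_dc = (zj - c) / s**2
            dln_ds = (zj - c) ** 2 / s**3
            contrib = common[:, mask].sum(axis=1, keepdims=True)
            gc[j, m] = float((contrib * dln_dc).sum())
            gs[j, m] = float((contrib * dln_ds).sum())
    return gc, gs


def anfis_train(
    model: AnfisModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 30,
    holdout: float = 0.25,
    seed: int = 42,
    learning_rate: float = 0.01,
) -> Tuple[AnfisModel, TrainHistory]:
    """Hybrid training: per-epoch LSE for consequents + one premise gradient step.

    The data are shuffled and split into training (1 - holdout) and holdout
    fractions, stratified by the target level when every level has at least
    two members.  The learning rate adapts Jang-style: x1.1 after an
    improving premise step, x0.5 (and revert) after a worsening one.  Raises
    on a non-finite loss.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if len(X) != len(y):
        raise ValueError("X and y must be aligned")
    levels, counts = np.unique(y, return_counts=True)
    strat = y if (len(levels) > 1 and counts.min() >= 2) else None
    if 0.0 < holdout < 1.0:
        Xtr, Xho, ytr, yho = train_test_split(
            X, y, test_size=holdout, random_state=seed, shuffle=True, stratify=strat)
    else:
        Xtr, Xho, ytr, yho = X, X[:0], y, y[:0]

    Ztr = (Xtr - model.x_mean) / model.x_scale
    Zho = (Xho - model.x_mean) / model.x_scale
    hist = TrainHistory()
    lr = learning_rate
    for _ in range(epochs):
        # (a) least-squares consequent update
        sse0 = _sse(model, Ztr, ytr)
        model.consequents = _lse_consequents(model, Ztr, ytr)
        sse1 = _sse(model, Ztr, ytr)
        if not np.isfinite(sse1):
            raise FloatingPointError(
                f"non-finite training loss after LSE step (before: {sse0:.3g})")
        hist.sse_before_lse.append(sse0)
        hist.sse_after_lse.append(sse1)
        hist.train_rmse.append(float(np.sqrt(sse1 / len(ytr))))
        if len(yho):
            r = anfis_forward(model, Zho) - yho
            hist.holdout_rmse.append(float(np.sqrt(np.mean(r**2))))

        # (b) one adaptive gradient step on the premise parameters
        gc, gs = _premise_gradients(model, Ztr, ytr)
        gnorm = np.sqrt(np.sum(gc**2) + np.sum(gs**2))
        if gnorm == 0.0:
            continue
        step_c, step_s = lr * gc / gnorm, lr * gs / gnorm
        model.centers = model.centers - step_c
        model.sigmas = np.maximum(model.sigmas - step_s, _SIGMA_FLOOR)
        sse2 = _sse(model, Ztr, ytr)
        if not np.isfinite(sse2):
            raise FloatingPointError("non-finite training loss after premise step")
        if sse2 <= sse1:
            lr *= 1.1
        else:
            model.centers = model.centers + step_c
            model.sigmas = np.maximum(model.sigmas + step_s, _SIGMA_FLOOR)
            lr *= 0.5
    return model, hist
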