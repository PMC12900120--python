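"""Small fully-connected networks for the hardness-classification benchmark.

Three baselines share one two-hidden-layer (32, 16) ReLU trunk trained with
Adam on full batches and early stopping on an inner stratified split:

* a softmax classifier,
* a CORAL ordinal head - K-1 cumulative binary logits sharing one weight
  vector with per-threshold biases, exploiting the ordered hardness scale,
* a Monte-Carlo-dropout classifier that keeps dropout active at inference
  and averages T stochastic passes.

The implementation is plain NumPy: the datasets here are tens of samples, so
a hand-rolled batch-gradient network is simpler and faster than pulling in a
deep-learning framework.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = ["TinyNet", "coral_head"]


def coral_head(scores: np.ndarray, biases: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """CORAL ordinal readout from shared scores and per-threshold biases.

    ``scores`` has shape (n,) (one shared score per sample); ``biases`` has
    K-1 entries.  The cumulative probabilities ``P(y > k) = sigmoid(s + b_k)``
    are made monotone non-increasing by ordering the biases descending; the
    predicted class (1-based) is one plus the number of cumulative
    probabilities above 0.5.

    Returns ``(cum_probs, classes)`` with shapes (n, K-1) and (n,).
    """
    s = np.atleast_1d(np.asarray(scores, float))
    b = np.sort(np.asarray(biases, float))[::-1]
    if b.size < 1:
        raise ValueError("need at least K - 1 = 1 threshold bias")
    logits = s[:, None] + b[None, :]
    probs = 1.0 / (1.0 + np.exp(-logits))
    classes = 1 + np.sum(probs > 0.5, axis=1)
    return probs, classes


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


class _Adam:
    def __init__(self, params: List[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class TinyNet:
    """Two-hidden-layer MLP with a softmax or CORAL head.

    Parameters mirror the benchmark protocol: standardized inputs, inner
    stratified 80/20 early-stopping split with patience 20, fixed seed.
    ``mc_passes > 0`` keeps dropout active at prediction time and averages
    that many stochastic forward passes (Monte-Carlo dropout).
    """

    def __init__(self, n_classes: int, head: str = "softmax",
                 hidden: Tuple[int, int] = (32, 16), dropout: float = 0.0,
                 mc_passes: int = 0, lr: float = 0.01, max_epochs: int = 400,
                 patience: int = 20, seed: int = 0):
        if head not in {"softmax", "coral"}:
            raise ValueError("head must be 'softmax' or 'coral'")
        self.n_classes = n_classes
        self.head = head
        self.hidden = hidden
        self.dropout = dropout
        self.mc_passes = mc_passes
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    # -- internals -----------------------------------------------------
    def _init_params(self, n_in: int, rng: np.random.Generator) -> List[np.ndarray]:
        h1, h2 = self.hidden
        n_out = self.n_classes if self.head == "softmax" else 1
        params = [
            rng.normal(0, np.sqrt(2.0 / n_in), (n_in, h1)), np.zeros(h1),
            rng.normal(0, np.sqrt(2.0 / h1), (h1, h2)), np.zeros(h2),
            rng.normal(0, np.sqrt(2.0 / h2), (h2, n_out)), np.zeros(n_out),
        ]
        if self.head == "coral":
            params.append(np.zeros(self.n_classes - 1))  # threshold biases
        return params

    def _forward(self, X: np.ndarray, params: List[np.ndarray],
                 rng: np.random.Generator | None) -> Tuple[np.ndarray, list]:
        W1, b1, W2, b2, W3, b3 = params[:6]
        z1 = X @ W1 + b1
        a1 = _relu(z1)
        m1 = 1.0
        if rng is not None and self.dropout > 0:
            m1 = (rng.random(a1.shape) >= self.dropout) / (1 - self.dropout)
            a1 = a1 * m1
        z2 = a1 @ W2 + b2
        a2 = _relu(z2)
        m2 = 1.0
        if rng is not None and self.dropout > 0:
            m2 = (rng.random(a2.shape) >= self.dropout) / (1 - self.dropout)
            a2 = a2 * m2
        out = a2 @ W3 + b3
        return out, [X, z1, a1, m1, z2, a2, m2]

    def _loss_grad(self, out: np.ndarray, y: np.ndarray, params: List[np.ndarray]
                   ) -> Tuple[float, np.ndarray, np.ndarray | None]:
        n = len(y)
        if self.head == "softmax":
            z = out - out.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-12)))
            dout = p
            dout[np.arange(n), y] -= 1.0
            return loss, dout / n, None
        # CORAL: binary cross-entropy on the K-1 cumulative targets
        biases = params[6]
        logits = out + biases[None, :]                 # out has one column
        targets = (y[:, None] > np.arange(self.n_classes - 1)[None, :]).astype(float)
        p = 1.0 / (1.0 + np.exp(-logits))
        loss = -float(np.mean(targets * np.log(p + 1e-12)
                              + (1 - targets) * np.log(1 - p + 1e-12)))
        dlogits = (p - targets) / (n * (self.n_classes - 1))
        dout = dlogits.sum(axis=1, keepdims=True)
        dbias = dlogits.sum(axis=0)
        return loss, dout, dbias

    def _backward(self, dout: np.ndarray, cache: list, params: List[np.ndarray]
                  ) -> List[np.ndarray]:
        X, z1, a1, m1, z2, a2, m2 = cache
        W1, b1, W2, b2, W3, b3 = params[:6]
        gW3 = a2.T @ dout
        gb3 = dout.sum(axis=0)
        da2 = (dout @ W3.T) * m2
        dz2 = da2 * (z2 > 0)
        gW2 = a1.T @ dz2
        gb2 = dz2.sum(axis=0)
        da1 = (dz2 @ W2.T) * m1
        dz1 = da1 * (z1 > 0)
        gW1 = X.T @ dz1
        gb1 = dz1.sum(axis=0)
        return [gW1, gb1, gW2, gb2, gW3, gb3]

    def _eval_loss(self, X: np.ndarray, y: np.ndarray, params: List[np.ndarray]) -> float:
        out, _ = self._forward(X, params, None)
        loss, _, _ = self._loss_grad(out, y, params)
        return loss

    # -- API -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "TinyNet":
        """Train on integer class labels 0..K-1 with early stopping."""
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        rng = np.random.default_rng(self.seed)
        _, counts = np.unique(y, return_counts=True)
        strat = y if counts.min() >= 2 else None
        Xtr, Xva, ytr, yva = train_test_split(
            X, y, test_size=0.2, random_state=self.seed, stratify=strat)
        params = self._init_params(X.shape[1], rng)
        opt = _Adam(params, self.lr)
        best = [p.copy() for p in params]
        best_loss = np.inf
        stale = 0
        for _ in range(self.max_epochs):
            out, cache = self._forward(Xtr, params, rng if self.dropout > 0 else None)
            loss, dout, dbias = self._loss_grad(out, ytr, params)
            grads = self._backward(dout, cache, params)
            if dbias is not None:
                grads.append(dbias)
            opt.step(params, grads)
            va = self._eval_loss(Xva, yva, params)
            if va < best_loss - 1e-6:
                best_loss = va
                best = [p.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        self.params_ = best
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if self.mc_passes > 0 and self.dropout > 0:
            rng = np.random.default_rng(self.seed + 1)
            acc = np.zeros((len(X), self.n_classes))
            for _ in range(self.mc_passes):
                acc += self._proba_once(X, rng)
            return acc / self.mc_passes
        return self._proba_once(X, None)

    def _proba_once(self, X: np.ndarray, rng) -> np.ndarray:
        out, _ = self._forward(X, self.params_, rng)
        if self.head == "softmax":
            z = out - out.max(axis=1, keepdims=True)
            p = np.exp(z)
            return p / p.sum(axis=1, keepdims=True)
        cum, _ = coral_head(out[:, 0], self.params_[6])
        # class probabilities from cumulative P(y > k)
        full = np.hstack([np.ones((len(X), 1)), cum, np.zeros((len(X), 1))])
        return full[:, :-1] - full[:, 1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.head == "coral" and self.mc_passes == 0:
            out, _ = self._forward(np.asarray(X, float), self.params_, None)
            _, cls = coral_head(out[:, 0], self.params_[6])
            return cls - 1
        return np.argmax(self.predict_proba(X), axis=1)
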