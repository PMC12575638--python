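"""Small classifiers on flat parameter vectors: a multinomial-logistic
(softmax) model and a one-hidden-layer tanh network.

Every federated stage — the personalized informative model, local client
training, update aggregation — operates on one flat parameter vector shared
by all parties, so the learners expose loss/gradient as plain functions of
that vector. Per-sample squared gradient norms are available in closed
form; for the linear model it is ``||p - y||^2 * (1 + ||x||^2)`` (weight
block plus bias block), which the sample-importance scoring relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "LinearModelSpec",
    "init_params",
    "unpack",
    "softmax",
    "predict_proba",
    "predict",
    "accuracy",
    "nll_loss",
    "grad",
    "per_sample_sq_grad_norm",
    "sgd_train",
    "fit_logistic",
    "saliency_attribution",
]


@dataclass(frozen=True)
class LinearModelSpec:
    """Architecture descriptor shared by all federated parties.

    ``hidden == 0`` is the plain softmax model; ``hidden > 0`` inserts one
    tanh hidden layer of that width.
    """

    n_features: int
    n_classes: int
    hidden: int = 0

    @property
    def n_params(self) -> int:
        if self.hidden == 0:
            return self.n_classes * (self.n_features + 1)
        return self.hidden * (self.n_features + 1) + self.n_classes * (self.hidden + 1)


def init_params(spec: LinearModelSpec, seed: int = 0) -> np.ndarray:
    """Zero start for the linear model; small deterministic gaussian start
    (symmetry breaking) for the hidden-layer variant."""
    if spec.hidden == 0:
        return np.zeros(spec.n_params)
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 0.1, size=spec.n_params)
    W1, b1, W2, b2 = unpack_mlp(w, spec)
    b1[:] = 0.0
    b2[:] = 0.0
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def unpack(w: np.ndarray, spec: LinearModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Split the flat vector into (weights[m, C], bias[C]) — linear only."""
    m, c = spec.n_features, spec.n_classes
    return w[: m * c].reshape(m, c), w[m * c :]


def unpack_mlp(
    w: np.ndarray, spec: LinearModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split the flat vector into (W1[m,h], b1[h], W2[h,C], b2[C])."""
    m, h, c = spec.n_features, spec.hidden, spec.n_classes
    i = 0
    W1 = w[i : i + m * h].reshape(m, h); i += m * h
    b1 = w[i : i + h]; i += h
    W2 = w[i : i + h * c].reshape(h, c); i += h * c
    b2 = w[i : i + c]
    return W1, b1, W2, b2


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _hidden_acts(w: np.ndarray, X: np.ndarray, spec: LinearModelSpec) -> np.ndarray:
    W1, b1, _, _ = unpack_mlp(w, spec)
    return np.tanh(X @ W1 + b1)


def predict_proba(w: np.ndarray, X: np.ndarray, spec: LinearModelSpec) -> np.ndarray:
    if spec.hidden == 0:
        W, b = unpack(w, spec)
        return softmax(X @ W + b)
    _, _, W2, b2 = unpack_mlp(w, spec)
    return softmax(_hidden_acts(w, X, spec) @ W2 + b2)


def predict(w: np.ndarray, X: np.ndarray, spec: LinearModelSpec) -> np.ndarray:
    return predict_proba(w, X, spec).argmax(axis=1)


def accuracy(w: np.ndarray, X: np.ndarray, y: np.ndarray, spec: LinearModelSpec) -> float:
    return float(np.mean(predict(w, X, spec) == y))


def _onehot(y: np.ndarray, c: int) -> np.ndarray:
    out = np.zeros((len(y), c))
    out[np.arange(len(y)), y] = 1.0
    return out


def nll_loss(
    w: np.ndarray, X: np.ndarray, y: np.ndarray, spec: LinearModelSpec, l2: float = 0.0
) -> float:
    """Mean cross-entropy plus 0.5*l2*||W||^2 (bias unpenalized)."""
    p = predict_proba(w, X, spec)
    ll = -np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None)).mean()
    if spec.hidden == 0:
        W, _ = unpack(w, spec)
        pen = np.sum(W * W)
    else:
        W1, _, W2, _ = unpack_mlp(w, spec)
        pen = np.sum(W1 * W1) + np.sum(W2 * W2)
    return float(ll + 0.5 * l2 * pen)

def grad(
    w: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: LinearModelSpec,
    l2: float = 0.0,
    mean: bool = True,
) -> np.ndarray:
    """Gradient of the cross-entropy (mean over samples, or plain sum)."""
    if spec.hidden == 0:
        p = predict_proba(w, X, spec)
        r = p - _onehot(y, spec.n_classes)
        if mean:
            r = r / len(y)
        gW = X.T @ r
        gb = r.sum(axis=0)
        W, _ = unpack(w, spec)
        if l2:
            gW = gW + l2 * W
        return np.concatenate([gW.ravel(), gb])
    W1, b1, W2, b2 = unpack_mlp(w, spec)
    a1 = np.tanh(X @ W1 + b1)
    p = softmax(a1 @ W2 + b2)
    d2 = p - _onehot(y, spec.n_classes)
    if mean:
        d2 = d2 / len(y)
    gW2 = a1.T @ d2
    gb2 = d2.sum(axis=0)
    d1 = (d2 @ W2.T) * (1.0 - a1 * a1)
    gW1 = X.T @ d1
    gb1 = d1.sum(axis=0)
    if l2:
        gW1 = gW1 + l2 * W1
        gW2 = gW2 + l2 * W2
    return np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])


def per_sample_sq_grad_norm(
    w: np.ndarray, X: np.ndarray, y: np.ndarray, spec: LinearModelSpec
) -> np.ndarray:
    """Squared gradient norm of the per-sample cross-entropy, closed form."""
    if spec.hidden == 0:
        p = predict_proba(w, X, spec)
        r = p - _onehot(y, spec.n_classes)
        return np.sum(r * r, axis=1) * (1.0 + np.sum(X * X, axis=1))
    W1, b1, W2, b2 = unpack_mlp(w, spec)
    a1 = np.tanh(X @ W1 + b1)
    p = softmax(a1 @ W2 + b2)
    d2 = p - _onehot(y, spec.n_classes)
    d1 = (d2 @ W2.T) * (1.0 - a1 * a1)
    return (
        np.sum(d2 * d2, axis=1) * (1.0 + np.sum(a1 * a1, axis=1))
        + np.sum(d1 * d1, axis=1) * (1.0 + np.sum(X * X, axis=1))
    )


def sgd_train(
    w0: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: LinearModelSpec,
    epochs: int = 5,
    batch_size: int = 64,
    lr: float = 1e-3,
    momentum: float = 0.9,
    seed: int = 0,
    l2: float = 0.0,
) -> np.ndarray:
    """Mini-batch heavy-ball SGD from a given starting vector."""
    rng = np.random.default_rng(seed)
    w = w0.copy()
    vel = np.zeros_like(w)
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            g = grad(w, X[idx], y[idx], spec, l2=l2)
            vel = momentum * vel - lr * g
            w = w + vel
    return w


def fit_logistic(
    X: np.ndarray, y: np.ndarray, spec: LinearModelSpec, l2: float = 1e-2
) -> np.ndarray:
    """Deterministic L-BFGS fit of the ridge-penalized softmax model."""
    res = minimize(
        nll_loss,
        init_params(spec),
        args=(X, y, spec, l2),
        jac=lambda w, X, y, spec, l2: grad(w, X, y, spec, l2=l2),
        method="L-BFGS-B",
        options={"maxiter": 200},
    )
    return res.x


def saliency_attribution(
    w: np.ndarray, X: np.ndarray, y: np.ndarray, spec: LinearModelSpec
) -> np.ndarray:
    """Mean |gradient x input| per feature — the attribution vector used to
    weigh clients during aggregation."""
    p = predict_proba(w, X, spec)
    r = p - _onehot(y, spec.n_classes)
    if spec.hidden == 0:
        W, _ = unpack(w, spec)
        gx = r @ W.T  # d loss / d x per sample
    else:
        W1, b1, W2, _ = unpack_mlp(w, spec)
        a1 = np.tanh(X @ W1 + b1)
        gx = ((r @ W2.T) * (1.0 - a1 * a1)) @ W1.T
    return np.abs(gx * X).mean(axis=0)
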