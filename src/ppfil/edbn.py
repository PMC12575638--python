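"""Entropy Deep Belief Network (EDBN): a stack of binary restricted
Boltzmann machines whose hidden widths are constrained by the information
entropy of their visible layer, trained layer-wise with CD-1 and fine-tuned
as a feed-forward classifier.

The entropy sizing rule bounds each hidden width between ceil(H_vo) — the
visible layer's information entropy in bits — and the visible unit count:
a maximally uncertain layer (all activation probabilities 1/2) carries one
bit per node, so its entropy equals the node count and the hidden layer may
not compress at all; near-constant layers may shrink down to one node.
Structure search greedily picks, layer by layer, the candidate width with
the lowest held-out reconstruction error.

Min-max-normalized inputs in [0, 1] are treated as Bernoulli activation
probabilities for the first visible layer. Mean-field probabilities (never
sampled states) are used for entropy estimates, reconstruction error and
the reported energy-style loss, keeping those quantities deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import TabularDataset

__all__ = [
    "RBMParams",
    "EDBNModel",
    "StructureSearchSpec",
    "EntropyEstimate",
    "layer_entropy",
    "hidden_size_bounds",
    "train_rbm_cd",
    "reconstruction_error",
    "rbm_loss",
    "search_structure",
    "finetune_and_predict",
]

_P_CLIP = 1e-6


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class RBMParams:
    """Binary RBM parameters: W (visible x hidden), visible bias a, hidden bias b."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray
    unit_type: str = "binary"

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def hidden_probs(self, v: np.ndarray) -> np.ndarray:
        return _sigmoid(v @ self.W + self.b)

    def visible_probs(self, h: np.ndarray) -> np.ndarray:
        return _sigmoid(h @ self.W.T + self.a)


@dataclass
class EntropyEstimate:
    p_on: np.ndarray  # per-node activation probability, clipped
    entropy_bits: float


@dataclass
class StructureSearchSpec:
    width_grids: list[list[int]]  # candidate widths per layer
    d_max: int = 3
    epochs_per_candidate: int = 20
    lr: float = 0.05
    batch_size: int = 32
    val_fraction: float = 0.2


@dataclass
class EDBNModel:
    rbms: list[RBMParams]
    head_W: np.ndarray | None = None  # top hidden -> classes
    head_b: np.ndarray | None = None
    widths: list[int] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.rbms)

    def propagate(self, X: np.ndarray) -> list[np.ndarray]:
        """Mean-field activations of every layer, input first."""
        acts = [X]
        for rbm in self.rbms:
            acts.append(rbm.hidden_probs(acts[-1]))
        return acts

    def to_json(self, path: str | Path) -> None:
        obj = {
            "widths": self.widths,
            "rbms": [
                {"W": r.W.tolist(), "a": r.a.tolist(), "b": r.b.tolist(), "unit_type": r.unit_type}
                for r in self.rbms
            ],
            "head_W": None if self.head_W is None else self.head_W.tolist(),
            "head_b": None if self.head_b is None else self.head_b.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "EDBNModel":
        obj = json.loads(Path(path).read_text())
        rbms = [
            RBMParams(np.asarray(r["W"]), np.asarray(r["a"]), np.asarray(r["b"]), r["unit_type"])
            for r in obj["rbms"]
        ]
        head_W = None if obj["head_W"] is None else np.asarray(obj["head_W"])
        head_b = None if obj["head_b"] is None else np.asarray(obj["head_b"])
        return cls(rbms, head_W, head_b, list(obj["widths"]))


def layer_entropy(activations: np.ndarray) -> EntropyEstimate:
    """Information entropy of a layer of Bernoulli nodes, in bits.

    p_i(1) is the column mean activation; each node contributes
    -p0*log2(p0) - p1*log2(p1), with probabilities clipped away from {0, 1}.
    """
    acts = np.asarray(activations, dtype=float)
    if acts.size == 0:
        raise ValueError("empty activations")
    p1 = np.clip(acts.mean(axis=0), _P_CLIP, 1.0 - _P_CLIP)
    p0 = 1.0 - p1
    h = -(p0 * np.log2(p0) + p1 * np.log2(p1))
    return EntropyEstimate(p_on=p1, entropy_bits=float(h.sum()))


def hidden_size_bounds(visible_activations: np.ndarray) -> tuple[int, int]:
    """Entropy sizing: ceil(H_vo) <= width <= visible count, floored at 1."""
    est = layer_entropy(visible_activations)
    n_vo = visible_activations.shape[1]
    n_min = max(1, int(np.ceil(est.entropy_bits - 1e-9)))
    return min(n_min, n_vo), n_vo


def train_rbm_cd(
    data: np.ndarray,
    width: int,
    epochs: int = 20,
    lr: float = 0.05,
    seed: int = 0,
    batch_size: int = 32,
    bounds: tuple[int, int] | None = None,
) -> RBMParams:
    """CD-1 training of a binary RBM on data in [0, 1].

    Hidden states are sampled in the positive phase; reconstructions use
    mean-field probabilities. Weights start N(0, 0.01^2), biases at zero.
    """
    if bounds is not None and not bounds[0] <= width <= bounds[1]:
        raise ValueError(f"width {width} outside entropy bounds {bounds}")
    rng = np.random.default_rng(seed)
    n_vis = data.shape[1]
    rbm = RBMParams(rng.normal(0.0, 0.01, size=(n_vis, width)), np.zeros(n_vis), np.zeros(width))
    n = data.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            v0 = data[order[start : start + batch_size]]
            ph0 = rbm.hidden_probs(v0)
            h0 = (rng.uniform(size=ph0.shape) < ph0).astype(float)
            v1 = rbm.visible_probs(h0)
            ph1 = rbm.hidden_probs(v1)
            k = len(v0)
            rbm.W += lr * (v0.T @ ph0 - v1.T @ ph1) / k
            rbm.a += lr * (v0 - v1).mean(axis=0)
            rbm.b += lr * (ph0 - ph1).mean(axis=0)
    return rbm


def reconstruction_error(rbm: RBMParams, data: np.ndarray) -> float:
    """Mean squared error of the one-step mean-field reconstruction."""
    if data.shape[1] != rbm.n_visible:
        raise ValueError("shape mismatch")
    recon = rbm.visible_probs(rbm.hidden_probs(data))
    return float(np.mean((data - recon) ** 2))


def rbm_loss(rbm: RBMParams, visible: np.ndarray, hidden: np.ndarray) -> float:
    """Sample-averaged energy-style loss
    L = (1/T) sum_t [ sum_ij W_ij v_i h_j + sum_i a_i v_i + sum_j b_j h_j ].

    Reported as a diagnostic only; it is not the training objective.
    """
    if visible.shape[0] != hidden.shape[0]:
        raise ValueError("sample count mismatch")
    inter = np.einsum("ti,ij,tj->t", visible, rbm.W, hidden)
    vis = visible @ rbm.a
    hid = hidden @ rbm.b
    return float(np.mean(inter + vis + hid))


def search_structure(data: np.ndarray, spec: StructureSearchSpec, seed: int = 0) -> EDBNModel:
    """Greedy layer-wise structure selection under the entropy constraints.

    For each layer up to d_max, candidate widths from the grid that fall in
    [ceil(H), n_visible] are CD-trained and scored by held-out
    reconstruction error; the argmin width is frozen and its mean-field
    activations feed the next layer.
    """
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    n_val = max(1, int(round(spec.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    acts_train, acts_val = data[train_idx], data[val_idx]

    rbms: list[RBMParams] = []
    widths: list[int] = []
    for k in range(min(spec.d_max, len(spec.width_grids))):
        lo, hi = hidden_size_bounds(acts_train)
        feasible = [w for w in spec.width_grids[k] if lo <= w <= hi]
        if not feasible:
            raise ValueError(
                f"layer {k}: no grid width inside entropy bounds [{lo}, {hi}]"
            )
        best_rbm, best_err, best_w = None, np.inf, None
        for w in feasible:
            rbm = train_rbm_cd(
                acts_train, w, epochs=spec.epochs_per_candidate, lr=spec.lr,
                seed=seed + 31 * k, batch_size=spec.batch_size, bounds=(lo, hi),
            )
            err = reconstruction_error(rbm, acts_val)
            if err < best_err:
                best_rbm, best_err, best_w = rbm, err, w
        rbms.append(best_rbm)
        widths.append(best_w)
        acts_train = best_rbm.hidden_probs(acts_train)
        acts_val = best_rbm.hidden_probs(acts_val)
    return EDBNModel(rbms=rbms, widths=widths)


def finetune_and_predict(
    model: EDBNModel,
    train: TabularDataset,
    test: TabularDataset,
    epochs: int = 150,
    lr: float = 0.5,
    seed: int = 0,
    batch_size: int = 32,
    momentum: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Unroll the stack into a sigmoid feed-forward net with a softmax head,
    fine-tune end-to-end on cross-entropy (heavy-ball SGD), and predict on
    the test split.

    Gradients are averaged over the mini-batch, so the default step size of
    0.5 corresponds to a per-sample step of ~1/batch_size; the saturating
    sigmoid stack needs steps of this order, plus momentum, to move at all.

    Returns (predicted labels, class probabilities) for the test data.
    """
    rng = np.random.default_rng(seed)
    classes = np.unique(train.labels)
    if np.setdiff1d(test.labels, classes).size:
        raise ValueError("test labels contain classes unseen in training")
    n_classes = len(classes)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in train.labels])

    Ws = [rbm.W.copy() for rbm in model.rbms]
    bs = [rbm.b.copy() for rbm in model.rbms]
    top = model.rbms[-1].n_hidden if model.rbms else train.n_features
    head_W = rng.normal(0.0, 0.01, size=(top, n_classes))
    head_b = np.zeros(n_classes)

    X, n = train.features, train.n_samples
    vel_Ws = [np.zeros_like(W) for W in Ws]
    vel_bs = [np.zeros_like(b) for b in bs]
    vel_hW = np.zeros_like(head_W)
    vel_hb = np.zeros_like(head_b)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            a = [X[idx]]
            for W, b in zip(Ws, bs):
                a.append(_sigmoid(a[-1] @ W + b))
            logits = a[-1] @ head_W + head_b
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            delta = p.copy()
            delta[np.arange(len(idx)), y[idx]] -= 1.0
            delta /= len(idx)
            back = delta @ head_W.T
            vel_hW = momentum * vel_hW - lr * (a[-1].T @ delta)
            vel_hb = momentum * vel_hb - lr * delta.sum(axis=0)
            head_W += vel_hW
            head_b += vel_hb
            for k in range(len(Ws) - 1, -1, -1):
                dz = back * a[k + 1] * (1.0 - a[k + 1])
                gW = a[k].T @ dz
                gb = dz.sum(axis=0)
                back = dz @ Ws[k].T
                vel_Ws[k] = momentum * vel_Ws[k] - lr * gW
                vel_bs[k] = momentum * vel_bs[k] - lr * gb
                Ws[k] += vel_Ws[k]
                bs[k] += vel_bs[k]

    model.head_W, model.head_b = head_W, head_b
    for rbm, W, b in zip(model.rbms, Ws, bs):
        rbm.W, rbm.b = W, b

    a_t = test.features
    for W, b in zip(Ws, bs):
        a_t = _sigmoid(a_t @ W + b)
    logits = a_t @ head_W + head_b
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    preds = classes[probs.argmax(axis=1)]
    return preds, probs
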