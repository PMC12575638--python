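"""Federated incremental learning: personalized informative models (PIM),
gradient-norm sample importance, bounded replay caches, local training and
the global round loop.

Each client holds a bounded memory of at most M past samples. When a new
task arrives the client updates its PIM — a copy of its auxiliary model
pulled toward the received global model by a mixing term q(lambda) =
(1 - lambda)/(2 lambda) — on its previous local samples, recording every
sample's squared gradient norm at each of the s PIM iterations. Importance
accumulates those norms with 1/p weights (early iterations count most),
and the top-M samples are cached for replay. Local training then runs E
epochs of momentum SGD on the new task plus the cache, and the resulting
updates pass through the privacy/robustness layer before aggregation and
ledger admission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import linear, secure
from .ledger import Ledger, append_block, digest_params, poc_score

__all__ = [
    "FILConfig",
    "GlobalModel",
    "PIM",
    "MemoryBuffer",
    "ClientState",
    "RoundContext",
    "mixing_coefficient",
    "pim_update",
    "sample_gradient_norm",
    "accumulate_importance",
    "select_cache",
    "local_train",
    "global_round",
]


@dataclass
class FILConfig:
    local_epochs: int = 5
    batch_size: int = 64
    lr: float = 1e-3
    momentum: float = 0.9
    rounds: int = 500
    cache_size: int = 50
    lam: float = 0.5  # PIM mixing parameter, grid-searched over (0, 1)
    pim_iters: int = 10  # s; the importance horizon S equals s
    cache_policy: str = "importance"  # "importance" | "random" (baseline)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lam < 1:
            raise ValueError("lambda must lie strictly inside (0, 1)")
        for name in ("local_epochs", "batch_size", "rounds", "cache_size", "pim_iters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class GlobalModel:
    params: np.ndarray
    round_index: int
    spec: linear.LinearModelSpec


@dataclass
class PIM:
    params: np.ndarray
    lam: float
    lr: float
    iters: int


@dataclass
class MemoryBuffer:
    capacity: int
    X: np.ndarray | None = None
    y: np.ndarray | None = None
    importance: np.ndarray | None = None

    @property
    def size(self) -> int:
        return 0 if self.X is None else len(self.X)


@dataclass
class ClientState:
    client_id: int
    spec: linear.LinearModelSpec
    local_w: np.ndarray
    pim: PIM
    buffer: MemoryBuffer
    task_X: np.ndarray | None = None
    task_y: np.ndarray | None = None
    prev_X: np.ndarray | None = None  # previous task's local samples
    prev_y: np.ndarray | None = None
    new_task: bool = False
    label_flip: tuple[float, np.random.Generator] | None = None  # attack hook
    task_counter: int = 0
    buffer_task: int = -1  # task index the cache was filled from

    def receive_task(self, X: np.ndarray, y: np.ndarray) -> None:
        """Push a new task; the old one becomes the caching candidate pool."""
        self.prev_X, self.prev_y = self.task_X, self.task_y
        self.task_X, self.task_y = X, y
        self.new_task = True
        self.task_counter += 1


def mixing_coefficient(lam: float) -> float:
    """q(lambda) = (1 - lambda)/(2 lambda), defined on (0, 1)."""
    if not 0 < lam < 1:
        raise ValueError("lambda must lie strictly inside (0, 1)")
    return (1.0 - lam) / (2.0 * lam)


def sample_gradient_norm(
    pim: PIM, spec: linear.LinearModelSpec, x: np.ndarray, y: int
) -> float:
    """Squared gradient norm of one sample's cross-entropy at the PIM."""
    g = linear.per_sample_sq_grad_norm(
        pim.params, np.atleast_2d(x), np.asarray([y]), spec
    )
    return float(g[0])


def pim_update(
    pim: PIM,
    global_params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: linear.LinearModelSpec,
    momentum: float = 0.9,
) -> tuple[PIM, np.ndarray]:
    """Run s PIM iterations and record per-sample squared gradient norms.

    Each iteration applies a heavy-ball step on the summed per-sample
    cross-entropy gradient plus the mixing pull q(lambda) (v - w) toward
    the global model. Returns the updated PIM and an (s, n) matrix of
    per-iteration squared gradient norms G^p.
    """
    if len(y) == 0:
        raise ValueError("PIM update needs at least one sample")
    q = mixing_coefficient(pim.lam)
    v = pim.params.copy()
    vel = np.zeros_like(v)
    norms = np.empty((pim.iters, len(y)))
    for p in range(pim.iters):
        norms[p] = linear.per_sample_sq_grad_norm(v, X, y, spec)
        g = linear.grad(v, X, y, spec, mean=False) + q * (v - global_params)
        vel = momentum * vel - pim.lr * g
        v = v + vel
    return PIM(params=v, lam=pim.lam, lr=pim.lr, iters=pim.iters), norms


def accumulate_importance(norm_history: np.ndarray) -> np.ndarray:
    """Importance I = sum_{p=1..S} (1/p) G^p — early iterations dominate.

    ``norm_history`` is (S, n); returns one importance per sample.
    """
    hist = np.atleast_2d(np.asarray(norm_history, dtype=float))
    weights = 1.0 / np.arange(1, hist.shape[0] + 1)
    return weights @ hist


def select_cache(
    X: np.ndarray, y: np.ndarray, importance: np.ndarray, capacity: int
) -> MemoryBuffer:
    """Keep the top-``capacity`` samples by importance; ties break toward
    the more recent (higher-index) sample."""
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    n = len(y)
    order = sorted(range(n), key=lambda i: (-importance[i], -i))
    keep = np.asarray(sorted(order[: min(capacity, n)]), dtype=int)
    return MemoryBuffer(capacity=capacity, X=X[keep], y=y[keep], importance=importance[keep])


def local_train(client: ClientState, global_params: np.ndarray, config: FILConfig) -> np.ndarray:
    """E epochs of momentum mini-batch SGD on current task + replay cache,
    starting from the received global model."""
    parts_X = [client.task_X] if client.task_X is not None else []
    parts_y = [client.task_y] if client.task_y is not None else []
    if client.buffer.size:
        parts_X.append(client.buffer.X)
        parts_y.append(client.buffer.y)
    X = np.concatenate(parts_X)
    y = np.concatenate(parts_y)
    if client.label_flip is not None:
        frac, rng = client.label_flip
        y = secure.flip_labels(y, frac, client.spec.n_classes, rng)
    w = linear.sgd_train(
        global_params, X, y, client.spec,
        epochs=config.local_epochs, batch_size=config.batch_size,
        lr=config.lr, momentum=config.momentum,
        seed=config.seed + 7919 * (client.client_id + 1),
    )
    client.local_w = w
    return w


def handle_new_task(client: ClientState, global_params: np.ndarray, config: FILConfig) -> None:
    """On task arrival: update the PIM on the previous local samples (old
    cache plus the task just finished), score them, and rebuild the bounded
    cache from the top-importance samples.

    The PIM is rebuilt at each task arrival from both knowledge sources:
    it warm-starts at the client's current local model and its update is
    pulled toward the received global model by the mixing term, so the
    recorded gradient norms measure how much a sample still challenges the
    combined local/global knowledge. On the very first task (empty history)
    the PIM step and scoring run on the incoming task data itself. Under
    the ``random`` cache policy the same candidate pool is subsampled
    uniformly — the ablation baseline.
    """
    prev_task_index = client.task_counter - 2
    parts_X, parts_y = [], []
    if client.buffer.size and client.buffer_task != prev_task_index:
        parts_X.append(client.buffer.X)
        parts_y.append(client.buffer.y)
    if client.prev_y is not None and len(client.prev_y):
        parts_X.append(client.prev_X)
        parts_y.append(client.prev_y)
    first_task = not parts_X
    if first_task:
        parts_X, parts_y = [client.task_X], [client.task_y]
    cand_X = np.concatenate(parts_X)
    cand_y = np.concatenate(parts_y)

    client.pim = PIM(
        params=client.local_w.copy(), lam=config.lam, lr=config.lr,
        iters=config.pim_iters,
    )
    client.pim, norms = pim_update(
        client.pim, global_params, cand_X, cand_y, client.spec, momentum=config.momentum
    )
    if config.cache_policy == "random":
        rng = np.random.default_rng(config.seed + 613 * (client.client_id + 1))
        m = min(config.cache_size, len(cand_y))
        keep = np.sort(rng.choice(len(cand_y), size=m, replace=False))
        client.buffer = MemoryBuffer(
            capacity=config.cache_size, X=cand_X[keep], y=cand_y[keep],
            importance=np.zeros(m),
        )
    else:
        importance = accumulate_importance(norms)
        client.buffer = select_cache(cand_X, cand_y, importance, config.cache_size)
    client.buffer_task = client.task_counter - 1 if first_task else prev_task_index
    client.new_task = False


@dataclass
class RoundContext:
    """Per-round wiring of the privacy, robustness, attack and ledger stages."""

    privacy: secure.PrivacyConfig | None = None
    attack: secure.AttackConfig | None = None
    filter_c: float = 3.0
    use_filter: bool = True
    weight_mode: str = "xai"  # "xai" | "samples"
    ledger: Ledger | None = None
    val_X: np.ndarray | None = None
    val_y: np.ndarray | None = None
    record_contributions: bool = False
    rng: np.random.Generator | None = None
    cumulative: dict[int, float] = field(default_factory=dict)


def _client_update(client: ClientState, w: np.ndarray) -> secure.ClientUpdate:
    n = len(client.task_y) if client.task_y is not None else client.buffer.size
    acc = 1.0
    attribution = None
    if client.task_y is not None and len(client.task_y):
        acc = linear.accuracy(w, client.task_X, client.task_y, client.spec)
        attribution = linear.saliency_attribution(w, client.task_X, client.task_y, client.spec)
    return secure.ClientUpdate(
        client_id=client.client_id, params=w, n_samples=max(1, n),
        val_accuracy=acc, attribution=attribution,
    )


def global_round(
    clients: list[ClientState],
    global_model: GlobalModel,
    config: FILConfig,
    ctx: RoundContext | None = None,
) -> GlobalModel:
    """One federated round: local work per client, then the secure
    aggregation path, then validation-gated ledger admission.

    Per client: receive the global model; on a new task run the PIM /
    importance / caching pipeline; train locally. Updates are clipped and
    LDP-perturbed when privacy is on, corrupted by the configured attack,
    screened by the robust filter, weighed, and averaged. If every update
    is filtered out the round aborts and the previous global model stands.
    """
    if not clients:
        raise ValueError("need at least one participating client")
    ctx = ctx or RoundContext()
    rng = ctx.rng if ctx.rng is not None else np.random.default_rng(
        config.seed + 104729 * (global_model.round_index + 1)
    )

    updates = []
    for client in clients:
        if client.new_task:
            handle_new_task(client, global_model.params, config)
        w = local_train(client, global_model.params, config)
        updates.append(_client_update(client, w))

    if ctx.privacy is not None:
        updates = [
            secure.ldp_perturb(secure.clip_update(u, ctx.privacy.clip_norm), ctx.privacy, rng)
            for u in updates
        ]
    if ctx.attack is not None:
        updates = secure.apply_attack(updates, ctx.attack, rng, filter_c=ctx.filter_c)

    if ctx.use_filter:
        kept, _ = secure.robust_filter(updates, c=ctx.filter_c)
    else:
        kept = updates
    if not kept:
        return global_model  # round aborts, previous global retained

    if ctx.weight_mode == "xai":
        weights = secure.xai_weights(kept)
    else:
        weights = secure.sample_count_weights(kept)
    new_params = secure.aggregate(kept, weights)

    val_acc = 1.0
    if ctx.val_X is not None:
        val_acc = linear.accuracy(new_params, ctx.val_X, ctx.val_y, global_model.spec)

    admitted = True
    if ctx.ledger is not None:
        payload = {
            "round": global_model.round_index + 1,
            "model_digest": digest_params(new_params),
            "n_clients": len(kept),
        }
        if ctx.record_contributions and ctx.val_X is not None:
            payload["contributions"] = _contributions(
                kept, weights, global_model, ctx, global_model.round_index + 1
            )
        admitted = append_block(ctx.ledger, payload, val_acc)
    if not admitted:
        return global_model

    return GlobalModel(
        params=new_params, round_index=global_model.round_index + 1, spec=global_model.spec
    )


def _contributions(kept, weights, global_model, ctx, round_index) -> list[dict]:
    """Leave-one-out proof-of-contribution records for the admitted round."""
    full = secure.aggregate(kept, weights)
    acc_full = linear.accuracy(full, ctx.val_X, ctx.val_y, global_model.spec)
    records = []
    for i, u in enumerate(kept):
        if len(kept) == 1:
            score = poc_score(acc_full, 0.0)
        else:
            rest = [v for j, v in enumerate(kept) if j != i]
            w_rest = np.delete(np.asarray(weights, float), i)
            without = secure.aggregate(rest, w_rest)
            acc_wo = linear.accuracy(without, ctx.val_X, ctx.val_y, global_model.spec)
            score = poc_score(acc_full, acc_wo)
        cum = ctx.cumulative.get(u.client_id, 0.0) + score
        ctx.cumulative[u.client_id] = cum
        records.append(
            {"client_id": int(u.client_id), "round": int(round_index),
             "score": float(score), "cumulative": float(cum)}
        )
    return records
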