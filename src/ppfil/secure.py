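"""Privacy and robustness layer: update clipping, local differential
privacy (LDP) perturbation, aberrant-update filtering, importance-weighted
aggregation, and the threat-model generators used to stress the pipeline.

Clients release clipped, noised parameter updates so the server never sees
exact local models. The robust filter drops updates whose distance to the
coordinate-wise median is an outlier under a median/MAD rule. Aggregation
is a normalized weighted mean of the kept updates (plus optional
attribution-driven deltas); weights combine local validation accuracy with
the cosine alignment between a client's feature-attribution vector and the
consensus attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ClientUpdate",
    "PrivacyConfig",
    "AttackConfig",
    "clip_update",
    "ldp_perturb",
    "robust_filter",
    "xai_weights",
    "aggregate",
    "apply_attack",
    "flip_labels",
    "LEVEL_MULTIPLIERS",
]

# privacy level 1..5 -> gaussian noise multiplier
LEVEL_MULTIPLIERS = {1: 0.25, 2: 0.5, 3: 1.0, 4: 2.0, 5: 4.0}
# privacy level 1..5 -> randomized-response sign-flip probability
LEVEL_FLIP_PROBS = {1: 0.05, 2: 0.1, 3: 0.2, 4: 0.3, 5: 0.4}
_RR_BUCKETS = 16


@dataclass
class ClientUpdate:
    client_id: int
    params: np.ndarray
    n_samples: int = 1
    val_accuracy: float = 1.0
    attribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class PrivacyConfig:
    mechanism: str = "gaussian"  # "gaussian" | "randomized-response"
    level: int | None = None  # 1..5, maps to noise multiplier / flip prob
    noise_multiplier: float | None = None  # overrides level when set
    clip_norm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.mechanism not in {"gaussian", "randomized-response"}:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.noise_multiplier is None and self.level is None:
            self.noise_multiplier = 1.0
        if self.noise_multiplier is None:
            self.noise_multiplier = LEVEL_MULTIPLIERS[self.level]


@dataclass
class AttackConfig:
    tag: str  # extra-noise | label-flip | stat-opt | dyn-opt | sybil | collusion
    n_attackers: int = 0
    noise_scale: float = 1.0  # extra-noise
    flip_fraction: float = 1.0  # label-flip
    gamma: float = 5.0  # stat-opt fixed scale
    gamma_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)  # dyn-opt
    n_sybils: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        known = {"extra-noise", "label-flip", "stat-opt", "dyn-opt", "sybil", "collusion"}
        if self.tag not in known:
            raise ValueError(f"unknown attack {self.tag!r}")
        if self.n_attackers < 0:
            raise ValueError("attacker count must be nonnegative")


def clip_update(update: ClientUpdate, clip_norm: float) -> ClientUpdate:
    """Rescale the vector to norm <= C, direction preserved."""
    if clip_norm <= 0:
        raise ValueError("clip norm must be positive")
    norm = float(np.linalg.norm(update.params))
    scale = min(1.0, clip_norm / norm) if norm > 0 else 1.0
    return replace(update, params=update.params * scale)


def ldp_perturb(
    update: ClientUpdate, cfg: PrivacyConfig, rng: np.random.Generator | None = None
) -> ClientUpdate:
    """Perturb a clipped update before release.

    Gaussian mode adds per-coordinate noise of scale multiplier * clip_norm
    (unbiased; zero multiplier is the identity). Randomized-response mode
    flips each coordinate's sign with a level-dependent probability and
    quantizes magnitudes into 16 buckets of [0, clip_norm].
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.mechanism == "gaussian":
        if cfg.noise_multiplier == 0:
            return replace(update, params=update.params.copy())
        sigma = cfg.noise_multiplier * cfg.clip_norm
        noise = rng.normal(0.0, sigma, size=update.params.shape)
        return replace(update, params=update.params + noise)
    # randomized response on sign bits, bucketed magnitudes
    p_flip = LEVEL_FLIP_PROBS.get(cfg.level or 3, 0.2)
    signs = np.sign(update.params)
    signs[signs == 0] = 1.0
    flip = rng.uniform(size=update.params.shape) < p_flip
    signs = np.where(flip, -signs, signs)
    width = cfg.clip_norm / _RR_BUCKETS
    mags = np.clip(np.abs(update.params), 0, cfg.clip_norm)
    mags = (np.floor(mags / width) + 0.5) * width
    return replace(update, params=signs * mags)


def robust_filter(
    updates: list[ClientUpdate], c: float = 3.0
) -> tuple[list[ClientUpdate], list[ClientUpdate]]:
    """Median/MAD outlier screen over update vectors.

    An update is excluded iff its distance to the coordinate-wise median
    deviates from the median distance by more than the larger of
    c * MAD (normal-consistent, i.e. scaled by 1.4826) and the median
    distance itself. The second term is a material-difference floor: with
    a dozen or fewer clients the sample MAD of the distances is so noisy
    that a bare c*MAD cut flags an honest client in a large fraction of
    rounds; requiring an outlier to also sit more than twice the typical
    distance from the consensus keeps honest rounds intact while still
    catching poisoned updates, whose distances are many times larger.
    Fewer than 3 updates cannot support a median estimate, so all are
    kept. Identical updates have zero dispersion and are never excluded.
    Returns (kept, excluded).
    """
    if len(updates) < 3:
        return list(updates), []
    stack = np.stack([u.params for u in updates])
    med = np.median(stack, axis=0)
    dists = np.linalg.norm(stack - med, axis=1)
    med_d = np.median(dists)
    mad = 1.4826 * np.median(np.abs(dists - med_d))
    thresh = max(c * mad, med_d)
    keep_mask = np.abs(dists - med_d) <= thresh
    kept = [u for u, k in zip(updates, keep_mask) if k]
    excluded = [u for u, k in zip(updates, keep_mask) if not k]
    return kept, excluded


def xai_weights(updates: list[ClientUpdate]) -> np.ndarray:
    """Per-client aggregation weights from accuracy x attribution alignment.

    W_k is proportional to the client's local validation accuracy times the
    nonnegative cosine similarity between its feature-attribution vector
    and the consensus (mean) attribution; missing attributions count as
    fully aligned. Weights normalize to 1; if every weight vanishes the
    rule falls back to sample-count weights.
    """
    if not updates:
        raise ValueError("no updates to weigh")
    attrs = [u.attribution for u in updates if u.attribution is not None]
    consensus = np.mean(np.stack(attrs), axis=0) if attrs else None
    raw = np.empty(len(updates))
    for i, u in enumerate(updates):
        sim = 1.0
        if u.attribution is not None and consensus is not None:
            na, nc = np.linalg.norm(u.attribution), np.linalg.norm(consensus)
            sim = max(0.0, float(u.attribution @ consensus / (na * nc))) if na > 0 and nc > 0 else 1.0
        raw[i] = u.val_accuracy * sim
    if raw.sum() <= 0:
        raw = np.array([float(u.n_samples) for u in updates])
    return raw / raw.sum()


def sample_count_weights(updates: list[ClientUpdate]) -> np.ndarray:
    """Plain FedAvg weighting by local sample counts."""
    raw = np.array([float(u.n_samples) for u in updates])
    return raw / raw.sum()


def aggregate(
    updates: list[ClientUpdate],
    weights: np.ndarray | None = None,
    xai_deltas: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized weighted mean of kept updates plus optional deltas:
    M = sum_k W_k (M_k + delta_k) / sum_k W_k. Deltas default to zero."""
    if not updates:
        raise ValueError("cannot aggregate an empty update set")
    stack = np.stack([u.params for u in updates])
    if xai_deltas is not None:
        stack = stack + np.asarray(xai_deltas, dtype=float)
    if weights is None:
        weights = np.ones(len(updates))
    weights = np.asarray(weights, dtype=float)
    return (weights[:, None] * stack).sum(axis=0) / weights.sum()


def flip_labels(
    y: np.ndarray, fraction: float, n_classes: int, rng: np.random.Generator
) -> np.ndarray:
    """Permute a fraction of labels to other classes (binary: inversion)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    y = y.copy()
    n_flip = int(round(fraction * len(y)))
    idx = rng.choice(len(y), size=n_flip, replace=False)
    if n_classes == 2:
        y[idx] = 1 - y[idx]
    else:
        shift = rng.integers(1, n_classes, size=n_flip)
        y[idx] = (y[idx] + shift) % n_classes
    return y


def apply_attack(
    updates: list[ClientUpdate],
    cfg: AttackConfig,
    rng: np.random.Generator,
    filter_c: float = 3.0,
) -> list[ClientUpdate]:
    """Corrupt the first ``n_attackers`` updates per the configured threat.

    extra-noise: additive gaussian noise of the stated scale.
    stat-opt:    attacker update = -gamma * mean honest direction, fixed gamma.
    dyn-opt:     gamma chosen per round as the largest grid value whose
                 crafted updates all evade the robust filter.
    sybil:       the attacker's update replicated under fabricated ids.
    collusion:   all attackers submit one shared crafted (stat-opt) update.
    label-flip corrupts training labels, not updates — use ``flip_labels``
    on attacker-held data before local training.
    """
    f = cfg.n_attackers
    if f == 0:
        return list(updates)
    if f >= len(updates):
        raise ValueError("attacker count must be below the client count")
    out = [replace(u, params=u.params.copy()) for u in updates]
    honest_mean = np.mean(np.stack([u.params for u in updates[f:]]), axis=0)

    if cfg.tag == "extra-noise":
        for u in out[:f]:
            u.params += rng.normal(0.0, cfg.noise_scale, size=u.params.shape)
        return out
    if cfg.tag == "label-flip":
        return out  # handled at the data stage
    if cfg.tag == "stat-opt":
        for u in out[:f]:
            u.params = -cfg.gamma * honest_mean
        return out
    if cfg.tag == "dyn-opt":
        # largest grid gamma whose crafted updates all evade the filter;
        # if every negative scaling is caught, hide behind the honest mean
        attacker_ids = {u.client_id for u in out[:f]}
        crafted = honest_mean.copy()
        for gamma in sorted(cfg.gamma_grid, reverse=True):
            trial = [replace(u, params=u.params) for u in out]
            for u in trial[:f]:
                u.params = -gamma * honest_mean
            _, excluded = robust_filter(trial, c=filter_c)
            if not any(e.client_id in attacker_ids for e in excluded):
                crafted = -gamma * honest_mean
                break
        for u in out[:f]:
            u.params = crafted.copy()
        return out
    if cfg.tag == "sybil":
        base = out[0]
        max_id = max(u.client_id for u in out)
        for s in range(cfg.n_sybils):
            out.append(
                ClientUpdate(
                    client_id=max_id + 1 + s,
                    params=base.params.copy(),
                    n_samples=base.n_samples,
                    val_accuracy=base.val_accuracy,
                    attribution=None if base.attribution is None else base.attribution.copy(),
                )
            )
        return out
    if cfg.tag == "collusion":
        shared = -cfg.gamma * honest_mean
        for u in out[:f]:
            u.params = shared.copy()
        return out
    raise ValueError(f"unknown attack {cfg.tag!r}")
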