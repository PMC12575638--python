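"""Tabular data containers, min-max normalization, synthetic generators and
client partitioning.

The synthetic generator emulates small clinical-style tabular datasets
(mixed continuous/ordinal features, a binary or small multi-class target):
``k_informative`` features carry a class-conditional location shift of a
stated standardized effect size, the remainder are pure noise. Task streams
model incremental learning: class-incremental streams introduce unseen
labels per task over a shared feature domain, domain-incremental streams
keep the label set fixed and shift the feature distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TabularDataset",
    "NormalizationParams",
    "SyntheticSpec",
    "TaskStream",
    "ClientPartition",
    "fit_minmax",
    "apply_minmax",
    "generate_synthetic_tabular",
    "generate_task_stream",
    "partition_clients",
    "train_test_split",
]


class DataError(ValueError):
    """Raised for schema, missing-value or partition problems."""


@dataclass
class NormalizationParams:
    """Per-feature (min, max) fitted on a reference (training) split only."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != self.maxs.shape:
            raise DataError("min/max shape mismatch")
        if np.any(self.maxs < self.mins):
            raise DataError("max < min for some feature")

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant (max == min) features."""
        return self.maxs == self.mins


@dataclass
class TabularDataset:
    """Feature matrix + integer labels + schema + normalization state."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    bounds: NormalizationParams | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise DataError("features must be 2-D")
        if len(self.labels) != self.features.shape[0]:
            raise DataError("labels length must equal sample count")
        if np.isnan(self.features).any():
            raise DataError("missing values are not accepted")
        if len(self.feature_names) != self.features.shape[1]:
            raise DataError("feature_names length must equal feature count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx: np.ndarray | Sequence[int]) -> "TabularDataset":
        idx = np.asarray(idx, dtype=int)
        return TabularDataset(
            self.features[idx], self.labels[idx], list(self.feature_names), self.bounds
        )

    def select_features(self, mask: np.ndarray) -> "TabularDataset":
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, keep in zip(self.feature_names, mask) if keep]
        bounds = None
        if self.bounds is not None:
            bounds = NormalizationParams(self.bounds.mins[mask], self.bounds.maxs[mask])
        return TabularDataset(self.features[:, mask], self.labels, names, bounds)

    def to_csv(self, path: str | Path, target: str = "target") -> None:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[target] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, target: str = "target") -> "TabularDataset":
        df = pd.read_csv(path)
        if target not in df.columns:
            raise DataError(f"target column {target!r} not found")
        if df.isna().any().any():
            raise DataError("missing values are not accepted")
        labels = df[target].to_numpy()
        if not np.allclose(labels, np.round(labels)):
            raise DataError("target column must hold integer labels")
        feats = df.drop(columns=[target])
        return cls(feats.to_numpy(dtype=float), labels.astype(int), list(feats.columns))


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic clinical-style tabular dataset."""

    n_samples: int = 600
    m_features: int = 20
    k_informative: int = 5
    effect_size: float = 1.5
    class_count: int = 2
    label_balance: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    ordinal_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.m_features < 1:
            raise DataError("counts must be positive")
        if not 0 <= self.k_informative <= self.m_features:
            raise DataError("k_informative must lie in [0, m_features]")
        if self.effect_size < 0:
            raise DataError("effect_size must be nonnegative")
        if self.class_count < 2:
            raise DataError("need at least two classes")
        if self.label_balance is not None:
            bal = np.asarray(self.label_balance, dtype=float)
            if len(bal) != self.class_count or not np.isclose(bal.sum(), 1.0):
                raise DataError("label_balance must sum to 1 over class_count entries")
        if self.class_count > 2 and 2**self.k_informative < self.class_count:
            raise DataError(
                "need at least log2(class_count) informative features to give "
                "every class a distinct mean pattern"
            )


@dataclass
class TaskStream:
    """Ordered incremental tasks, class- or domain-incremental."""

    tasks: list[TabularDataset]
    mode: str  # "class" | "domain"

    def __post_init__(self) -> None:
        if self.mode not in {"class", "domain"}:
            raise DataError("mode must be 'class' or 'domain'")

    @property
    def all_classes(self) -> np.ndarray:
        return np.unique(np.concatenate([t.labels for t in self.tasks]))


@dataclass
class ClientPartition:
    """client_id -> index set into a dataset, plus the scheme tag."""

    indices: dict[int, np.ndarray]
    scheme: str

    def __post_init__(self) -> None:
        all_idx = np.concatenate([v for v in self.indices.values()]) if self.indices else np.array([], int)
        if len(np.unique(all_idx)) != len(all_idx):
            raise DataError("client index sets overlap")

    @property
    def n_clients(self) -> int:
        return len(self.indices)

    @property
    def total(self) -> int:
        return int(sum(len(v) for v in self.indices.values()))


# ---------------------------------------------------------------------------
# normalization


def fit_minmax(train: TabularDataset) -> NormalizationParams:
    """Fit per-feature (min, max) on the training split only."""
    if train.n_samples == 0:
        raise DataError("cannot fit normalization on an empty dataset")
    return NormalizationParams(train.features.min(axis=0), train.features.max(axis=0))


def apply_minmax(data: TabularDataset, params: NormalizationParams) -> TabularDataset:
    """Linearly rescale each feature to [0, 1]: x' = (x - min)/(max - min).

    Constant (degenerate) columns map to 0.0; out-of-range values seen at
    apply time (test data outside the training range) are clipped to [0, 1].
    """
    if data.n_features != len(params.mins):
        raise DataError("column arity mismatch between data and params")
    span = params.maxs - params.mins
    safe = np.where(span == 0, 1.0, span)
    x = (data.features - params.mins) / safe
    x[:, params.degenerate] = 0.0
    x = np.clip(x, 0.0, 1.0)
    return TabularDataset(x, data.labels, list(data.feature_names), params)


# ---------------------------------------------------------------------------
# synthetic generation

_ORDINAL_LEVELS = 4  # mirrors small ordinal clinical codes (e.g. chest-pain type)


def _class_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-class mean vectors over the informative block.

    Binary case: classes sit at 0 and effect_size*noise_sd on every
    informative feature, so the standardized mean difference is exactly the
    effect size. Multi-class: classes take +-sep/2 patterns drawn as a
    seeded binary code with pairwise Hamming distance >= ceil(k/2), so any
    two classes differ by the stated effect on at least half the
    informative features — no class pair is near-confusable by design.
    """
    k, c = spec.k_informative, spec.class_count
    sep = spec.effect_size * spec.noise_sd
    if c == 2:
        return np.vstack([np.zeros(k), np.full(k, sep)])
    min_dist = max(1, int(np.ceil(k / 2)))
    patterns: list[np.ndarray] = []
    tries = 0
    while len(patterns) < c:
        cand = rng.integers(0, 2, size=k)
        tries += 1
        if tries > 10000:
            if min_dist == 1:
                raise DataError(
                    f"cannot place {c} distinct class means on {k} informative features"
                )
            # relax the distance requirement if the code is infeasible
            min_dist -= 1
            tries = 0
        if all(np.sum(cand != p) >= min_dist for p in patterns):
            patterns.append(cand)
    return (np.asarray(patterns, dtype=float) - 0.5) * sep


def generate_synthetic_tabular(spec: SyntheticSpec) -> TabularDataset:
    """Draw a synthetic dataset per the spec; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    bal = (
        np.full(spec.class_count, 1.0 / spec.class_count)
        if spec.label_balance is None
        else np.asarray(spec.label_balance, dtype=float)
    )
    labels = rng.choice(spec.class_count, size=spec.n_samples, p=bal)
    means = _class_means(spec, rng)
    x = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.m_features))
    if spec.k_informative:
        x[:, : spec.k_informative] += means[labels]
    # a trailing block of noise features is discretized to small ordinal codes
    n_ord = int(round(spec.ordinal_fraction * (spec.m_features - spec.k_informative)))
    if n_ord:
        block = x[:, spec.m_features - n_ord :]
        q = np.quantile(block, np.linspace(0, 1, _ORDINAL_LEVELS + 1)[1:-1], axis=0)
        x[:, spec.m_features - n_ord :] = (block[None] > q[:, None, :]).sum(axis=0)
    names = [f"f{j}" for j in range(spec.m_features)]
    return TabularDataset(x, labels, names)


def generate_task_stream(
    base: SyntheticSpec, n_tasks: int, mode: str = "class", domain_shift: float = 1.0
) -> TaskStream:
    """Build an incremental task stream from a base recipe.

    Class-incremental: the label set is split into ``n_tasks`` disjoint
    groups and task t holds only its group's classes (union of task label
    sets equals the full label set). Domain-incremental: every task shares
    the label set; task t's features are shifted by ``t * domain_shift *
    noise_sd`` on the informative block.
    """
    if n_tasks < 1:
        raise DataError("need at least one task")
    if mode == "class":
        if base.class_count < n_tasks:
            raise DataError("class-incremental streams need class_count >= n_tasks")
        groups = np.array_split(np.arange(base.class_count), n_tasks)
        full = generate_synthetic_tabular(base)
        tasks = []
        for g in groups:
            idx = np.flatnonzero(np.isin(full.labels, g))
            tasks.append(full.subset(idx))
        return TaskStream(tasks, "class")
    if mode == "domain":
        tasks = []
        for t in range(n_tasks):
            spec_t = replace(base, seed=base.seed + 1000 * t)
            ds = generate_synthetic_tabular(spec_t)
            if t and base.k_informative:
                ds.features[:, : base.k_informative] += t * domain_shift * base.noise_sd
            tasks.append(ds)
        return TaskStream(tasks, "domain")
    raise DataError("mode must be 'class' or 'domain'")


# ---------------------------------------------------------------------------
# partitioning and splitting


def partition_clients(
    data: TabularDataset,
    n_clients: int,
    scheme: str = "iid",
    seed: int = 0,
    alpha: float = 0.5,
    quota: float | None = None,
) -> ClientPartition:
    """Assign sample indices to simulated clients.

    Schemes: ``iid`` shuffles and deals evenly; ``per-class-quota`` gives
    every client ``floor(quota * class size)`` samples of each class (quota
    defaults to 1/n_clients); ``dirichlet`` draws per-client class
    proportions from Dirichlet(alpha) to induce label skew.
    """
    if n_clients < 1:
        raise DataError("need at least one client")
    rng = np.random.default_rng(seed)
    n = data.n_samples
    if scheme == "iid":
        perm = rng.permutation(n)
        parts = np.array_split(perm, n_clients)
        return ClientPartition({k: np.sort(p) for k, p in enumerate(parts)}, scheme)
    if scheme == "per-class-quota":
        frac = 1.0 / n_clients if quota is None else quota
        out: dict[int, list[int]] = {k: [] for k in range(n_clients)}
        for c in data.classes:
            idx = rng.permutation(np.flatnonzero(data.labels == c))
            take = int(np.floor(frac * len(idx)))
            if take < 1:
                raise DataError(f"quota infeasible: class {c} has only {len(idx)} samples")
            if take * n_clients > len(idx):
                raise DataError("quota infeasible: clients would overlap")
            for k in range(n_clients):
                out[k].extend(idx[k * take : (k + 1) * take])
        return ClientPartition({k: np.sort(np.asarray(v, int)) for k, v in out.items()}, scheme)
    if scheme == "dirichlet":
        out = {k: [] for k in range(n_clients)}
        for c in data.classes:
            idx = rng.permutation(np.flatnonzero(data.labels == c))
            props = rng.dirichlet(np.full(n_clients, alpha))
            cuts = (np.cumsum(props)[:-1] * len(idx)).astype(int)
            for k, chunk in enumerate(np.split(idx, cuts)):
                out[k].extend(chunk)
        return ClientPartition({k: np.sort(np.asarray(v, int)) for k, v in out.items()}, scheme)
    raise DataError(f"unknown scheme {scheme!r}")


def train_test_split(
    data: TabularDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[TabularDataset, TabularDataset]:
    """Stratified train/test split (default 80/20)."""
    if not 0 < test_fraction < 1:
        raise DataError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in data.classes:
        idx = rng.permutation(np.flatnonzero(data.labels == c))
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test])
    test_mask = np.zeros(data.n_samples, dtype=bool)
    test_mask[np.asarray(test_idx, int)] = True
    return data.subset(np.flatnonzero(~test_mask)), data.subset(np.flatnonzero(test_mask))
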