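"""Chaotic Bobcat Optimization Algorithm (CBOA) wrapper feature selection.

A population of ``N`` candidate positions in [0, 1]^m is evolved for ``T``
iterations. Initialization uses a logistic chaotic map; exploration moves
each bobcat toward a randomly chosen fitter member ("prey"); exploitation
applies a small iteration-decaying perturbation; each move is kept only if
it does not worsen the objective (greedy acceptance). Positions binarize to
feature subsets by thresholding, and the objective is

    J(subset) = (1 - CV accuracy of a surrogate classifier) + alpha*|subset|/m,

minimized. The surrogate is a ridge-penalized softmax fit under repeated
3-fold stratified cross-validation (averaging the replicates damps
fold-assignment luck); distinct masks are memoized so repeated visits cost
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import linear
from .data import TabularDataset

__all__ = [
    "SearchBounds",
    "CBOAConfig",
    "BobcatPopulation",
    "CBOAResult",
    "chaotic_init_population",
    "binarize_position",
    "evaluate_fitness",
    "candidate_prey_set",
    "exploration_step",
    "exploitation_step",
    "greedy_accept",
    "run_cboa",
    "exhaustive_best_subset",
    "FitnessCache",
]

_LOGISTIC_FIXED_POINTS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


@dataclass
class SearchBounds:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.upper < self.lower):
            raise ValueError("upper bound below lower bound")

    @classmethod
    def unit(cls, m: int) -> "SearchBounds":
        return cls(np.zeros(m), np.ones(m))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class CBOAConfig:
    pop_size: int = 30
    max_iters: int = 100
    threshold: float = 0.5
    alpha: float = 0.01  # sparsity penalty weight
    cv_folds: int = 3
    cv_repeats: int = 3  # repeated CV averages out fold-assignment luck
    surrogate_l2: float = 1e-2
    seed: int = 0
    chaos_warmup: int = 50

    def __post_init__(self) -> None:
        if self.pop_size < 2 or self.max_iters < 1:
            raise ValueError("pop_size >= 2 and max_iters >= 1 required")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class BobcatPopulation:
    positions: np.ndarray  # N x m
    fitness: np.ndarray  # N
    iteration: int = 0


@dataclass
class CBOAResult:
    best_position: np.ndarray
    best_mask: np.ndarray
    best_objective: float
    trace: np.ndarray  # best objective per iteration, non-increasing


def _logistic_iterates(c0: np.ndarray, n_warmup: int) -> np.ndarray:
    c = c0.copy()
    for _ in range(n_warmup):
        c = 4.0 * c * (1.0 - c)
    return c


def chaotic_init_population(
    bounds: SearchBounds, config: CBOAConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Positions x = lb + (ub - lb) * c, with c logistic-map iterates.

    Seeds are drawn per dimension and nudged off the map's fixed points
    {0, 1/4, 1/2, 3/4, 1}, then warmed up so the initial sheet is well
    mixed over (0, 1).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = len(bounds.lower)
    c0 = rng.uniform(0.01, 0.99, size=(config.pop_size, m))
    near = np.min(np.abs(c0[..., None] - _LOGISTIC_FIXED_POINTS), axis=-1) < 1e-6
    c0[near] += 1e-3
    c = _logistic_iterates(c0, config.chaos_warmup)
    return bounds.lower + (bounds.upper - bounds.lower) * c


def binarize_position(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Feature d is selected iff x_d > threshold; an empty mask is repaired
    to the argmax coordinate so a subset is never empty."""
    mask = np.asarray(position) > threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


class FitnessCache:
    """Memoizes the subset objective.

    Fold assignments (cv_repeats independent replicates of cv_folds
    stratified folds) are frozen per cache, so the objective landscape is
    deterministic and the averaged accuracy damps single-split luck —
    without averaging, a pure-noise feature that happens to flip one test
    prediction outweighs the sparsity penalty. The cache can be shared
    across search runs on the same dataset.
    """

    def __init__(self, data: TabularDataset, config: CBOAConfig):
        self.data = data
        self.config = config
        self._cache: dict[bytes, float] = {}
        self._fold_sets = [
            _stratified_folds(data.labels, config.cv_folds, 9973 * r + 1)
            for r in range(config.cv_repeats)
        ]
        self.n_evals = 0

    def objective(self, mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            self._cache[key] = self._evaluate(mask)
        return self._cache[key]

    def _evaluate(self, mask: np.ndarray) -> float:
        self.n_evals += 1
        X = self.data.features[:, mask]
        y = self.data.labels
        spec = linear.LinearModelSpec(X.shape[1], len(self.data.classes))
        accs = []
        for folds in self._fold_sets:
            correct = 0
            for test_idx in folds:
                train = np.ones(len(y), dtype=bool)
                train[test_idx] = False
                w = linear.fit_logistic(X[train], y[train], spec, l2=self.config.surrogate_l2)
                correct += int(np.sum(linear.predict(w, X[test_idx], spec) == y[test_idx]))
            accs.append(correct / len(y))
        return (1.0 - float(np.mean(accs))) + self.config.alpha * mask.sum() / self.data.n_features


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk)
    return [np.asarray(f, int) for f in folds]


def evaluate_fitness(
    position: np.ndarray, data: TabularDataset, config: CBOAConfig, cache: FitnessCache | None = None
) -> float:
    """Objective of a continuous position via its binarized subset."""
    cache = FitnessCache(data, config) if cache is None else cache
    return cache.objective(binarize_position(position, config.threshold))


def candidate_prey_set(fitness: np.ndarray, i: int) -> np.ndarray:
    """Indices of strictly fitter members: CP_i = {k : F_k < F_i, k != i}."""
    return np.flatnonzero(fitness < fitness[i])


def exploration_step(
    position: np.ndarray, prey: np.ndarray, rng: np.random.Generator, bounds: SearchBounds
) -> np.ndarray:
    """Move toward the selected prey: x' = x + (1 - 2r)(SP - I x), with
    r ~ U[0,1] and I in {1, 2} equiprobable per dimension."""
    r = rng.uniform(size=position.shape)
    I = rng.integers(1, 3, size=position.shape)
    return bounds.clip(position + (1.0 - 2.0 * r) * (prey - I * position))


def exploitation_step(
    position: np.ndarray, t: int, rng: np.random.Generator, bounds: SearchBounds
) -> np.ndarray:
    """Local pursuit move: x' = x + ((1 - 2r)/(1 + t)) x, shrinking with the
    iteration count t (1-based)."""
    r = rng.uniform(size=position.shape)
    return bounds.clip(position + ((1.0 - 2.0 * r) / (1.0 + t)) * position)


def greedy_accept(
    old_position: np.ndarray, old_f: float, new_position: np.ndarray, new_f: float
) -> tuple[np.ndarray, float]:
    """Keep the candidate iff it is no worse (new_f <= old_f)."""
    if new_f <= old_f:
        return new_position, new_f
    return old_position, old_f


def run_cboa(
    data: TabularDataset, config: CBOAConfig, cache: FitnessCache | None = None
) -> CBOAResult:
    """Full CBOA search over feature subsets of ``data`` (normalized train
    split). Returns the best subset found and the per-iteration trace.

    A ``FitnessCache`` may be passed in to share memoized subset objectives
    across repeated searches on the same dataset (the landscape does not
    depend on the search seed).
    """
    rng = np.random.default_rng(config.seed)
    m = data.n_features
    bounds = SearchBounds.unit(m)
    cache = FitnessCache(data, config) if cache is None else cache
    X = chaotic_init_population(bounds, config, rng)
    pop = BobcatPopulation(
        positions=X,
        fitness=np.array([evaluate_fitness(x, data, config, cache) for x in X]),
    )

    best_i = int(np.argmin(pop.fitness))
    best_pos, best_f = pop.positions[best_i].copy(), float(pop.fitness[best_i])
    trace = np.empty(config.max_iters)

    for t in range(1, config.max_iters + 1):
        pop.iteration = t
        X, F = pop.positions, pop.fitness
        for i in range(config.pop_size):
            prey_idx = candidate_prey_set(F, i)
            if len(prey_idx):
                prey = X[rng.choice(prey_idx)]
                cand = exploration_step(X[i], prey, rng, bounds)
                f_cand = evaluate_fitness(cand, data, config, cache)
                X[i], F[i] = greedy_accept(X[i], F[i], cand, f_cand)
            cand = exploitation_step(X[i], t, rng, bounds)
            f_cand = evaluate_fitness(cand, data, config, cache)
            X[i], F[i] = greedy_accept(X[i], F[i], cand, f_cand)
        i_min = int(np.argmin(F))
        if F[i_min] <= best_f:
            best_pos, best_f = X[i_min].copy(), float(F[i_min])
        trace[t - 1] = best_f

    return CBOAResult(
        best_position=best_pos,
        best_mask=binarize_position(best_pos, config.threshold),
        best_objective=best_f,
        trace=trace,
    )


def exhaustive_best_subset(
    data: TabularDataset, config: CBOAConfig, cache: FitnessCache | None = None
) -> tuple[np.ndarray, float]:
    """Brute-force optimum over all non-empty subsets (oracle for small m)."""
    m = data.n_features
    cache = FitnessCache(data, config) if cache is None else cache
    best_mask, best_f = None, np.inf
    for code in range(1, 2**m):
        mask = np.array([(code >> d) & 1 for d in range(m)], dtype=bool)
        f = cache.objective(mask)
        if f < best_f:
            best_mask, best_f = mask, f
    return best_mask, float(best_f)
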