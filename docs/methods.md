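# Methods

`ppfil` simulates, on one machine, a privacy-preserving federated
incremental learning pipeline for small clinical-style tabular datasets:
metaheuristic wrapper feature selection, federated rounds with replay
caching, local differential privacy, Byzantine-robust aggregation, a
hash-chained model ledger, and a final entropy-sized deep-belief-network
classifier. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Synthetic data

The generator emulates tables like the Kaggle heart-disease and breast
cancer datasets: `n` samples, `m` mixed continuous/ordinal features of
which `k` are class-informative, integer labels. Informative features
carry a class-conditional location shift; the standardized mean separation
equals `effect_size` (binary case: class 0 at 0, class 1 at
`effect_size * noise_sd` on every informative feature). For more than two
classes, each class takes a +-sep/2 pattern from a seeded binary code with
pairwise Hamming distance at least ceil(k/2), so no two classes are
near-confusable; this requires `2^k >= class_count`. A trailing quarter of
the noise features is discretized to four ordinal levels, mirroring coded
clinical variables. Defaults (`n=600, m=20, k=5, effect=1.5`) are the
working scale throughout: a few hundred patients per site, moderate class
overlap.

What the generator does **not** emulate: missing values, measurement
artifacts, correlated features, covariate shift between sites beyond the
explicit domain-incremental mode, and label noise. Passing tests therefore
demonstrate algorithmic correctness and qualitative behaviour (monotone
privacy/utility trade-off, attack mitigation orderings), not clinical
performance.

Min-max normalization is fitted on the 80% training split only and applied
with clipping to [0, 1] elsewhere; constant columns map to 0. Task streams
are class-incremental (disjoint label groups per task over a shared
feature domain) or domain-incremental (fixed labels, per-task mean shift).
Client partitions: IID deal, per-class quota (each client receives an
equal fraction of every class), or Dirichlet(alpha) label skew.

## Feature selection (chaotic bobcat search)

A population of `N=30` positions in `[0,1]^m` evolves for `T` iterations.
Initialization uses logistic-map iterates (`c <- 4c(1-c)`, 50 warm-up
steps, seeds nudged off the fixed points {0, 1/4, 1/2, 3/4, 1}).
Exploration moves a position toward a uniformly chosen strictly-fitter
member (`x' = x + (1-2r)(SP - I x)`, `r~U[0,1]`, `I in {1,2}`);
exploitation adds the decaying perturbation `x' = x + ((1-2r)/(1+t)) x`.
Moves are clipped to the bounds and kept only if the objective does not
worsen, which makes the best-so-far trace exactly non-increasing.

Positions binarize at threshold 0.5 (empty masks repaired to the argmax
coordinate). The objective, minimized, is

    J(S) = (1 - CV accuracy of a ridge-penalized softmax on S) + alpha |S|/m,

with `alpha = 0.01`. Accuracy is averaged over **three independent
replicates** of 3-fold stratified cross-validation, frozen per dataset so
the landscape is deterministic. The replication removes fold-assignment
luck: with a single split, a noise feature that happens to flip one test
prediction gains ~1/n accuracy, which exceeds the per-feature sparsity
penalty `alpha/m`, and the search — an effective maximizer over thousands
of masks — collects such features erratically. Distinct masks are
memoized; a cache can be shared across search seeds because the landscape
does not depend on them.

**Recovery ceiling.** Replication cannot remove *dataset-level* chance
correlations: at n~500, a few of the pure-noise features correlate with
the labels at |r| ~ 0.1 in the realized sample, which is genuine in-sample
signal worth a few tenths of a percent of CV accuracy — an order of
magnitude more than `alpha/m`. The selected subset therefore reliably
contains every truly informative feature plus roughly three such
chance-correlated extras (Jaccard ~ 0.6 against the generating truth at
the default scale), and this is a property of the objective on finite
data, not of the search: the exhaustive oracle picks the same subsets.
Recovering the generating truth exactly would need a per-feature penalty
several times larger than the default, at the cost of dropping genuinely
weak features on real data.

## Federated incremental learning

All parties share one flat parameter vector for a small softmax classifier
(optionally with one tanh hidden layer). Hyperparameters follow the
standard federated recipe: local epochs E=5, batch size B=64, momentum
0.9. The reference configuration trains for 500 rounds at learning rate
1e-3; the desk-scale experiments here run ~25 rounds and raise the rate to
0.05 so the optimization budget (steps x rate) is comparable.

When a new task arrives, a client rebuilds its **personalized informative
model** (PIM): warm-started from its local model, updated for `s=10`
iterations on its previous local samples with the summed cross-entropy
gradient plus the mixing pull `q(lambda)(v - w)` toward the received
global model, `q(lambda) = (1-lambda)/(2 lambda)`, default `lambda = 0.5`
(a grid over {0.1..0.9} is the tuning protocol; 1.0 is outside the
domain). Each iteration records every candidate sample's squared gradient
norm; importance accumulates them as `I = sum_p G^p / p`, weighting the
early phase most. The top-M samples (M=50, ties to the more recent) become
the replay cache; local training then runs on the new task plus the cache.

**What the forgetting experiment shows.** On the standard two-task stream
(four classes, two unseen classes per task), importance caching retains
old-task accuracy consistently better than a uniform-random cache, but by
roughly 1-2 percentage points, not more. This is expected for a convex or
shallow learner on independent Gaussian-like data: a uniform subsample is
already a near-optimal summary of the old task, and top-M gradient-norm
selection concentrates on margin samples whose extra value is modest (and
whose noise content grows as class overlap grows). Larger selection gains
reported for deep models on real data do not transfer to this model class
at this scale; the module test asserts the direction of the effect, not a
large margin.

## Privacy and robustness

Client updates are clipped to L2 norm `C` (default 1; for the softmax
model, rescaling the whole vector leaves the decision function's argmax
unchanged) and perturbed per coordinate with Gaussian noise of scale
`multiplier * C` — unbiased, with "privacy level" 1-5 mapping to
multipliers {0.25, 0.5, 1, 2, 4}. A randomized-response variant flips sign
bits with a level-dependent probability and buckets magnitudes into 16
bins. Noise is applied to model updates (not raw data or gradients). No
formal (epsilon, delta) accounting is claimed.

The robust filter computes the coordinate-wise median update, each
update's distance to it, and excludes updates whose distance deviates from
the median distance by more than the larger of `c=3` times the
normal-consistent MAD (1.4826 x raw MAD) and the median distance itself.
The floor matters at federation scale: with a dozen clients the sample MAD
of the distances is noisy enough that a bare `c*MAD` cut flags an honest
client in roughly 40% of rounds, while poisoned updates sit at distances
many times the honest median — so requiring an outlier to also be more
than twice the typical distance from the consensus restores specificity
(no exclusions in ~300 simulated honest rounds) without costing
detection. Aggregation weights
combine local validation accuracy with the nonnegative cosine similarity
between a client's saliency attribution (mean |gradient x input| per
feature) and the consensus attribution; plain sample-count weighting is
the FedAvg baseline. The aggregate is the normalized weighted mean, so it
lies coordinate-wise inside the kept updates' convex hull.

Threat generators: additive-noise updates, label flipping on attacker-held
data, fixed negative scaling of the honest mean (static optimization),
filter-adaptive scaling (the largest grid gamma whose crafted update
evades the filter, falling back to mimicking the honest mean), Sybil
replication under fabricated ids, and collusion (all attackers submit one
crafted update). The label-flip study uses the one-hidden-layer learner:
averaging in a label-inverted *linear* model only rescales logits and
leaves accuracy untouched, so a linear pipeline cannot exhibit the damage
the filter is meant to prevent. The privacy sweep uses 32 clients so the
aggregate noise (shrinking with sqrt(K)) stays graded across multipliers,
and both sweeps evaluate on a 2000-sample fresh draw to keep Monte-Carlo
noise on the reported means well under a percentage point.

## Ledger

Blocks carry the SHA-256 digest of the serialized global parameter vector
plus round metadata; hashing is over key-sorted, compact, UTF-8 JSON with
floats rounded to 12 significant digits (platform-stable byte encoding).
Timestamps are logical round counters. A block is admitted only if the
round's validation accuracy clears the threshold (default: previous best
minus one percentage point). Validation checks every stored hash before
every link, so a tampered block is reported at its own index.
Proof-of-contribution is the leave-one-out marginal validation-accuracy
gain, floored at zero; the proposer is the cumulative argmax (ties to the
lowest client id).

## Entropy deep belief network

Binary RBMs are trained with CD-1 (learning rate 0.05, batch 32, weights
N(0, 0.01^2)); normalized features in [0, 1] serve as Bernoulli
probabilities for the first visible layer. A layer's information entropy
is `H = sum_i [p_i(0) log2 1/p_i(0) + p_i(1) log2 1/p_i(1)]` with
activation probabilities clipped at 1e-6; each hidden width is constrained
to `ceil(H_vo) <= width <= N_vo` (floored at one node for near-constant
layers). Structure search greedily picks, per layer up to depth 3, the
grid width with the lowest held-out one-step mean-field reconstruction
error. The energy-style loss `L = (1/T) sum_t [v W h + a v + b h]` is
computed exactly as defined and reported as a diagnostic only — its sign
convention is that of a positive energy, so it is never used as a training
objective.

For classification the stack unrolls into a sigmoid feed-forward network
with a softmax head, fine-tuned end-to-end by heavy-ball SGD on
cross-entropy. Gradients are batch means, so the default step of 0.5 is a
per-sample step of ~1/64; saturating sigmoid stacks need steps of this
order plus momentum, and narrow stacks (width ~4) need several hundred
epochs where 20-unit stacks converge in 150.

## Numerical and degenerate-input conventions

- Degenerate (constant) feature columns normalize to 0.0; out-of-range
  values clip to [0, 1].
- Precision/recall with empty denominators are defined as 0; F is the
  standard harmonic mean; multi-class metrics are macro one-vs-rest with
  label 1 the binary positive class.
- `loss_percent = 100 - accuracy` is reported for parity with
  complement-style loss tables, always alongside (never in place of) the
  true cross-entropy.
- Probabilities are clipped at 1e-12 before logs; simulated latency and
  throughput are wall-clock counters, flagged hardware-dependent and
  excluded from any correctness claim.
- Every stochastic component draws from `numpy.random.default_rng` seeded
  from the experiment seed; equal seeds reproduce bit-identical runs.

## Known limitations

Single-process simulation only (no networking, scheduling, or real
consensus); linear/one-hidden-layer base learners inside the federated
loop (the deep classifier runs once, after training); Gaussian LDP without
composition accounting; attack implementations follow the spirit, not the
letter, of the optimization-based attacks they are named after; and the
synthetic generator's independence assumptions understate the difficulty
of real clinical tables.
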