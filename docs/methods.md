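# Methods

This note records the models, estimators, numerical conventions and
design choices behind `surrogenes`, and what the synthetic benchmarks
do and do not demonstrate.

## Mutual-information estimator

Relevance and redundancy both use the mutual information of a bivariate
Gaussian with correlation ρ, I = −½ ln(1 − ρ²), in nats. This is exact
when the pair is jointly Gaussian and otherwise a monotone transform of
|ρ|, so the greedy argmax depends only on the correlation structure.
Conventions:

- ρ² is clamped at 1 − 1e-12, making the MI of a perfect correlation a
  large finite value (≈13.8 nats). Exact duplicate features therefore
  receive the maximum representable redundancy penalty while every
  score stays finite and comparable.
- Zero-variance features are assigned ρ = 0 (MI 0). An undefined
  correlation must never win or poison an argmax.
- The phenotype is encoded ordinally by its position in `class_order`.
  Disease phases are ordered (normal → primary → metastatic), so a
  monotone expression trend along progression produces high |ρ|. Both
  Pearson (default) and Spearman are available; feature–feature
  redundancy uses the same correlation method as feature–label
  relevance, keeping a single estimator throughout.

## Greedy mRMR ranking

Step 1 selects the feature with maximal relevance; each later step
selects the candidate maximizing q = relevance − mean MI against the
selected set. Exact score ties break by smallest input index, making
the ranking fully deterministic. Because the procedure is greedy and
forward-only, rankings nest: the length-k ranking is the k-prefix of
the length-n ranking. The IFS sweep exploits this by evaluating
prefixes of one ranking instead of re-running the selection per N; a
cross-check test verifies the equivalence on small instances, and an
independently coded exhaustive per-step argmax serves as the oracle for
the ranking itself.

## Distance and prediction engines

All engines use the cosine distance d = 1 − e₁·e₂/(‖e₁‖‖e₂‖) on the
selected feature vectors: range [0, 2], symmetric, invariant to
positive rescaling of either sample — the natural choice when overall
intensity differs between arrays but the expression *profile* carries
the signal. Zero-norm vectors have no direction and raise an error
rather than returning an arbitrary value.

Deterministic tie rules (the choice of rule is a convention; having one
is what matters for reproducibility):

- nearest-neighbor ties → smallest training index;
- 5-NN vote ties → the tied label whose nearest representative is
  closest to the query;
- centroid-distance ties → earlier class in `class_order`.

Jackknife validation predicts each sample from the other n − 1. The
held-out sample is excluded from the neighbor pool and from centroid
computation (centroids are recomputed inside every fold), so no
information about the held-out label can reach its own prediction; a
mutation test asserts this. Overall accuracy is the fraction of correct
predictions, identical to (TP+TN)/(TP+TN+FP+FN) under one-vs-rest
micro-summing. Pairwise accuracies (e.g. NT vs MT) restrict the scored
set to samples whose *true* label is in the pair.

## Incremental feature selection

The curve records every engine's jackknife accuracy for N = 1..max_n
(default max_n = min(400, ranking length)). The optimum is the smallest
N attaining the maximum accuracy of the selecting engine; `nn1` is the
default selecting engine and the sweep is cheap enough that all three
engines are evaluated when requested. Two jackknife accuracies are
treated as tied when they differ by less than 1e-12 — they are ratios
of integer counts over a common denominator, so genuine ties are exact
and the tolerance only absorbs float noise.

## Interaction network and bridge genes

Edge lists follow the STRING flat-file convention (`protein1 protein2
combined_score`, integer scores 0–1000, optional header). Ingest drops
edges below the confidence threshold (default 400, STRING's "medium
confidence"; the threshold is a user-visible parameter), collapses
duplicate pairs to their maximum score, and discards self-loops.

Shortest paths use Dijkstra's algorithm. Default edge weight is 1 per
edge (hop mode): a shortest path then minimizes the number of
intermediate partners, which matches how bridging genes are read off a
PPI sub-network. Score-derived weights (1 − score/1000) are available
as an option. Among equal-weight paths the lexicographically smallest
node sequence is returned, by greedy reconstruction over a
distance-to-target map; `all_shortest` instead unions every tied path
into the sub-network. Disconnected seed pairs and seeds missing from
the graph are recorded as unresolved rather than raised, as long as at
least two seeds resolve. Floating-point path weights are compared with
a 1e-9 relative tolerance; note that a score of exactly 1000 yields a
zero-weight edge in score mode, which is legitimate but makes "the"
shortest path non-unique up to zero-weight detours — the deterministic
reconstruction guards against cycling through a visited-set check.

## Synthetic data generator

The expression generator emulates a three-phase progression microarray
study. Defaults mirror the emulated study scale: 167 samples split
77/66/24 (NT/PT/MT), 4 informative probes with 2 redundant copies each,
188 null probes (200 total), effect size 3, within-class SD 1.

- **Informative probes** are class-conditional Gaussians whose means
  move by `effect_size` × within-class SD per phase step, monotonically
  ordered across phases. Directions alternate: half the probes increase
  along progression, half decrease. With a single shared direction all
  three class-mean vectors would be parallel and cosine distance could
  not separate the classes at all; alternating signs preserves the
  per-probe monotone signal while giving the phases distinct profiles,
  which is what real phase signatures look like (progression induces
  both up- and down-regulation).
- **Within-class covariance.** Informative-probe noise mixes an
  independent component with a per-sample shared factor loading on the
  progression direction (`signature_noise_share` = 0.2 of the
  variance). This emulates sample-level heterogeneity — tumor purity
  and tissue composition move all signature genes coherently along the
  progression axis — and it is what makes the benchmark non-trivial:
  with purely independent noise, two or three planted probes already
  separate the classes perfectly and the size-selection rule has
  nothing left to trade off. The per-probe within-class SD remains
  exactly 1, so `effect_size` keeps its stated meaning.
- **Redundant copies** are their parent's values plus N(0, 0.5) noise —
  noisy re-measurements (parent–copy ρ ≈ 0.98), not independent
  redraws, so the redundancy penalty has a known correct behavior:
  defer copies until every independent signal family is selected.
- **Null probes** are label-independent Gaussians. Baselines sit in
  [5, 15] arbitrary units (evenly spaced for informative probes,
  uniform for nulls), away from the origin so cosine geometry is
  well-behaved; values are not clipped at zero, a declared
  simplification of expression scales.
- Ground truth (probe roles, parent links) is always returned as a
  sidecar table; recovery means every informative probe is represented
  in the optimal set by itself or one of its copies.

The graph generator plants seed genes joined by short bridge chains
(each planted edge at the maximum of `score_range`, so any in-range
threshold retains them) over an Erdős–Rényi background among the
background nodes. Background edges never touch the planted structure,
so the planted bridges are the unique seed-to-seed routes and recovery
can be checked exactly; tests additionally construct interacting
bridges by hand to exercise the case where a shared bridge node
shortcuts a longer planted chain.

What the benchmarks do **not** show: the generator has no chip or batch
effects, no heavy-tailed intensity distributions, no missing values
beyond what ingest tests construct, and its class-conditional Gaussian
form is a declared stand-in — no claim is made about the distribution
of real MAS 5.0-scaled data. Passing recovery tests demonstrates the
algorithmic chain is correct and well-calibrated on its stated model,
not that a four-gene set suffices for any particular real dataset.

## Determinism

All simulation randomness flows from NumPy `default_rng(seed)` in the
config; ranking, jackknife, IFS and path extraction are deterministic
given their inputs (tie rules above). Two pipeline runs with the same
config and seed produce byte-identical artifacts; consequently the run
report contains config echo, seed and versions but no wall-clock
timings — those go to the log stream.

## Problem sizes

Tests and the acceptance script run the expression pipeline at the full
emulated study scale (167 samples, 200 probes) with the ranking and the
IFS sweep truncated at 50 features — the planted signal occupies the
first dozen ranks, so deeper sweeps only extend the flat tail of the
curve. Recovery statistics use 20 independent simulation seeds;
shortest-path oracle checks use 50 random graphs of up to 20 nodes, and
bridge recovery 10 seeded graphs.
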