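# Methods

## Problem and model

Given a DNA alignment, a set of user-defined data blocks (site sets), and
an information criterion, the task is to find the partitioning scheme —
a set partition of the blocks into subsets, each subset sharing one
substitution model — with the best criterion score. All searches here
operate under a single model family and a single fixed tree:

* **Substitution model.** GTR+Γ only. The proportion-of-invariant-sites
  parameter is deliberately excluded: it is confounded with the gamma
  shape, and unstable estimates of either would corrupt the parameter
  distances the clustering relies on.
* **Tree.** The topology is fixed before any model selection: a
  neighbor-joining tree on Jukes–Cantor distances (saturated pairwise
  distances capped at 5.0 substitutions/site), or a user Newick tree.
  Model selection is insensitive to the exact non-random topology, so no
  topology search is performed.
* **Linked branch lengths.** One set of relative branch lengths is
  estimated on the whole alignment under GTR+Γ and then frozen. Each
  subset gets a single free rate multiplier m_s ∈ [1e−6, 200] rescaling
  those lengths. This keeps the per-subset model at 10 parameters
  (9 + multiplier) instead of 9 + (2T−3), at the cost of ignoring
  heterotachy (no per-subset branch lengths, no covarion behaviour).

## Likelihood engine

Felsenstein pruning over compressed site patterns, vectorized per gamma
category with the symmetric eigendecomposition of the reversible rate
matrix. Per-pattern rescaling at every internal node prevents underflow;
a zero-probability pattern yields −∞ with a warning rather than an
exception. The discrete gamma uses k = 4 equal-probability categories
with *mean-of-category* rates (conditional means via regularized
incomplete gamma functions), renormalized so the category mean is
exactly 1.

Fitting is deterministic coordinate ascent: base frequencies are fixed at
the observed proportions over the subset's sites (one pseudocount per
base — frequencies are not ML-optimized, trading a sliver of likelihood
for speed and stability in small subsets); then the rate multiplier, the
gamma shape α ∈ [0.01, 100], and the five free exchangeabilities
∈ [1e−4, 1e4] (GT ≡ 1) are each refined by a bounded scalar search on a
log scale (absolute tolerance 1e−3 on the log10 parameter), cycling until
the log-likelihood gains less than 1e−3 per cycle (at most 12 cycles). A
subset with no variable sites is flagged `degenerate` and pinned at the
α upper bound and multiplier lower bound. Branch lengths ∈ [1e−8, 50]
are optimized one at a time in round-robin passes (gain < 1e−3 per pass
stops a round; 20-pass guard), alternating twice with re-optimization of
the global model parameters. There is no randomness anywhere in fitting:
identical inputs give bit-identical fits, which the caching and
determinism guarantees rely on.

## Scoring

k(S, T) = 9S + (S−1) + (2T−3). The branch lengths are counted even
though they are constant across schemes; this offsets absolute scores
relative to tools that omit them but cannot change any ranking. n is the
total alignment length in sites for every scheme, including schemes
evaluated mid-search. AICc raises an explicit error when n − k − 1 ≤ 0
instead of returning a misleading value. AIC is available but
discouraged; AICc or BIC should be used.

## Subset similarity

Four parameter categories: overall rate (m_s × total tree length), base
frequencies (4-vector), GTR exchangeabilities (6-vector, GT ≡ 1 in both
fits so the vectors are commensurable), and α (scalar). Per category:
Euclidean distances, then division by the current maximum (an all-zero
matrix stays zero), then multiplication by the user weight, then
summation — normalize first, weight second. Normalization is relative to
the *current* subsets and is redone from freshly fitted parameters after
every merge; parameters of a merged subset are always re-estimated from
its sites, never averaged from its children, because averaging is a
biased and unreliable surrogate for the joint ML fit. Zero-weight
categories are skipped entirely, which also keeps the 1000-block
strict-clustering run cheap. Ties in the most-similar pair break to the
lexicographically smallest index pair under the deterministic subset
ordering (smallest contained site, then block names).

## Searches

All searches share a fit cache keyed by the subset's site set; a subset
is fitted at most once per run (or never, if a warm cache is supplied),
and the ledger records distinct subsets fitted and schemes scored.
"Improvement" always means *strictly* lower score — no epsilon — so runs
are deterministic and terminate.

* **Exhaustive**: restricted-growth-string enumeration of all Bell(N)
  partitions, refused above N = 12.
* **Greedy**: all C(S,2) merges scored per iteration; first-best wins
  ties.
* **Strict clustering**: N−1 similarity-driven merges, score consulted
  only at the end over the N recorded schemes. Exactly 2N−1 subsets are
  fitted — the source of the O(N) scaling (1999 evaluations for
  N = 1000).
* **Relaxed clustering**: the top S = max(1, ⌈P/100 · #pairs⌉) most
  similar pairs are trial-merged per iteration (ceiling chosen so P = 0
  still evaluates one pair and P = 100 evaluates all); the best
  strictly-improving merge is applied. When candidate schemes tie, the
  pair earliest in the distance ordering wins. With P = 100 the
  trajectory coincides with greedy whenever no two candidate schemes
  have exactly equal scores (scores are sums of cached fits, so the
  comparison is exact, not approximate).

Defaults: weights 1,0,0,0 (rate-only similarity) and P = 10 — the
settings that balance robustness and cost in practice; base-frequency
driven similarity in particular is known to mislead clustering when
subsets are small.

## Synthetic data

The simulator draws, per site, a gamma category uniformly, a root state
from the block's stationary frequencies, and then propagates states
root-to-tip with exp(Q · t · m_block · r_cat) — exactly the process the
fitting side assumes, minus alignment error, indels, heterotachy and
base-composition non-stationarity, which real data have and these tests
therefore do not probe. Recovery fixtures place `n_blocks` contiguous
blocks round-robin into `n_classes` rate classes with geometrically
spaced multipliers (spread 5 by default, i.e. classes at rates 1 and 5),
2000 sites per block, on a random 6-taxon tree grown by sequential
attachment with uniform(0.05, 0.2) branch lengths — sizes at which
rate-class recovery is expected but not trivial, and which keep the full
10-seed recovery experiment and the 20-instance exhaustive-vs-heuristic
comparison (4 taxa, 40 sites/block, N ∈ {4,5,6}) at desk scale. The
default GTR used in simulation is mildly AT-rich and transition-biased,
with α = 1.

## Known limitations

* Exact numerical agreement with PartitionFinder/RAxML is not a goal:
  optimizer tolerances, frequency handling and parameter-count
  conventions differ between tools; rankings of schemes, not absolute
  scores, are the supported comparison surface.
* Amino-acid alphabets, +I models, unlinked branch lengths, NEXUS
  alignment input and interleaved PHYLIP are out of scope.
* The greedy/relaxed-P=100 equivalence is a property of this
  implementation's shared tie-breaking; it is not a claim about other
  tools' greedy searches.
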