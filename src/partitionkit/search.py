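"""Partitioning-scheme search: exhaustive, greedy, strict and relaxed
hierarchical clustering.

All four algorithms start from the scheme in which every data block is its
own subset and explore merges. The expensive operation is fitting a
subset's GTR+G model; every fitted subset is cached for the lifetime of a
run (and can be shared across runs on the same data), so each distinct
subset is fitted at most once. Scoring a scheme only sums cached subset
log-likelihoods.

* ``exhaustive_search`` scores every set partition of the blocks (Bell(N)
  schemes) — the ground-truth optimum, feasible only for small N.
* ``greedy_search`` evaluates all pairwise merges each iteration and
  applies the best one while it strictly improves the score (O(N^2)
  subset fits overall).
* ``strict_cluster_search`` always merges the most similar pair
  (no score involved in the merge choice), producing exactly N schemes
  with N .. 1 subsets from 2N-1 subset fits, and returns the best-scoring
  of those N. It is not a hill-climber: the trajectory may worsen.
* ``relaxed_cluster_search`` interpolates: each iteration trial-merges the
  top P% most similar pairs and keeps the best-scoring merge if it
  improves the score. P=0 evaluates a single pair per iteration (strict
  clustering's choice set, but hill-climbing); P=100 evaluates every pair,
  matching the greedy search.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Protocol, Sequence

import numpy as np

from .data_model import Alignment, DataBlock, PartitioningScheme, Subset, WeightVector
from .phylo_likelihood import GammaModel, GTRParams, SubsetFit, Tree, fit_subset
from .scoring import SchemeScore, score_scheme
from .subset_similarity import combined_distance, most_similar_pair

__all__ = [
    "SubsetEvaluator",
    "AlignmentEvaluator",
    "StubEvaluator",
    "SearchState",
    "SearchResult",
    "enumerate_schemes",
    "exhaustive_search",
    "greedy_search",
    "strict_cluster_search",
    "top_pairs",
    "relaxed_cluster_search",
    "save_fit_cache",
    "load_fit_cache",
]

ENUMERATION_GUARD = 12


class SubsetEvaluator(Protocol):
    def fit(self, subset: Subset) -> SubsetFit: ...


@dataclass
class AlignmentEvaluator:
    """Fits subsets by maximum likelihood on the fixed tree."""

    alignment: Alignment
    tree: Tree

    def fit(self, subset: Subset) -> SubsetFit:
        return fit_subset(self.alignment, subset, self.tree)


@dataclass
class StubEvaluator:
    """Deterministic synthetic fits for algorithm accounting and tests.

    Parameters are derived from a CRC of the subset's site set (mixed with
    ``salt``), so repeated calls agree bit-for-bit without any likelihood
    computation.
    """

    fit_fn: Callable[[Subset], SubsetFit] | None = None
    salt: int = 0

    def fit(self, subset: Subset) -> SubsetFit:
        if self.fit_fn is not None:
            return self.fit_fn(subset)
        seed = (zlib.crc32(repr(subset.sites).encode()) ^ self.salt) & 0x7FFFFFFF
        rng = np.random.default_rng(seed)
        freqs = rng.dirichlet(np.ones(4) * 10)
        rates = tuple(float(x) for x in rng.uniform(0.5, 2.0, size=5)) + (1.0,)
        return SubsetFit(
            subset=subset,
            lnL=-float(subset.n_sites) * rng.uniform(1.0, 2.0),
            rate_multiplier=float(rng.uniform(0.2, 5.0)),
            gtr=GTRParams(rates=rates, freqs=tuple(float(f) for f in freqs)),
            gamma=GammaModel(alpha=float(rng.uniform(0.2, 5.0))),
            subset_rate=float(rng.uniform(0.2, 5.0)),
            n_sites=subset.n_sites,
        )


@dataclass
class SearchState:
    """Shared run state: evaluator, fit cache, and the evaluation ledger.

    The cache maps a subset's site tuple to its fit and is never evicted;
    ``subsets_fitted`` counts cache misses (distinct subsets actually
    evaluated), ``schemes_scored`` counts scheme scorings.
    """

    evaluator: SubsetEvaluator
    criterion: str
    n_sites: int
    n_taxa: int
    cache: dict[tuple[int, ...], SubsetFit] = field(default_factory=dict)
    subsets_fitted: int = 0
    schemes_scored: int = 0

    def fit(self, subset: Subset) -> SubsetFit:
        hit = self.cache.get(subset.sites)
        if hit is not None:
            return hit
        fit = self.evaluator.fit(subset)
        self.cache[subset.sites] = fit
        self.subsets_fitted += 1
        return fit

    def score(self, scheme: PartitioningScheme) -> SchemeScore:
        for sub in scheme.subsets:
            self.fit(sub)
        self.schemes_scored += 1
        return score_scheme(
            scheme, self.cache, self.criterion, self.n_sites, self.n_taxa
        )


@dataclass(frozen=True)
class SearchResult:
    best_scheme: PartitioningScheme
    best_score: SchemeScore
    trajectory: tuple[tuple[int, float], ...]  # (n_subsets, score) accepted/recorded
    subsets_fitted: int
    schemes_scored: int
    log: tuple[dict, ...]  # one record per scheme scored


def _log_entry(iteration: int, score: SchemeScore) -> dict:
    return {
        "iteration": iteration,
        "n_subsets": len(score.scheme),
        "lnL": score.lnL,
        "k": score.k,
        "score": score.score,
    }


# ---------------------------------------------------------------------------
# exhaustive enumeration


def enumerate_schemes(blocks: Sequence[DataBlock]) -> Iterator[PartitioningScheme]:
    """Yield every set partition of the blocks exactly once (restricted
    growth strings); there are Bell(N) of them. Guarded at N <= 12."""
    n = len(blocks)
    if n < 1:
        raise ValueError("need at least one data block")
    if n > ENUMERATION_GUARD:
        raise ValueError(
            f"refusing to enumerate set partitions of {n} blocks "
            f"(guard: {ENUMERATION_GUARD}); use a heuristic search"
        )
    blocks = list(blocks)
    a = [0] * n  # restricted growth string
    while True:
        groups: dict[int, list[DataBlock]] = {}
        for idx, g in enumerate(a):
            groups.setdefault(g, []).append(blocks[idx])
        yield PartitioningScheme(
            frozenset(Subset.from_blocks(g) for g in groups.values())
        )
        # next restricted growth string
        for i in range(n - 1, 0, -1):
            if a[i] <= max(a[:i]):
                a[i] += 1
                for j in range(i + 1, n):
                    a[j] = 0
                break
        else:
            return


def exhaustive_search(
    state: SearchState, blocks: Sequence[DataBlock]
) -> SearchResult:
    """Score every possible scheme and return the global optimum."""
    best: SchemeScore | None = None
    trajectory: list[tuple[int, float]] = []
    log: list[dict] = []
    for i, scheme in enumerate(enumerate_schemes(blocks)):
        score = state.score(scheme)
        trajectory.append((len(scheme), score.score))
        log.append(_log_entry(i, score))
        if best is None or score.score < best.score:
            best = score
    assert best is not None
    return SearchResult(
        best_scheme=best.scheme,
        best_score=best,
        trajectory=tuple(trajectory),
        subsets_fitted=state.subsets_fitted,
        schemes_scored=state.schemes_scored,
        log=tuple(log),
    )


# ---------------------------------------------------------------------------
# hill-climbing merge searches


def _candidate_pairs_all(subsets: list[Subset]) -> list[tuple[int, int]]:
    n = len(subsets)
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _hill_climb(
    state: SearchState,
    blocks: Sequence[DataBlock],
    pair_chooser: Callable[[SearchState, list[Subset]], list[tuple[int, int]]],
) -> SearchResult:
    """Common scaffold for greedy and relaxed clustering: per iteration,
    score the chosen candidate merges and apply the best one if it
    strictly improves the current score."""
    scheme = PartitioningScheme.singletons(blocks)
    current = state.score(scheme)
    trajectory = [(len(scheme), current.score)]
    log = [_log_entry(0, current)]
    iteration = 0
    while len(scheme) > 1:
        iteration += 1
        subsets = scheme.sorted_subsets()
        pairs = pair_chooser(state, subsets)
        best_candidate: SchemeScore | None = None
        for i, j in pairs:
            candidate = scheme.merge(subsets[i], subsets[j])
            score = state.score(candidate)
            log.append(_log_entry(iteration, score))
            if best_candidate is None or score.score < best_candidate.score:
                best_candidate = score
        assert best_candidate is not None
        if best_candidate.score < current.score:
            current = best_candidate
            scheme = current.scheme
            trajectory.append((len(scheme), current.score))
        else:
            break
    return SearchResult(
        best_scheme=current.scheme,
        best_score=current,
        trajectory=tuple(trajectory),
        subsets_fitted=state.subsets_fitted,
        schemes_scored=state.schemes_scored,
        log=tuple(log),
    )


def greedy_search(state: SearchState, blocks: Sequence[DataBlock]) -> SearchResult:
    """Best-improving merge per iteration over *all* subset pairs; stops
    when no merge strictly improves the score."""
    return _hill_climb(state, blocks, lambda _s, subs: _candidate_pairs_all(subs))


def top_pairs(d: np.ndarray, percent: float) -> list[tuple[int, int]]:
    """The top P% most similar subset pairs, most similar first.

    Pairs are ranked by ascending distance (ties by lexicographic pair
    order); S = max(1, ceil(P/100 * number of pairs)), so P=0 yields the
    single most similar pair and P=100 yields every pair.
    """
    if not (0.0 <= percent <= 100.0):
        raise ValueError("percent must lie in [0, 100]")
    n = d.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort(key=lambda p: (d[p[0], p[1]], p[0], p[1]))
    s = max(1, math.ceil(percent / 100.0 * len(pairs)))
    return pairs[:s]


def relaxed_cluster_search(
    state: SearchState,
    blocks: Sequence[DataBlock],
    weights: WeightVector,
    percent: float = 10.0,
) -> SearchResult:
    """Hill-climbing over the top P% most similar merges per iteration.

    Distances are recomputed from freshly fitted parameters (and
    re-normalized) on the current subsets at every iteration.
    """

    def chooser(st: SearchState, subsets: list[Subset]) -> list[tuple[int, int]]:
        fits = [st.fit(sub) for sub in subsets]
        d = combined_distance(fits, weights)
        return top_pairs(d, percent)

    return _hill_climb(state, blocks, chooser)


# ---------------------------------------------------------------------------
# strict clustering


def strict_cluster_search(
    state: SearchState,
    blocks: Sequence[DataBlock],
    weights: WeightVector,
) -> SearchResult:
    """Agglomerate the most similar pair N-1 times, then pick the best of
    the N recorded schemes.

    The merge choice never consults the score, so the trajectory can
    worsen; exactly 2N-1 distinct subsets are fitted (N singletons plus
    N-1 merged subsets) and exactly N schemes are scored.
    """
    scheme = PartitioningScheme.singletons(blocks)
    recorded = [state.score(scheme)]
    trajectory = [(len(scheme), recorded[0].score)]
    log = [_log_entry(0, recorded[0])]
    iteration = 0
    while len(scheme) > 1:
        iteration += 1
        subsets = scheme.sorted_subsets()
        fits = [state.fit(sub) for sub in subsets]
        i, j = most_similar_pair(combined_distance(fits, weights))
        scheme = scheme.merge(subsets[i], subsets[j])
        score = state.score(scheme)
        recorded.append(score)
        trajectory.append((len(scheme), score.score))
        log.append(_log_entry(iteration, score))
    best = min(recorded, key=lambda s: s.score)  # ties: earliest recorded
    return SearchResult(
        best_scheme=best.scheme,
        best_score=best,
        trajectory=tuple(trajectory),
        subsets_fitted=state.subsets_fitted,
        schemes_scored=state.schemes_scored,
        log=tuple(log),
    )


# ---------------------------------------------------------------------------
# fit-cache persistence (re-runs skip completed subsets)


def save_fit_cache(path: str | Path, cache: dict[tuple[int, ...], SubsetFit]) -> None:
    records = []
    for sites, fit in cache.items():
        records.append(
            {
                "sites": list(sites),
                "blocks": sorted(fit.subset.blocks),
                "lnL": fit.lnL,
                "rate_multiplier": fit.rate_multiplier,
                "rates": list(fit.gtr.rates),
                "freqs": list(fit.gtr.freqs),
                "alpha": fit.gamma.alpha,
                "k_categories": fit.gamma.k,
                "subset_rate": fit.subset_rate,
                "n_sites": fit.n_sites,
                "degenerate": fit.degenerate,
            }
        )
    Path(path).write_text(json.dumps(records, indent=1))


def load_fit_cache(path: str | Path) -> dict[tuple[int, ...], SubsetFit]:
    cache: dict[tuple[int, ...], SubsetFit] = {}
    for rec in json.loads(Path(path).read_text()):
        sites = tuple(rec["sites"])
        fit = SubsetFit(
            subset=Subset(blocks=frozenset(rec["blocks"]), sites=sites),
            lnL=rec["lnL"],
            rate_multiplier=rec["rate_multiplier"],
            gtr=GTRParams(rates=tuple(rec["rates"]), freqs=tuple(rec["freqs"])),
            gamma=GammaModel(alpha=rec["alpha"], k=rec["k_categories"]),
            subset_rate=rec["subset_rate"],
            n_sites=rec["n_sites"],
            degenerate=rec.get("degenerate", False),
        )
        cache[sites] = fit
    return cache
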