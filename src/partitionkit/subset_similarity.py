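"""Weighted four-category distance between fitted subsets.

Subset similarity is measured on the fitted model parameters, grouped into
four categories: the overall subset rate (rate multiplier times shared
tree length), the four base frequencies, the six GTR exchangeabilities
(with GT fixed at 1 in every fit, so the vectors are comparable), and the
gamma shape alpha. For each category a Euclidean distance matrix is
computed across the current subsets, normalized so its maximum entry is 1,
scaled by a user weight, and the four matrices are summed — a weighted
Manhattan (city-block) distance over normalized category distances.

Normalization is per category and per clustering iteration: it is always
relative to the *current* set of subsets, so the matrices must be rebuilt
from freshly fitted parameters after every merge, never averaged from the
merged children.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_model import WeightVector
from .phylo_likelihood import SubsetFit

__all__ = [
    "CATEGORIES",
    "category_distance_matrix",
    "normalize_matrix",
    "combined_distance",
    "most_similar_pair",
]

CATEGORIES = ("rate", "freqs", "gtr", "alpha")


def _category_vectors(fits: Sequence[SubsetFit], category: str) -> np.ndarray:
    if category == "rate":
        return np.array([[f.subset_rate] for f in fits])
    if category == "freqs":
        return np.array([f.gtr.freqs for f in fits])
    if category == "gtr":
        return np.array([f.gtr.rates for f in fits])
    if category == "alpha":
        return np.array([[f.gamma.alpha] for f in fits])
    raise ValueError(f"unknown parameter category {category!r}")


def category_distance_matrix(
    fits: Sequence[SubsetFit], category: str
) -> np.ndarray:
    """Pairwise Euclidean distances between the subsets' parameter vectors
    for one category. Symmetric with zero diagonal."""
    if len(fits) < 2:
        raise ValueError("need at least two fitted subsets")
    vecs = _category_vectors(fits, category)
    return squareform(pdist(vecs, metric="euclidean"))


def normalize_matrix(d: np.ndarray) -> np.ndarray:
    """Scale a distance matrix so its maximum entry is 1; an all-zero
    matrix (identically fitted subsets) is returned unchanged."""
    mx = d.max()
    if mx <= 0.0:
        return d.copy()
    return d / mx


def combined_distance(
    fits: Sequence[SubsetFit], weights: WeightVector
) -> np.ndarray:
    """Weighted sum of the per-category normalized distance matrices.

    Categories with zero weight contribute nothing and are skipped, so the
    result is independent of their parameter values.
    """
    n = len(fits)
    if n < 2:
        raise ValueError("need at least two fitted subsets")
    out = np.zeros((n, n))
    for w, category in zip(weights.as_tuple(), CATEGORIES):
        if w == 0.0:
            continue
        out += w * normalize_matrix(category_distance_matrix(fits, category))
    return out


def most_similar_pair(d: np.ndarray) -> tuple[int, int]:
    """Index pair (i, j), i < j, with the smallest off-diagonal distance;
    ties break to the lexicographically smallest pair."""
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two subsets")
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    best = int(np.argmin(vals))  # argmin returns the first minimum:
    # triu_indices orders pairs lexicographically, giving the tie rule
    return int(iu[0][best]), int(iu[1][best])
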