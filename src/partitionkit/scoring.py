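"""Information-criterion scoring of subsets and partitioning schemes.

Because subsets own disjoint sites and share the fixed tree, the
log-likelihood of a whole scheme is simply the sum of its subsets'
log-likelihoods — scoring a scheme from cached subset fits involves no new
likelihood evaluations.

Parameter counting (DNA, GTR+G, linked branch lengths): each subset
contributes 5 free exchangeabilities + 3 free base frequencies + 1 gamma
shape = 9 parameters; a scheme with S subsets adds S-1 free rate
multipliers (one multiplier is absorbed by the shared branch-length
scale); and the 2T-3 linked branch lengths are counted once. The branch
lengths are constant across schemes, so they shift absolute scores but
never change rankings.

``n`` is the total number of alignment sites, the sample size of the
whole-alignment model comparison. Lower scores indicate better fit. AICc
should be preferred to AIC whenever the two disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .data_model import PartitioningScheme, Subset
from .phylo_likelihood import SubsetFit

__all__ = [
    "SchemeScore",
    "OverParameterizedError",
    "count_parameters",
    "criterion_score",
    "score_scheme",
]

PARAMS_PER_SUBSET = 9  # 5 exchangeabilities + 3 frequencies + 1 alpha


class OverParameterizedError(ValueError):
    """AICc is undefined when n - k - 1 <= 0."""


@dataclass(frozen=True)
class SchemeScore:
    scheme: PartitioningScheme
    lnL: float
    k: int
    n: int
    criterion: str
    score: float


def count_parameters(scheme: PartitioningScheme | int, n_taxa: int) -> int:
    """Free-parameter count of a partitioning scheme with linked branch
    lengths: ``9*S + (S - 1) + (2T - 3)`` for S subsets and T taxa."""
    s = len(scheme) if isinstance(scheme, PartitioningScheme) else int(scheme)
    if s < 1:
        raise ValueError("a scheme needs at least one subset")
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    return PARAMS_PER_SUBSET * s + (s - 1) + (2 * n_taxa - 3)


def criterion_score(lnL: float, k: int, n: int, criterion: str) -> float:
    """AIC, AICc or BIC from a log-likelihood; lower is better."""
    if n < 1:
        raise ValueError("sample size must be positive")
    if k < 0:
        raise ValueError("parameter count must be non-negative")
    aic = 2.0 * k - 2.0 * lnL
    if criterion == "AIC":
        return aic
    if criterion == "AICc":
        if n - k - 1 <= 0:
            raise OverParameterizedError(
                f"AICc undefined: k={k} parameters with n={n} sites "
                f"(need n - k - 1 > 0)"
            )
        return aic + 2.0 * k * (k + 1) / (n - k - 1)
    if criterion == "BIC":
        return k * math.log(n) - 2.0 * lnL
    raise ValueError(f"unknown criterion {criterion!r}")


def score_scheme(
    scheme: PartitioningScheme,
    fits: Mapping[tuple[int, ...], SubsetFit],
    criterion: str,
    n_sites: int,
    n_taxa: int,
) -> SchemeScore:
    """Score a scheme from cached subset fits (keyed by subset site tuple).

    Pure and evaluation-free: every subset must already be fitted.
    """
    total = 0.0
    for sub in scheme.subsets:
        fit = fits.get(sub.sites)
        if fit is None:
            raise KeyError(
                f"no cached fit for subset with blocks {sorted(sub.blocks)}"
            )
        total += fit.lnL
    k = count_parameters(scheme, n_taxa)
    return SchemeScore(
        scheme=scheme,
        lnL=total,
        k=k,
        n=n_sites,
        criterion=criterion,
        score=criterion_score(total, k, n_sites, criterion),
    )
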