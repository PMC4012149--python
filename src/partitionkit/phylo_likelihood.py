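"""Fixed-topology GTR+Gamma likelihood engine.

All partitioning-scheme searches in this package share one tree: the
topology is estimated once (neighbor joining on Jukes-Cantor distances, or
a user-supplied Newick tree) and never revisited, and one set of *linked*
relative branch lengths is estimated on the whole alignment under GTR+G
and then held fixed. Each subset of sites is fitted with its own GTR
exchangeabilities, empirical base frequencies, gamma shape, and a scalar
rate multiplier that rescales the shared branch lengths.

Likelihoods are computed with Felsenstein's pruning algorithm over
compressed site patterns, with per-pattern rescaling to avoid underflow,
and a discrete-gamma rate mixture (equal-probability categories, each
represented by its conditional mean rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, gammaincinv

from .data_model import Alignment, Subset

__all__ = [
    "Tree",
    "GTRParams",
    "GammaModel",
    "SubsetFit",
    "build_starting_tree",
    "jc_distance_matrix",
    "gtr_rate_matrix",
    "discrete_gamma_rates",
    "transition_probabilities",
    "subset_log_likelihood",
    "estimate_linked_branch_lengths",
    "fit_subset",
]

BASES = "ACGT"
# exchangeability order follows the upper triangle: AC, AG, AT, CG, CT, GT
RATE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

MIN_BRANCH = 1e-8
MAX_BRANCH = 50.0
ALPHA_BOUNDS = (0.01, 100.0)
RATE_MULT_BOUNDS = (1e-6, 200.0)
EXCH_BOUNDS = (1e-4, 1e4)
MAX_JC_DISTANCE = 5.0

# IUPAC ambiguity codes -> indicator over {A, C, G, T}; gaps fully ambiguous
_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT",
}
_CODE_CHARS = sorted(_AMBIG)
_CHAR_TO_CODE = {c: i for i, c in enumerate(_CODE_CHARS)}
_CODE_VECTORS = np.zeros((len(_CODE_CHARS), 4))
for _c, _i in _CHAR_TO_CODE.items():
    for _b in _AMBIG[_c]:
        _CODE_VECTORS[_i, BASES.index(_b)] = 1.0


class LikelihoodError(RuntimeError):
    """Numerical failure inside the likelihood engine."""


# ---------------------------------------------------------------------------
# trees


@dataclass(frozen=True)
class Tree:
    """An unrooted tree stored rooted-for-traversal at an internal node.

    Nodes are integers; leaves ``0 .. n_taxa-1`` follow ``taxon_names``
    order. ``parent[i]`` and ``lengths[i]`` describe the edge above node
    ``i`` (undefined for the root). ``postorder`` lists internal nodes in
    child-before-parent order.
    """

    taxon_names: tuple[str, ...]
    parent: tuple[int, ...]
    lengths: tuple[float, ...]
    root: int

    def __post_init__(self) -> None:
        if any(l < 0 for i, l in enumerate(self.lengths) if i != self.root):
            raise ValueError("branch lengths must be non-negative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def branch_nodes(self) -> list[int]:
        """Nodes that carry an edge (everything except the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if i != self.root:
                kids[p].append(i)
        return kids

    def postorder_internal(self) -> list[int]:
        kids = self.children()
        order: list[int] = []
        stack = [self.root]
        seen = []
        while stack:
            node = stack.pop()
            seen.append(node)
            stack.extend(kids[node])
        for node in reversed(seen):
            if kids[node]:
                order.append(node)
        return order

    def total_length(self) -> float:
        return float(sum(self.lengths[i] for i in self.branch_nodes))

    def with_lengths(self, lengths: Sequence[float]) -> "Tree":
        if len(lengths) != self.n_nodes:
            raise ValueError("need one length per node (root entry ignored)")
        return replace(self, lengths=tuple(float(x) for x in lengths))

    # -- conversions --------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, taxon_names: Sequence[str]) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        dtree.deroot()
        return cls.from_dendropy(dtree, taxon_names)

    @classmethod
    def from_dendropy(
        cls, dtree: "dendropy.Tree", taxon_names: Sequence[str]
    ) -> "Tree":
        taxon_names = tuple(taxon_names)
        leaf_index = {name: i for i, name in enumerate(taxon_names)}
        leaves = [lf for lf in dtree.leaf_node_iter()]
        labels = {lf.taxon.label for lf in leaves}
        if labels != set(taxon_names):
            missing = sorted(set(taxon_names) - labels)
            extra = sorted(labels - set(taxon_names))
            raise ValueError(
                f"tree/alignment taxa mismatch (missing={missing}, extra={extra})"
            )
        n_internal = sum(1 for n in dtree.preorder_node_iter() if not n.is_leaf())
        n_nodes = len(taxon_names) + n_internal
        parent = [0] * n_nodes
        lengths = [0.0] * n_nodes
        ids: dict[object, int] = {}
        next_internal = len(taxon_names)
        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                idx = leaf_index[node.taxon.label]
            else:
                idx = next_internal
                next_internal += 1
            ids[node] = idx
            if node.parent_node is None:
                root = idx
            else:
                parent[idx] = ids[node.parent_node]
                lengths[idx] = max(0.0, float(node.edge.length or 0.0))
        return cls(
            taxon_names=taxon_names,
            parent=tuple(parent),
            lengths=tuple(lengths),
            root=root,
        )

    def to_newick(self) -> str:
        kids = self.children()

        def render(node: int) -> str:
            if not kids[node]:
                label = self.taxon_names[node]
            else:
                label = "(" + ",".join(render(c) for c in kids[node]) + ")"
            if node == self.root:
                return label + ";"
            return f"{label}:{self.lengths[node]:.10g}"

        return render(self.root)


def jc_distance_matrix(alignment: Alignment) -> np.ndarray:
    """Pairwise Jukes-Cantor-corrected distances.

    Only sites where both taxa carry an unambiguous base are compared;
    saturated pairs (p-distance >= 3/4) are capped at ``MAX_JC_DISTANCE``
    with a warning.
    """
    n = alignment.n_taxa
    codes = np.zeros(alignment.matrix.shape, dtype=np.int8)
    plain = {b: i for i, b in enumerate(BASES)}
    flat = np.vectorize(lambda c: plain.get(c, -1), otypes=[np.int8])
    codes = flat(alignment.matrix)
    dist = np.zeros((n, n))
    capped = False
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                d = MAX_JC_DISTANCE
                capped = True
            else:
                p = float((codes[i][ok] != codes[j][ok]).sum()) / m
                if p >= 0.75:
                    d = MAX_JC_DISTANCE
                    capped = True
                else:
                    d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = d
    if capped:
        warnings.warn(
            f"saturated pairwise distances capped at {MAX_JC_DISTANCE}",
            RuntimeWarning,
            stacklevel=2,
        )
    return dist


def build_starting_tree(
    alignment: Alignment, user_newick: str | None = None
) -> Tree:
    """Deterministic starting topology: user tree if given, otherwise
    neighbor joining on Jukes-Cantor distances.

    Model selection is robust to the exact (non-random) topology used, so
    the topology is estimated once and fixed for the whole analysis.
    """
    if user_newick is not None:
        return Tree.from_newick(user_newick, alignment.taxon_names)
    if alignment.n_taxa < 3:
        raise ValueError("need at least 3 taxa to build an unrooted tree")
    if alignment.n_taxa == 3:
        d = jc_distance_matrix(alignment)
        a, b, c = alignment.taxon_names
        la = max(0.0, (d[0, 1] + d[0, 2] - d[1, 2]) / 2)
        lb = max(0.0, (d[0, 1] + d[1, 2] - d[0, 2]) / 2)
        lc = max(0.0, (d[0, 2] + d[1, 2] - d[0, 1]) / 2)
        newick = f"({a}:{la:.10g},{b}:{lb:.10g},{c}:{lc:.10g});"
        return Tree.from_newick(newick, alignment.taxon_names)
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    d = jc_distance_matrix(alignment)
    sk = nj(SkbioDM(d, ids=list(alignment.taxon_names)))
    newick = str(sk).strip()
    tree = Tree.from_newick(newick, alignment.taxon_names)
    # NJ can emit small negative estimates; clamp to zero
    lengths = [max(0.0, l) for l in tree.lengths]
    return tree.with_lengths(lengths)


# ---------------------------------------------------------------------------
# substitution model


@dataclass(frozen=True)
class GTRParams:
    """GTR exchangeabilities (AC, AG, AT, CG, CT, GT; GT fixed to 1) and
    stationary base frequencies (A, C, G, T)."""

    rates: tuple[float, float, float, float, float, float] = (1.0,) * 6
    freqs: tuple[float, float, float, float] = (0.25,) * 4

    def __post_init__(self) -> None:
        if len(self.rates) != 6 or len(self.freqs) != 4:
            raise ValueError("GTR needs 6 exchangeabilities and 4 frequencies")
        if any(r <= 0 for r in self.rates):
            raise ValueError("exchangeabilities must be positive")
        if any(f <= 0 for f in self.freqs):
            raise ValueError("frequencies must be positive")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


@dataclass(frozen=True)
class GammaModel:
    """Discrete-gamma among-site rate variation (shape ``alpha``, ``k``
    equal-probability categories)."""

    alpha: float
    k: int = 4

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.k < 1:
            raise ValueError("need at least one rate category")


@dataclass(frozen=True)
class SubsetFit:
    """Maximum-likelihood fit of one subset on the fixed tree."""

    subset: Subset
    lnL: float
    rate_multiplier: float
    gtr: GTRParams
    gamma: GammaModel
    subset_rate: float  # rate_multiplier x sum of shared branch lengths
    n_sites: int
    degenerate: bool = False


def gtr_rate_matrix(gtr: GTRParams) -> np.ndarray:
    """Instantaneous GTR rate matrix Q with mean substitution rate 1.

    Q_ij = s_ij * pi_j for i != j; rows sum to zero; scaled so
    sum_i pi_i * (-Q_ii) = 1. Satisfies detailed balance.
    """
    pi = np.asarray(gtr.freqs)
    s = np.zeros((4, 4))
    for rate, (i, j) in zip(gtr.rates, RATE_PAIRS):
        s[i, j] = s[j, i] = rate
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -float(np.dot(pi, np.diag(q)))
    return q / mean_rate


def discrete_gamma_rates(gamma: GammaModel) -> np.ndarray:
    """Category rates for the discrete-gamma mixture.

    Equal-probability quantile bins of Gamma(alpha, mean 1); each category
    rate is the conditional mean of the density within its bin, then the
    vector is renormalized so the mean is exactly 1.
    """
    a, k = gamma.alpha, gamma.k
    if k == 1:
        return np.ones(1)
    probs = np.arange(1, k) / k
    # bin boundaries on the Gamma(a, scale=1/a) scale
    bounds = gammaincinv(a, probs) / a
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X | bin] * P(bin) = [regularized incomplete gamma of shape a+1] / a * a
    cdf_hi = np.where(np.isinf(upper), 1.0, gammainc(a + 1, upper * a))
    cdf_lo = gammainc(a + 1, lower * a)
    rates = k * (cdf_hi - cdf_lo)
    return rates / rates.mean()


def _eigen(q: np.ndarray, freqs: Sequence[float]):
    """Symmetric eigendecomposition of a reversible Q."""
    pi = np.asarray(freqs)
    d = np.sqrt(pi)
    b = (q * d[:, None]) / d[None, :]
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    u = evecs / d[:, None]  # right eigenvectors of Q
    uinv = evecs.T * d[None, :]
    return evals, u, uinv


def transition_probabilities(
    q: np.ndarray,
    t: float,
    rate: float = 1.0,
    freqs: Sequence[float] | None = None,
) -> np.ndarray:
    """P(t) = exp(Q * t * rate) via symmetric eigendecomposition.

    ``freqs`` are the stationary frequencies of Q; when omitted they are
    recovered from Q's left null space.
    """
    if t < 0 or rate < 0:
        raise ValueError("branch length and rate must be non-negative")
    if freqs is None:
        evals, evecs = np.linalg.eig(q.T)
        idx = int(np.argmin(np.abs(evals)))
        pi = np.real(evecs[:, idx])
        pi = pi / pi.sum()
    else:
        pi = np.asarray(freqs)
    evals, u, uinv = _eigen(q, pi)
    p = (u * np.exp(evals * t * rate)[None, :]) @ uinv
    if not np.all(np.isfinite(p)):
        raise LikelihoodError(
            f"non-finite transition probabilities (t={t}, rate={rate}, Q={q!r})"
        )
    if p.min() < -1e-12:
        raise LikelihoodError(f"negative transition probability {p.min()}")
    return np.clip(p, 0.0, None)


# ---------------------------------------------------------------------------
# pruning


def _encode_patterns(alignment: Alignment, sites: Sequence[int]):
    """Compress subset columns into unique site patterns.

    Returns (leaf likelihood tensor of shape (n_taxa, n_patterns, 4),
    pattern weights).
    """
    cols = alignment.matrix[:, list(sites)]
    codes = np.array(
        [[_CHAR_TO_CODE[c] for c in row] for row in cols], dtype=np.int16
    )
    patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
    leaf = _CODE_VECTORS[patterns.T]  # (n_taxa, n_patterns, 4)
    return leaf, counts.astype(float)


def _pruning_lnl(
    tree: Tree,
    leaf: np.ndarray,
    weights: np.ndarray,
    gtr: GTRParams,
    gamma: GammaModel,
    branch_scale: float,
) -> float:
    """Scaled Felsenstein pruning with an equal-weight gamma mixture."""
    q = gtr_rate_matrix(gtr)
    evals, u, uinv = _eigen(q, gtr.freqs)
    rates = discrete_gamma_rates(gamma)
    pi = np.asarray(gtr.freqs)
    n_patterns = leaf.shape[1]
    kids = tree.children()
    post = tree.postorder_internal()
    lengths = np.asarray(tree.lengths)

    k = len(rates)
    # transition matrices for every (category, edge) pair at once
    t_eff = lengths[None, :] * branch_scale * rates[:, None]  # (k, nodes)
    p_all = np.einsum(
        "ij,cej,jl->ceil", u, np.exp(t_eff[..., None] * evals[None, None, :]), uinv
    )
    np.clip(p_all, 0.0, None, out=p_all)
    partial = np.empty((tree.n_nodes, k, n_patterns, 4))
    partial[: tree.n_taxa] = leaf[:, None, :, :]
    logscale = np.zeros((k, n_patterns))
    for node in post:
        acc = np.ones((k, n_patterns, 4))
        for child in kids[node]:
            acc *= np.matmul(partial[child], p_all[:, child].transpose(0, 2, 1))
        mx = acc.max(axis=2)
        zero = mx <= 0.0
        safe = np.where(zero, 1.0, mx)
        partial[node] = acc / safe[:, :, None]
        logscale += np.where(zero, -np.inf, np.log(safe))
    lik = partial[tree.root] @ pi  # (k, n_patterns)
    with np.errstate(divide="ignore"):
        site_logl = np.log(lik) + logscale
    # average the mixture in log space
    mx = site_logl.max(axis=0)
    ok = np.isfinite(mx)
    out = np.full(n_patterns, -np.inf)
    out[ok] = mx[ok] + np.log(
        np.mean(np.exp(site_logl[:, ok] - mx[ok][None, :]), axis=0)
    )
    if np.any(~np.isfinite(out)):
        warnings.warn(
            "zero site likelihood: data impossible under the model",
            RuntimeWarning,
            stacklevel=2,
        )
        return -np.inf
    return float(np.dot(weights, out))


def subset_log_likelihood(
    alignment: Alignment,
    subset: Subset,
    tree: Tree,
    rate_multiplier: float,
    gtr: GTRParams,
    gamma: GammaModel,
) -> float:
    """Log-likelihood of a subset's sites on the fixed tree, with branch
    lengths scaled by ``rate_multiplier``."""
    leaf, weights = _encode_patterns(alignment, subset.sites)
    return _pruning_lnl(tree, leaf, weights, gtr, gamma, rate_multiplier)


# ---------------------------------------------------------------------------
# fitting


def _observed_freqs(alignment: Alignment, sites: Sequence[int]) -> np.ndarray:
    """Base proportions over the given sites, one pseudocount per base."""
    cols = alignment.matrix[:, list(sites)]
    counts = np.array([np.sum(cols == b) for b in BASES], dtype=float) + 1.0
    return counts / counts.sum()


def _opt_scalar(fun, lo, hi, x0, log_scale=True, xatol=1e-3):
    """Maximize ``fun`` over [lo, hi] with a bounded scalar search,
    optionally on a log10 scale. Returns (x, f(x)); never worse than x0."""
    f0 = fun(x0)
    if log_scale:
        res = minimize_scalar(
            lambda y: -fun(10.0 ** y),
            bounds=(np.log10(lo), np.log10(hi)),
            method="bounded",
            options={"xatol": xatol},
        )
        x, f = 10.0 ** res.x, -res.fun
    else:
        res = minimize_scalar(
            lambda y: -fun(y), bounds=(lo, hi), method="bounded",
            options={"xatol": xatol},
        )
        x, f = float(res.x), -res.fun
    if f >= f0:
        return x, f
    return x0, f0


def _fit_params_on_patterns(
    tree: Tree,
    leaf: np.ndarray,
    weights: np.ndarray,
    freqs: np.ndarray,
    *,
    fit_rate: bool,
    rate0: float = 1.0,
    tol: float = 1e-3,
    max_cycles: int = 12,
):
    """Coordinate-wise GTR+G fit: cycle over {rate multiplier, alpha,
    exchangeabilities} until the lnL gain per full cycle drops below tol."""
    rates = [1.0] * 6
    alpha = 1.0
    rate_mult = rate0

    def lnl(rates_, alpha_, mult_):
        gtr = GTRParams(rates=tuple(rates_), freqs=tuple(freqs))
        return _pruning_lnl(tree, leaf, weights, gtr, GammaModel(alpha_), mult_)

    best = lnl(rates, alpha, rate_mult)
    for _ in range(max_cycles):
        start = best
        if fit_rate:
            rate_mult, best = _opt_scalar(
                lambda m: lnl(rates, alpha, m),
                *RATE_MULT_BOUNDS,
                rate_mult,
            )
        alpha, best = _opt_scalar(
            lambda a: lnl(rates, a, rate_mult), *ALPHA_BOUNDS, alpha
        )
        for idx in range(5):  # GT (index 5) stays fixed at 1
            def f(r, idx=idx):
                trial = list(rates)
                trial[idx] = r
                return lnl(trial, alpha, rate_mult)

            rates[idx], best = _opt_scalar(f, *EXCH_BOUNDS, rates[idx])
        if best - start < tol:
            break
    gtr = GTRParams(rates=tuple(rates), freqs=tuple(freqs))
    return gtr, GammaModel(alpha), rate_mult, best


def estimate_linked_branch_lengths(
    alignment: Alignment,
    tree: Tree,
    *,
    tol: float = 1e-3,
    max_passes: int = 20,
    outer_rounds: int = 2,
) -> Tree:
    """Optimize the shared branch lengths on the whole alignment under
    GTR+G (empirical frequencies).

    Branch lengths are refined one at a time (bounded scalar search,
    round-robin passes until the lnL gain per pass falls below ``tol``),
    alternating with re-optimization of the global model parameters.
    These *relative* lengths are then fixed; each subset only rescales
    them with its own rate multiplier.
    """
    all_sites = range(alignment.n_sites)
    leaf, weights = _encode_patterns(alignment, list(all_sites))
    freqs = _observed_freqs(alignment, list(all_sites))
    lengths = np.clip(np.asarray(tree.lengths, dtype=float), MIN_BRANCH, MAX_BRANCH)
    lengths[tree.root] = 0.0
    current = tree.with_lengths(lengths)

    for _ in range(outer_rounds):
        gtr, gamma, _, best = _fit_params_on_patterns(
            current, leaf, weights, freqs, fit_rate=False
        )
        converged = False
        for _pass in range(max_passes):
            start = best
            for node in current.branch_nodes:
                def f(x, node=node):
                    trial = np.asarray(current.lengths).copy()
                    trial[node] = x
                    return _pruning_lnl(
                        current.with_lengths(trial), leaf, weights, gtr, gamma, 1.0
                    )

                new_len, best = _opt_scalar(
                    f, MIN_BRANCH, MAX_BRANCH, current.lengths[node]
                )
                trial = np.asarray(current.lengths).copy()
                trial[node] = new_len
                current = current.with_lengths(trial)
            if best - start < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                "branch-length optimization hit the pass limit; "
                "returning best lengths so far",
                RuntimeWarning,
                stacklevel=2,
            )
    return current


def fit_subset(alignment: Alignment, subset: Subset, tree: Tree) -> SubsetFit:
    """Maximum-likelihood GTR+G fit of one subset on the fixed tree.

    Frequencies are the observed base proportions over the subset's sites
    (one pseudocount per base); the five free exchangeabilities, alpha and
    the rate multiplier are optimized numerically. ``subset_rate`` — the
    quantity the similarity metric uses — is the rate multiplier times the
    total shared tree length.
    """
    leaf, weights = _encode_patterns(alignment, subset.sites)
    freqs = _observed_freqs(alignment, subset.sites)
    variable = any(
        len({c for c in alignment.matrix[:, s] if c in BASES}) > 1
        for s in subset.sites
    )
    if not variable:
        gtr = GTRParams(freqs=tuple(freqs))
        gamma = GammaModel(ALPHA_BOUNDS[1])
        mult = RATE_MULT_BOUNDS[0]
        lnl = _pruning_lnl(tree, leaf, weights, gtr, gamma, mult)
        return SubsetFit(
            subset=subset,
            lnL=lnl,
            rate_multiplier=mult,
            gtr=gtr,
            gamma=gamma,
            subset_rate=mult * tree.total_length(),
            n_sites=subset.n_sites,
            degenerate=True,
        )
    gtr, gamma, mult, lnl = _fit_params_on_patterns(
        tree, leaf, weights, freqs, fit_rate=True
    )
    return SubsetFit(
        subset=subset,
        lnL=lnl,
        rate_multiplier=mult,
        gtr=gtr,
        gamma=gamma,
        subset_rate=mult * tree.total_length(),
        n_sites=subset.n_sites,
    )
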