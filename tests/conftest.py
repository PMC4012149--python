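import itertools

import numpy as np
import pytest

from partitionkit.data_model import Alignment, DataBlock, Subset
from partitionkit.phylo_likelihood import (
    BASES,
    GammaModel,
    GTRParams,
    Tree,
    discrete_gamma_rates,
    gtr_rate_matrix,
    transition_probabilities,
)
from partitionkit.synthetic_data import BlockModel, random_tree, simulate_alignment


@pytest.fixture
def tiny_alignment():
    return Alignment(
        taxon_names=("a", "b"),
        matrix=np.array([list("ACGT"), list("ACGT")], dtype="<U1"),
    )


@pytest.fixture
def small_sim():
    """5-taxon, 2-block simulated alignment with a rate contrast."""
    rng = np.random.default_rng(42)
    tree = random_tree(5, rng)
    models = [
        BlockModel("slow", 300, rate_multiplier=1.0),
        BlockModel("fast", 300, rate_multiplier=4.0),
    ]
    alignment, blocks = simulate_alignment(tree, models, rng)
    return alignment, blocks, tree


def random_gtr(rng):
    rates = tuple(float(x) for x in rng.uniform(0.3, 3.0, size=5)) + (1.0,)
    freqs = rng.dirichlet(np.ones(4) * 5)
    freqs = freqs / freqs.sum()
    return GTRParams(rates=rates, freqs=tuple(float(f) for f in freqs))


def brute_force_lnl(alignment, sites, tree, rate_multiplier, gtr, gamma):
    """Independent likelihood oracle: explicit summation over every
    combination of internal-node states, per site, per gamma category."""
    q = gtr_rate_matrix(gtr)
    rates = discrete_gamma_rates(gamma)
    pi = np.asarray(gtr.freqs)
    kids = tree.children()
    internal = [n for n in range(tree.n_nodes) if kids[n]]
    code = {b: i for i, b in enumerate(BASES)}
    total = 0.0
    for s in sites:
        site_lik = 0.0
        for r in rates:
            p_edge = {
                n: transition_probabilities(
                    q, tree.lengths[n] * rate_multiplier, rate=float(r),
                    freqs=gtr.freqs,
                )
                for n in range(tree.n_nodes)
                if n != tree.root
            }
            cat_lik = 0.0
            for states in itertools.product(range(4), repeat=len(internal)):
                assign = dict(zip(internal, states))
                for leaf_idx in range(tree.n_taxa):
                    assign[leaf_idx] = code[alignment.matrix[leaf_idx, s]]
                term = pi[assign[tree.root]]
                for n in range(tree.n_nodes):
                    if n == tree.root:
                        continue
                    term *= p_edge[n][assign[tree.parent[n]], assign[n]]
                cat_lik += term
            site_lik += cat_lik / len(rates)
        total += np.log(site_lik)
    return float(total)


def make_blocks(sizes):
    out, start = [], 0
    for i, m in enumerate(sizes):
        out.append(DataBlock(name=f"b{i + 1}", sites=tuple(range(start, start + m))))
        start += m
    return out
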