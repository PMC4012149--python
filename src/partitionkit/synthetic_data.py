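"""Simulation of alignments with known block structure.

Every block evolves on a shared tree under its own GTR+Gamma model with a
block-specific rate multiplier — the data-generating process the
partitioning machinery assumes. Fixtures produced here (alignment +
config + tree + true scheme) make every other module testable end-to-end
with a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import (
    Alignment,
    DataBlock,
    PartitioningScheme,
    Subset,
    WeightVector,
)
from .phylo_likelihood import (
    BASES,
    GammaModel,
    GTRParams,
    Tree,
    discrete_gamma_rates,
    gtr_rate_matrix,
    transition_probabilities,
)

__all__ = [
    "BlockModel",
    "RecoveryFixture",
    "random_tree",
    "simulate_alignment",
    "corner_weight_vectors",
    "make_recovery_fixture",
]

# a moderately AT-rich, transition-biased model typical of nuclear DNA
DEFAULT_GTR = GTRParams(
    rates=(1.3, 4.0, 1.1, 0.9, 4.5, 1.0),
    freqs=(0.30, 0.20, 0.20, 0.30),
)
DEFAULT_ALPHA = 1.0


@dataclass(frozen=True)
class BlockModel:
    """Generating model for one data block."""

    name: str
    n_sites: int
    rate_multiplier: float = 1.0
    gtr: GTRParams = DEFAULT_GTR
    gamma: GammaModel = GammaModel(DEFAULT_ALPHA)

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("blocks need at least one site")
        if self.rate_multiplier < 0:
            raise ValueError("rate multiplier must be non-negative")


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    length_range: tuple[float, float] = (0.05, 0.2),
) -> Tree:
    """Random unrooted binary topology grown by sequential attachment,
    with branch lengths drawn uniformly from ``length_range``."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    names = [f"t{i + 1}" for i in range(n_taxa)]

    # grow a newick structure as nested lists, attaching each new taxon to
    # a uniformly chosen existing edge
    edges: list[list] = [[names[0]], [names[1]], [names[2]]]  # root trifurcation
    tree_struct: list = edges[:]
    all_edges = edges[:]
    for name in names[3:]:
        target = all_edges[rng.integers(0, len(all_edges))]
        # replace target's content with an internal node joining old + new
        old = list(target)
        new_leaf = [name]
        inner_old = old
        target.clear()
        target.append(inner_old)
        target.append(new_leaf)
        all_edges.append(inner_old)
        all_edges.append(new_leaf)

    def render(node) -> str:
        if len(node) == 1 and isinstance(node[0], str):
            label = node[0]
        else:
            label = "(" + ",".join(render(c) for c in node) + ")"
        return f"{label}:{rng.uniform(*length_range):.6f}"

    newick = "(" + ",".join(render(e) for e in tree_struct) + ");"
    return Tree.from_newick(newick, names)


def simulate_alignment(
    tree: Tree,
    models: list[BlockModel],
    seed: int | np.random.Generator,
) -> tuple[Alignment, list[DataBlock]]:
    """Evolve each block along the tree under its model.

    Per site: a gamma category rate is drawn (uniformly over the equal-
    probability categories), the root state is drawn from the block's
    stationary frequencies, and states propagate root-to-tip with
    transition probabilities over branch length x block rate multiplier x
    site category rate. Blocks are laid out contiguously in block order.
    Fully reproducible from the seed.
    """
    if not models:
        raise ValueError("need at least one block model")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kids = tree.children()
    preorder: list[int] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        preorder.append(node)
        stack.extend(kids[node])

    columns: list[np.ndarray] = []
    blocks: list[DataBlock] = []
    offset = 0
    for model in models:
        q = gtr_rate_matrix(model.gtr)
        cat_rates = discrete_gamma_rates(model.gamma)
        m = model.n_sites
        cats = rng.integers(0, len(cat_rates), size=m)
        states = np.empty((tree.n_nodes, m), dtype=np.int64)
        states[tree.root] = rng.choice(4, size=m, p=np.asarray(model.gtr.freqs))
        # per-edge transition matrices per category, sampled root-to-tip
        for node in preorder:
            if node == tree.root:
                continue
            p_cat = [
                transition_probabilities(
                    q,
                    tree.lengths[node] * model.rate_multiplier,
                    rate=float(r),
                    freqs=model.gtr.freqs,
                )
                for r in cat_rates
            ]
            parent_states = states[tree.parent[node]]
            u = rng.random(m)
            probs = np.array([p_cat[c][s] for c, s in zip(cats, parent_states)])
            states[node] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        columns.append(states[: tree.n_taxa])
        blocks.append(
            DataBlock(name=model.name, sites=tuple(range(offset, offset + m)))
        )
        offset += m
    codes = np.concatenate(columns, axis=1)
    matrix = np.array(list(BASES))[codes]
    return Alignment(taxon_names=tree.taxon_names, matrix=matrix), blocks


def corner_weight_vectors() -> list[WeightVector]:
    """The 15 binary similarity-weight vectors: every combination of 0/1
    weights over (rate, freqs, gtr, alpha) except all-zeros.

    Ordered by binary counting with w_rate as the most significant bit:
    (0,0,0,1), (0,0,1,0), ..., (1,1,1,1).
    """
    out = []
    for m in range(1, 16):
        bits = tuple(float((m >> s) & 1) for s in (3, 2, 1, 0))
        out.append(WeightVector(*bits))
    return out


@dataclass(frozen=True)
class RecoveryFixture:
    """A simulated dataset with known true partitioning scheme."""

    alignment: Alignment
    blocks: list[DataBlock]
    tree: Tree
    models: list[BlockModel]
    true_scheme: PartitioningScheme

    def write(self, out_dir: str | Path) -> Path:
        """Write alignment (FASTA), tree (Newick) and a config file into
        ``out_dir``; returns the config path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta = out / "alignment.fasta"
        with fasta.open("w") as fh:
            for name in self.alignment.taxon_names:
                fh.write(f">{name}\n{self.alignment.sequence(name)}\n")
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        lines = [
            "alignment = alignment.fasta;",
            "branchlengths = linked;",
            "models = GTR+G;",
            "model_selection = BIC;",
            "user_tree_topology = tree.nwk;",
            "",
            "[data_blocks]",
        ]
        for b in self.blocks:
            lines.append(f"{b.name} = {b.sites[0] + 1}-{b.sites[-1] + 1};")
        lines += ["", "[schemes]", "search = rcluster;", "rcluster_percent = 10;"]
        cfg = out / "analysis.cfg"
        cfg.write_text("\n".join(lines) + "\n")
        return cfg


def make_recovery_fixture(
    n_blocks: int = 6,
    n_classes: int = 2,
    sites_per_block: int = 2000,
    rate_spread: float = 5.0,
    seed: int = 0,
    n_taxa: int = 6,
) -> RecoveryFixture:
    """Simulate ``n_blocks`` contiguous blocks assigned round-robin to
    ``n_classes`` rate classes with geometrically spaced rate multipliers
    (1, rate_spread, rate_spread^2, ...). The true scheme groups blocks by
    class."""
    if n_classes > n_blocks:
        raise ValueError("cannot have more classes than blocks")
    rng = np.random.default_rng(seed)
    tree = random_tree(n_taxa, rng)
    models = []
    class_of: list[int] = []
    for i in range(n_blocks):
        cls = i % n_classes
        class_of.append(cls)
        models.append(
            BlockModel(
                name=f"block{i + 1}",
                n_sites=sites_per_block,
                rate_multiplier=rate_spread**cls,
            )
        )
    alignment, blocks = simulate_alignment(tree, models, rng)
    groups: dict[int, list[DataBlock]] = {}
    for blk, cls in zip(blocks, class_of):
        groups.setdefault(cls, []).append(blk)
    true_scheme = PartitioningScheme(
        frozenset(Subset.from_blocks(g) for g in groups.values())
    )
    return RecoveryFixture(
        alignment=alignment,
        blocks=blocks,
        tree=tree,
        models=models,
        true_scheme=true_scheme,
    )
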