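"""Synthetic data: random topologies, ground-truth CCDs, and replicate
"posterior" samples.

These stand in for MCMC output in tests and benchmarks.  The Yule topology
sampler produces the topology law of a pure-birth (equivalently, for
topologies, coalescent) process by uniform pairwise joins; ground-truth CCDs
are built from a pool of such topologies with Dirichlet-distributed split
probabilities, so the exact truth is enumerable and every experiment is
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ccd import CCDGraph, count_trees, enumerate_trees, sample_tree
from .trees import Clade, CladeSplit, RootedTopology, TaxonSet, TreeSample

__all__ = [
    "FixtureConfig",
    "default_taxa",
    "yule_topology",
    "leaf_spr",
    "random_ccd",
    "synth_posterior",
    "enumerate_trees",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of a synthetic ground-truth distribution.

    ``concentration`` is the symmetric Dirichlet parameter for each clade's
    split probabilities (1.0 = uniform on the simplex, i.e. diffuse); a
    ``pool_size``-step topology random walk seeds the clade/split support;
    ``display_cap`` optionally rejects truths displaying more trees than the
    enumeration oracle can handle.
    """

    n_taxa: int
    seed: int
    concentration: float = 1.0
    pool_size: int = 4
    display_cap: int | None = None
    sizes: tuple[int, ...] = (3, 10, 30)

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("fixtures need at least three taxa")


def default_taxa(n: int) -> TaxonSet:
    """Taxon sets ``t01 .. tn`` used by the generators."""
    width = len(str(n))
    return TaxonSet([f"t{str(i + 1).zfill(width)}" for i in range(n)])


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def yule_topology(n: int, rng, taxa: TaxonSet | None = None) -> RootedTopology:
    """A random labeled topology under the Yule (pure-birth) process.

    Implemented by uniform pairwise joins of the extant lineages, which gives
    exactly the Yule topology distribution (divergence times are never used
    downstream and are not generated).
    """
    if n < 2:
        raise ValueError("need at least two taxa")
    rng = _as_rng(rng)
    if taxa is None:
        taxa = default_taxa(n)
    elif len(taxa) != n:
        raise ValueError("taxon set size does not match n")
    lineages = [1 << i for i in range(n)]
    splits: list[CladeSplit] = []
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b1, b2 = lineages[i], lineages[j]
        splits.append(CladeSplit(Clade(b1, taxa), Clade(b2, taxa)))
        lineages[i] = b1 | b2
        del lineages[j]
    return RootedTopology.from_splits(taxa, splits)


def _tree_struct(topo: RootedTopology):
    def rec(clade: Clade):
        if clade.is_leaf:
            return clade.bits
        a, b = topo.children[clade]
        return (rec(a), rec(b))

    return rec(topo.taxa.full_clade)


def _struct_bits(node) -> int:
    if isinstance(node, int):
        return node
    return _struct_bits(node[0]) | _struct_bits(node[1])


def _remove_leaf(node, bit: int):
    a, b = node
    if a == bit:
        return b
    if b == bit:
        return a
    if _struct_bits(a) & bit:
        return (_remove_leaf(a, bit), b)
    return (a, _remove_leaf(b, bit))


def _attach_at(node, target_bits: int, bit: int):
    if _struct_bits(node) == target_bits:
        return (node, bit)
    a, b = node
    if target_bits & _struct_bits(a) == target_bits:
        return (_attach_at(a, target_bits, bit), b)
    return (a, _attach_at(b, target_bits, bit))


def _struct_splits(node, taxa: TaxonSet, out: list[CladeSplit]) -> int:
    if isinstance(node, int):
        return node
    b1 = _struct_splits(node[0], taxa, out)
    b2 = _struct_splits(node[1], taxa, out)
    out.append(CladeSplit(Clade(b1, taxa), Clade(b2, taxa)))
    return b1 | b2


def leaf_spr(topo: RootedTopology, rng, moves: int = 1) -> RootedTopology:
    """Perturb a resolved topology by pruning a random leaf and regrafting it
    on a random remaining branch, ``moves`` times.  Produces nearby
    topologies sharing most clades with the original."""
    rng = _as_rng(rng)
    taxa = topo.taxa
    struct = _tree_struct(topo)
    for _ in range(moves):
        leaf_bit = 1 << int(rng.integers(len(taxa)))
        reduced = _remove_leaf(struct, leaf_bit)
        if isinstance(reduced, int):
            struct = (reduced, leaf_bit)
            continue
        subtrees: list[int] = []

        def collect(node):
            subtrees.append(_struct_bits(node))
            if not isinstance(node, int):
                collect(node[0])
                collect(node[1])

        collect(reduced)
        target = subtrees[int(rng.integers(len(subtrees)))]
        struct = _attach_at(reduced, target, leaf_bit)
    splits: list[CladeSplit] = []
    _struct_splits(struct, taxa, splits)
    return RootedTopology.from_splits(taxa, splits)


def random_ccd(
    n_taxa: int,
    rng,
    concentration: float = 1.0,
    pool_size: int = 4,
    display_cap: int | None = None,
    taxa: TaxonSet | None = None,
    spr_moves: int = 1,
) -> CCDGraph:
    """A random ground-truth CCD.

    The forest network is the union of a *pool* of mutually similar
    topologies: a leaf-prune-regraft random walk of ``pool_size`` steps
    (``spr_moves`` moves per step) started from a Yule topology.  Posterior
    distributions concentrate on similar trees, so the walk's trees share
    clades and their recombinations give the network a rich displayed-tree
    set -- a union of independent topologies would share almost nothing and
    display only the pool itself.  Each clade's split probabilities are
    drawn from a symmetric Dirichlet(``concentration``).  If ``display_cap``
    is given, pools whose network displays more trees are redrawn
    (deterministically, from the same generator stream) so the truth stays
    enumerable.
    """
    rng = _as_rng(rng)
    if taxa is None:
        taxa = default_taxa(n_taxa)
    for _ in range(200):
        splits_by_parent: dict[Clade, set[CladeSplit]] = {}
        topo = yule_topology(n_taxa, rng, taxa=taxa)
        for _ in range(pool_size):
            for split in topo.splits:
                splits_by_parent.setdefault(split.parent_clade, set()).add(split)
            topo = leaf_spr(topo, rng, moves=spr_moves)
        graph_splits: dict[Clade, list[tuple[CladeSplit, float]]] = {}
        for parent in sorted(splits_by_parent, key=lambda c: (c.size, c.bits)):
            options = sorted(splits_by_parent[parent], key=lambda s: (s.left.bits, s.right.bits))
            probs = rng.dirichlet([concentration] * len(options))
            graph_splits[parent] = list(zip(options, probs.tolist()))
        ccd = CCDGraph(taxa, graph_splits, flavor="synthetic")
        if display_cap is None or count_trees(ccd) <= display_cap:
            return ccd
    raise RuntimeError("could not draw a truth CCD under the display cap")


def random_ccd_from_config(config: FixtureConfig) -> CCDGraph:
    return random_ccd(
        config.n_taxa,
        np.random.default_rng(config.seed),
        concentration=config.concentration,
        pool_size=config.pool_size,
        display_cap=config.display_cap,
    )


def synth_posterior(
    truth: CCDGraph,
    sizes,
    replicates: int,
    rng,
) -> list[dict[int, TreeSample]]:
    """Replicate "posterior" samples of nested sizes drawn i.i.d. from a
    truth CCD.

    Within one replicate the subsamples share draws (the size-3 sample is a
    prefix of the size-10 sample, and so on), mirroring how a single MCMC
    chain is subsampled.  Returns one ``{size: TreeSample}`` dict per
    replicate.
    """
    rng = _as_rng(rng)
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1:
        raise ValueError("sizes must be positive integers")
    out: list[dict[int, TreeSample]] = []
    for _ in range(replicates):
        draws = [sample_tree(truth, rng) for _ in range(sizes[-1])]
        out.append({s: TreeSample.from_topologies(draws[:s]) for s in sizes})
    return out
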