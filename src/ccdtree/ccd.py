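"""Conditional clade distributions over rooted binary tree topologies.

A posterior tree sample is condensed into clade and clade-split frequencies
(:func:`tally`).  From these a *CCD graph* is built: a rooted bipartite graph
of clades and clade splits where every non-leaf clade carries a probability
distribution over its child splits.  The graph defines a distribution over
all trees it displays -- the probability of a tree is the product of its
splits' conditional probabilities, and these probabilities sum to one over
the displayed trees.

Three parametrizations are provided:

* **CCD1** -- conditional split probabilities are observed split frequencies,
  ``Pr(S | C) = f(S) / f(C)``.
* **CCD0** -- the split set is expanded to every split formable from observed
  clades, and probabilities are normalized so that a displayed tree ``T`` has
  probability proportional to the product of its clades' Monte Carlo
  probabilities ``f(C) / k``.
* **CCD2** -- an extended graph whose vertices are (clade, sibling-context)
  pairs, so a split's probability also conditions on the clade split its
  parent is part of.

Distribution queries (tree probability, sampling, exact tree counts, entropy
and the number equivalent, clade probabilities, enumeration) are answered by
dynamic programming over the graph and work uniformly for all flavors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Protocol, Sequence

import numpy as np
from scipy.special import logsumexp

from .trees import Clade, CladeSplit, RootedTopology, TaxonSet, TreeSample

__all__ = [
    "CladeFrequencyTable",
    "CCDGraph",
    "ExtendedCCDGraph",
    "SampleDistribution",
    "TreeDistribution",
    "ROOT_CONTEXT",
    "tally",
    "build_ccd0",
    "build_ccd1",
    "build_ccd2",
    "expand_splits",
    "tree_probability",
    "sample_tree",
    "count_trees",
    "entropy",
    "clade_probability",
    "clade_probabilities",
    "enumerate_trees",
    "detect_outliers",
    "OutlierFlag",
    "save_ccd",
    "load_ccd",
]

_PROB_TOL = 1e-9


class TreeDistribution(Protocol):
    """Common query contract satisfied by sample distributions and CCDs."""

    taxa: TaxonSet

    def probability(self, tree: RootedTopology) -> float: ...

    def sample(self, rng) -> RootedTopology: ...


# ---------------------------------------------------------------------------
# frequency tables


@dataclass(frozen=True)
class CladeFrequencyTable:
    """Clade and clade-split counts ``f(C)``, ``f(S)`` from a sample of ``k``
    trees.

    Invariants (checked by :meth:`validate`): ``f(S) <= f(C)`` for each split
    of ``C``; split counts of a non-leaf observed clade sum to ``f(C)``; the
    root and every singleton have count ``k``.
    """

    taxa: TaxonSet
    k: int
    clade_count: Mapping[Clade, int]
    split_count: Mapping[CladeSplit, int]

    def credibility(self, clade: Clade) -> float:
        """Monte Carlo clade probability ``f(C) / k`` (0 if unobserved)."""
        return self.clade_count.get(clade, 0) / self.k

    def nontrivial_clades(self) -> list[Clade]:
        return [c for c in self.clade_count if not c.is_trivial]

    def validate(self) -> None:
        per_parent: dict[Clade, int] = {}
        for split, f_s in self.split_count.items():
            parent = split.parent_clade
            if f_s > self.clade_count.get(parent, 0):
                raise ValueError(f"split count exceeds clade count at {split!r}")
            per_parent[parent] = per_parent.get(parent, 0) + f_s
        for clade, f_c in self.clade_count.items():
            if clade.is_leaf:
                continue
            if per_parent.get(clade, 0) != f_c:
                raise ValueError(f"split counts of {clade!r} do not sum to f(C)")
        if self.clade_count.get(self.taxa.full_clade) != self.k:
            raise ValueError("root clade count must equal the sample size")
        for lab in self.taxa:
            if self.clade_count.get(self.taxa.singleton(lab)) != self.k:
                raise ValueError("singleton clade counts must equal the sample size")


def tally(sample: TreeSample) -> CladeFrequencyTable:
    """Count clade and clade-split frequencies over a tree sample."""
    clade_count: dict[Clade, int] = {}
    split_count: dict[CladeSplit, int] = {}
    for topo, mult in sample:
        for clade in topo.clades:
            clade_count[clade] = clade_count.get(clade, 0) + mult
        for split in topo.splits:
            split_count[split] = split_count.get(split, 0) + mult
    table = CladeFrequencyTable(sample.taxa, sample.k, clade_count, split_count)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# CCD graphs


def _canonical_split_order(item):
    split = item[0]
    return (split.left.bits, split.right.bits)


class CCDGraph:
    """A forest network with conditional split probabilities per clade.

    ``splits`` maps each non-leaf clade to its child splits and probabilities
    ``Pr(S | C)``; every non-leaf clade's probabilities sum to one.  The
    ``flavor`` records the parametrization ("ccd0", "ccd1", or another label
    for synthetic graphs).  CCD0 graphs additionally carry the Monte Carlo
    clade credibilities ``f(C)/k`` used by sum-of-clade-credibility scoring.
    """

    def __init__(
        self,
        taxa: TaxonSet,
        splits: Mapping[Clade, Sequence[tuple[CladeSplit, float]]],
        flavor: str = "custom",
        clade_credibility: Mapping[Clade, float] | None = None,
        validate: bool = True,
    ):
        self.taxa = taxa
        self.flavor = flavor
        self.clade_credibility = dict(clade_credibility) if clade_credibility else None
        self._splits = {
            clade: tuple(sorted(entries, key=_canonical_split_order))
            for clade, entries in splits.items()
        }
        clades = {taxa.full_clade}
        for clade, entries in self._splits.items():
            clades.add(clade)
            for split, _ in entries:
                clades.update((split.left, split.right))
        self.clades = frozenset(clades)
        self._split_prob = {
            split: p for entries in self._splits.values() for split, p in entries
        }
        self._clade_probs: dict[Clade, float] | None = None
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        root = self.taxa.full_clade
        if root not in self._splits:
            raise ValueError("the root clade must have at least one split")
        non_root = set()
        for clade, entries in self._splits.items():
            if not entries:
                raise ValueError(f"non-leaf clade {clade!r} has no splits")
            total = 0.0
            for split, p in entries:
                if split.parent_clade != clade:
                    raise ValueError(f"split {split!r} is not a split of {clade!r}")
                if not 0.0 <= p <= 1.0 + _PROB_TOL:
                    raise ValueError(f"probability of {split!r} outside [0, 1]")
                total += p
                non_root.update((split.left, split.right))
            if abs(total - 1.0) > _PROB_TOL:
                raise ValueError(f"split probabilities of {clade!r} sum to {total}")
        for clade in self.clades:
            if not clade.is_leaf and clade not in self._splits:
                raise ValueError(f"reachable clade {clade!r} has no splits")
            if clade != root and clade not in non_root:
                raise ValueError(f"clade {clade!r} is unreachable from the root")

    def splits_of(self, clade: Clade) -> tuple[tuple[CladeSplit, float], ...]:
        return self._splits.get(clade, ())

    def split_probability(self, split: CladeSplit) -> float:
        return self._split_prob.get(split, 0.0)

    # -- generic vertex API used by the dynamic programs --------------------

    @property
    def root_key(self) -> Clade:
        return self.taxa.full_clade

    def vertex_keys(self) -> Iterator[Clade]:
        return iter(self.clades)

    def vertex_splits(self, key: Clade):
        return [(split, p, split.left, split.right) for split, p in self._splits.get(key, ())]

    @staticmethod
    def _sort_key(key: Clade):
        return (key.size, key.bits)

    @staticmethod
    def _clade_of(key: Clade) -> Clade:
        return key

    # -- distribution contract ---------------------------------------------

    def probability(self, tree: RootedTopology) -> float:
        return tree_probability(self, tree)

    def sample(self, rng) -> RootedTopology:
        return sample_tree(self, rng)

    def __repr__(self) -> str:
        n_splits = sum(len(v) for v in self._splits.values())
        return f"CCDGraph(flavor={self.flavor!r}, clades={len(self.clades)}, splits={n_splits})"


class _RootContext:
    """Distinguished sibling context of the root clade in a CCD2 graph."""

    __slots__ = ()

    def __repr__(self) -> str:
        return "ROOT"


ROOT_CONTEXT = _RootContext()


class ExtendedCCDGraph:
    """CCD2: clade vertices are distinguished by their sibling clade.

    Vertices are ``(clade, context)`` pairs where the context is the sibling
    clade under which the clade occurs (or :data:`ROOT_CONTEXT` for the root
    clade).  Each non-leaf vertex carries a distribution over its splits:
    ``Pr(S | C, sibling)``.
    """

    def __init__(
        self,
        taxa: TaxonSet,
        vertex_splits: Mapping[tuple[Clade, object], Sequence[tuple[CladeSplit, float]]],
        validate: bool = True,
    ):
        self.taxa = taxa
        self.flavor = "ccd2"
        self._vertex_splits = {
            key: tuple(sorted(entries, key=_canonical_split_order))
            for key, entries in vertex_splits.items()
        }
        keys = {(taxa.full_clade, ROOT_CONTEXT)}
        for (clade, ctx), entries in self._vertex_splits.items():
            keys.add((clade, ctx))
            for split, _ in entries:
                keys.add((split.left, split.right))
                keys.add((split.right, split.left))
        self._keys = frozenset(keys)
        self.clades = frozenset(clade for clade, _ in keys)
        if validate:
            self.validate()

    def validate(self) -> None:
        if (self.taxa.full_clade, ROOT_CONTEXT) not in self._vertex_splits:
            raise ValueError("the root vertex must have at least one split")
        for (clade, ctx), entries in self._vertex_splits.items():
            total = 0.0
            for split, p in entries:
                if split.parent_clade != clade:
                    raise ValueError(f"split {split!r} is not a split of {clade!r}")
                if not 0.0 <= p <= 1.0 + _PROB_TOL:
                    raise ValueError("probability outside [0, 1]")
                total += p
            if abs(total - 1.0) > _PROB_TOL:
                raise ValueError(f"probabilities at vertex ({clade!r}, {ctx!r}) sum to {total}")
        for clade, ctx in self._keys:
            if not clade.is_leaf and (clade, ctx) not in self._vertex_splits:
                raise ValueError(f"non-leaf vertex ({clade!r}, {ctx!r}) has no splits")

    @property
    def root_key(self):
        return (self.taxa.full_clade, ROOT_CONTEXT)

    def vertex_keys(self):
        return iter(self._keys)

    def vertex_splits(self, key):
        entries = self._vertex_splits.get(key, ())
        return [
            (split, p, (split.left, split.right), (split.right, split.left))
            for split, p in entries
        ]

    @staticmethod
    def _sort_key(key):
        clade, ctx = key
        ctx_bits = -1 if ctx is ROOT_CONTEXT else ctx.bits
        return (clade.size, clade.bits, ctx_bits)

    @staticmethod
    def _clade_of(key) -> Clade:
        return key[0]

    def probability(self, tree: RootedTopology) -> float:
        return tree_probability(self, tree)

    def sample(self, rng) -> RootedTopology:
        return sample_tree(self, rng)

    def __repr__(self) -> str:
        return f"ExtendedCCDGraph(vertices={len(self._keys)})"


class SampleDistribution:
    """The empirical distribution of a tree sample (Monte Carlo
    probabilities ``multiplicity / k``)."""

    def __init__(self, sample: TreeSample):
        self.sample_data = sample
        self.taxa = sample.taxa
        self._probs = {topo: mult / sample.k for topo, mult in sample}
        self._order = sorted(self._probs, key=lambda t: t.canonical_key())

    def probability(self, tree: RootedTopology) -> float:
        return self._probs.get(tree, 0.0)

    def sample(self, rng) -> RootedTopology:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        u = rng.random()
        acc = 0.0
        for topo in self._order:
            acc += self._probs[topo]
            if u < acc:
                return topo
        return self._order[-1]

    def support(self) -> list[tuple[RootedTopology, float]]:
        return [(topo, self._probs[topo]) for topo in self._order]

    def clade_probability(self, clade: Clade) -> float:
        return sum(p for topo, p in self._probs.items() if clade in topo.clades)

    def __repr__(self) -> str:
        return f"SampleDistribution(k={self.sample_data.k}, topologies={len(self._probs)})"


# ---------------------------------------------------------------------------
# construction


def build_ccd1(table: CladeFrequencyTable) -> CCDGraph:
    """CCD1: the observed splits with ``Pr(S | C) = f(S) / f(C)``."""
    splits: dict[Clade, list[tuple[CladeSplit, float]]] = {}
    for split, f_s in table.split_count.items():
        parent = split.parent_clade
        splits.setdefault(parent, []).append((split, f_s / table.clade_count[parent]))
    return CCDGraph(table.taxa, splits, flavor="ccd1")


def expand_splits(table: CladeFrequencyTable) -> set[CladeSplit]:
    """Every clade split formable from observed clades: all ``{C1, C2}`` with
    ``C1``, ``C2`` and ``C1 ∪ C2`` observed, ``C1 ∩ C2 = ∅``.

    A superset of the observed splits.  Implemented per parent clade by
    hash-testing complements of observed sub-clades; quadratic in the number
    of observed clades in the worst case.
    """
    observed = {c.bits: c for c in table.clade_count}
    result: set[CladeSplit] = set()
    clades = list(table.clade_count)
    for parent in clades:
        if parent.is_leaf:
            continue
        pb = parent.bits
        for cand in clades:
            cb = cand.bits
            if cb >= pb or cb & pb != cb:
                continue
            comp = pb ^ cb
            if cb > comp:
                continue  # canonical half only
            if comp in observed:
                result.add(CladeSplit(cand, observed[comp]))
    return result


def build_ccd0(table: CladeFrequencyTable) -> CCDGraph:
    """CCD0: expanded split set, probabilities normalized so a displayed tree
    has probability proportional to the product of its clades' Monte Carlo
    probabilities ``f(C) / k``.

    Uses the subtree-sum recursion ``z(leaf) = 1`` and
    ``z(C) = (f(C)/k) * sum over splits of z(C1) z(C2)``; then
    ``Pr({C1,C2} | C) = z(C1) z(C2) / sum over splits of C``.  Computed in
    log space so deep trees do not underflow.
    """
    expanded = expand_splits(table)
    by_parent: dict[Clade, list[CladeSplit]] = {}
    for split in expanded:
        by_parent.setdefault(split.parent_clade, []).append(split)
    log_z: dict[Clade, float] = {}
    log_k = math.log(table.k)
    probs: dict[Clade, list[tuple[CladeSplit, float]]] = {}
    for clade in sorted(table.clade_count, key=lambda c: (c.size, c.bits)):
        if clade.is_leaf:
            log_z[clade] = 0.0
            continue
        child_splits = sorted(by_parent[clade], key=lambda s: (s.left.bits, s.right.bits))
        terms = [log_z[s.left] + log_z[s.right] for s in child_splits]
        log_total = logsumexp(terms)
        log_z[clade] = math.log(table.clade_count[clade]) - log_k + log_total
        probs[clade] = [
            (s, math.exp(t - log_total)) for s, t in zip(child_splits, terms)
        ]
    credibility = {c: f / table.k for c, f in table.clade_count.items()}
    return CCDGraph(table.taxa, probs, flavor="ccd0", clade_credibility=credibility)


def build_ccd2(sample: TreeSample) -> ExtendedCCDGraph:
    """CCD2: split probabilities conditioned on the parent clade *and* its
    sibling context, tallied directly from the sample."""
    vertex_count: dict[tuple[Clade, object], int] = {}
    split_count: dict[tuple[Clade, object], dict[CladeSplit, int]] = {}
    for topo, mult in sample:
        stack: list[tuple[Clade, object]] = [(sample.taxa.full_clade, ROOT_CONTEXT)]
        while stack:
            clade, ctx = stack.pop()
            if clade.is_leaf:
                continue
            key = (clade, ctx)
            vertex_count[key] = vertex_count.get(key, 0) + mult
            c1, c2 = topo.children[clade]
            split = CladeSplit(c1, c2)
            counts = split_count.setdefault(key, {})
            counts[split] = counts.get(split, 0) + mult
            stack.append((c1, c2))
            stack.append((c2, c1))
    vertex_splits = {
        key: [(split, cnt / vertex_count[key]) for split, cnt in counts.items()]
        for key, counts in split_count.items()
    }
    return ExtendedCCDGraph(sample.taxa, vertex_splits)


# ---------------------------------------------------------------------------
# dynamic programs (generic over CCDGraph and ExtendedCCDGraph)


def _ordered_keys(graph) -> list:
    """Vertex keys in bottom-up (ascending clade size) order; deterministic."""
    return sorted(graph.vertex_keys(), key=graph._sort_key)


def tree_probability(dist, tree: RootedTopology) -> float:
    """Probability of a resolved topology under a distribution.

    For CCD graphs this is the product of the conditional split probabilities
    along the tree (context-aware for CCD2), accumulated in log space; a tree
    requiring any split absent from the graph has probability exactly 0.
    """
    if dist.taxa.labels != tree.taxa.labels:
        raise ValueError("tree and distribution must share the taxon set")
    if not tree.resolved:
        raise ValueError("tree probabilities are defined for resolved topologies")
    if isinstance(dist, SampleDistribution):
        return dist.probability(tree)
    if isinstance(dist, CCDGraph):
        log_p = 0.0
        for split in tree.splits:
            p = dist.split_probability(split)
            if p <= 0.0:
                return 0.0
            log_p += math.log(p)
        return math.exp(log_p)
    if isinstance(dist, ExtendedCCDGraph):
        log_p = 0.0
        stack: list[tuple[Clade, object]] = [(tree.taxa.full_clade, ROOT_CONTEXT)]
        while stack:
            clade, ctx = stack.pop()
            if clade.is_leaf:
                continue
            c1, c2 = tree.children[clade]
            want = CladeSplit(c1, c2)
            p = 0.0
            for split, q, _, _ in dist.vertex_splits((clade, ctx)):
                if split == want:
                    p = q
                    break
            if p <= 0.0:
                return 0.0
            log_p += math.log(p)
            stack.append((c1, c2))
            stack.append((c2, c1))
        return math.exp(log_p)
    raise TypeError(f"unsupported distribution type {type(dist)!r}")


def sample_tree(ccd, rng) -> RootedTopology:
    """Draw a topology from a CCD by sampling a split at each clade top-down.

    The sampling distribution equals :func:`tree_probability`; with a seeded
    generator the draw is deterministic.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    splits: list[CladeSplit] = []
    stack = [ccd.root_key]
    while stack:
        key = stack.pop()
        entries = ccd.vertex_splits(key)
        if not entries:
            continue
        u = rng.random()
        acc = 0.0
        chosen = entries[-1]
        for entry in entries:
            acc += entry[1]
            if u < acc:
                chosen = entry
                break
        split, _, k1, k2 = chosen
        splits.append(split)
        stack.append(k2)
        stack.append(k1)
    return RootedTopology.from_splits(ccd.taxa, splits)


def count_trees(ccd) -> int:
    """Exact number of distinct topologies displayed by the graph, via the
    bottom-up recursion ``t(C) = sum over splits of t(C1) t(C2)`` with
    arbitrary-precision integers."""
    t: dict = {}
    for key in _ordered_keys(ccd):
        entries = ccd.vertex_splits(key)
        if not entries:
            t[key] = 1
        else:
            t[key] = sum(t[k1] * t[k2] for _, _, k1, k2 in entries)
    return t[ccd.root_key]


def entropy(ccd) -> tuple[float, float]:
    """Shannon entropy H (nats) of the tree distribution and the number
    equivalent ``Ne = exp(H)``, the effective number of distinct topologies.

    Uses the per-clade recursion
    ``H*(C) = sum over splits -Pr(S) (log Pr(S) - H*(C1) - H*(C2))`` with
    ``H*(leaf) = 0``.
    """
    h: dict = {}
    for key in _ordered_keys(ccd):
        entries = ccd.vertex_splits(key)
        total = 0.0
        for _, p, k1, k2 in entries:
            if p > 0.0:
                total += -p * (math.log(p) - h[k1] - h[k2])
        h[key] = total
    h_root = h[ccd.root_key]
    return h_root, math.exp(h_root)


def clade_probabilities(ccd) -> dict[Clade, float]:
    """Probability that a tree drawn from the CCD contains each clade.

    Top-down pass: the root has probability 1 and each split propagates
    ``p(parent) * Pr(S | parent)`` to its children; within one tree the
    incoming split instances of a clade are disjoint events, so the sums are
    exact clade probabilities.
    """
    p: dict = {ccd.root_key: 1.0}
    for key in reversed(_ordered_keys(ccd)):
        pk = p.get(key, 0.0)
        if pk == 0.0:
            continue
        for _, q, k1, k2 in ccd.vertex_splits(key):
            w = pk * q
            p[k1] = p.get(k1, 0.0) + w
            p[k2] = p.get(k2, 0.0) + w
    out: dict[Clade, float] = {}
    for key, value in p.items():
        clade = ccd._clade_of(key)
        out[clade] = out.get(clade, 0.0) + (value if key != ccd.root_key else 0.0)
    out[ccd._clade_of(ccd.root_key)] = 1.0
    return out


def clade_probability(ccd, clade: Clade) -> float:
    """Probability of one clade under the CCD (0 if absent from the graph)."""
    if isinstance(ccd, SampleDistribution):
        return ccd.clade_probability(clade)
    if isinstance(ccd, CCDGraph):
        if ccd._clade_probs is None:
            ccd._clade_probs = clade_probabilities(ccd)
        return ccd._clade_probs.get(clade, 0.0)
    return clade_probabilities(ccd).get(clade, 0.0)


def enumerate_trees(ccd, cap: int = 10**6) -> list[tuple[RootedTopology, float]]:
    """All displayed topologies with exact probabilities, by recursive
    expansion of clade splits.  Refuses graphs displaying more than ``cap``
    trees (check :func:`count_trees` first)."""
    n = count_trees(ccd)
    if n > cap:
        raise ValueError(f"CCD displays {n} trees, more than the cap {cap}")
    expansions: dict = {}
    for key in _ordered_keys(ccd):
        entries = ccd.vertex_splits(key)
        if not entries:
            expansions[key] = [((), 1.0)]
            continue
        options: list[tuple[tuple[CladeSplit, ...], float]] = []
        for split, p, k1, k2 in entries:
            for s1, p1 in expansions[k1]:
                for s2, p2 in expansions[k2]:
                    options.append((s1 + s2 + (split,), p * p1 * p2))
        expansions[key] = options
    taxa = ccd.taxa
    return [
        (RootedTopology.from_splits(taxa, splits), p)
        for splits, p in expansions[ccd.root_key]
    ]


# ---------------------------------------------------------------------------
# outlier detection


@dataclass(frozen=True)
class OutlierFlag:
    """Advisory diagnostic for a sampled topology that may be leftover burnin.

    ``isolated`` means every nontrivial clade of the topology was observed
    only in copies of the topology itself (and the topology is a minority of
    the sample), so a CCD1/CCD2 gives it probability ``multiplicity / k``
    regardless of how aberrant it is.  ``once_clades`` / ``once_splits`` list
    its clades and splits observed exactly once in the whole sample.
    """

    topology: RootedTopology
    multiplicity: int
    isolated: bool
    once_clades: tuple[Clade, ...]
    once_splits: tuple[CladeSplit, ...]


def detect_outliers(sample: TreeSample, table: CladeFrequencyTable) -> list[OutlierFlag]:
    """Flag sampled topologies that share no clades with the rest of the
    sample or contain once-observed clades/splits.  Purely advisory; nothing
    is removed."""
    if sample.k < 2:
        raise ValueError("outlier detection needs a sample of at least two trees")
    flags: list[OutlierFlag] = []
    for topo, mult in sample:
        nontrivial = topo.nontrivial_clades()
        isolated = (
            2 * mult <= sample.k
            and all(table.clade_count[c] == mult for c in nontrivial)
        )
        once_clades = tuple(
            sorted((c for c in nontrivial if table.clade_count[c] == 1), key=lambda c: c.bits)
        )
        once_splits = tuple(
            sorted(
                (s for s in topo.splits if table.split_count.get(s, 0) == 1),
                key=lambda s: (s.left.bits, s.right.bits),
            )
        )
        if isolated or once_clades or once_splits:
            flags.append(OutlierFlag(topo, mult, isolated, once_clades, once_splits))
    return flags


# ---------------------------------------------------------------------------
# serialization (JSON lines)


def _hex(bits: int) -> str:
    return format(bits, "x")


def save_ccd(ccd, path: str | Path) -> None:
    """Write a CCD graph to a JSON-lines file.

    Line 1 is a header with the flavor and taxon labels; each further line is
    one clade (or clade-context vertex for CCD2) with its splits as pairs of
    hex bit masks and probabilities.
    """
    lines = []
    if isinstance(ccd, CCDGraph):
        header = {
            "format": "ccd-graph",
            "version": 1,
            "kind": "ccd",
            "flavor": ccd.flavor,
            "taxa": list(ccd.taxa.labels),
        }
        lines.append(json.dumps(header))
        for clade in sorted(ccd.clades, key=lambda c: (c.size, c.bits)):
            entries = ccd.splits_of(clade)
            if not entries:
                continue
            rec = {
                "clade": _hex(clade.bits),
                "splits": [[_hex(s.left.bits), _hex(s.right.bits), p] for s, p in entries],
            }
            if ccd.clade_credibility is not None:
                rec["credibility"] = ccd.clade_credibility.get(clade, 0.0)
            lines.append(json.dumps(rec))
    elif isinstance(ccd, ExtendedCCDGraph):
        header = {
            "format": "ccd-graph",
            "version": 1,
            "kind": "ccd2",
            "flavor": "ccd2",
            "taxa": list(ccd.taxa.labels),
        }
        lines.append(json.dumps(header))
        for key in _ordered_keys(ccd):
            entries = ccd._vertex_splits.get(key, ())
            if not entries:
                continue
            clade, ctx = key
            rec = {
                "clade": _hex(clade.bits),
                "context": "root" if ctx is ROOT_CONTEXT else _hex(ctx.bits),
                "splits": [[_hex(s.left.bits), _hex(s.right.bits), p] for s, p in entries],
            }
            lines.append(json.dumps(rec))
    else:
        raise TypeError(f"cannot serialize {type(ccd)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_ccd(path: str | Path):
    """Read a CCD graph written by :func:`save_ccd`; all graph invariants are
    re-validated on load."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError("empty CCD file")
    header = json.loads(lines[0])
    if header.get("format") != "ccd-graph":
        raise ValueError("not a CCD graph file")
    taxa = TaxonSet(header["taxa"])
    kind = header.get("kind", "ccd")
    if kind == "ccd":
        splits: dict[Clade, list[tuple[CladeSplit, float]]] = {}
        credibility: dict[Clade, float] = {}
        has_cred = False
        for line in lines[1:]:
            rec = json.loads(line)
            clade = Clade(int(rec["clade"], 16), taxa)
            entries = [
                (CladeSplit(Clade(int(a, 16), taxa), Clade(int(b, 16), taxa)), p)
                for a, b, p in rec["splits"]
            ]
            splits[clade] = entries
            if "credibility" in rec:
                has_cred = True
                credibility[clade] = rec["credibility"]
        return CCDGraph(
            taxa,
            splits,
            flavor=header.get("flavor", "custom"),
            clade_credibility=credibility if has_cred else None,
        )
    if kind == "ccd2":
        vertex_splits: dict[tuple[Clade, object], list[tuple[CladeSplit, float]]] = {}
        for line in lines[1:]:
            rec = json.loads(line)
            clade = Clade(int(rec["clade"], 16), taxa)
            ctx = ROOT_CONTEXT if rec["context"] == "root" else Clade(int(rec["context"], 16), taxa)
            vertex_splits[(clade, ctx)] = [
                (CladeSplit(Clade(int(a, 16), taxa), Clade(int(b, 16), taxa)), p)
                for a, b, p in rec["splits"]
            ]
        return ExtendedCCDGraph(taxa, vertex_splits)
    raise ValueError(f"unknown CCD kind {kind!r}")
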