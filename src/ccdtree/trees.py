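"""Rooted tree topologies, posterior tree samples, and topology distances.

A rooted binary tree topology on a taxon set is represented by its clades:
each clade is a bit vector over the taxa, and each internal node contributes
one clade split -- an unordered pair of disjoint sibling clades whose union is
the parent clade.  Topology identity is clade-set identity: branch lengths,
node labels, and child rotation are ignored, which matches how posterior tree
samples are summarized.

Parsing of Newick and Nexus tree files (including BEAST-style ``.trees`` files
with translate blocks) is delegated to :mod:`dendropy`; the Newick writer is
local so that clade-support annotations can be emitted as BEAST-style
``[&key=value]`` node metadata.
"""

from __future__ import annotations

import math
import os
import re
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "TaxonSet",
    "Clade",
    "CladeSplit",
    "RootedTopology",
    "TreeSample",
    "parse_trees",
    "write_tree",
    "write_sample",
    "rf_distance",
    "relative_rf",
]


class TaxonSet:
    """An ordered, indexed set of distinct taxon labels."""

    __slots__ = ("labels", "index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if len(labels) < 2:
            raise ValueError("a taxon set needs at least two taxa")
        if any(not isinstance(lab, str) or not lab for lab in labels):
            raise ValueError("taxon labels must be non-empty strings")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate taxon labels")
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self.index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"

    def clade(self, members: Iterable[str]) -> "Clade":
        """Build the clade containing exactly ``members``."""
        bits = 0
        for lab in members:
            if lab not in self.index:
                raise KeyError(f"unknown taxon {lab!r}")
            bits |= 1 << self.index[lab]
        return Clade(bits, self)

    def singleton(self, label: str) -> "Clade":
        return self.clade([label])

    @property
    def full_clade(self) -> "Clade":
        return Clade((1 << len(self)) - 1, self)


class Clade:
    """A clade: a nonempty subset of the taxon set stored as a bit mask.

    Bit ``i`` corresponds to taxon ``taxa.labels[i]``.  Equality and hashing
    are by bit content; the full taxon set and all singletons are valid
    clades.
    """

    __slots__ = ("bits", "taxa")

    def __init__(self, bits: int, taxa: TaxonSet):
        n = len(taxa)
        if not isinstance(bits, int) or bits <= 0 or bits >> n:
            raise ValueError("clade bit mask must be nonzero and within the taxon set")
        self.bits = bits
        self.taxa = taxa

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    @property
    def is_leaf(self) -> bool:
        return self.bits.bit_count() == 1

    @property
    def is_root(self) -> bool:
        return self.bits == (1 << len(self.taxa)) - 1

    @property
    def is_trivial(self) -> bool:
        """Leaves and the full taxon set are trivial (present in every tree)."""
        return self.is_leaf or self.is_root

    def labels(self) -> tuple[str, ...]:
        return tuple(lab for i, lab in enumerate(self.taxa.labels) if self.bits >> i & 1)

    def issubset(self, other: "Clade") -> bool:
        return self.bits & other.bits == self.bits

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Clade)
            and self.bits == other.bits
            and self.taxa.labels == other.taxa.labels
        )

    def __hash__(self) -> int:
        return hash(self.bits)

    def __lt__(self, other: "Clade") -> bool:
        return self.bits < other.bits

    def __repr__(self) -> str:
        return "{" + ",".join(self.labels()) + "}"


class CladeSplit:
    """An unordered pair of disjoint clades partitioning their parent clade.

    Stored in canonical order: the child with the smaller bit mask first, so
    hashing and iteration order are deterministic.
    """

    __slots__ = ("left", "right")

    def __init__(self, a: Clade, b: Clade):
        if a.taxa.labels != b.taxa.labels:
            raise ValueError("clades of a split must share one taxon set")
        if a.bits & b.bits:
            raise ValueError("clades of a split must be disjoint")
        if a.bits > b.bits:
            a, b = b, a
        self.left = a
        self.right = b

    @property
    def parent_clade(self) -> Clade:
        return Clade(self.left.bits | self.right.bits, self.left.taxa)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CladeSplit)
            and self.left.bits == other.left.bits
            and self.right.bits == other.right.bits
            and self.left.taxa.labels == other.left.taxa.labels
        )

    def __hash__(self) -> int:
        return hash((self.left.bits, self.right.bits))

    def __repr__(self) -> str:
        return f"{''.join(self.left.labels())}|{''.join(self.right.labels())}"


class RootedTopology:
    """A rooted tree topology given by a laminar family of clades.

    The clade family always contains the full taxon set and all singletons.
    For a fully resolved (binary) topology there are exactly ``n - 1``
    non-leaf clades, each carrying exactly one clade split.  Unresolved
    topologies (as produced by greedy consensus) carry splits only at binary
    nodes and have ``resolved = False``.
    """

    __slots__ = ("taxa", "clades", "splits", "children", "resolved", "_key")

    def __init__(self, taxa: TaxonSet, clades: Iterable[Clade]):
        clade_set = set(clades)
        clade_set.add(taxa.full_clade)
        for lab in taxa:
            clade_set.add(taxa.singleton(lab))
        ordered = sorted(clade_set, key=lambda c: (c.size, c.bits))
        # laminar check: any two clades are disjoint or nested
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                inter = a.bits & b.bits
                if inter and inter != a.bits and inter != b.bits:
                    raise ValueError(f"clades {a!r} and {b!r} overlap but are not nested")
        # parent of each clade = smallest strict superset
        children: dict[Clade, list[Clade]] = {c: [] for c in clade_set}
        for c in ordered[:-1]:
            parent = next(p for p in ordered if c.bits != p.bits and c.issubset(p))
            children[parent].append(c)
        children = {
            p: tuple(sorted(kids, key=lambda c: c.bits & -c.bits))
            for p, kids in children.items()
        }
        for p, kids in children.items():
            if kids and sum(k.bits for k in kids) != p.bits:
                raise ValueError(f"children of {p!r} do not partition it")
        splits = frozenset(
            CladeSplit(kids[0], kids[1]) for kids in children.values() if len(kids) == 2
        )
        n = len(taxa)
        nonleaf = [c for c in clade_set if not c.is_leaf]
        self.taxa = taxa
        self.clades = frozenset(clade_set)
        self.splits = splits
        self.children = children
        self.resolved = len(nonleaf) == n - 1 and all(
            len(children[c]) == 2 for c in nonleaf
        )
        self._key = frozenset(c.bits for c in clade_set)

    @classmethod
    def from_splits(cls, taxa: TaxonSet, splits: Iterable[CladeSplit]) -> "RootedTopology":
        """Build a fully resolved topology from its clade splits."""
        clades: set[Clade] = set()
        parents: set[int] = set()
        for s in splits:
            clades.update((s.left, s.right))
            p = s.parent_clade
            if p.bits in parents:
                raise ValueError(f"clade {p!r} has more than one split")
            parents.add(p.bits)
            clades.add(p)
        topo = cls(taxa, clades)
        if not topo.resolved:
            raise ValueError("splits do not describe a fully resolved topology")
        return topo

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def nontrivial_clades(self) -> frozenset[Clade]:
        return frozenset(c for c in self.clades if not c.is_trivial)

    def contains_clade(self, clade: Clade) -> bool:
        return clade in self.clades

    def newick(self, annotations: Mapping[Clade, float] | None = None, key: str = "support") -> str:
        return write_tree(self, annotations=annotations, key=key)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RootedTopology)
            and self.taxa.labels == other.taxa.labels
            and self._key == other._key
        )

    def __hash__(self) -> int:
        return hash((self.taxa.labels, self._key))

    def __repr__(self) -> str:
        return f"RootedTopology({self.newick()})"

    def canonical_key(self) -> tuple[int, ...]:
        """Deterministic sort key: the sorted clade bit masks."""
        return tuple(sorted(self._key))


class TreeSample:
    """A multiset of resolved topologies on one taxon set.

    ``k`` is the total tree count (sum of multiplicities); identical
    topologies are merged.
    """

    __slots__ = ("taxa", "topologies", "k")

    def __init__(self, taxa: TaxonSet, topologies: Sequence[tuple[RootedTopology, int]]):
        merged: dict[RootedTopology, int] = {}
        for topo, mult in topologies:
            if topo.taxa.labels != taxa.labels:
                raise ValueError("all topologies must share the taxon set")
            if not topo.resolved:
                raise ValueError("tree samples contain only resolved topologies")
            if mult <= 0:
                raise ValueError("multiplicities must be positive")
            merged[topo] = merged.get(topo, 0) + mult
        if not merged:
            raise ValueError("empty tree sample")
        self.taxa = taxa
        self.topologies = tuple(merged.items())
        self.k = sum(merged.values())

    @classmethod
    def from_topologies(cls, topologies: Iterable[RootedTopology]) -> "TreeSample":
        topologies = list(topologies)
        if not topologies:
            raise ValueError("empty tree sample")
        return cls(topologies[0].taxa, [(t, 1) for t in topologies])

    def __len__(self) -> int:
        return len(self.topologies)

    def __iter__(self) -> Iterator[tuple[RootedTopology, int]]:
        return iter(self.topologies)


# ---------------------------------------------------------------------------
# parsing and writing


def _read_source(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and "\n" not in source and "(" not in source and os.path.exists(source):
        return Path(source).read_text()
    if isinstance(source, str) and os.path.sep in source and os.path.exists(source):
        return Path(source).read_text()
    return source


def parse_trees(
    source: str | Path,
    format: str = "newick",
    burnin_fraction: float = 0.1,
) -> TreeSample:
    """Read a sample of rooted binary trees from Newick or Nexus input.

    Parameters
    ----------
    source
        Path to a tree file, or the file content itself.
    format
        ``"newick"`` or ``"nexus"`` (Nexus TREES blocks with optional
        TRANSLATE are honored).
    burnin_fraction
        Fraction of leading trees (in file order) discarded before
        multiplicity merging; default 0.1 as is conventional for MCMC output.

    Branch lengths and node annotations are ignored: two trees with the same
    clade set are merged into one topology with summed multiplicity.  The
    taxon order of the first retained tree defines the :class:`TaxonSet`.
    """
    if not 0 <= burnin_fraction < 1:
        raise ValueError("burnin_fraction must lie in [0, 1)")
    schema = format.lower()
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    text = _read_source(source)
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema=schema,
            rooting="default-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ValueError(f"could not parse {schema} input: {exc}") from None
    if len(tree_list) == 0:
        raise ValueError("no trees found in input")
    drop = math.floor(burnin_fraction * len(tree_list))
    retained = list(tree_list)[drop:]
    if not retained:
        raise ValueError("empty sample after burnin")

    labels = []
    for leaf in retained[0].leaf_node_iter():
        lab = leaf.taxon.label if leaf.taxon is not None else leaf.label
        labels.append(lab)
    # canonical (sorted) label order so topologies from different files on the
    # same taxa are directly comparable
    taxa = TaxonSet(sorted(labels))
    full = (1 << len(taxa)) - 1

    topologies: list[tuple[RootedTopology, int]] = []
    for tree in retained:
        bits_of: dict[object, int] = {}
        splits: list[CladeSplit] = []
        for node in tree.postorder_node_iter():
            kids = node.child_nodes()
            if not kids:
                lab = node.taxon.label if node.taxon is not None else node.label
                if lab is None or lab not in taxa.index:
                    raise ValueError(f"taxon {lab!r} not present in all trees")
                bits_of[node] = 1 << taxa.index[lab]
            else:
                if len(kids) != 2:
                    raise ValueError(
                        "input trees must be rooted and binary "
                        f"(found a node with {len(kids)} children)"
                    )
                b1, b2 = bits_of[kids[0]], bits_of[kids[1]]
                splits.append(CladeSplit(Clade(b1, taxa), Clade(b2, taxa)))
                bits_of[node] = b1 | b2
        if bits_of[tree.seed_node] != full:
            raise ValueError("trees do not all share the same taxa")
        topologies.append((RootedTopology.from_splits(taxa, splits), 1))
    return TreeSample(taxa, topologies)


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|\-]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _newick_recursive(
    topo: RootedTopology,
    clade: Clade,
    annotations: Mapping[Clade, float] | None,
    key: str,
    label_of,
) -> str:
    if clade.is_leaf:
        s = label_of(clade.labels()[0])
    else:
        parts = [
            _newick_recursive(topo, child, annotations, key, label_of)
            for child in topo.children[clade]
        ]
        s = "(" + ",".join(parts) + ")"
    if annotations is not None and clade in annotations:
        s += f"[&{key}={format(float(annotations[clade]), '.12g')}]"
    return s


def write_tree(
    tree: RootedTopology,
    annotations: Mapping[Clade, float] | None = None,
    key: str = "support",
    label_of=None,
) -> str:
    """Serialize a topology to Newick, optionally with BEAST-style metadata.

    ``annotations`` maps clades of the tree to numbers; each annotated node is
    suffixed with ``[&key=value]``.  The output round-trips through
    :func:`parse_trees` (comments are ignored on input).
    """
    if annotations is not None:
        for clade in annotations:
            if clade not in tree.clades:
                raise ValueError(f"annotation for clade {clade!r} not in tree")
    if label_of is None:
        label_of = _quote_label
    return _newick_recursive(tree, tree.taxa.full_clade, annotations, key, label_of) + ";"


def write_sample(sample: TreeSample, format: str = "nexus") -> str:
    """Serialize a tree sample to a Nexus TREES block (with translate) or
    plain Newick, expanding multiplicities in order."""
    fmt = format.lower()
    expanded: list[RootedTopology] = []
    for topo, mult in sample:
        expanded.extend([topo] * mult)
    if fmt == "newick":
        return "\n".join(t.newick() for t in expanded) + "\n"
    if fmt != "nexus":
        raise ValueError(f"unknown tree format {format!r}")
    labels = sample.taxa.labels
    number = {lab: str(i + 1) for i, lab in enumerate(labels)}
    lines = ["#NEXUS", "", "Begin taxa;", f"\tDimensions ntax={len(labels)};", "\tTaxlabels"]
    lines += [f"\t\t{_quote_label(lab)}" for lab in labels]
    lines += ["\t\t;", "End;", "", "Begin trees;", "\tTranslate"]
    lines += [
        f"\t\t{number[lab]} {_quote_label(lab)}" + ("," if i < len(labels) - 1 else "")
        for i, lab in enumerate(labels)
    ]
    lines.append("\t\t;")
    for i, topo in enumerate(expanded):
        nwk = write_tree(topo, label_of=lambda lab: number[lab])
        lines.append(f"tree STATE_{i} = {nwk}")
    lines += ["End;", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# topology distances


def rf_distance(t1: RootedTopology, t2: RootedTopology) -> float:
    """Rooted Robinson-Foulds distance: half the size of the symmetric
    difference of the two nontrivial clade sets.

    A half-integer; zero iff the topologies have identical clade sets.
    """
    if t1.taxa.labels != t2.taxa.labels:
        raise ValueError("topologies must share the taxon set")
    c1 = {c.bits for c in t1.nontrivial_clades()}
    c2 = {c.bits for c in t2.nontrivial_clades()}
    return len(c1 ^ c2) / 2


def relative_rf(estimate: RootedTopology, truth: RootedTopology) -> float:
    """RF distance normalized by ``n - 2``, the number of nontrivial clades of
    a resolved tree: the fraction of the true tree's clades the estimate got
    wrong.  Requires a resolved truth and at least three taxa."""
    if not truth.resolved:
        raise ValueError("reference tree must be fully resolved")
    n = len(truth.taxa)
    if n < 3:
        raise ValueError("relative RF distance needs at least three taxa")
    return rf_distance(estimate, truth) / (n - 2)
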