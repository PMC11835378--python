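"""Point-estimate topologies summarizing a posterior tree sample.

Four estimators are provided:

* :func:`mcc_tree` -- the sampled tree maximizing the product of Monte Carlo
  clade probabilities (maximum clade credibility; restricted to the sample).
* :func:`greedy_consensus` -- the greedy majority-rule consensus: clades are
  accepted in decreasing frequency when compatible with those already
  accepted; may be unresolved.
* :func:`map_tree` -- the maximum-probability tree of a CCD (any flavor),
  found by dynamic programming over the clade graph.
* :func:`mscc_tree` -- the tree in a CCD0 maximizing the *sum* of clade
  credibilities.

All tie-breaks are deterministic (documented per estimator), so repeated runs
on the same input give byte-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .ccd import (
    CCDGraph,
    CladeFrequencyTable,
    ExtendedCCDGraph,
    _ordered_keys,
    clade_probabilities,
    tally,
)
from .trees import Clade, CladeSplit, RootedTopology, TreeSample

__all__ = [
    "PointEstimate",
    "mcc_tree",
    "greedy_consensus",
    "map_tree",
    "mscc_tree",
    "highest_density_topology",
]


@dataclass(frozen=True)
class PointEstimate:
    """A summary topology with its criterion value and clade supports.

    ``score`` is the value of the estimator's own criterion on ``tree``
    (clade credibility product for MCC, tree probability for MAP, sum of
    clade credibilities for MSCC and greedy consensus); ``support`` maps the
    tree's nontrivial clades to probability annotations.
    """

    tree: RootedTopology
    method: str
    score: float
    support: Mapping[Clade, float]


def _log_clade_credibility(topo: RootedTopology, table: CladeFrequencyTable) -> float:
    return math.fsum(
        math.log(table.clade_count[c] / table.k) for c in topo.nontrivial_clades()
    )


def mcc_tree(sample: TreeSample, table: CladeFrequencyTable | None = None) -> PointEstimate:
    """Maximum clade credibility tree: the *sampled* topology maximizing the
    product of its clades' Monte Carlo probabilities ``f(C)/k`` (trivial
    clades contribute a factor of one and are skipped).

    Ties are broken toward higher multiplicity, then canonical clade-set
    order.
    """
    if table is None:
        table = tally(sample)
    best = None
    for topo, mult in sample:
        log_score = _log_clade_credibility(topo, table)
        key = (-log_score, -mult, topo.canonical_key())
        if best is None or key < best[0]:
            best = (key, topo, log_score)
    _, topo, log_score = best
    support = {c: table.credibility(c) for c in topo.nontrivial_clades()}
    return PointEstimate(topo, "mcc", math.exp(log_score), support)


def greedy_consensus(table: CladeFrequencyTable) -> PointEstimate:
    """Greedy majority-rule consensus tree.

    Nontrivial clades are processed in decreasing frequency and accepted when
    compatible (nested or disjoint) with every clade accepted so far; the
    result may be unresolved.  Ties in frequency are broken toward larger
    clades, then canonical bit order -- a deterministic stand-in for the
    conventional arbitrary tie-break.
    """
    ordered = sorted(
        table.nontrivial_clades(),
        key=lambda c: (-table.clade_count[c], -c.size, c.bits),
    )
    accepted: list[Clade] = []
    for cand in ordered:
        ok = True
        for acc in accepted:
            inter = cand.bits & acc.bits
            if inter and inter != cand.bits and inter != acc.bits:
                ok = False
                break
        if ok:
            accepted.append(cand)
    tree = RootedTopology(table.taxa, accepted)
    support = {c: table.credibility(c) for c in accepted}
    score = math.fsum(support.values())
    return PointEstimate(tree, "greedy-consensus", score, support)


def _backtrack(ccd, choice: dict) -> RootedTopology:
    splits: list[CladeSplit] = []
    stack = [ccd.root_key]
    while stack:
        key = stack.pop()
        entry = choice.get(key)
        if entry is None:
            continue
        split, k1, k2 = entry
        splits.append(split)
        stack.append(k1)
        stack.append(k2)
    return RootedTopology.from_splits(ccd.taxa, splits)


def map_tree(ccd: CCDGraph | ExtendedCCDGraph) -> PointEstimate:
    """The maximum-probability (MAP) tree of a CCD.

    Dynamic program in log space: ``Pr*(leaf) = 1`` and ``Pr*(C)`` is the
    maximum over splits of ``Pr(S | C) Pr*(C1) Pr*(C2)``; ties go to the
    canonical-first split.  The returned score equals the tree's probability
    under the CCD.
    """
    best: dict = {}
    choice: dict = {}
    for key in _ordered_keys(ccd):
        entries = ccd.vertex_splits(key)
        if not entries:
            best[key] = 0.0
            continue
        best_log = -math.inf
        for split, p, k1, k2 in entries:
            if p <= 0.0:
                continue
            cand = math.log(p) + best[k1] + best[k2]
            if cand > best_log:
                best_log = cand
                choice[key] = (split, k1, k2)
        best[key] = best_log
    tree = _backtrack(ccd, choice)
    probs = clade_probabilities(ccd)
    support = {c: probs.get(c, 0.0) for c in tree.nontrivial_clades()}
    return PointEstimate(tree, f"{ccd.flavor}-map", math.exp(best[ccd.root_key]), support)


def mscc_tree(ccd0: CCDGraph) -> PointEstimate:
    """The tree in a CCD0 maximizing the sum of clade credibilities
    ``f(C)/k`` over its nontrivial clades (trivial clades add the same
    constant to every tree and are skipped).

    Requires a CCD0 graph, which carries the clade credibilities; ties go to
    the canonical-first split.
    """
    if not isinstance(ccd0, CCDGraph) or ccd0.flavor != "ccd0" or ccd0.clade_credibility is None:
        raise ValueError("the MSCC tree is defined for CCD0 graphs")
    cred = ccd0.clade_credibility
    best: dict = {}
    choice: dict = {}
    for key in _ordered_keys(ccd0):
        entries = ccd0.vertex_splits(key)
        own = 0.0 if key.is_trivial else cred.get(key, 0.0)
        if not entries:
            best[key] = own
            continue
        best_sum = -math.inf
        for split, _, k1, k2 in entries:
            cand = best[k1] + best[k2]
            if cand > best_sum:
                best_sum = cand
                choice[key] = (split, k1, k2)
        best[key] = own + best_sum
    tree = _backtrack(ccd0, choice)
    probs = clade_probabilities(ccd0)
    support = {c: probs.get(c, 0.0) for c in tree.nontrivial_clades()}
    return PointEstimate(tree, "ccd0-mscc", best[ccd0.root_key], support)


def highest_density_topology(
    topologies: Sequence[RootedTopology], densities: Sequence[float]
) -> RootedTopology:
    """Pass-through estimator: the topology of the sampled state with highest
    posterior density (ties broken by canonical order).  Provided for
    comparison only; it is not part of the recommended estimators."""
    if len(topologies) != len(densities) or not topologies:
        raise ValueError("need one density per topology")
    best = min(zip(topologies, densities), key=lambda td: (-td[1], td[0].canonical_key()))
    return best[0]
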