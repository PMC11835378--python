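"""Accuracy and precision metrics for tree distributions and point
estimators, plus a desk-scale benchmark harness.

All distribution metrics compare an estimated distribution against an
enumerable *golden* reference: the mean absolute error (MAE) of tree
probabilities over the reference support, the mean relative error (MRE) over
a credible set or over clades, the rank of the reference's top tree in the
estimate, and the mean absolute probability difference between two replicate
estimates.  Point-estimator precision is the Robinson-Foulds distance
between the replicate estimates.

The benchmark (:func:`run_benchmark`) emulates the subsampling design of
posterior-summary comparisons: random ground-truth CCDs play the golden
distribution, replicate samples of nested sizes are drawn from each, and
Sample/CCD0/CCD1/CCD2 estimates are scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ccd import (
    SampleDistribution,
    build_ccd0,
    build_ccd1,
    build_ccd2,
    clade_probability,
    count_trees,
    entropy,
    enumerate_trees,
    tally,
    tree_probability,
)
from .estimators import map_tree
from .simulate import random_ccd, synth_posterior
from .trees import RootedTopology, rf_distance

__all__ = [
    "credible_set",
    "mae",
    "mre",
    "top_tree_rank",
    "replicate_precision",
    "point_estimator_precision",
    "BenchmarkConfig",
    "run_benchmark",
    "count_wins",
]

_ENUM_CAP = 10**6


def _support(dist, cap: int = _ENUM_CAP) -> list[tuple[RootedTopology, float]]:
    """Enumerated support of a distribution as (topology, probability)."""
    if isinstance(dist, SampleDistribution):
        return dist.support()
    return enumerate_trees(dist, cap=cap)


def _rank_order(items):
    """Sort (topology, probability) pairs by decreasing probability with
    canonical-order tie-breaking."""
    return sorted(items, key=lambda tp: (-tp[1], tp[0].canonical_key()))


def credible_set(reference, level: float, reference_items=None) -> list[RootedTopology]:
    """The smallest prefix of reference trees, ranked by decreasing
    probability, whose cumulative probability reaches ``level``."""
    if not 0.0 < level <= 1.0:
        raise ValueError("credibility level must lie in (0, 1]")
    items = _rank_order(reference_items if reference_items is not None else _support(reference))
    out: list[RootedTopology] = []
    acc = 0.0
    for topo, p in items:
        out.append(topo)
        acc += p
        if acc >= level - 1e-12:
            break
    return out


def mae(estimate, reference, reference_items=None) -> float:
    """Mean absolute difference of tree probabilities over the trees of the
    reference distribution."""
    items = reference_items if reference_items is not None else _support(reference)
    if not items:
        raise ValueError("empty reference distribution")
    return float(
        np.mean([abs(tree_probability(estimate, t) - p) for t, p in items])
    )


def mre(estimate, reference, subset=0.95, reference_items=None) -> float:
    """Mean relative error of tree (or clade) probabilities.

    ``subset`` is either a credibility level -- the error is averaged over
    the reference's credible set at that level -- or ``"clades"``, in which
    case it is averaged over all clades of the reference distribution using
    clade probabilities on both sides.
    """
    if subset == "clades":
        if isinstance(reference, SampleDistribution):
            ref_clades = {
                c: reference.clade_probability(c)
                for topo, _ in reference.support()
                for c in topo.clades
            }
        else:
            ref_clades = {
                c: clade_probability(reference, c) for c in reference.clades
            }
        errs = [
            abs(clade_probability(estimate, c) - p) / p
            for c, p in sorted(ref_clades.items(), key=lambda cp: cp[0].bits)
            if p > 0
        ]
        return float(np.mean(errs))
    items = reference_items if reference_items is not None else _support(reference)
    probs = dict(items)
    chosen = credible_set(reference, float(subset), reference_items=items)
    errs = [
        abs(tree_probability(estimate, t) - probs[t]) / probs[t] for t in chosen
    ]
    return float(np.mean(errs))


def top_tree_rank(estimate, reference, reference_items=None, cap: int = _ENUM_CAP) -> int:
    """1-based rank of the reference's most probable tree within the
    estimate's probability ordering (ties by canonical order).

    If the estimate's support is too large to enumerate, the rank is computed
    within a candidate pool: the reference support plus the estimate's MAP
    tree.
    """
    items = reference_items if reference_items is not None else _support(reference)
    top = _rank_order(items)[0][0]
    if isinstance(estimate, SampleDistribution):
        est_items = estimate.support()
    elif count_trees(estimate) <= cap:
        est_items = enumerate_trees(estimate, cap=cap)
    else:
        pool = {t for t, _ in items}
        pool.add(map_tree(estimate).tree)
        est_items = [(t, tree_probability(estimate, t)) for t in pool]
    p_top = tree_probability(estimate, top)
    key_top = (-p_top, top.canonical_key())
    rank = 1
    seen = False
    for topo, p in est_items:
        if topo == top:
            seen = True
            continue
        if (-p, topo.canonical_key()) < key_top:
            rank += 1
    if not seen and p_top == 0.0:
        rank = len(est_items) + 1
    return rank


def replicate_precision(est_a, est_b) -> float:
    """Mean absolute difference of tree probabilities between two replicate
    distributions, over the union of their supports."""
    sup_a = dict(_support(est_a))
    sup_b = dict(_support(est_b))
    union = sorted(set(sup_a) | set(sup_b), key=lambda t: t.canonical_key())
    if not union:
        return 0.0
    return float(
        np.mean([abs(sup_a.get(t, 0.0) - sup_b.get(t, 0.0)) for t in union])
    )


def point_estimator_precision(tree_a: RootedTopology, tree_b: RootedTopology) -> float:
    """RF distance between the point estimates of two replicates."""
    return rf_distance(tree_a, tree_b)


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of a desk-scale accuracy/precision benchmark.

    The golden reference for each simulated dataset is the generating CCD
    itself (the exact truth), not a mega-sample.  ``entropy_bins`` > 1 splits
    datasets into that many quantile bins of golden-distribution entropy.
    """

    n_datasets: int = 3
    n_taxa: int = 6
    sizes: tuple[int, ...] = (3, 10, 30)
    replicates: int = 2
    seed: int = 0
    concentration: float = 1.0
    pool_size: int = 4
    display_cap: int = 20000
    levels: tuple[float, ...] = (0.5, 0.95)
    labels: tuple[str, ...] = ("sample", "ccd0", "ccd1", "ccd2")
    entropy_bins: int = 0

    def __post_init__(self):
        if self.n_datasets < 1 or self.replicates < 1:
            raise ValueError("need at least one dataset and one replicate")
        if not self.sizes or min(self.sizes) < 1:
            raise ValueError("invalid subsample size grid")
        bad = set(self.labels) - {"sample", "ccd0", "ccd1", "ccd2"}
        if bad:
            raise ValueError(f"unknown distribution labels: {sorted(bad)}")

    @classmethod
    def from_file(cls, path) -> "BenchmarkConfig":
        """Read a flat ``key=value`` configuration file (one pair per line,
        ``#`` comments; tuple values comma-separated)."""
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key in ("sizes",):
                kwargs[key] = tuple(int(v) for v in value.split(","))
            elif key in ("levels",):
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("labels",):
                kwargs[key] = tuple(v.strip() for v in value.split(","))
            elif key in ("concentration",):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
        return cls(**kwargs)


def _build_distributions(sample, labels):
    out = {}
    table = None
    if {"ccd0", "ccd1"} & set(labels):
        table = tally(sample)
    if "sample" in labels:
        out["sample"] = SampleDistribution(sample)
    if "ccd0" in labels:
        out["ccd0"] = build_ccd0(table)
    if "ccd1" in labels:
        out["ccd1"] = build_ccd1(table)
    if "ccd2" in labels:
        out["ccd2"] = build_ccd2(sample)
    return out


def run_benchmark(config: BenchmarkConfig | str | Path) -> pd.DataFrame:
    """Run the benchmark and return a tidy report table.

    One row per (dataset, size, replicate, distribution label, metric); the
    precision metric compares replicates 0 and 1 and is stored with
    ``replicate = "0-1"``.  Deterministic for a fixed config and seed.
    """
    if not isinstance(config, BenchmarkConfig):
        config = BenchmarkConfig.from_file(config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_datasets)
    rows = []

    def add(dataset, h, size, replicate, label, metric, value):
        rows.append(
            {
                "dataset": dataset,
                "entropy": h,
                "size": size,
                "replicate": replicate,
                "label": label,
                "metric": metric,
                "value": float(value),
            }
        )

    for d in range(config.n_datasets):
        rng = np.random.default_rng(seeds[d])
        truth = random_ccd(
            config.n_taxa,
            rng,
            concentration=config.concentration,
            pool_size=config.pool_size,
            display_cap=config.display_cap,
        )
        golden_items = enumerate_trees(truth, cap=config.display_cap)
        h, _ = entropy(truth)
        replicates = synth_posterior(truth, config.sizes, config.replicates, rng)
        built = []
        for r, per_size in enumerate(replicates):
            by_size = {}
            for size in sorted(config.sizes):
                dists = _build_distributions(per_size[size], config.labels)
                by_size[size] = dists
                for label, dist in dists.items():
                    add(d, h, size, str(r), label, "mae",
                        mae(dist, truth, reference_items=golden_items))
                    for level in config.levels:
                        add(d, h, size, str(r), label, f"mre_{int(level * 100)}",
                            mre(dist, truth, subset=level, reference_items=golden_items))
                    add(d, h, size, str(r), label, "mre_clades",
                        mre(dist, truth, subset="clades"))
                    add(d, h, size, str(r), label, "top_rank",
                        top_tree_rank(dist, truth, reference_items=golden_items))
            built.append(by_size)
        if config.replicates >= 2:
            for size in sorted(config.sizes):
                for label in config.labels:
                    add(d, h, size, "0-1", label, "precision",
                        replicate_precision(built[0][size][label], built[1][size][label]))
    report = pd.DataFrame(rows)
    if config.entropy_bins > 1:
        ent = report.groupby("dataset")["entropy"].first()
        bins = pd.qcut(ent, q=config.entropy_bins, labels=False, duplicates="drop")
        report["entropy_bin"] = report["dataset"].map(bins)
    return report


def count_wins(report: pd.DataFrame, metric: str = "mae") -> pd.DataFrame:
    """Tally how often each distribution label achieves the best (lowest)
    value of ``metric`` per (dataset, size, replicate) cell.

    Returns a table of win counts per size and label (and entropy bin when
    present).  Ties go to the first label in sorted order, deterministically.
    """
    sub = report[report["metric"] == metric]
    group_cols = ["dataset", "size", "replicate"]
    winners = (
        sub.sort_values(["value", "label"])
        .groupby(group_cols, as_index=False)
        .first()
    )
    keys = ["size", "label"]
    if "entropy_bin" in report.columns:
        keys = ["entropy_bin"] + keys
    wins = winners.groupby(keys).size().reset_index(name="wins")
    return wins
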