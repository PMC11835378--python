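"""Distribution metrics and the benchmark harness."""

import pytest

from ccdtree import (
    BenchmarkConfig,
    SampleDistribution,
    build_ccd1,
    count_wins,
    credible_set,
    mae,
    mre,
    point_estimator_precision,
    replicate_precision,
    run_benchmark,
    tally,
    top_tree_rank,
)
from ccdtree.trees import TreeSample
from conftest import sample_from


@pytest.fixture(scope="module")
def seven_tree_pair(seven_tree_sample):
    """The sample distribution and its induced CCD1 on the worked example."""
    table = tally(seven_tree_sample)
    return SampleDistribution(seven_tree_sample), build_ccd1(table)


def _weighted_sample(weighted_newicks):
    topos = []
    for nwk, mult in weighted_newicks:
        topo = sample_from([nwk]).topologies[0][0]
        topos.append((topo, mult))
    return SampleDistribution(TreeSample(topos[0][0].taxa, topos))


class TestCredibleSet:
    def test_majority_tree_alone_at_half(self):
        dist = _weighted_sample([("((A,B),C);", 6), ("((A,C),B);", 3), ("((B,C),A);", 1)])
        assert len(credible_set(dist, 0.5)) == 1

    def test_level_95_forces_all_three(self):
        dist = _weighted_sample([("((A,B),C);", 6), ("((A,C),B);", 3), ("((B,C),A);", 1)])
        assert len(credible_set(dist, 0.95)) == 3

    def test_worked_example_ccd1_needs_three_trees_for_half(self, seven_tree_pair):
        _, ccd1 = seven_tree_pair
        chosen = credible_set(ccd1, 0.5)
        assert len(chosen) == 3  # 12/49 + 9/49 + 8/49 = 29/49 >= 1/2
        assert chosen[0] == sample_from(["((A,(B,C)),(D,E));"]).topologies[0][0]

    def test_invalid_level_rejected(self, seven_tree_pair):
        with pytest.raises(ValueError):
            credible_set(seven_tree_pair[0], 0.0)


class TestMAE:
    def test_zero_for_identical(self, seven_tree_pair):
        ref, _ = seven_tree_pair
        assert mae(ref, ref) == 0.0

    def test_hand_example(self):
        ref = _weighted_sample([("((A,B),C);", 1), ("((A,C),B);", 1)])
        est = _weighted_sample([("((A,B),C);", 1)])
        assert mae(est, ref) == pytest.approx(0.5)

    def test_seven_tree_sample_vs_ccd1(self, seven_tree_pair):
        ref, ccd1 = seven_tree_pair
        # mean(|9/49 - 3/7|, |8/49 - 2/7|, |8/49 - 2/7|) = 8/49
        assert mae(ccd1, ref) == pytest.approx(8 / 49, abs=1e-12)

    def test_bounded_by_one(self, seven_tree_pair):
        ref, ccd1 = seven_tree_pair
        assert mae(ccd1, ref) <= 1.0


class TestMRE:
    def test_zero_for_identical(self, seven_tree_pair):
        ref, _ = seven_tree_pair
        assert mre(ref, ref, subset=0.95) == 0.0

    def test_hand_example_at_half(self):
        ref = _weighted_sample([("((A,B),C);", 8), ("((A,C),B);", 2)])
        est = _weighted_sample([("((A,B),C);", 4), ("((A,C),B);", 6)])
        # credible set at 0.5 = {top tree}; |0.4 - 0.8| / 0.8 = 0.5
        assert mre(est, ref, subset=0.5) == pytest.approx(0.5)

    def test_clade_mode_zero_for_ccd1_vs_source(self, seven_tree_pair):
        ref, ccd1 = seven_tree_pair
        # CCD1 clade probabilities equal the Monte Carlo ones
        assert mre(ccd1, ref, subset="clades") == pytest.approx(0.0, abs=1e-12)


class TestTopTreeRank:
    def test_identical_distributions_rank_one(self, seven_tree_pair):
        ref, _ = seven_tree_pair
        assert top_tree_rank(ref, ref) == 1

    def test_simple_inversion(self):
        ref = _weighted_sample([("((A,B),C);", 2), ("((A,C),B);", 1)])
        est = _weighted_sample([("((A,B),C);", 2), ("((A,C),B);", 3)])
        assert top_tree_rank(est, ref) == 2

    def test_worked_example_ccd1_ranks_sample_top_second(self, seven_tree_pair):
        ref, ccd1 = seven_tree_pair
        assert top_tree_rank(ccd1, ref) == 2


class TestPrecision:
    def test_identical_estimates(self, seven_tree_pair):
        ref, ccd1 = seven_tree_pair
        assert replicate_precision(ccd1, ccd1) == 0.0

    def test_disjoint_supports(self):
        a = _weighted_sample([("((A,B),C);", 1)])
        b = _weighted_sample([("((A,C),B);", 1)])
        assert replicate_precision(a, b) == pytest.approx(1.0)

    def test_matches_direct_summation(self, seven_tree_sample):
        first = TreeSample(seven_tree_sample.taxa, list(seven_tree_sample)[:2])
        second = TreeSample(seven_tree_sample.taxa, list(seven_tree_sample)[1:])
        da = build_ccd1(tally(first))
        db = build_ccd1(tally(second))
        value = replicate_precision(da, db)
        from ccdtree import enumerate_trees

        sup_a = dict(enumerate_trees(da))
        sup_b = dict(enumerate_trees(db))
        union = set(sup_a) | set(sup_b)
        direct = sum(abs(sup_a.get(t, 0.0) - sup_b.get(t, 0.0)) for t in union) / len(union)
        assert value == pytest.approx(direct, abs=1e-15)

    def test_point_estimator_precision_is_rf(self):
        a = sample_from(["(((A,B),C),(D,E));"]).topologies[0][0]
        b = sample_from(["(((A,(B,C)),D),E);"]).topologies[0][0]
        assert point_estimator_precision(a, b) == 2.0


class TestBenchmark:
    def test_row_count_arithmetic(self):
        config = BenchmarkConfig(
            n_datasets=2, n_taxa=5, sizes=(3, 10), replicates=2, seed=42,
            pool_size=3, display_cap=5000,
        )
        report = run_benchmark(config)
        per_cell = 5  # mae, mre_50, mre_95, mre_clades, top_rank
        accuracy_rows = 2 * 2 * 2 * 4 * per_cell
        precision_rows = 2 * 2 * 4
        assert len(report) == accuracy_rows + precision_rows
        assert set(report["label"]) == {"sample", "ccd0", "ccd1", "ccd2"}

    def test_deterministic_under_seed(self):
        config = BenchmarkConfig(
            n_datasets=1, n_taxa=5, sizes=(3,), replicates=2, seed=7,
            pool_size=3, display_cap=5000,
        )
        a = run_benchmark(config)
        b = run_benchmark(config)
        assert a.equals(b)

    def test_mae_shrinks_with_sample_size(self):
        """Consistency: CCD1 rebuilt from larger samples of a CCD1 truth gets
        closer to it (averaged over seeded datasets)."""
        config = BenchmarkConfig(
            n_datasets=8, n_taxa=6, sizes=(5, 80), replicates=1, seed=1234,
            pool_size=3, display_cap=5000, labels=("ccd1",),
        )
        report = run_benchmark(config)
        sub = report[report["metric"] == "mae"]
        means = sub.groupby("size")["value"].mean()
        assert means[80] < means[5]

    def test_config_file_roundtrip(self, tmp_path):
        path = tmp_path / "bench.cfg"
        path.write_text(
            "n_datasets = 2\nn_taxa = 5\nsizes = 3,10\nreplicates = 2\n"
            "seed = 9\npool_size = 3\ndisplay_cap = 4000\n# comment\n"
        )
        config = BenchmarkConfig.from_file(path)
        assert config.sizes == (3, 10) and config.seed == 9

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkConfig(sizes=())
        with pytest.raises(ValueError):
            BenchmarkConfig(labels=("sample", "bogus"))

    def test_win_counting(self):
        config = BenchmarkConfig(
            n_datasets=2, n_taxa=5, sizes=(3,), replicates=1, seed=2,
            pool_size=3, display_cap=5000,
        )
        report = run_benchmark(config)
        wins = count_wins(report, metric="mae")
        assert wins["wins"].sum() == 2  # one winner per dataset cell
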