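"""CCD construction, distribution queries, and the enumeration oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from ccdtree import (
    CladeSplit,
    SampleDistribution,
    build_ccd0,
    build_ccd1,
    build_ccd2,
    clade_probability,
    count_trees,
    detect_outliers,
    entropy,
    enumerate_trees,
    expand_splits,
    load_ccd,
    random_ccd,
    sample_tree,
    save_ccd,
    synth_posterior,
    tally,
    tree_probability,
)
from conftest import sample_from


class TestTally:
    def test_seven_tree_split_and_clade_counts(self, seven_tree_sample, seven_tree_table):
        taxa = seven_tree_sample.taxa
        counts = {
            ("ABC", "DE"): 3,
            ("ABCD", "E"): 2,
            ("ABCE", "D"): 2,
            ("AB", "C"): 3,
            ("A", "BC"): 4,
        }
        for (a, b), expected in counts.items():
            split = CladeSplit(taxa.clade(a), taxa.clade(b))
            assert seven_tree_table.split_count[split] == expected
        assert seven_tree_table.clade_count[taxa.clade("ABC")] == 7
        assert seven_tree_table.k == 7

    def test_single_tree_counts_equal_k(self):
        sample = sample_from(["((A,B),C);"] * 5)
        table = tally(sample)
        assert set(table.clade_count.values()) == {5}
        assert set(table.split_count.values()) == {5}

    def test_invariants_hold_on_random_samples(self):
        rng = np.random.default_rng(7)
        truth = random_ccd(6, rng, pool_size=3)
        for per_size in synth_posterior(truth, [12], 3, rng):
            tally(per_size[12]).validate()  # raises on violation


class TestCCD1:
    def test_worked_example_conditional_probabilities(self, seven_tree_sample, seven_tree_table):
        taxa = seven_tree_sample.taxa
        ccd1 = build_ccd1(seven_tree_table)
        assert ccd1.split_probability(
            CladeSplit(taxa.clade("ABC"), taxa.clade("DE"))
        ) == pytest.approx(3 / 7, abs=1e-15)
        assert ccd1.split_probability(
            CladeSplit(taxa.clade("A"), taxa.clade("BC"))
        ) == pytest.approx(4 / 7, abs=1e-15)

    def test_cherry_split_is_deterministic(self, seven_tree_table):
        taxa = seven_tree_table.taxa
        ccd1 = build_ccd1(seven_tree_table)
        (split, p), = ccd1.splits_of(taxa.clade("AB"))
        assert p == 1.0

    def test_worked_example_tree_probabilities(self, seven_tree_sample, seven_tree_table):
        ccd1 = build_ccd1(seven_tree_table)
        sampled = {topo: mult for topo, mult in seven_tree_sample}
        probs = sorted(
            tree_probability(ccd1, t) for t in sampled
        )
        assert probs == pytest.approx([8 / 49, 8 / 49, 9 / 49], abs=1e-12)
        u1 = sample_from(["((A,(B,C)),(D,E));"]).topologies[0][0]
        assert tree_probability(ccd1, u1) == pytest.approx(12 / 49, abs=1e-12)

    def test_undisplayed_tree_has_probability_zero(self, seven_tree_table):
        ccd1 = build_ccd1(seven_tree_table)
        absent = sample_from(["((((A,C),B),D),E);"]).topologies[0][0]
        assert tree_probability(ccd1, absent) == 0.0

    def test_worked_example_tree_count_is_six(self, seven_tree_table):
        ccd1 = build_ccd1(seven_tree_table)
        assert count_trees(ccd1) == 6
        assert len(enumerate_trees(ccd1)) == 6


class TestCCD0:
    def test_worked_example_ccd0_matches_ccd1(self, seven_tree_table):
        """On the worked example the expansion adds nothing and the two
        parametrizations display the same six probabilities."""
        assert expand_splits(seven_tree_table) == set(seven_tree_table.split_count)
        probs0 = {t: p for t, p in enumerate_trees(build_ccd0(seven_tree_table))}
        probs1 = {t: p for t, p in enumerate_trees(build_ccd1(seven_tree_table))}
        assert set(probs0) == set(probs1)
        for t in probs0:
            assert probs0[t] == pytest.approx(probs1[t], abs=1e-12)

    def test_expansion_adds_unobserved_split(self, expansion_table):
        taxa = expansion_table.taxa
        unobserved = CladeSplit(taxa.clade("AB"), taxa.clade("CD"))
        assert unobserved not in expansion_table.split_count
        assert unobserved in expand_splits(expansion_table)

    def test_single_tree_expansion_is_its_own_splits(self):
        table = tally(sample_from(["(((A,B),C),D);"] * 3))
        assert expand_splits(table) == set(table.split_count)

    def test_proportional_to_clade_credibility_product(self, expansion_table):
        ccd0 = build_ccd0(expansion_table)
        items = enumerate_trees(ccd0)
        ratios = [
            p / math.prod(expansion_table.credibility(c) for c in t.nontrivial_clades())
            for t, p in items
        ]
        assert max(ratios) - min(ratios) < 1e-12 * max(ratios)
        assert sum(p for _, p in items) == pytest.approx(1.0, abs=1e-12)

    def test_single_tree_sample_is_deterministic(self):
        table = tally(sample_from(["(((A,B),C),D);"] * 3))
        ccd0 = build_ccd0(table)
        (tree, p), = enumerate_trees(ccd0)
        assert p == pytest.approx(1.0, abs=1e-15)


class TestCCD2:
    def test_worked_example_displays_only_sampled_trees(self, seven_tree_sample):
        ccd2 = build_ccd2(seven_tree_sample)
        displayed = {t for t, _ in enumerate_trees(ccd2)}
        assert displayed == {t for t, _ in seven_tree_sample}

    def test_worked_example_probabilities_are_monte_carlo(self, seven_tree_sample):
        ccd2 = build_ccd2(seven_tree_sample)
        for topo, mult in seven_tree_sample:
            assert tree_probability(ccd2, topo) == pytest.approx(mult / 7, abs=1e-12)

    def test_single_tree_sample(self):
        sample = sample_from(["(((A,B),C),D);"] * 2)
        ccd2 = build_ccd2(sample)
        assert count_trees(ccd2) == 1
        assert tree_probability(ccd2, sample.topologies[0][0]) == pytest.approx(1.0)

    def test_containment_chain(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            truth = random_ccd(6, rng, pool_size=3)
            sample = synth_posterior(truth, [15], 1, rng)[0][15]
            table = tally(sample)
            trees2 = {t for t, _ in enumerate_trees(build_ccd2(sample))}
            trees1 = {t for t, _ in enumerate_trees(build_ccd1(table))}
            trees0 = {t for t, _ in enumerate_trees(build_ccd0(table))}
            assert trees2 <= trees1 <= trees0


class TestQueries:
    def test_entropy_uniform_and_deterministic(self):
        det = build_ccd1(tally(sample_from(["((A,B),C);"] * 4)))
        h, ne = entropy(det)
        assert h == 0.0 and ne == 1.0
        # two equiprobable root splits -> uniform over 2 trees
        uni = build_ccd1(tally(sample_from(["((A,B),C);", "((A,C),B);"])))
        h, ne = entropy(uni)
        assert h == pytest.approx(math.log(2), abs=1e-12)
        assert ne == pytest.approx(2.0, abs=1e-12)

    def test_entropy_matches_enumeration(self, seven_tree_table):
        ccd1 = build_ccd1(seven_tree_table)
        h, _ = entropy(ccd1)
        oracle = -sum(p * math.log(p) for _, p in enumerate_trees(ccd1))
        assert h == pytest.approx(oracle, abs=1e-12)

    def test_clade_probability_theorem_on_worked_example(self, seven_tree_table):
        taxa = seven_tree_table.taxa
        ccd1 = build_ccd1(seven_tree_table)
        assert clade_probability(ccd1, taxa.clade("ABC")) == pytest.approx(1.0, abs=1e-12)
        assert clade_probability(ccd1, taxa.clade("AB")) == pytest.approx(3 / 7, abs=1e-12)
        assert clade_probability(ccd1, taxa.clade("A")) == pytest.approx(1.0, abs=1e-12)
        assert clade_probability(ccd1, taxa.clade("AD")) == 0.0

    def test_sampling_deterministic_ccd(self):
        ccd = build_ccd1(tally(sample_from(["(((A,B),C),D);"] * 2)))
        rng = np.random.default_rng(0)
        draws = {sample_tree(ccd, rng) for _ in range(10)}
        assert len(draws) == 1

    def test_sampling_matches_probabilities(self, seven_tree_table):
        """Chi-square goodness of fit of sampled frequencies against the six
        enumerated tree probabilities."""
        ccd1 = build_ccd1(seven_tree_table)
        items = enumerate_trees(ccd1)
        rng = np.random.default_rng(20240101)
        n = 4000
        counts = {t: 0 for t, _ in items}
        for _ in range(n):
            counts[sample_tree(ccd1, rng)] += 1
        observed = [counts[t] for t, _ in items]
        expected = [p * n for _, p in items]
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_seeded_sampling_is_reproducible(self, seven_tree_table):
        ccd1 = build_ccd1(seven_tree_table)
        a = [sample_tree(ccd1, np.random.default_rng(5)) for _ in range(1)]
        b = [sample_tree(ccd1, np.random.default_rng(5)) for _ in range(1)]
        assert a == b


class TestSampleDistribution:
    def test_probabilities_and_support(self, seven_tree_sample):
        dist = SampleDistribution(seven_tree_sample)
        total = sum(p for _, p in dist.support())
        assert total == pytest.approx(1.0, abs=1e-15)
        top = max(dist.support(), key=lambda tp: tp[1])
        assert top[1] == pytest.approx(3 / 7)
        absent = sample_from(["((A,(B,C)),(D,E));"]).topologies[0][0]
        assert dist.probability(absent) == 0.0


class TestOutliers:
    def test_isolated_minority_topology_flagged(self):
        sample = sample_from(
            ["((((A,B),C),D),E);"] * 9 + ["(((C,(D,E)),B),A);"]
        )
        table = tally(sample)
        flags = detect_outliers(sample, table)
        assert len(flags) == 1
        flag = flags[0]
        assert flag.isolated and flag.multiplicity == 1
        assert flag.once_clades  # every clade of the outlier is once-observed
        ccd1 = build_ccd1(table)
        assert tree_probability(ccd1, flag.topology) == pytest.approx(1 / 10, abs=1e-12)

    def test_homogeneous_sample_unflagged(self):
        sample = sample_from(["((A,B),C);"] * 6)
        assert detect_outliers(sample, tally(sample)) == []

    def test_worked_example_unflagged(self, seven_tree_sample, seven_tree_table):
        assert detect_outliers(seven_tree_sample, seven_tree_table) == []


class TestSerialization:
    @pytest.mark.parametrize("flavor", ["ccd0", "ccd1", "ccd2"])
    def test_roundtrip_preserves_distribution(self, seven_tree_sample, seven_tree_table, tmp_path, flavor):
        if flavor == "ccd0":
            ccd = build_ccd0(seven_tree_table)
        elif flavor == "ccd1":
            ccd = build_ccd1(seven_tree_table)
        else:
            ccd = build_ccd2(seven_tree_sample)
        path = tmp_path / "graph.jsonl"
        save_ccd(ccd, path)
        loaded = load_ccd(path)
        orig = {t: p for t, p in enumerate_trees(ccd)}
        back = {t: p for t, p in enumerate_trees(loaded)}
        assert set(orig) == set(back)
        for t in orig:
            assert orig[t] == back[t]  # json round-trips floats exactly
        if flavor == "ccd0":
            est_orig = sorted((c.bits, v) for c, v in ccd.clade_credibility.items() if not c.is_trivial)
            est_back = sorted((c.bits, v) for c, v in loaded.clade_credibility.items())
            # loader only sees non-leaf entries; compare the shared clades
            shared = dict(est_back)
            for bits, v in est_orig:
                if bits in shared:
                    assert shared[bits] == v
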