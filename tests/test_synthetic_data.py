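import numpy as np
import pytest
from scipy.stats import chisquare

from modelbench import (
    PhyloTree,
    SimulationConfig,
    benchmark_suite,
    random_tree,
    simulate_alignment,
    transition_matrix,
)
from modelbench.exceptions import InvalidInputError
from modelbench.model_space import build_rate_matrix, list_models


class TestRandomTree:
    def test_tip_and_edge_counts(self):
        tree = random_tree(5, seed=1)
        assert tree.n_tips == 5
        assert tree.n_edges == 7

    def test_seeded_runs_are_identical(self):
        a = random_tree(30, seed=42).to_newick()
        b = random_tree(30, seed=42).to_newick()
        assert a == b

    def test_different_seeds_differ(self):
        assert random_tree(30, seed=1).to_newick() != random_tree(30, seed=2).to_newick()

    def test_total_length_concentrates_around_exponential_mean(self):
        # 197 iid exp(0.1) lengths: mean 19.7, sd sqrt(197)*0.1 ~ 1.40
        tree = random_tree(100, branch_length_mean=0.1, seed=3)
        assert abs(tree.total_length - 19.7) < 4 * np.sqrt(197) * 0.1

    def test_too_few_taxa_rejected(self):
        with pytest.raises(InvalidInputError):
            random_tree(2)


class TestSimulateAlignment:
    def test_zero_branch_lengths_copy_root_state(self):
        tree = random_tree(6, seed=0)
        tree.lengths[:] = 0.0
        cfg = SimulationConfig(model="JC", n_taxa=6, n_sites=40, seed=5)
        aln = simulate_alignment(tree, cfg)
        assert all(np.array_equal(aln.codes[0], aln.codes[i]) for i in range(6))

    def test_output_shape(self):
        tree = random_tree(8, seed=2)
        cfg = SimulationConfig(model="HKY+G", n_taxa=8, n_sites=123, seed=2,
                               exchangeabilities=[3.0],
                               freqs=[0.3, 0.2, 0.3, 0.2], alpha=0.8)
        aln = simulate_alignment(tree, cfg)
        assert (aln.n_taxa, aln.n_sites) == (8, 123)
        assert aln.provenance["model"] == "HKY+G"

    def test_jc_base_frequencies_near_uniform(self):
        tree = random_tree(5, seed=9)
        cfg = SimulationConfig(model="JC", n_taxa=5, n_sites=10_000, seed=9)
        aln = simulate_alignment(tree, cfg)
        freqs = aln.base_frequencies()
        assert np.all((freqs > 0.23) & (freqs < 0.27))

    def test_seeded_simulation_is_bit_identical(self):
        tree = random_tree(6, seed=4)
        cfg = SimulationConfig(model="K80+I", n_taxa=6, n_sites=200, seed=11,
                               exchangeabilities=[4.0], p_inv=0.3)
        a = simulate_alignment(tree, cfg)
        b = simulate_alignment(tree, cfg)
        assert np.array_equal(a.codes, b.codes)

    def test_heterogeneity_flag_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            SimulationConfig(model="JC", alpha=0.5)  # alpha without +G
        with pytest.raises(InvalidInputError):
            SimulationConfig(model="JC+I", p_inv=None)

    def test_invariant_fraction_exceeds_p_inv(self):
        tree = random_tree(8, branch_length_mean=0.3, seed=6)
        cfg = SimulationConfig(model="JC+I", n_taxa=8, n_sites=20_000, seed=6,
                               p_inv=0.5)
        aln = simulate_alignment(tree, cfg)
        constant = np.all(aln.codes == aln.codes[0], axis=0).mean()
        assert constant > 0.5

    def test_tip_pair_joint_distribution_matches_transition_probabilities(self):
        """Empirical joint tip-state frequencies converge to the
        stationary-weighted transition matrix over the connecting path."""
        tree = PhyloTree(["a", "b", "c"], [3, 3, 3, -1], [0.15, 0.25, 0.1, 0.0])
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        rm = build_rate_matrix("HKY", [3.0], pi)
        cfg = SimulationConfig(model="HKY", n_taxa=3, n_sites=50_000, seed=13,
                               exchangeabilities=[3.0], freqs=pi)
        aln = simulate_alignment(tree, cfg)
        # reversibility: joint of (a, b) = pi_x P_xy(t_a + t_b)
        P = transition_matrix(rm, 0.4)
        expected = (rm.pi[:, None] * P) * aln.n_sites
        observed = np.zeros((4, 4))
        np.add.at(observed, (aln.codes[0], aln.codes[1]), 1)
        stat = chisquare(observed.ravel(), expected.ravel())
        assert stat.pvalue > 0.01


class TestBenchmarkSuite:
    def test_scaled_suite_covers_registry(self):
        suite = benchmark_suite(6, 60, seed=1)
        assert len(suite) == 88
        names = {truth.model.name for _, truth in suite}
        assert names == {m.name for m in list_models()}
        for aln, truth in suite:
            assert aln.codes.shape == (6, 60)
            assert aln.provenance["model"] == truth.model.name

    def test_subset_and_determinism(self):
        one = benchmark_suite(5, 100, seed=2, models=["HKY+G"])
        two = benchmark_suite(5, 100, seed=2, models=["HKY+G"])
        assert len(one) == 1
        assert np.array_equal(one[0][0].codes, two[0][0].codes)
        assert one[0][1].tree.to_newick() == two[0][1].tree.to_newick()

    def test_per_dataset_substream_is_independent_of_subset(self):
        # the HKY+G dataset is identical whether simulated alone or
        # as part of a larger subset (substream = seed + rank)
        alone = benchmark_suite(5, 80, seed=3, models=["HKY+G"])[0][0]
        with_others = {
            t.model.name: a
            for a, t in benchmark_suite(5, 80, seed=3, models=["JC", "HKY+G", "GTR"])
        }["HKY+G"]
        assert np.array_equal(alone.codes, with_others.codes)
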