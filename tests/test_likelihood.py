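import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chi2 as chi2_dist
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest

from modelbench import (
    Alignment,
    LikelihoodEngine,
    PhyloTree,
    SimulationConfig,
    compress_patterns,
    discrete_gamma_rates,
    fit_model,
    log_likelihood,
    nj_tree,
    random_tree,
    simulate_alignment,
    transition_matrix,
)
from modelbench.exceptions import InvalidInputError
from modelbench.model_space import build_rate_matrix, get_model
from modelbench.synthetic_data import draw_model_params
from tests.conftest import brute_force_lnl


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        rm = build_rate_matrix("GTR", [1, 2, 3, 4, 5, 1], [0.1, 0.2, 0.3, 0.4])
        assert np.allclose(transition_matrix(rm, 0.0), np.eye(4), atol=1e-12)

    def test_jc_closed_form_at_t_01(self):
        rm = build_rate_matrix("JC")
        P = transition_matrix(rm, 0.1)
        assert P[0, 0] == pytest.approx(0.25 + 0.75 * math.exp(-0.4 / 3), abs=1e-10)

    @pytest.mark.parametrize("t", [0.0, 0.01, 0.5, 3.0, 50.0])
    def test_rows_are_stochastic(self, t):
        rm = build_rate_matrix("TrN", [2.0, 5.0, 1.0], [0.4, 0.3, 0.2, 0.1])
        P = transition_matrix(rm, t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((P >= 0) & (P <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            transition_matrix(build_rate_matrix("JC"), -0.1)


class TestDiscreteGamma:
    def test_category_means_match_numerical_integration(self):
        alpha, n_cat = 0.5, 4
        rates = discrete_gamma_rates(alpha, n_cat)
        # independent oracle: conditional means by direct quadrature
        edges = [0.0] + list(
            gamma_dist.ppf(np.arange(1, n_cat) / n_cat, alpha, scale=1 / alpha)
        ) + [np.inf]
        for k in range(n_cat):
            num, _ = quad(
                lambda x: x * gamma_dist.pdf(x, alpha, scale=1 / alpha),
                edges[k], edges[k + 1],
            )
            assert rates[k] == pytest.approx(num * n_cat, rel=1e-6)

    @pytest.mark.parametrize("alpha", [0.05, 0.3, 1.0, 5.0, 50.0])
    def test_mean_one_and_increasing(self, alpha):
        rates = discrete_gamma_rates(alpha)
        assert rates.mean() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(rates) > 0)

    def test_huge_alpha_collapses_to_point_mass(self):
        assert np.allclose(discrete_gamma_rates(1e6), 1.0, atol=1e-2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            discrete_gamma_rates(0.0)
        with pytest.raises(InvalidInputError):
            discrete_gamma_rates(1.0, 0)


class TestPatternCompression:
    def test_identical_columns_collapse(self):
        aln = Alignment.from_strings(["a", "b"], ["AAA", "CCC"])
        pt = compress_patterns(aln)
        assert pt.n_patterns == 1
        assert pt.weights.tolist() == [3.0]

    def test_distinct_columns_keep_weight_one(self):
        aln = Alignment.from_strings(["a", "b"], ["ACGT", "CGTA"])
        pt = compress_patterns(aln)
        assert pt.n_patterns == 4
        assert np.all(pt.weights == 1)

    def test_weights_conserve_sites_and_order_first_occurrence(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 5, size=(4, 300)).astype(np.uint8)
        aln = Alignment(["a", "b", "c", "d"], codes)
        pt = compress_patterns(aln)
        assert pt.weights.sum() == 300
        # first pattern is literally the first column
        assert np.array_equal(pt.patterns[:, 0], codes[:, 0])


class TestPruningLikelihood:
    def test_single_uniform_site_on_zero_length_tree(self):
        tree = PhyloTree(["a", "b", "c"], [3, 3, 3, -1], [0.0, 0.0, 0.0, 0.0])
        aln = Alignment.from_strings(["a", "b", "c"], ["A", "A", "A"])
        lnl = log_likelihood(tree, "JC", {}, aln)
        assert lnl == pytest.approx(math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration_on_small_trees(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(3, 6))
        model = get_model(
            str(rng.choice(["JC", "HKY", "GTR", "K80+G", "TrN+I", "HKY+I+G"]))
        )
        params = draw_model_params(model, rng)
        tree = random_tree(n_taxa, rng=rng)
        cfg = SimulationConfig(model=model, n_taxa=n_taxa, n_sites=8,
                               seed=seed, **params)
        aln = simulate_alignment(tree, cfg, rng=rng)
        mine = log_likelihood(tree, model, params, aln)
        oracle = brute_force_lnl(tree, model, params, aln)
        assert mine == pytest.approx(oracle, abs=1e-8)

    def test_site_likelihoods_sum_to_one_over_all_columns(self):
        import itertools

        tree = random_tree(4, seed=2)
        cols = np.array(
            list(itertools.product(range(4), repeat=4)), dtype=np.uint8
        ).T
        aln = Alignment([f"t{i+1}" for i in range(4)], cols)
        total = 0.0
        lnl_all = [
            log_likelihood(tree, "HKY", {"exchangeabilities": [3.0],
                                         "freqs": [0.1, 0.2, 0.3, 0.4]},
                           Alignment(aln.taxa, cols[:, [j]]))
            for j in range(256)
        ]
        total = np.exp(lnl_all).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_taxon_order_and_rerooting(self):
        import dendropy

        rng = np.random.default_rng(8)
        tree = random_tree(7, rng=rng)
        cfg = SimulationConfig(model="JC", n_taxa=7, n_sites=120, seed=8)
        aln = simulate_alignment(tree, cfg)
        params = {}
        base = log_likelihood(tree, "JC", params, aln)
        # shuffle alignment rows
        perm = rng.permutation(7)
        shuffled = Alignment([aln.taxa[i] for i in perm], aln.codes[perm])
        assert log_likelihood(tree, "JC", params, shuffled) == pytest.approx(
            base, abs=1e-9
        )
        # reroot the same unrooted tree elsewhere
        dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                                  preserve_underscores=True)
        node = dtree.seed_node.child_nodes()[0]
        if node.is_leaf():
            node = dtree.seed_node.child_nodes()[-1]
        dtree.reroot_at_node(node, update_bipartitions=False)
        rerooted = PhyloTree.from_newick(
            dtree.as_string(schema="newick"), taxa_order=aln.taxa
        )
        assert log_likelihood(rerooted, "JC", params, aln) == pytest.approx(
            base, abs=1e-6
        )

    def test_numba_kernel_agrees_with_numpy_path(self, small_jc_alignment):
        aln, tree = small_jc_alignment
        eng = LikelihoodEngine(tree, compress_patterns(aln))
        eng.set_model(get_model("JC+G"), [], None, alpha=0.6)
        fast = eng.lnl()
        eng._kernel_ok = False
        assert eng.lnl() == pytest.approx(fast, abs=1e-9)

    def test_deep_tree_does_not_underflow(self):
        tree = random_tree(100, seed=1)
        cfg = SimulationConfig(model="JC", n_taxa=100, n_sites=50, seed=1)
        aln = simulate_alignment(tree, cfg)
        lnl = log_likelihood(tree, "JC", {}, aln)
        assert np.isfinite(lnl)

    def test_taxa_mismatch_rejected(self, small_jc_alignment):
        aln, tree = small_jc_alignment
        bad = Alignment([f"x{i}" for i in range(5)], aln.codes)
        with pytest.raises(InvalidInputError):
            log_likelihood(tree, "JC", {}, bad)


class TestNJTree:
    def test_recovers_true_split_with_long_internal_branch(self):
        taxa = ["a", "b", "c", "d"]
        # ((a,b),(c,d)) with a long internal edge
        parent = np.array([4, 4, 5, 5, -1, 4])
        lengths = np.array([0.05, 0.05, 0.05, 0.05, 0.0, 0.8])
        tree = PhyloTree(taxa, parent, lengths)
        cfg = SimulationConfig(model="JC", n_taxa=4, n_sites=2000, seed=3)
        aln = simulate_alignment(tree, cfg)
        est = nj_tree(aln)
        # ab|cd split present: either a,b or c,d are siblings below a
        # non-root internal node (the other pair then hangs off the root)
        assert (est.parent[0] == est.parent[1]) or (est.parent[2] == est.parent[3])

    def test_three_taxa_yield_unique_topology(self):
        aln = Alignment.from_strings(["a", "b", "c"],
                                     ["ACGTACGTAC", "ACGTACGTAA", "ACGTTCGTAA"])
        tree = nj_tree(aln)
        assert tree.n_tips == 3
        assert tree.n_edges == 3

    def test_identical_sequences_give_clamped_star(self):
        aln = Alignment.from_strings(["a", "b", "c", "d"], ["ACGT"] * 4)
        tree = nj_tree(aln)
        mask = np.ones(tree.n_nodes, dtype=bool)
        mask[tree.root] = False
        assert np.all(tree.lengths[mask] >= 1e-6)
        assert tree.total_length < 1e-3


class TestFitModel:
    def test_k80_parameter_recovery_moderate_scale(self):
        tree = random_tree(20, seed=21)
        cfg = SimulationConfig(model="K80", n_taxa=20, n_sites=5000, seed=21,
                               exchangeabilities=[4.0])
        aln = simulate_alignment(tree, cfg)
        fit = fit_model(aln, "K80", tree=tree, tol=1e-4, max_sweeps=20)
        kappa = fit.estimates["exchangeabilities"][0]
        assert 3.3 < kappa < 4.7
        assert fit.converged

    def test_nested_models_never_lose_likelihood(self, small_jc_alignment):
        aln, tree = small_jc_alignment
        jc = fit_model(aln, "JC", tree=tree)
        gtr = fit_model(aln, "GTR", tree=tree)
        assert gtr.lnl >= jc.lnl - 1e-6

    def test_refit_from_estimates_is_a_fixed_point(self, small_jc_alignment):
        aln, tree = small_jc_alignment
        first = fit_model(aln, "K80", tree=tree, tol=1e-6, max_sweeps=50)
        second = fit_model(
            aln, "K80", tree=first.tree, tol=1e-6, max_sweeps=50,
            init_estimates={"exchangeabilities":
                            first.estimates["exchangeabilities"][:1]},
        )
        # fixed point up to the line-search resolution
        assert abs(second.lnl - first.lnl) < 1e-3

    def test_non_convergence_is_flagged_not_hidden(self):
        tree = random_tree(10, seed=31)
        cfg = SimulationConfig(model="GTR+I+G", n_taxa=10, n_sites=800, seed=31,
                               exchangeabilities=[2, 4, 1.5, 1.2, 5],
                               freqs=[0.3, 0.2, 0.2, 0.3], alpha=0.5, p_inv=0.2)
        aln = simulate_alignment(tree, cfg)
        fit = fit_model(aln, "GTR+I+G", tree=tree, tol=1e-9, max_sweeps=1)
        assert not fit.converged

    def test_true_tree_mode_reads_provenance(self):
        suite_aln = simulate_alignment(
            random_tree(5, seed=41),
            SimulationConfig(model="JC", n_taxa=5, n_sites=200, seed=41),
        )
        fit = fit_model(suite_aln, "JC", tree="true")
        assert np.isfinite(fit.lnl)

    def test_likelihood_ratio_null_distribution_is_chi2_df1(self):
        """2*(lnL_K80 - lnL_JC) on JC-generated data follows chi-squared(1)
        across replicates (K80 adds one free parameter)."""
        stats = []
        for rep in range(200):
            tree = random_tree(6, seed=1000 + rep)
            cfg = SimulationConfig(model="JC", n_taxa=6, n_sites=300,
                                   seed=1000 + rep)
            aln = simulate_alignment(tree, cfg)
            jc = fit_model(aln, "JC", tree=tree, tol=1e-7, max_sweeps=30)
            k80 = fit_model(aln, "K80", tree=tree, tol=1e-7, max_sweeps=30)
            stats.append(max(2 * (k80.lnl - jc.lnl), 0.0))
        res = kstest(stats, chi2_dist(df=1).cdf)
        assert res.pvalue > 0.01
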