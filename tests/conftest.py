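import itertools

import numpy as np
import pytest

from modelbench import (
    Alignment,
    SimulationConfig,
    random_tree,
    simulate_alignment,
)
from modelbench.model_space import build_rate_matrix, spectral_decomposition


@pytest.fixture
def small_jc_alignment():
    tree = random_tree(5, seed=7)
    cfg = SimulationConfig(model="JC", n_taxa=5, n_sites=500, seed=7)
    return simulate_alignment(tree, cfg), tree


@pytest.fixture
def tiny_alignment():
    return Alignment.from_strings(
        ["a", "b", "c"], ["ACGTAC", "ACGTTC", "ACGANC"]
    )


def brute_force_lnl(tree, model, params, aln, n_cat=4):
    """Exhaustive-enumeration site likelihoods: sums over all internal-node
    state assignments.  Independent of the pruning implementation."""
    from modelbench.likelihood import discrete_gamma_rates

    rm = build_rate_matrix(
        model, params.get("exchangeabilities", ()), params.get("freqs")
    )
    lam, A, B = spectral_decomposition(rm)

    def pmat(t):
        return (A * np.exp(lam * t)[None, :]) @ B

    rates = (
        discrete_gamma_rates(params["alpha"], n_cat)
        if model.plus_g
        else np.ones(1)
    )
    p_inv = params.get("p_inv", 0.0) if model.plus_i else 0.0
    internals = [v for v in tree.postorder() if v >= tree.n_tips]
    total = 0.0
    for s in range(aln.n_sites):
        col = aln.codes[:, s]
        var_lik = 0.0
        for rate in rates:
            P = {v: pmat(tree.lengths[v] * rate) for v in range(tree.n_nodes)}
            site = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                states = dict(zip(internals, assign))
                pr = rm.pi[states[tree.root]]
                for v in range(tree.n_nodes):
                    if v == tree.root:
                        continue
                    parent_state = states[tree.parent[v]]
                    if v < tree.n_tips:
                        if col[v] == 4:
                            continue  # missing: marginalizes to 1
                        pr *= P[v][parent_state, col[v]]
                    else:
                        pr *= P[v][parent_state, states[v]]
                site += pr
            var_lik += site / len(rates)
        inv_lik = 0.0
        if p_inv > 0:
            inv_lik = sum(
                rm.pi[x]
                for x in range(4)
                if all(c == x or c == 4 for c in col)
            )
        total += np.log(p_inv * inv_lik + (1 - p_inv) * var_lik)
    return total
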