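"""Simulation of random trees and alignments under any registry model.

This module emulates the benchmark design used throughout the package:
one alignment per registry model (88 in the full suite), each evolved on
its own random unrooted tree of 100 taxa with 10,000 sites.  Generating
parameters per dataset are drawn from documented priors (see
``draw_model_params``) and recorded in the alignment's provenance, so a
run is reproducible bit-for-bit from its seed.

Sites evolve independently down the tree: the root state is drawn from
the stationary frequencies and each child state from P(t * r_s), where
r_s is the site's rate multiplier (0 with probability p_inv under +I, a
mean-1 gamma draw under +G, the product under +I+G).  Simulation uses
continuous gamma rates; inference uses the usual 4 discrete categories —
that mismatch is deliberate, mirroring how simulators and inference
tools differ in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import Alignment
from .exceptions import InvalidInputError
from .model_space import (
    SubstitutionModel,
    build_rate_matrix,
    complexity_rank,
    get_model,
    list_models,
    spectral_decomposition,
)
from .trees import PhyloTree

#: Default branch-length law: exponential mean, truncation floor.
DEFAULT_BRANCH_MEAN = 0.1
DEFAULT_BRANCH_MIN = 1e-4


@dataclass
class SimulationConfig:
    """Everything needed to evolve one alignment.

    ``alpha`` must be supplied exactly when the model carries +G, and
    ``p_inv`` exactly when it carries +I.
    """

    model: SubstitutionModel
    n_taxa: int = 100
    n_sites: int = 10_000
    exchangeabilities: Sequence[float] = ()
    freqs: Sequence[float] | None = None
    alpha: float | None = None
    p_inv: float | None = None
    branch_length_mean: float = DEFAULT_BRANCH_MEAN
    branch_length_min: float = DEFAULT_BRANCH_MIN
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.model, str):
            self.model = get_model(self.model)
        if self.model.plus_g != (self.alpha is not None):
            raise InvalidInputError(
                f"{self.model.name}: alpha must be given iff the model has +G"
            )
        if self.model.plus_i != (self.p_inv is not None):
            raise InvalidInputError(
                f"{self.model.name}: p_inv must be given iff the model has +I"
            )
        if self.alpha is not None and self.alpha <= 0:
            raise InvalidInputError("alpha must be positive")
        if self.p_inv is not None and not (0 <= self.p_inv < 1):
            raise InvalidInputError("p_inv must be in [0, 1)")

    def params(self) -> dict:
        out = {"exchangeabilities": list(map(float, self.exchangeabilities))}
        if self.freqs is not None:
            out["freqs"] = list(map(float, self.freqs))
        if self.alpha is not None:
            out["alpha"] = float(self.alpha)
        if self.p_inv is not None:
            out["p_inv"] = float(self.p_inv)
        return out


def random_tree(
    n_taxa: int,
    branch_length_mean: float = DEFAULT_BRANCH_MEAN,
    branch_length_min: float = DEFAULT_BRANCH_MIN,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """Uniformly random unrooted binary topology with i.i.d. branch lengths.

    The topology is built by stepwise addition — each new tip attaches to
    an edge chosen uniformly at random — which yields every unrooted
    labelled binary topology with equal probability.  Branch lengths are
    i.i.d. exponential with the given mean, truncated below.
    """
    if n_taxa < 3:
        raise InvalidInputError(f"need at least 3 taxa, got {n_taxa}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_nodes = 2 * n_taxa - 2
    root = n_taxa
    parent = np.full(n_nodes, -1, dtype=np.int64)
    parent[0:3] = root
    edges = [0, 1, 2]  # child node of every current edge
    next_internal = n_taxa + 1
    for tip in range(3, n_taxa):
        c = edges[int(rng.integers(len(edges)))]
        m = next_internal
        next_internal += 1
        parent[m] = parent[c]
        parent[c] = m
        parent[tip] = m
        edges.extend([tip, m])
    lengths = np.maximum(
        rng.exponential(branch_length_mean, size=n_nodes), branch_length_min
    )
    lengths[root] = 0.0
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    return PhyloTree(taxa, parent, lengths)


def simulate_alignment(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Evolve an alignment down ``tree`` under ``config``.

    Columns are i.i.d.; the result is reproducible given ``config.seed``
    (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.model
    rm = build_rate_matrix(model, config.exchangeabilities, config.freqs)
    lam, A, B = spectral_decomposition(rm)
    n_sites = config.n_sites

    rates = np.ones(n_sites)
    if model.plus_g:
        rates = rng.gamma(config.alpha, 1.0 / config.alpha, size=n_sites)
    if model.plus_i:
        rates[rng.random(n_sites) < config.p_inv] = 0.0

    states = np.empty((tree.n_nodes, n_sites), dtype=np.uint8)
    states[tree.root] = rng.choice(4, size=n_sites, p=rm.pi)
    for v in tree.preorder():
        if v == tree.root:
            continue
        t = tree.lengths[v]
        E = np.exp(np.outer(rates * t, lam))  # (sites, 4)
        rows = np.einsum("sj,jk->sk", A[states[tree.parent[v]]] * E, B)
        np.clip(rows, 0.0, None, out=rows)
        rows /= rows.sum(axis=1, keepdims=True)
        u = rng.random(n_sites)
        states[v] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)

    provenance = {
        "model": model.name,
        "params": config.params(),
        "seed": config.seed,
        "tree": tree.to_newick(),
    }
    return Alignment(list(tree.taxa), states[: tree.n_tips], provenance)


def draw_model_params(
    model: SubstitutionModel, rng: np.random.Generator
) -> dict:
    """Draw realistic generating parameters for one registry model.

    Exchangeabilities are log-uniform on [0.5, 8] relative to the
    reference (GT) rate; estimated frequencies are Dirichlet(10,10,10,10);
    alpha is uniform on [0.3, 2]; p_inv uniform on [0.1, 0.5].
    """
    n_free = model.n_rate_classes - 1
    exch = np.exp(rng.uniform(math.log(0.5), math.log(8.0), size=n_free))
    out: dict = {"exchangeabilities": exch.tolist()}
    if model.freq_mode == "estimated":
        out["freqs"] = rng.dirichlet([10.0, 10.0, 10.0, 10.0]).tolist()
    if model.plus_g:
        out["alpha"] = float(rng.uniform(0.3, 2.0))
    if model.plus_i:
        out["p_inv"] = float(rng.uniform(0.1, 0.5))
    return out


@dataclass
class TruthRecord:
    """Ground truth for one benchmark dataset."""

    model: SubstitutionModel
    params: dict
    tree: PhyloTree
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "model": self.model.name,
            "params": self.params,
            "seed": self.seed,
            "tree": self.tree.to_newick(),
        }


def benchmark_suite(
    n_taxa: int = 100,
    n_sites: int = 10_000,
    seed: int = 0,
    models: Sequence[SubstitutionModel | str] | None = None,
) -> list[tuple[Alignment, TruthRecord]]:
    """One simulated dataset per registry model (88 by default).

    Each dataset gets its own random tree and generating parameters,
    drawn from an independent substream seeded at ``seed + rank`` where
    ``rank`` is the model's complexity rank — so individual datasets can
    be regenerated without rebuilding the whole suite.
    """
    if models is None:
        models = list_models()
    models = [get_model(m) if isinstance(m, str) else m for m in models]
    suite = []
    for model in models:
        sub_seed = seed + complexity_rank(model)
        rng = np.random.default_rng(sub_seed)
        params = draw_model_params(model, rng)
        tree = random_tree(n_taxa, rng=rng)
        config = SimulationConfig(
            model=model, n_taxa=n_taxa, n_sites=n_sites, seed=sub_seed, **params
        )
        aln = simulate_alignment(tree, config, rng=rng)
        suite.append((aln, TruthRecord(model, params, tree, sub_seed)))
    return suite
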