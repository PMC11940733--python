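"""Maximum-likelihood evaluation of substitution models on a fixed tree.

The engine implements Felsenstein's pruning recursion over compressed
site patterns, vectorized across patterns and discrete-gamma rate
categories, with per-node rescaling of partial likelihoods so that
100-taxon trees do not underflow.  Rate heterogeneity follows the usual
conventions: +G uses ``n_cat`` equiprobable discrete categories with
category-mean rates; +I mixes in a zero-rate class with probability
``p_inv`` whose contribution is evaluated in closed form (a zero-rate
site can only be a constant column, with probability pi_x).

Model fitting alternates branch-length passes (per-branch Brent
searches on cached partials from a single post-order + pre-order
traversal, plus a global tree-scale search) with a joint Powell
direction-set search over the free model parameters — log scale for
exchangeabilities and alpha, bounded for p_inv, logit coordinates for
frequencies.  Powell is used rather than one-parameter-at-a-time
ascent because the exchangeability coordinates are strongly correlated
under the reference-rate parameterization.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import MISSING, Alignment
from .exceptions import InvalidInputError, NumericError
from .model_space import (
    RateMatrix,
    SubstitutionModel,
    build_rate_matrix,
    get_model,
    param_count,
    spectral_decomposition,
)
from .trees import PhyloTree

#: Bounds used by the coordinate optimizer.
_MIN_BRANCH = 1e-8
_MAX_BRANCH = 10.0
_LOG_RATE_BOUNDS = (math.log(1e-3), math.log(1e3))
_LOG_ALPHA_BOUNDS = (math.log(0.02), math.log(100.0))
_PINV_BOUNDS = (1e-9, 0.9)
_FREQ_LOGIT_BOUNDS = (-8.0, 8.0)
#: Saturation cap for JC-corrected distances.
MAX_DISTANCE = 5.0

try:  # optional compiled pruning kernel; the numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(fastmath=True)
    def _prune_kernel(post_internal, children, n_children, n_tips, P, tipcodes, pi):
        """Postorder pruning pass: per-pattern root-summed likelihood
        (mixed over categories with equal weights) and log scale factors."""
        n_nodes, ncat, _, _ = P.shape
        npat = tipcodes.shape[1]
        M = np.empty((n_nodes, ncat, 4, npat))
        logscale = np.zeros(npat)
        for v in range(n_tips):
            for c in range(ncat):
                for i in range(4):
                    for p in range(npat):
                        code = tipcodes[v, p]
                        M[v, c, i, p] = 1.0 if code >= 4 else P[v, c, i, code]
        n_int = post_internal.shape[0]
        since = 0
        out = np.empty(npat)
        for idx in range(n_int):
            v = post_internal[idx]
            k0 = children[v, 0]
            k1 = children[v, 1]
            D = np.empty((ncat, 4, npat))
            for c in range(ncat):
                for i in range(4):
                    for p in range(npat):
                        D[c, i, p] = M[k0, c, i, p] * M[k1, c, i, p]
            if n_children[v] == 3:
                k2 = children[v, 2]
                for c in range(ncat):
                    for i in range(4):
                        for p in range(npat):
                            D[c, i, p] *= M[k2, c, i, p]
            is_root = idx == n_int - 1
            since += 1
            if since >= 8 or is_root:
                since = 0
                for p in range(npat):
                    m = 0.0
                    for c in range(ncat):
                        for i in range(4):
                            if D[c, i, p] > m:
                                m = D[c, i, p]
                    if m > 0.0:
                        inv = 1.0 / m
                        for c in range(ncat):
                            for i in range(4):
                                D[c, i, p] *= inv
                        logscale[p] += np.log(m)
                    else:
                        logscale[p] = -np.inf
            if is_root:
                for p in range(npat):
                    s = 0.0
                    for c in range(ncat):
                        for i in range(4):
                            s += pi[i] * D[c, i, p]
                    out[p] = s / ncat
                return out, logscale
            for c in range(ncat):
                for i in range(4):
                    Pi0 = P[v, c, i, 0]
                    Pi1 = P[v, c, i, 1]
                    Pi2 = P[v, c, i, 2]
                    Pi3 = P[v, c, i, 3]
                    for p in range(npat):
                        M[v, c, i, p] = (
                            Pi0 * D[c, 0, p]
                            + Pi1 * D[c, 1, p]
                            + Pi2 * D[c, 2, p]
                            + Pi3 * D[c, 3, p]
                        )
        return out, logscale  # unreachable; keeps numba's type inference happy


def transition_matrix(rm: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a reversible rate matrix, via spectral form."""
    if t < 0:
        raise InvalidInputError(f"branch length must be >= 0, got {t}")
    lam, A, B = spectral_decomposition(rm)
    P = (A * np.exp(lam * t)[None, :]) @ B
    np.clip(P, 0.0, 1.0, out=P)
    return P


@lru_cache(maxsize=1024)
def _gamma_rates_cached(alpha: float, n_cat: int) -> tuple:
    bounds = gamma_dist.ppf(np.arange(1, n_cat) / n_cat, alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1, alpha * bounds), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, alpha * bounds)])
    rates = n_cat * (upper - lower)
    return tuple(rates / rates.mean())


def discrete_gamma_rates(alpha: float, n_cat: int = 4) -> np.ndarray:
    """Mean rates of ``n_cat`` equiprobable categories of a mean-1 gamma.

    This is the standard discretization for +G models: category
    boundaries at gamma quantiles i/n_cat, category rate = conditional
    mean within the category; the returned rates average exactly 1.
    """
    if alpha <= 0:
        raise InvalidInputError(f"alpha must be positive, got {alpha}")
    if n_cat < 1:
        raise InvalidInputError(f"n_cat must be >= 1, got {n_cat}")
    if n_cat == 1:
        return np.ones(1)
    # X ~ Gamma(shape=alpha, scale=1/alpha); E[X; X <= q] = I(alpha*q; alpha+1)
    # (cached: optimizers re-request the same alpha many times per fit)
    return np.array(_gamma_rates_cached(float(alpha), int(n_cat)))


@dataclass
class PatternTable:
    """Distinct alignment columns with multiplicities."""

    taxa: list[str]
    patterns: np.ndarray  # (n_taxa, n_patterns) uint8
    weights: np.ndarray  # (n_patterns,)
    n_sites: int

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]


def compress_patterns(aln: Alignment) -> PatternTable:
    """Collapse identical columns, preserving first-occurrence order."""
    if aln.n_sites == 0 or aln.n_taxa == 0:
        raise InvalidInputError("cannot compress an empty alignment")
    cols, first, counts = np.unique(
        aln.codes, axis=1, return_index=True, return_counts=True
    )
    order = np.argsort(first, kind="stable")
    return PatternTable(
        taxa=list(aln.taxa),
        patterns=np.ascontiguousarray(cols[:, order]),
        weights=counts[order].astype(float),
        n_sites=aln.n_sites,
    )


@dataclass
class FitResult:
    """Maximized log-likelihood and estimates for one model on one alignment."""

    model: SubstitutionModel
    lnl: float
    estimates: dict
    tree: PhyloTree
    k: int
    converged: bool
    n_sites: int
    n_sweeps: int = 0
    alignment_id: str | None = None


class LikelihoodEngine:
    """Pruning likelihood for one (tree, pattern table) pair.

    The engine holds per-tip partial-likelihood templates and the
    constant-column indicator used for the +I closed form; model
    parameters are installed with :meth:`set_model` and branch lengths
    are free arguments, so the same engine serves a whole optimization.
    """

    def __init__(self, tree: PhyloTree, patterns: PatternTable):
        if set(tree.taxa) != set(patterns.taxa):
            raise InvalidInputError("tree tips and alignment taxa differ")
        self.tree = tree
        self.pat = patterns
        row_of = {name: i for i, name in enumerate(patterns.taxa)}
        self._tip_rows = np.array([row_of[name] for name in tree.taxa])
        npat = patterns.n_patterns
        # (n_tips, 4, npat): state indicators, all-ones for missing data
        self.tip_partials = np.zeros((tree.n_tips, 4, npat))
        for tip in range(tree.n_tips):
            col = patterns.patterns[self._tip_rows[tip]]
            ok = col == MISSING
            self.tip_partials[tip][:, ok] = 1.0
            known = ~ok
            self.tip_partials[tip][col[known], np.flatnonzero(known)] = 1.0
        # (npat, 4): can this pattern be a constant column of state x?
        pats = patterns.patterns
        self.const_ok = np.stack(
            [np.all((pats == x) | (pats == MISSING), axis=0) for x in range(4)],
            axis=1,
        ).astype(float)
        self.w = patterns.weights
        # flat structure arrays for the compiled kernel
        post = tree.postorder()
        self._post_internal = np.asarray(
            [v for v in post if v >= tree.n_tips], dtype=np.int64
        )
        self._children_arr = np.full((tree.n_nodes, 3), -1, dtype=np.int64)
        self._n_children = np.zeros(tree.n_nodes, dtype=np.int64)
        for v in range(tree.n_nodes):
            kids = tree.children[v]
            self._n_children[v] = len(kids)
            for j, c in enumerate(kids):
                self._children_arr[v, j] = c
        self._tipcodes = np.ascontiguousarray(
            patterns.patterns[self._tip_rows].astype(np.int64)
        )
        self._kernel_ok = _HAVE_NUMBA and int(self._n_children.max()) <= 3
        # model state installed by set_model()
        self.model: SubstitutionModel | None = None

    # ------------------------------------------------------------------
    def set_model(
        self,
        model: SubstitutionModel,
        exchangeabilities=(),
        freqs=None,
        alpha: float | None = None,
        p_inv: float | None = None,
        n_cat: int = 4,
    ) -> None:
        rm = build_rate_matrix(model, exchangeabilities, freqs)
        self.model = model
        self.rm = rm
        self.pi = rm.pi
        self.lam, self.A, self.B = spectral_decomposition(rm)
        if model.plus_g:
            if alpha is None:
                raise InvalidInputError(f"{model.name} requires alpha")
            self.rates = discrete_gamma_rates(alpha, n_cat)
        else:
            if alpha is not None:
                raise InvalidInputError(f"{model.name} does not accept alpha")
            self.rates = np.ones(1)
        if model.plus_i:
            if p_inv is None:
                raise InvalidInputError(f"{model.name} requires p_inv")
            if not (0 <= p_inv < 1):
                raise InvalidInputError("p_inv must be in [0, 1)")
            self.p_inv = float(p_inv)
        else:
            if p_inv is not None:
                raise InvalidInputError(f"{model.name} does not accept p_inv")
            self.p_inv = 0.0
        self.cat_weight = 1.0 / len(self.rates)
        self.log_const = np.log(
            np.clip(self.p_inv * (self.const_ok @ self.pi), 1e-300, None)
        )
        self._has_inv = model.plus_i

    # ------------------------------------------------------------------
    def _pmats(self, ts: np.ndarray) -> np.ndarray:
        """Transition matrices for an array of scaled times, shape (*, 4, 4)."""
        E = np.exp(ts[..., None] * self.lam)
        P = (self.A * E[..., None, :]) @ self.B
        np.clip(P, 0.0, None, out=P)
        return P

    def _edge_pmats(self, blens: np.ndarray) -> np.ndarray:
        """(n_nodes, n_cat, 4, 4) matrices; the root entry is unused."""
        ts = np.clip(blens, 0.0, None)[:, None] * self.rates[None, :]
        return self._pmats(ts)

    def _site_logl(self, site_var_log: np.ndarray) -> np.ndarray:
        if self._has_inv:
            return np.logaddexp(
                self.log_const, math.log1p(-self.p_inv) + site_var_log
            )
        return site_var_log

    def lnl(self, blens: np.ndarray | None = None) -> float:
        """Full pruning log-likelihood at the given branch lengths."""
        if blens is None:
            blens = self.tree.lengths
        tree = self.tree
        P = self._edge_pmats(blens)
        if self._kernel_ok:
            S, logscale = _prune_kernel(
                self._post_internal,
                self._children_arr,
                self._n_children,
                tree.n_tips,
                np.ascontiguousarray(P),
                self._tipcodes,
                self.pi,
            )
            with np.errstate(divide="ignore"):
                site_var_log = np.log(S) + logscale
            total = self.w @ self._site_logl(site_var_log)
            if np.isnan(total):
                raise NumericError("log-likelihood evaluated to NaN")
            return float(total)
        npat = self.pat.n_patterns
        M: list = [None] * tree.n_nodes
        logscale = np.zeros(npat)
        since_rescale = 0
        for v in tree.postorder():
            if v < tree.n_tips:
                M[v] = np.matmul(P[v], self.tip_partials[v])
                continue
            kids = tree.children[v]
            D = M[kids[0]] * M[kids[1]]
            for c in kids[2:]:
                D *= M[c]
            since_rescale += 1
            # partials shrink multiplicatively; rescale periodically
            if since_rescale >= 8 or v == tree.root:
                since_rescale = 0
                m = D.max(axis=(0, 1))
                bad = m <= 0
                if bad.any():
                    m = np.where(bad, 1.0, m)
                    with np.errstate(divide="ignore"):
                        logscale = logscale + np.where(bad, -np.inf, np.log(m))
                else:
                    logscale = logscale + np.log(m)
                D /= m[None, None, :]
            if v == tree.root:
                root_D = D
            else:
                M[v] = np.matmul(P[v], D)
            for c in kids:  # free memory eagerly
                M[c] = None
        S = self.cat_weight * np.einsum("x,cxp->cp", self.pi, root_D).sum(axis=0)
        with np.errstate(divide="ignore"):
            site_var_log = np.log(S) + logscale
        total = self.w @ self._site_logl(site_var_log)
        if np.isnan(total):
            raise NumericError("log-likelihood evaluated to NaN")
        return float(total)

    # ------------------------------------------------------------------
    def _directional_partials(self, blens: np.ndarray):
        """Down (D), message (M) and up (B) partials with log scales.

        ``M[v]`` is the message v sends to its parent, ``D[v]`` the
        partial at an internal v from its subtree, and ``B[v]`` the
        partial seen by v from the rest of the tree, expressed at the
        parent-side states of v's edge (stationary frequencies folded
        in at the root).  Scales: sM, sD, sB are per-pattern log factors.
        """
        tree = self.tree
        npat = self.pat.n_patterns
        P = self._edge_pmats(blens)
        M: list = [None] * tree.n_nodes
        D: list = [None] * tree.n_nodes
        sM = [None] * tree.n_nodes
        zero = np.zeros(npat)
        for v in tree.postorder():
            if v < tree.n_tips:
                M[v] = np.matmul(P[v], self.tip_partials[v])
                sM[v] = zero
                continue
            Dv = M[tree.children[v][0]].copy()
            for c in tree.children[v][1:]:
                Dv *= M[c]
            sv = sum(sM[c] for c in tree.children[v])
            m = np.clip(Dv.max(axis=(0, 1)), 1e-300, None)
            Dv /= m[None, None, :]
            sv = sv + np.log(m)
            D[v], sM[v] = Dv, sv
            if v != tree.root:
                M[v] = np.matmul(P[v], Dv)
        B: list = [None] * tree.n_nodes
        sB = [None] * tree.n_nodes
        for v in tree.preorder():
            if v < tree.n_tips:
                continue
            kids = tree.children[v]
            if v == tree.root:
                base = np.broadcast_to(
                    self.pi[None, :, None], (len(self.rates), 4, npat)
                ).copy()
                sbase = zero
            else:
                base = np.matmul(P[v].transpose(0, 2, 1), B[v])
                sbase = sB[v]
            for u in kids:
                Bu = base.copy()
                su = sbase.copy()
                for s in kids:
                    if s is not u:
                        Bu *= M[s]
                        su = su + sM[s]
                m = np.clip(Bu.max(axis=(0, 1)), 1e-300, None)
                Bu /= m[None, None, :]
                B[u], sB[u] = Bu, su + np.log(m)
        return P, M, D, sM, B, sB

    def optimize_branch_lengths(
        self, blens: np.ndarray, xatol: float = 1e-3, window: float | None = None
    ) -> np.ndarray:
        """One pass of per-branch Brent optimization (log scale).

        Partials are cached from a single two-way traversal and used for
        every branch in the pass (they go slightly stale as branches
        update); callers should accept the pass only if the full
        likelihood improved.  ``window`` restricts each search to a
        log-scale neighbourhood of the current value (useful after the
        first pass, when lengths are already near their optima).
        """
        tree = self.tree
        _, _, D, sM, B, sB = self._directional_partials(blens)
        new = blens.copy()
        lo, hi = math.log(_MIN_BRANCH), math.log(_MAX_BRANCH)
        for v in tree.preorder():
            if v == tree.root:
                continue
            Dv = self.tip_partials[v][None] if v < tree.n_tips else D[v]
            sDv = 0.0 if v < tree.n_tips else sM[v]
            Bv, sBv = B[v], sB[v]
            scale = sBv + sDv

            def neg(logt):
                P = self._pmats(math.exp(logt) * self.rates)
                T = np.matmul(P, Dv)
                T *= Bv
                S = self.cat_weight * T.sum(axis=(0, 1))
                with np.errstate(divide="ignore"):
                    site = np.log(np.clip(S, 1e-300, None)) + scale
                return -(self.w @ self._site_logl(site))

            x0 = math.log(max(new[v], _MIN_BRANCH))
            if window is None:
                bounds = (lo, hi)
            else:
                bounds = (max(lo, x0 - window), min(hi, x0 + window))
            res = minimize_scalar(
                neg, bounds=bounds, method="bounded", options={"xatol": xatol}
            )
            if res.fun < neg(x0):
                new[v] = math.exp(res.x)
        return new

    def optimize_branch_scale(
        self, blens: np.ndarray, xatol: float = 1e-3
    ) -> np.ndarray:
        """Brent search over one multiplier applied to every branch length.

        Cheap and removes the rate-scale/tree-scale zigzag that slows
        pure coordinate ascent (e.g. after p_inv or exchangeability
        updates changed the effective substitution rate)."""

        def neg(logs):
            return -self.lnl(np.clip(blens * math.exp(logs), 0.0, _MAX_BRANCH))

        res = minimize_scalar(
            neg, bounds=(-2.0, 2.0), method="bounded", options={"xatol": xatol}
        )
        if res.fun < neg(0.0):
            return np.clip(blens * math.exp(res.x), 0.0, _MAX_BRANCH)
        return blens


def log_likelihood(
    tree: PhyloTree,
    model: SubstitutionModel | str,
    params: dict,
    patterns: PatternTable | Alignment,
) -> float:
    """Pruning log-likelihood of ``patterns`` on ``tree`` under ``model``.

    ``params`` may contain ``exchangeabilities``, ``freqs``, ``alpha``
    and ``p_inv`` as applicable to the model's flags.
    """
    if isinstance(model, str):
        model = get_model(model)
    if isinstance(patterns, Alignment):
        patterns = compress_patterns(patterns)
    engine = LikelihoodEngine(tree, patterns)
    engine.set_model(
        model,
        params.get("exchangeabilities", ()),
        params.get("freqs"),
        params.get("alpha"),
        params.get("p_inv"),
    )
    return engine.lnl()


# ----------------------------------------------------------------------
def jc_distance_matrix(aln: Alignment, max_distance: float = MAX_DISTANCE):
    """Pairwise JC-corrected distances; saturated pairs capped."""
    n = aln.n_taxa
    codes = aln.codes
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (codes[i] != MISSING) & (codes[j] != MISSING)
            nv = int(valid.sum())
            if nv == 0:
                dist = max_distance
            else:
                p = float((codes[i][valid] != codes[j][valid]).sum()) / nv
                if p >= 0.75 - 1e-12:
                    dist = max_distance
                else:
                    dist = -0.75 * math.log1p(-4.0 * p / 3.0)
                    dist = min(dist, max_distance)
            d[i, j] = d[j, i] = dist
    return d


def nj_tree(aln: Alignment, min_branch: float = 1e-6) -> PhyloTree:
    """Neighbor-joining tree from JC-corrected distances.

    Negative NJ branch lengths are clamped to ``min_branch``; this is
    the fixed base topology used when fitting all candidate models to
    one alignment.
    """
    if aln.n_taxa < 3:
        raise InvalidInputError("neighbor joining needs at least 3 taxa")
    from skbio import DistanceMatrix
    from skbio.tree import nj as _nj

    dm = DistanceMatrix(jc_distance_matrix(aln), ids=aln.taxa)
    buf = io.StringIO()
    _nj(dm).write(buf)
    tree = PhyloTree.from_newick(buf.getvalue(), taxa_order=aln.taxa)
    mask = np.ones(tree.n_nodes, dtype=bool)
    mask[tree.root] = False
    tree.lengths[mask] = np.maximum(tree.lengths[mask], min_branch)
    return tree


# ----------------------------------------------------------------------
def _initial_estimates(aln: Alignment, model: SubstitutionModel) -> dict:
    est: dict = {"exchangeabilities": np.ones(model.n_rate_classes)}
    if model.freq_mode == "estimated":
        est["freqs"] = aln.base_frequencies(pseudocount=1.0)
    else:
        est["freqs"] = np.full(4, 0.25)
    if model.plus_g:
        est["alpha"] = 1.0
    if model.plus_i:
        est["p_inv"] = 0.1
    return est


def fit_model(
    aln: Alignment,
    model: SubstitutionModel | str,
    tree: PhyloTree | str = "nj",
    optimize_branch_lengths: bool = True,
    tol: float = 1e-6,
    max_sweeps: int = 50,
    param_xatol: float = 1e-3,
    include_branch_lengths_in_k: bool = True,
    empirical_freqs: bool = False,
    init_estimates: dict | None = None,
    alignment_id: str | None = None,
) -> FitResult:
    """Maximize the likelihood of ``model`` on ``aln`` over a fixed topology.

    ``tree`` may be a PhyloTree, ``"nj"`` (neighbor-joining base tree) or
    ``"true"`` (the generating tree recorded in the alignment's
    provenance).  Optimization is coordinate ascent over free model
    parameters plus per-branch length passes, stopping when a sweep
    improves lnL by less than ``tol`` (converged) or after
    ``max_sweeps`` sweeps (returned with ``converged=False``).

    With ``empirical_freqs`` the stationary frequencies of
    estimated-frequency models are fixed at the observed base counts
    (the "+F" convention of the common selection programs) instead of
    being ML-optimized; they still count as 3 free parameters.
    """
    if isinstance(model, str):
        model = get_model(model)
    if isinstance(tree, str):
        if tree == "nj":
            tree = nj_tree(aln)
        elif tree == "true":
            newick = aln.provenance.get("tree")
            if not newick:
                raise InvalidInputError(
                    "tree='true' requires a tree in the alignment provenance"
                )
            tree = PhyloTree.from_newick(newick, taxa_order=aln.taxa)
        else:
            raise InvalidInputError(f"unknown tree mode {tree!r}")
    else:
        tree = tree.copy()

    patterns = compress_patterns(aln)
    engine = LikelihoodEngine(tree, patterns)
    est = _initial_estimates(aln, model)
    if init_estimates:
        for key in ("alpha", "p_inv"):
            if key in init_estimates and key in est:
                est[key] = float(init_estimates[key])
        if "exchangeabilities" in init_estimates:
            ex = np.asarray(init_estimates["exchangeabilities"], dtype=float)
            est["exchangeabilities"][: ex.size] = ex
        if "freqs" in init_estimates and model.freq_mode == "estimated":
            est["freqs"] = np.asarray(init_estimates["freqs"], dtype=float)
    blens = np.clip(tree.lengths.copy(), _MIN_BRANCH, _MAX_BRANCH)
    blens[tree.root] = 0.0

    def install():
        engine.set_model(
            model,
            est["exchangeabilities"],
            est["freqs"] if model.freq_mode == "estimated" else None,
            est.get("alpha"),
            est.get("p_inv"),
        )

    install()
    current = engine.lnl(blens)

    # Free model parameters as one bounded vector: log exchangeabilities,
    # frequency logits (relative to T), log alpha, p_inv.  They are
    # optimized jointly with Powell's method — repeated Brent line
    # searches along an evolving direction set — which handles the
    # strong correlation between exchangeability coordinates that makes
    # naive one-at-a-time ascent crawl.
    coords: list[tuple] = []
    for i in range(model.n_rate_classes - 1):
        coords.append((f"rate{i}", _LOG_RATE_BOUNDS))
    if model.freq_mode == "estimated" and not empirical_freqs:
        for j in range(3):
            coords.append((f"logit{j}", _FREQ_LOGIT_BOUNDS))
    if model.plus_g:
        coords.append(("log_alpha", _LOG_ALPHA_BOUNDS))
    if model.plus_i:
        coords.append(("p_inv", _PINV_BOUNDS))

    def get_x() -> np.ndarray:
        x = []
        for name, _ in coords:
            if name.startswith("rate"):
                x.append(math.log(est["exchangeabilities"][int(name[4:])]))
            elif name.startswith("logit"):
                j = int(name[5:])
                x.append(math.log(est["freqs"][j] / est["freqs"][3]))
            elif name == "log_alpha":
                x.append(math.log(est["alpha"]))
            else:
                x.append(est["p_inv"])
        return np.array(x)

    def apply_x(x: np.ndarray) -> None:
        logits = None
        for (name, _), xi in zip(coords, x):
            if name.startswith("rate"):
                est["exchangeabilities"][int(name[4:])] = math.exp(xi)
            elif name.startswith("logit"):
                if logits is None:
                    logits = np.log(est["freqs"][:3] / est["freqs"][3])
                logits[int(name[5:])] = xi
            elif name == "log_alpha":
                est["alpha"] = math.exp(xi)
            else:
                est["p_inv"] = xi
        if logits is not None:
            expl = np.exp(np.append(logits, 0.0))
            est["freqs"] = expl / expl.sum()

    def neg(x: np.ndarray) -> float:
        apply_x(x)
        install()
        return -engine.lnl(blens)

    bounds = [b for _, b in coords]
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        at_entry = current
        # branch lengths first: they start from a sensible tree, so the
        # (expensive) joint parameter search then works on good lengths
        if optimize_branch_lengths:
            scaled = engine.optimize_branch_scale(blens, xatol=param_xatol)
            scaled_lnl = engine.lnl(scaled)
            if scaled_lnl > current:
                blens, current = scaled, scaled_lnl
            # repeat passes while they pay: stale-partial passes are weak,
            # and a second round is much cheaper than an extra full sweep
            for _ in range(3):
                candidate = engine.optimize_branch_lengths(
                    blens,
                    xatol=3 * param_xatol,
                    window=None if sweeps == 1 else 0.75,
                )
                cand_lnl = engine.lnl(candidate)
                gain = cand_lnl - current
                if gain > 0:
                    blens, current = candidate, cand_lnl
                if gain < max(tol, 1e-9):
                    break
        if coords:
            x0 = get_x()
            res = minimize(
                neg,
                x0,
                method="Powell",
                bounds=bounds,
                # direction-set iterations are spread across sweeps: the
                # first sweep learns the correlated directions, later
                # sweeps refine one iteration at a time between
                # branch-length passes
                options={
                    "xtol": param_xatol,
                    "ftol": tol / max(1.0, abs(current)),
                    "maxiter": 3 if sweeps == 1 else 1,
                    "maxfev": 150 * (len(coords) + 1),
                },
            )
            if -res.fun > current:
                apply_x(np.asarray(res.x))
                current = -float(res.fun)
            else:
                apply_x(x0)
            install()
        if current - at_entry < tol:
            converged = True
            break

    tree.lengths = blens
    estimates = {
        "exchangeabilities": np.asarray(est["exchangeabilities"], dtype=float),
        "freqs": np.asarray(est["freqs"], dtype=float),
    }
    if model.plus_g:
        estimates["alpha"] = float(est["alpha"])
    if model.plus_i:
        estimates["p_inv"] = float(est["p_inv"])
    return FitResult(
        model=model,
        lnl=current,
        estimates=estimates,
        tree=tree,
        k=param_count(model, aln.n_taxa, include_branch_lengths_in_k),
        converged=converged,
        n_sites=aln.n_sites,
        n_sweeps=sweeps,
        alignment_id=alignment_id
        if alignment_id is not None
        else aln.provenance.get("id"),
    )
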