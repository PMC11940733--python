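# Methods

## The model space

`modelbench` works with the 88 named time-reversible nucleotide
substitution models commonly offered by DNA model-selection programs:
11 exchangeability symmetry classes (JC/F81, K80/HKY, TrNef/TrN,
TPM1–3 with their unequal-frequency twins, TIM1–3 with their
equal-frequency twins, TVMef/TVM, SYM/GTR), each in an equal-frequency
and an estimated-frequency variant, each with four among-site-rate
variants (none, +I, +G, +I+G).  A symmetry class is a partition of the
six unordered nucleotide pairs {AC, AG, AT, CG, CT, GT} into shared-rate
groups, encoded as a six-digit string in that pair order (HKY is
`010010`: transitions AG and CT share one rate, transversions the
other).  Free parameters: `k_rates` = number of rate groups − 1,
`k_freq` = 0 or 3, `k_het` = 0–2, so `k_model` ranges from 0 (JC) to 10
(GTR+I+G).

The registry is ordered by complexity: ascending `k_model`, ties broken
alphabetically by name.  This ordering is a package convention — any
deterministic tie-break would do, and positions of equal-`k` models are
not comparable across conventions.  The "similarity" rule used by the
agreement layer calls two models similar when their positions in this
ordering differ by at most 4 (a free-parameter-difference variant is
available behind the `metric="params"` flag).

Rate matrices follow the standard reversible parameterization
Q_ij = r_ij·π_j (i≠j), normalized so −Σ_i π_i Q_ii = 1; branch lengths
are therefore expected substitutions per site.  Exchangeabilities are
relative to the last (GT-containing) rate class, which is fixed at 1.

## Information criteria

For a fit with maximized log-likelihood lnL and k free parameters on an
alignment of n sites:

    AIC  = −2 lnL + 2k
    AICc = AIC + 2k(k+1)/(n − k − 1)
    BIC  = −2 lnL + k ln n

`n` is the alignment length in sites — the convention of the common
selection programs; it is a convention, not a derived quantity, since
sites are the exchangeable observations here.  By default `k` includes
the 2t−3 branch lengths of the unrooted tree on t taxa (also the
programs' convention); because that term is constant across models on a
fixed topology it never changes a within-alignment ranking, and both
conventions are exposed.  Ties are broken by smaller k, then lower
complexity rank, so selections are deterministic.

A consequence used by the tests: whenever ln n > 2 (n ≥ 8), if AIC and
BIC disagree on the argmin then the BIC choice has no more parameters —
this is a theorem about the penalty ordering, not an empirical finding.

## Likelihood computation

Site likelihoods are computed by Felsenstein's pruning recursion over
distinct alignment columns (pattern compression), vectorized across
patterns and rate categories.  Transition matrices come from the
spectral decomposition of the reversible Q through its symmetric
similarity transform, so P(t) is exact for any t.  Partial likelihoods
are rescaled every few internal nodes with per-pattern log
accumulators; 100-taxon trees evaluate without underflow.  Gaps, N and
ambiguity codes contribute all-ones partial vectors (missing data).

Rate heterogeneity: +G uses 4 equiprobable discrete gamma categories
with category-mean rates (the category means are computed from the
regularized incomplete gamma function and average exactly 1); +I mixes
in a zero-rate class with probability p_inv whose contribution is
evaluated in closed form (a zero-rate site is constant, likelihood
π_x).  Under +I the variable-rate classes are *not* rescaled by
1/(1−p_inv); the simulator uses the same convention (site rate = 0 with
probability p_inv, otherwise a mean-1 gamma draw), so simulation and
inference agree about what a branch length means.  The simulator draws
continuous gamma rates while inference uses 4 discrete categories —
a deliberate mismatch that mirrors how simulators and inference tools
differ on real projects.

The pruning pass exists twice: a numba-compiled kernel (used when
available) and a pure-numpy reference path.  They agree to the last
bit on the suite's checks, and both are validated against a brute-force
oracle that enumerates all internal-node state assignments on trees of
up to 5 taxa.

## Model fitting

Fitting maximizes lnL over free model parameters and branch lengths on
a fixed topology (no tree search).  Each sweep:

1. a Brent line search on a single multiplier applied to all branch
   lengths (removes the tree-scale/rate-scale interaction, which is the
   slowest direction of naive coordinate ascent — e.g. after a p_inv
   update changes the effective substitution rate);
2. one or more passes of per-branch Brent optimization on the log
   scale, using up/down partial vectors cached from a single
   post-order + pre-order traversal (partials go slightly stale within
   a pass; a pass is accepted only if the full likelihood improved);
3. a joint search over the free model parameters — log
   exchangeabilities, frequency logits, log alpha, p_inv — by Powell's
   direction-set method, i.e. repeated Brent line searches along an
   adaptively updated direction set.  Plain one-parameter-at-a-time
   ascent crawls here because the exchangeability coordinates are
   strongly correlated under the reference-rate parameterization;
   Powell's first iteration is exactly coordinate ascent and later
   iterations follow the learned diagonal directions.

Sweeps repeat until the improvement falls below `tol` (default 1e−6,
up to 50 sweeps); a fit that stops on the sweep cap is returned with
`converged=False`, never silently.  Defaults: optimizer starts at
exchangeabilities 1, empirical (or uniform) frequencies, alpha 1.0,
p_inv 0.1.  The +I+G pair is weakly identifiable: only lnL is
contract-guaranteed, not the alpha/p_inv split.  With the default line
search resolution, repeated fits reproduce lnL to about ±1e−3; the
tests treat that as the optimizer's precision floor.

Stationary frequencies of estimated-frequency models can either be
ML-optimized (single-fit default) or fixed at the empirical base
counts while still being charged 3 parameters — the "+F" accounting of
jModelTest and ModelTest-NG.  The benchmark pipeline uses the empirical
convention, which matches those programs and roughly halves the cost of
the richest fits.

Base trees: `"nj"` builds a neighbor-joining tree from JC-corrected
distances (saturated distances capped at 5.0 substitutions/site,
negative NJ branch lengths clamped to 1e−6) and holds the topology
fixed across all candidate fits for an alignment; `"true"` uses the
generating tree from the alignment's provenance, isolating criterion
behaviour from tree-estimation error.

## The synthetic benchmark

The generator emulates a standard model-recovery design: one alignment
per registry model, each on its own random tree.  Defaults are 100 taxa
and 10,000 sites per alignment, with 88 datasets in the full suite.
Topologies are uniformly random (stepwise addition), branch lengths
i.i.d. exponential with mean 0.1 truncated below at 1e−4 — realistic,
identifiable trees with expected length ≈ 19.7 for 100 taxa.
Generating parameters are drawn once per dataset from documented
priors: exchangeabilities log-uniform on [0.5, 8] relative to the GT
rate, frequencies Dirichlet(10,10,10,10), alpha uniform on [0.3, 2],
p_inv uniform on [0.1, 0.5]; all recorded in the alignment provenance
together with the seed and the tree.  Each dataset uses the substream
`seed + complexity_rank(model)`, so any single dataset can be
regenerated without the rest; suite runs are bit-identical given a
seed.

What the generator does *not* emulate: indels and alignment error,
compositional heterogeneity across lineages, heterotachy, recombination
and non-treelike signal, and selection-driven site dependence.  Passing
benchmarks therefore demonstrate criterion behaviour under the models'
own assumptions, not robustness to real-data violations of them.

The full-scale experiment (88 datasets × 88 candidate fits × 100 taxa ×
10,000 sites) takes hours on one CPU.  The test suite and the
acceptance script run a scaled variant chosen to preserve the
phenomenon while fitting a CI budget: 20 taxa, 2,000 sites, and a
24-model space (8 symmetry families × {none, +I, +G};
`REDUCED_BENCHMARK_MODELS`).  At this scale BIC's per-parameter penalty
ln 2000 ≈ 7.6 still dominates AIC's 2, so the qualitative result —
BIC recovers the generating model most often and selects the simpler
model whenever it disagrees with AIC — is stable across seeds, while
absolute recovery percentages are lower than at full scale (weak
effects drawn from the priors are harder to detect at 2,000 sites).
Pipeline fits use `tol=0.05` and at most 6 sweeps: criterion scores of
competing models differ by far more than 0.05 nats, so looser per-fit
convergence does not move the argmin; fits that stop on the cap are
flagged in the report.

## Contingency statistics

The agreement layer produces labels × (Yes, No) tables; the stats layer
applies Pearson's chi-squared test of independence with expected counts
from the margins and **no continuity correction** (also for 2×2
tables), Cramér's V = √(χ²/(N·(min(r,c)−1))) without bias correction,
and post-hoc pairwise row comparisons whose raw p-values are adjusted
by Benjamini–Hochberg step-up.  These choices were validated against a
published set of such tables bundled as fixtures
(`modelbench/data/reference_counts.json`): every chi-squared, raw p,
adjusted p and V reproduces at printed precision.  Two printed cells
are excluded as rounding slips in the source: a V printed as 0.53 that
computes to 0.5247, and an adjusted p printed as 2.20e−29 that computes
to 2.2107e−29 (R's own `chisq.test` + `p.adjust(method="fdr")` confirm
the computed value digit for digit).

## Degenerate inputs and numerical edges

* All-missing columns are admissible; they contribute likelihood 1.
* Zero branch lengths are admissible in evaluation (P(0) = I exactly);
  the simulator truncates lengths below 1e−4, the optimizer keeps them
  in [1e−8, 10].
* Identical sequences give an NJ star with clamped 1e−6 branches.
* Saturated distance pairs (p ≥ 0.75) are capped at 5.0.
* A likelihood of exactly −inf (impossible data under zero-length
  branches) is returned as −inf; NaN raises a `NumericError`.

## Known limitations

* No topology search: fits condition on a fixed tree (NJ or truth); the
  benchmark's recovery numbers do not include tree-estimation error the
  way a full program run would.
* The +I+G decomposition is reported but not guaranteed stable.
* AICc's small-sample correction uses n = sites; for k approaching n
  (tiny alignments, branch lengths included in k) AICc is refused
  rather than extrapolated.
* The 24-model scaled space omits the TPM/TIM/TVM families and +I+G
  variants; the full 88-model space is available to `run_benchmark`
  when the time budget allows.
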