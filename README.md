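# modelbench

Benchmarking information-criterion selection of nucleotide substitution
models.

Choosing a substitution model (JC, HKY, GTR+I+G, …) is the first step
of most phylogenetic analyses, and the choice is usually delegated to a
program that scores candidate models with an information criterion.
Which criterion should you trust?  `modelbench` answers that question
the empirical way: it simulates alignments whose generating model is
known, fits every candidate model by maximum likelihood, selects the
best model under AIC, AICc and BIC, and measures how often each
criterion recovers the truth.  It also ships the contingency-table
statistics (chi-squared tests of independence, pairwise post-hoc
comparisons with Benjamini–Hochberg adjustment, Cramér's V) used to
compare selection behaviour across criteria and across programs such as
jModelTest2, ModelTest-NG and IQ-TREE, together with a bundled set of
published comparison tables it reproduces exactly.

It is aimed at molecular evolution researchers and method developers
who want a transparent, scriptable re-implementation of the
model-selection benchmark loop rather than a black-box program wrapper.

## The core quantities

Each candidate model is scored on an alignment of *n* sites by its
maximized log-likelihood lnL (Felsenstein pruning on a fixed tree) and
free-parameter count *k*:

    AIC  = −2 lnL + 2k
    AICc = AIC + 2k(k+1)/(n − k − 1)
    BIC  = −2 lnL + k ln n

Smaller is better; BIC's per-parameter penalty ln n exceeds AIC's 2
whenever n ≥ 8, which is why BIC systematically prefers simpler models
— and, on simulated data, recovers the generating model far more often.
The model space is the standard 88-model DNA registry (11
exchangeability classes × equal/estimated frequencies × {none, +I, +G,
+I+G}).

## Worked example

```python
from modelbench import benchmark_suite, fit_model, select_best

# one simulated dataset: HKY+G on a random 12-taxon tree
aln, truth = benchmark_suite(n_taxa=12, n_sites=2000, seed=7,
                             models=["HKY+G"])[0]

fits = [fit_model(aln, name, tree=truth.tree, alignment_id="demo")
        for name in ("JC", "HKY", "HKY+G", "GTR+I+G")]
for criterion in ("AIC", "BIC"):
    rec = select_best(fits, criterion)
    print(criterion, rec.best, round(rec.table['score'].iloc[0], 2))
```

prints

```
AIC HKY+G 29973.0
BIC HKY+G 30118.62
```

Both criteria recover the generating model here; the scores are the
criterion values of the winning model (−2lnL plus penalty, with branch
lengths counted in k).  On harder draws AIC often overshoots to a
richer model while BIC stays on the truth — run the pipeline to
quantify that:

```python
from modelbench.cli_io import BenchmarkConfig, run_benchmark, REDUCED_BENCHMARK_MODELS
report = run_benchmark(BenchmarkConfig(n_taxa=20, n_sites=2000, seed=1,
                                       models=list(REDUCED_BENCHMARK_MODELS)))
print(report.recovery_percent())
```

```
{'AIC': 79.2, 'AICc': 79.2, 'BIC': 95.8}
```

i.e. over 24 datasets BIC recovered the generating model 95.8% of the
time against 79.2% for AIC/AICc — the pattern that holds at every scale
we test.

There is also a CLI: `modelbench simulate | fit | select | benchmark |
stats | reproduce | models` (see `modelbench --help`).

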