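# permdiff

Permutation-validated differential DNA methylation and expression
analysis for small two-group designs (RRBS + RNA-seq).

Small-n omics comparisons — six livers per feed group, four RNA-seq
replicates per group — face a credibility problem: per-locus p-values
rest on distributional assumptions, and a handful of samples can
separate for reasons unrelated to the contrast of interest. `permdiff`
implements the analysis pattern that addresses this directly: run the
per-locus test, then re-run the *entire* analysis under group-label
permutations and report how many discoveries a wrong labelling
produces. The package bundles:

- a **beta-binomial Wald test** per CpG with coverage-weighted
  dispersion shrinkage (counts m ~ BetaBin(t, μ, φ) with
  Var = t·μ(1−μ)(1+(t−1)φ)), BH-adjusted;
- a **running-sum DMR caller** over per-CpG f-statistics:
  s_i = max(0, s_{i−1} + log2(f_i/mean f) − p·(d_i − d_{i−1})), a
  region spanning its first CpG to the maximal-score CpG each time the
  score returns to zero;
- a **permutation engine** (exhaustive or random labelled assignments,
  composition classes, empirical FDR = mean null count / observed
  count) that accepts any per-feature test;
- **expression analysis**: Welch t on log2(FPKM+1), volcano classes,
  k-means expression profiles, directional hypergeometric gene-set
  tests, expression-matched background sampling;
- **genome context**: promoter/island/shore/intergenic feature
  enrichment (Fisher exact), TSS-distance window enrichment
  (hypergeometric + Holm), nested TSS-window methylation PCA with
  group-segregation tests, nearest-gene assignment, promoter
  methylation–expression association;
- a **synthetic-data generator** producing annotation, a bimodal
  RRBS-like methylome (80% of CpGs above 0.8 methylation, 6% below
  0.1, a methylation dip with an RRBS coverage peak at CpG-island
  promoters) and expression matrices with planted, recorded effects.

See `docs/methods.md` for the models, assumptions and numerical
policies.

## Worked example

```python
from permdiff import (SimulationConfig, simulate_annotation,
                      simulate_methylome, DifferentialMethylation,
                      random_assignments, permutation_discovery_counts,
                      betabin_wald_test)

cfg = SimulationConfig(seed=1)          # 6 vs 6, 100 planted DMLs at Δβ=0.3
model = simulate_annotation(cfg)
meth, truth = simulate_methylome(model, cfg)

res = DifferentialMethylation(meth).fit(min_cov=10)
print(res.summary())
```

```
Differential methylation (beta-binomial Wald test)
==================================================
groups:              control vs low1C
samples:             12
sites tested:        59405
f-track sites:       39871 (coverage >= 10 in all samples)
significant q<0.05:  101
mean dispersion:     0.0144
mean f-statistic:    1.338
```

101 CpGs pass q < 0.05 — the 100 planted loci (96 of them recovered)
plus a few false positives. How many would a wrong labelling find?

```python
assigns = random_assignments(meth.samples, (6, 6), n=100, seed=2,
                             reference_groups=meth.groups)
summary = permutation_discovery_counts(
    meth, lambda tab, g: betabin_wald_test(tab.relabel(g)),
    "q", 0.05, assigns, meth.groups)
print(summary.observed, round(summary.mean_null, 2),
      round(summary.empirical_fdr, 4))
```

```
101 0.51 0.005
```

Random relabellings discover on average half a site; the excess of
the true labelling over the permutation null (~100) matches the
planted signal, and the empirical FDR is 0.005. Regions come from the
same fit:

```python
dmrs = res.call_dmrs(penalty=0.02)      # list of DMR records
```

A console script mirrors the library
(`permdiff simulate|diffmeth|dmr|permute|diffexpr|geneset-test`).

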