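# Methods

`permdiff` implements the statistical core of a two-group epigenomic
study design: reduced-representation bisulfite sequencing (RRBS)
methylation counts and RNA-seq abundances measured in a control and a
treatment group, analysed with per-locus tests whose biological
credibility is established by re-running the entire analysis under
group-label permutations. Everything is exercised on a synthetic
generator with planted ground truth, so each stage's operating
characteristics (calibration, power, bias) are measured rather than
assumed.

## Per-CpG differential methylation

Methylated/total read counts (m_si, t_si) for sample *s* at CpG *i* are
modelled as beta-binomial: conditional on a sample-level methylation
proportion p_si ~ Beta with mean μ_gi (the group mean) and dispersion
φ_i, the count m_si ~ Binomial(t_si, p_si), giving

    Var(m_si) = t_si · μ(1−μ) · (1 + (t_si − 1) φ_i).

**Dispersion estimation.** φ_i is estimated per site by the method of
moments from residuals of sample proportions around the group-pooled
means, with an (n−1)/n degrees-of-freedom correction so the estimator
is unbiased at equal coverages. Per-site estimates are then shrunk
toward the 10%-trimmed mean of all finite estimates:

    φ_shrunk = w φ̂ + (1 − w) φ̄,   w = T / (T + T0),

where T is the site's total coverage and T0 = 240 reads (the prior's
pseudo-coverage, equivalent to 20 reads in each of 12 samples). The
weight therefore grows with the information available at the site.
Simulation at coverage 30 with 12 samples recovers a known φ within
25% (see the test suite).

**Wald test.** Group proportions are estimated as pooled reads
Σm/Σt; their variances use the beta-binomial form divided by (Σt)².
The statistic (μ̂1 − μ̂2)/se is referred to a two-sided standard
normal — the convention of the DSS family of beta-binomial locus
tests. At 6 vs 6 samples this reference is mildly anti-conservative
(measured null rejection ≈ 0.063 at α = 0.05); the permutation layer
below, not the asymptotic p-value, carries the inferential weight.
μ estimates used inside the variance are clamped to
[1/(Σt+2), 1 − 1/(Σt+2)] so the variance never degenerates at
boundary proportions. Sites with zero coverage throughout a group are
flagged untested. Multiplicity is controlled by Benjamini–Hochberg.

**Coverage policy.** The locus test uses every sample with reads at a
site. The f-statistic track and all PCA analyses instead require a
minimum of 10 reads in *every* sample, reflecting the stricter
completeness these multivariate summaries need.

## Running-sum DMR caller

For every retained CpG the one-way ANOVA f-statistic (between-group
over within-group variance of sample methylation proportions) is
computed; proportions, not counts, are the unit of analysis. Sites
with zero within-group variance get the capped value 1/ε (ε = 1e−8)
and are excluded from the genome-wide mean f. The running score is

    s_i = max(0, s_{i−1} + log2(f_i / mean f) − p · (d_i − d_{i−1})),

with separation penalty p = 0.02 per bp by default. A region is
emitted whenever the score returns to zero after being positive (or
at a chromosome end while positive), spanning its first CpG to the
argmax CpG; the region's score is the maximal s. Boundary policies:
the score resets across chromosomes and the first CpG of a chromosome
carries no gap term (its predecessor distance is undefined); f = 0
forces the score to zero via a clamped log-ratio. The recursion is
verified exactly against an O(n²) direct-maximisation oracle and, at
p = 0, against the clipped maximum-subarray (Kadane) limit.

A note on monotonicity: a larger penalty can never increase the score
anywhere, but it *can* split one positive run into two, so the count
of emitted regions is not monotone in the penalty; only the scores
are. No significance is attached to region scores — regions are
descriptive, ranked summaries of the locus statistics.

## Permutation empirical FDR

Labelled group assignments are either enumerated exhaustively
(C(n, n1) of them; both orientations of each partition count) or drawn
uniformly at random with replacement, mirroring repeated shuffles with
R's `sample()`. Each assignment carries a composition class — how
many samples of one true group sit together in an assigned set
("4+0", "3+1", "2+2" for a 4 vs 4 design) — because discovery counts
are expected to rise sharply for assignments close to the true split.
The per-feature test is injected as a callable, so the same engine
serves the expression and the methylation analyses. The empirical
false-discovery ratio is

    eFDR = mean(null discovery counts) / observed count,

reported as NaN when nothing is observed. In exhaustive mode the two
true-partition assignments are excluded from the null mean; in random
mode a drawn true assignment is kept by default (togglable), since
uniform sampling schemes typically impose no exclusion. The
observed-minus-mean-null difference estimates the number of
discoveries attributable to the true grouping; on synthetic data it
recovers the planted DML count within ±30%.

## Differential expression

The per-gene test is deliberately plain: Welch's t on log2(FPKM + 1)
(pseudocount 1), BH-adjusted, with log2 fold change computed from
(mean + 1) abundances, treatment over control. It is mildly
conservative at 4 vs 4 (Satterthwaite df); its purpose is to be a
well-understood, label-exchangeable plumbing test for the permutation
engine, not a read-count model. Volcano classes use strict
inequalities (|FC| > 2, q < 0.05). k-means clustering of significant
genes (k = 12 by default) runs on log2(FPKM + 1) with cluster-mean
profiles min–max scaled per row, as displayed in heat maps.
Directional gene-set enrichment is the upper-tail hypergeometric
probability of observing at least k direction-significant genes in a
set of K given M of N in the universe (default universe: all tested
genes). Expression-matched backgrounds sample non-target genes to
match the targets' per-decile expression distribution, falling back
to sampling with replacement (with a warning) when a bin is exhausted.

## Genome context

Intervals are 0-based half-open throughout; BED on disk. Features:
strand-aware promoters (5 kb upstream of the TSS, clamped at
chromosome bounds), introns = transcript minus exon, island shores =
5 kb flanks minus island bp, intergenic = complement of gene bodies
padded by 50 kb. Categories may overlap (a promoter CpG can sit in an
island) and are tested independently: per feature a 2×2 Fisher exact
test of DML membership with log2((k/n_dml)/(K/n_sites)) as the
enrichment ratio. TSS-distance windows (1 kb wide, 500 bp step,
±5 kb) get upper-tail hypergeometric p-values given window totals and
the global DML rate, Holm-adjusted across non-empty windows. The
|statistic|-by-distance profile reports per-distance means and a
Gaussian-kernel smoothed curve (bandwidth 50 bp, count-weighted).

**Nested TSS-window PCA.** For each of eight nested extents per side
(600…4800 bp, a geometry chosen to bracket the 1600–4800 bp zone
where upstream group signals are expected; the widths are
configurable), a sample × TSS matrix of window mean methylation is
built — a CpG near several TSSs contributes to each, and window means
are unweighted means of per-site levels (a coverage-weighted option
exists). TSSs with no covered CpG are dropped. PCA is centred and
unscaled; PC1 scores are compared between groups with a two-sample
t-test and an exact Mann–Whitney U test, and "separated" flags
disjoint group ranges on PC1. Complete 6 vs 6 separation has exact
two-sided MWU p = 2/C(12,6) ≈ 0.00216.

Nearest-gene assignment uses interval distance (0 when overlapping,
40 kb cap, ties to the smaller gene start). The promoter
methylation–expression association is a Spearman correlation of
per-gene mean promoter methylation against mean log2 expression with
a permutation p-value; constant inputs are flagged degenerate with
ρ = 0 by convention.

## Synthetic generator

The generator emulates the *structure* of an RRBS + RNA-seq liver
study, not any particular genome:

- **Annotation.** Two 4 Mb chromosomes; 400 transcripts with 2–7 exons
  on a jittered grid confined to the first 60% of each chromosome (the
  remainder provides genuine intergenic space); 250 CpG islands of
  mean length 800 bp, a Bernoulli 70% of them centred on TSSs; CpG
  sites with exponential spacing (mean 150 bp background, 30 bp inside
  islands), ~60k sites in total.
- **Methylome.** Latent site methylation from a three-component Beta
  mixture — high Beta(30, 2), low Beta(0.8, 25), intermediate
  Beta(2, 2). Sites within ±200 bp of a TSS draw from the low
  component (the TSS dip); background component probabilities are then
  solved so the net genome-wide fractions hit the configured profile
  (80% of sites above 0.8, 6% below 0.1) regardless of annotation
  geometry. Coverage is negative-binomial (mean 30, size 5), tripled
  inside islands to emulate RRBS enrichment; counts are beta-binomial
  with dispersion φ = 0.01. A multiplicative dip was considered and
  rejected: it moves high-methylation sites into the middle of the
  distribution and cannot hold the bimodal profile fixed.
- **Planted effects.** 100 DMLs at |Δβ| = 0.3 (sign random, flipped
  when infeasible for the latent level, resampled and logged when both
  directions are infeasible), placed inside promoters and optionally
  in runs of consecutive CpGs for region-scale signals. Optionally a
  group-wide shift confined to a strand-oriented upstream distance
  band (default 1600–4800 bp) for segregation studies. Expression:
  log-normal baselines (log2 mean 5, sd 2), lognormal replicate noise
  (CV 0.2), 100 planted genes at |log2FC| = 2, down-regulated with
  probability 0.68.
- **Determinism.** One global seed; each stage (annotation, methylome,
  expression) derives its own numpy sub-stream, so regenerating one
  stage never perturbs another.

What the generator does *not* emulate: read-level artefacts (bisulfite
conversion failure, mapping bias, strand effects), non-CpG
methylation, correlated methylation between neighbouring CpGs beyond
the planted clusters, library-size and GC effects in expression, and
any coupling between the methylation and expression layers. Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under a clean generative model, not performance
on real libraries.

## Problem sizes and numerical choices

Test and acceptance runs use the default ~60k-site genome for
effect-recovery checks, a single-chromosome ~5k-site genome for null
calibration sweeps (20 seeds), 20–30 random permutations per seed
inside the test suite and 100 in the acceptance script, and a
40-transcript genome for the nested-window PCA power study so
neighbouring TSS windows do not overlap. These sizes were chosen as
the smallest at which the measured quantities stabilise. Tolerances:
f-statistic vs oracle exact to 1e−10; DMR scores vs oracle to 1e−9;
type-I bands [0.03, 0.07]; mixture fidelity ±0.05 (high) / ±0.03
(low). Degenerate inputs (zero within-variance, zero-coverage groups,
constant PCA matrices, empty windows or bins) follow the explicit
policies above rather than raising blindly; each has a dedicated test.
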