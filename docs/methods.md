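# Methods

This note documents the statistical machinery behind `nohelp`: the models,
the defaults and why they are what they are, what the synthetic data does
and does not emulate, and the numerical choices that affect results.

## Differential-expression model

Counts for gene *g* in sample *j* are modelled negative-binomial with mean
μ<sub>gj</sub> proportional to the sample's effective library size and a
single dispersion φ shared by all genes, variance = μ + φμ². A common
dispersion (rather than per-gene estimates with shrinkage) is a deliberate
simplification: with 3 replicates per condition, per-gene dispersions are
extremely noisy, and the exact-test framework below needs one φ anyway.
The consequence is that genes whose true dispersion is far above the common
value will be slightly anticonservative, and vice versa.

**Effective library size.** Column sums times TMM factors. TMM (trimmed
mean of M-values) compares each sample to a reference (the sample whose
upper-quartile proportion is closest to the mean), trims the 30% most
extreme log-ratios (M) and 5% most extreme log-abundances (A)
symmetrically, and averages the surviving M weighted by inverse asymptotic
variance; factors are rescaled to geometric mean 1. TMM is on by default in
the DE path: when a non-negligible fraction of genes is truly differential,
their contribution to the library size shifts every null gene's CPM, and we
measured the false-discovery proportion at q < 0.01 rising from ~2% to ~23%
on the standard fixture when TMM is disabled. The scoring path
(correlations) deliberately uses plain CPM: Pearson correlation is
invariant to per-sample rescaling, so factors cannot change a score, and
the score's definition calls for plain normalized read counts.

**Dispersion estimation.** Samples are scaled to the geometric mean of the
effective library sizes, rounded half-up to integer pseudo-counts. φ
maximizes the sum over genes and conditions of the NB log-likelihood of the
within-group pseudo-counts *conditional on their group sum*. Conditioning
removes the per-gene group mean as a nuisance parameter; maximizing the
unconditional likelihood with free means instead would estimate within-group
variance with divisor *n* rather than *n* − 1 and bias φ low by roughly
(*n* − 1)/*n* — at *n* = 3 we measured 0.062 for a true φ of 0.1, which
inflates the type-I error well past nominal. The search is a 25-point
log-spaced grid on [1e-4, 5] refined by golden section to 1e-8 on the log
scale; it is fully deterministic. Data with zero within-group variance
drive the estimate to the grid's lower bound (φ → 0 is the Poisson limit).

**Exact test.** Pseudo-counts are summed per condition; under the null the
group sums are NB with mean *n*<sub>i</sub>μ and dispersion φ/*n*<sub>i</sub>
(the NB family is closed under summation of iid terms). The two-sided
p-value of the observed split (s<sub>A</sub>, s<sub>B</sub>) of the total T
is the sum of conditional probabilities of all splits whose probability is
at most that of the observed one (with a 1e-12 relative margin for
floating-point ties); the conditional law is evaluated by direct
enumeration of all T + 1 splits in log space. At φ = 0 this reduces exactly
to the two-sided exact binomial test on T with success probability
n<sub>A</sub>/(n<sub>A</sub>+n<sub>B</sub>). T = 0 returns p = 1 by
convention. Rounding pseudo-counts half-up keeps the enumeration on
integers; the quantile-adjustment refinements found in the exact-test
literature are out of scope and their omission is visible only as mild
conservatism at very small counts.

**FDR.** Benjamini–Hochberg step-up, q(i) = min<sub>j≥i</sub> p(j)·m/j
capped at 1, reported in input order. The signature keeps q < 0.01 (the
threshold is a parameter), ordered by q ascending, then |log2 fc|
descending, then gene id — fully deterministic. Fold changes are
log2((CPM̄<sub>NoHelp</sub> + 0.5) / (CPM̄<sub>Help</sub> + 0.5)); the 0.5
offset avoids infinities and matters only for near-zero means.

## No Help score

Centroids are arithmetic means of CPM expression per condition, restricted
to signature genes present in the reference (absent genes are dropped with
a logged count; fewer than `min_overlap` = 10 shared genes is an error —
a correlation over fewer genes is noise). The score of a profile is the
difference of its Pearson correlations with the No-Help and Help centroids,
both computed on the identical overlap gene set. It lives in [−2, 2], is
exactly antisymmetric under centroid swap, and is invariant to shifting or
positively rescaling the query profile.

Correlations are computed on untransformed CPM by default. Raw-CPM Pearson
is dominated by high-expression genes; a log2(CPM + 1) option exists for
users who prefer variance-stabilized similarity. The default follows the
score's plain definition on normalized read counts, and the package's own
validation (mixture recovery, sign separation of the reference samples)
passes under it.

Gene ids are matched exactly after uppercasing and whitespace-stripping, so
mouse-style and human-style symbol casings meet without a mapping table;
for genuine cross-species use a two-column mapping table is applied first,
keeping only pairs that are one-to-one in both directions (ambiguous
orthologs are dropped and counted rather than guessed).

## GSEA

The ranking metric is signal-to-noise, (mean<sub>A</sub> −
mean<sub>B</sub>)/(sd<sub>A</sub> + sd<sub>B</sub>), each sd floored at
max(0.2·|group mean|, 1e-8) — the floor keeps near-constant genes from
dominating. Ties order lexicographically by gene id, making ranks
deterministic across platforms. The enrichment score walks the ranked
list: hits add |metric|<sup>p</sup> normalized over hits (p = 1 by
default; p = 0 gives the classical unweighted statistic), misses subtract
1/(N − N<sub>hits</sub>); ES is the extremum of the running sum (first
index of maximal magnitude when tied) and the leading edge is the hits at
or before it (at or after, for negative ES).

Significance defaults to gene-set permutation — random same-size sets —
because the intended designs have 3 samples per arm, where phenotype
permutation supports only C(6,3) = 20 splits. Phenotype mode exists and
switches to exhaustive enumeration of all splits whenever there are at
most 10,000, making it exact (and seed-independent) for small designs.
p = (1 + #{same-sign null ES at least as extreme}) / (1 + #same-sign
nulls), never zero by construction; NES divides ES by the mean magnitude of
same-sign nulls. p-values are one-tailed in the direction of the observed
ES; with few same-sign nulls the p floor 1/(1 + #same-sign) is the honest
resolution limit.

## Group statistics

Two groups: classical pooled-variance Student's t (not Welch), two-tailed.
Degenerate zero-variance input returns t = 0, p = 1 when means agree and is
an error otherwise. Matched designs: within-subject one-way ANOVA on the
complete subjects × conditions table, F = MS<sub>condition</sub> /
MS<sub>subject×condition</sub>; Tukey pairwise p-values use the
studentized-range distribution q = |mean difference| /
√(MS<sub>err</sub>/n<sub>subjects</sub>) with (k−1)(n−1) error df,
evaluated by scipy's quadrature implementation of the studentized-range
tail (validated in the test suite against a Monte-Carlo oracle of the
range of k normal means over an independent chi scale). Sphericity is
assumed, as is standard for the small designs this targets; no
Greenhouse–Geisser correction is applied.

## Synthetic data

`simulate_reference` draws per-gene baseline means log-normal
(mean_log_mu = 3.3, sd_log_mu = 1.2 on the natural-log scale), giving a
median baseline around 27 with a realistically heavy right tail; expected
counts are the condition's mean proportions times a library size drawn
uniformly from 0.8–1.2 million, and counts are gamma-Poisson (NB) with the
configured φ. DE genes (10% by default) get ±2 log2 units applied to the
No-Help condition, half up, half down. The default design — 2000 genes,
3 vs 3, φ = 0.1, seed 17 — mirrors the small sorted-population bulk
RNA-seq settings the method targets while keeping the full test suite fast;
the dispersion and replicate numbers are typical of such experiments.

Query panels are convex mixtures w·c<sub>NoHelp</sub> + (1−w)·c<sub>Help</sub>
with gene-wise Gaussian noise of sd 0.2 × the mixed value, floored at zero
— multiplicative-scale noise preserves the correlation structure that the
score reads while keeping expression non-negative. Mixtures emulate the
graded predysfunctional → exhausted continuum conceptually, not its
biology.

What the generator does **not** emulate: real gene–gene correlation,
per-gene dispersion heterogeneity, batch effects, GC/length biases, or any
actual immunological gene content. Passing tests therefore demonstrate
statistical correctness of the machinery under its own model, not that a
particular biological dataset will reproduce any published gene list; with
reference data from public repositories the derived signature will depend
on the DE engine and its settings, and this package's exact test is not
expected to match an external tool's list gene-for-gene.

## Degenerate inputs and numerical conventions

- All-zero gene matrices, empty filters, zero library sizes, constant
  profiles and insufficient signature overlap raise errors rather than
  returning NaN.
- An empty signature (no gene passes the FDR threshold) is a valid,
  warned result — it is what a null dataset should produce.
- TMM falls back to factor 1 with a warning when no genes survive
  trimming; the exact test returns p = 1 for an all-zero gene.
- Problem sizes in the test suite (500–5000 genes, 200 permutation
  replicates, 1e5-resample oracles) were chosen as the smallest sizes at
  which the calibration bands are statistically meaningful.
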