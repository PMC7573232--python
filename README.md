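# nohelp

Tools for the transcriptional **"No Help" analysis** of CD8+ T cells: deriving
a differential-expression signature that separates CD8+ T cells primed
*without* CD4+ T cell help from helped ones, scoring any query expression
profile for its similarity to the helper-deprived state, and testing
published gene sets for enrichment in the Help vs No-Help contrast.

The package is aimed at computational immunologists who have bulk RNA-seq
count matrices (e.g. sorted predysfunctional TCF-1+ vs terminally exhausted
TCF-1− CD8+ T cells, or patient-matched PD-1-high/intermediate/negative
TILs) and want to ask: *how "helpless" does this population look?*

## The method

**Signature derivation.** For a two-condition reference (No-Help vs Help,
*n* replicates each), genes with all-zero counts are removed and each gene
is tested with a negative-binomial exact test: samples are scaled to a
common effective library size (TMM-adjusted), counts are summed per
condition, and the two-sided p-value is the total conditional probability of
all splits of the grand total *T* = *s*<sub>A</sub> + *s*<sub>B</sub> no
more probable than the observed one, under per-group NB laws with a single
common dispersion φ (variance = μ + φμ²) estimated by conditional maximum
likelihood. Benjamini–Hochberg q-values are computed and genes with
q < 0.01 form the signature, each with a direction and a log2 fold change on
CPM group means.

**No Help score.** Reference CPM expression is averaged per condition over
the signature genes, giving two centroids. A query profile *x* scores

    NoHelpScore(x) = r(x, c_NoHelp) − r(x, c_Help)

where *r* is the Pearson correlation over the signature genes shared by
query and reference. Positive scores mean the query transcriptome is closer
to the helper-deprived state. A one-to-one gene-id mapping table lets
profiles from another identifier namespace (e.g. human orthologs) be scored
against a mouse-derived signature.

**GSEA.** Genes pass a ≥5-reads-in-every-sample filter, are TMM-CPM
normalized and ranked by signal-to-noise; a gene set's enrichment score is
the extremum of the weighted Kolmogorov–Smirnov-like running sum, with a
permutation null (random same-size sets, or exhaustive label permutation
for small designs), NES = ES / mean |same-sign null ES|.

**Statistics.** Score groups are compared with the unpaired pooled-variance
Student's t-test, or, for subject-matched populations, repeated-measures
one-way ANOVA with Tukey's studentized-range pairwise tests.

A seeded synthetic-data generator (NB counts with known DE truth, centroid
mixture query panels, renamed "cross-species" variants, GMT files of the
true sets) makes the whole pipeline testable end to end with no downloads.

## Worked example

```sh
python examples/01_derive_signature.py
```

prints (exactly, given the fixed seed):

```
reference: 2000 genes x 6 samples, 200 truly differential
signature: 185 genes at FDR < 0.01 (dispersion phi = 0.099)
sensitivity = 0.915  (fraction of true DE genes recovered)
false-discovery proportion = 0.011  (fraction of called genes that are null; BH controls this at 1% in expectation)
top gene: gene00523, log2 fold change +2.91 (No-Help over Help), q = 4.99e-10
```

The simulation plants 200 differential genes at |log2 fc| = 2 with
dispersion φ = 0.1 among 2000, 3 vs 3 replicates; the pipeline recovers 91%
of them with an observed false-discovery proportion of 1.1%, and the
dispersion estimate (0.099) matches the generating value. The other
examples score centroid mixtures (`02`, scores rise monotonically from
−0.55 at w = 0 to +0.50 at w = 1), run GSEA (`03`, true up-set
NES = +3.46, p = 0.0018), score through an ortholog mapping (`04`,
identical scores before/after renaming), and compare score groups (`05`).

The same pipeline is available as a CLI:

```sh
nohelp --seed 17 --out-dir fixtures simulate
nohelp --out-dir fixtures derive-signature \
    --counts fixtures/ref_counts.tsv --meta fixtures/ref_meta.tsv
nohelp --out-dir fixtures score --signature fixtures/signature.tsv \
    --reference fixtures/ref_counts.tsv --ref-meta fixtures/ref_meta.tsv \
    --query fixtures/query_mixtures.tsv
nohelp --seed 1 --out-dir fixtures gsea --counts fixtures/ref_counts.tsv \
    --meta fixtures/ref_meta.tsv --gmt fixtures/true_de_sets.gmt
```

Every command writes a JSON run-manifest next to its output; seeded runs
are byte-identical on repetition.

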