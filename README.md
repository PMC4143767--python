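# goftscan

A window-based association scan for whole-genome sequencing data that
combines the evidence of common and rare variants with a goodness-of-fit
statistic, and assesses it by permutation.

## The problem

Single-variant association tests miss two kinds of true signal: common
variants with small allelic effects, and rare variants whose effects may
be strong per allele but are carried by too few individuals to reach
significance on their own.  Both leave a faint, *sparse* trace across a
genomic region — a handful of p-values that are smaller than uniformity
predicts, without any single one crossing a genome-wide threshold.

`goftscan` tests fixed-width genomic windows (10 kbp by default) rather
than single variants.  Within a window, every testable variant — and
every run of rare variants, collapsed into one burden pseudo-variant —
contributes an association p-value, and the window-level question
becomes a goodness-of-fit test: *do these L p-values look like a sample
from Uniform(0,1)?*

## The statistic

Let `p_(1) <= ... <= p_(L)` be the window's sorted p-values.  The
Berk–Jones statistic is

```
G = L * max_{1<=j<=L} 2 K(j/L, p_(j)),

K(t, x) = t log(t/x) + (1-t) log((1-t)/(1-x))   for 0 < x < t < 1,
        = 0                                      for 0 <= t <= x <= 1,
```

i.e. the (one-sided) Kullback–Leibler divergence between the empirical
fraction of p-values at or below `p_(j)` and its null expectation.  At
`j = L` the analytic limit `K(1, x) = -log(x)` is used.  G is large when
some prefix of the sorted p-values arrives earlier than uniformity
allows — the maximisation adapts to the signal's sparsity instead of
fixing attention on the single smallest p-value.  This family of
statistics is asymptotically optimal for detecting weak, sparse effects,
which is exactly the regime of the missing-heritability problem.

Significance is empirical: the sample-to-phenotype assignment is
permuted M times (M = 1000 by default), G is recomputed each time
(preserving the window's linkage-disequilibrium structure, since
genotype rows are never broken apart), and

```
p_s = #{ G_s^(m) >= G_s } / M .
```

Rare variants (sample MAF < 5% by default) occurring between adjacent
common variants are collapsed by genotype summation before testing;
per-variant p-values come from an OLS slope t-test (quantitative trait)
or a logistic score test (binary trait), with optional covariates.
Because the statistic needs only p-values, a second study's per-variant
p-values (e.g. an array-based GWAS analysed elsewhere) can be merged
into each window's set before computing G — p-value-level meta-analysis.

## Worked example

```python
from goftscan import (CollapseConfig, SimScenario, scan, select_causal,
                      simulate_genotypes, simulate_phenotype)

scn = SimScenario(n_samples=200, n_windows=20, variants_per_window=12,
                  fraction_rare=0.9, rare_maf_range=(0.005, 0.03),
                  true_window_fraction=0.2, causal_per_true_window=8,
                  effect_size=0.5, seed=8)
gm, windows = simulate_genotypes(scn)
truth = select_causal(gm, windows, scn)
pheno = simulate_phenotype(gm, truth, scn)
results = scan(gm, pheno, windows, collapse=CollapseConfig(), M=500, seed=8)
```

Ranking the results by empirical p-value (`examples/scan_simulated_cohort.py`
prints the full table):

```
                window   L        G   p_emp  causal
  chrSIM:140000-150000   7   13.757   0.000  yes
    chrSIM:50000-60000   3   11.571   0.000  yes
    chrSIM:30000-40000   3   10.679   0.008  yes
  chrSIM:120000-130000   3    5.425   0.084
    chrSIM:10000-20000   1    5.004   0.090
```

`L` is the window's p-value count after collapsing (12 raw variants
shrink to a few burden columns plus the common sites), `G` the
Berk–Jones statistic, and `p_emp` the fraction of 500 permutations whose
statistic reached the observed one — `0.000` means none did
(p < 1/500).  Three of the four truly causal windows head the ranking.

The other scripts in `examples/` each demonstrate one capability:
`window_statistic.py` (the statistic itself), `rare_variant_collapsing.py`
(burden coding and the power it buys), `meta_analysis.py` (merging an
external p-value source), and `files_and_cli.py` (dosage/phenotype files
and the `goftscan run` command line).

## Command line

```bash
goftscan run --genotypes cohort.vcf --phenotype pheno.tsv \
             --window-width 10000 --permutations 1000 --seed 1 --out scan
goftscan simulate --scenario scenario.txt --out sim
goftscan meta --results scan --external gwas_pvalues.tsv --out merged
```

`run` accepts VCF (GT or DS) or dosage TSV genotypes and writes a
per-window results table, the window BED, per-window p-value sets, a
variant classification table and a reproducibility manifest.

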