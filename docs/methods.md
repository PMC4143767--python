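# Methods

## Model and procedure

`goftscan` treats a genomic window of L testable variants as a multiple
testing problem.  Under the global null of no association, the
per-variant p-values are (approximately) independent draws from
Uniform(0,1); association anywhere in the window makes some of them
stochastically small.  The window statistic is the Berk–Jones
goodness-of-fit statistic

G = L · max_{1≤j≤L} 2·K(j/L, p_(j)),

where p_(1) ≤ … ≤ p_(L) are the sorted p-values and K(t,x) is the
Kullback–Leibler divergence between Bernoulli(t) and Bernoulli(x),
restricted to the one-sided region x < t (only *early* arrivals count)
and zero otherwise.  The maximisation over the sorted ranks lets the
statistic adapt to the sparsity of the signal: it does not commit to the
minimum p-value, nor average all of them, but finds the prefix of the
empirical distribution that deviates most from uniformity.  Statistics
of this family attain the optimal detection boundary for weak, sparse
Gaussian-means signals, the asymptotic stand-in for regression-based
association in large samples.

The full scan is:

1. **Segmentation.** Tile each chromosome with half-open windows of a
   fixed width (default 10 kbp), anchored at coordinate 0.  A variant at
   1-based position P belongs to the window containing offset P−1.
2. **Classification and collapsing.** Compute each variant's sample MAF
   from dosages (MAF = min(f, 1−f), f = mean dosage / 2).  Variants with
   MAF strictly below the threshold (default 5%) are rare.  Within each
   window, maximal runs of rare variants delimited by common variants
   are summed sample-wise into one burden pseudo-variant each; runs
   before the first and after the last common variant form their own
   groups.  Monomorphic variants are dropped.  Runs never cross window
   boundaries — the window is the analysis unit.
3. **Per-variant tests.** Quantitative traits: two-sided t-test on the
   OLS slope of trait on additive dosage, computed as the (partial)
   correlation form so that a whole block of permutations is one matrix
   product; covariates are removed from both sides first
   (Frisch–Waugh–Lovell), with the degrees of freedom adjusted.  Binary
   traits: logistic score test against the covariates-only null model
   (intercept-only null in closed form; with covariates, one null GLM
   fit per trait column).  Both reduce to textbook formulas and are
   cross-checked against statsmodels in the test suite.
4. **Permutation null.** The trait vector is permuted relative to the
   genotype rows M times (default 1000, matching common practice for
   this scan).  Genotype rows are never broken apart, so LD within every
   window is preserved exactly.  One permutation stream per replicate
   index m (seeded by (seed, m)) is shared across all windows: this is
   computationally economical and valid because exchangeability is
   genome-wide, and it makes results independent of window scheduling.
   The empirical p-value is #{G^(m) ≥ G_obs}/M with the weak inequality;
   it can be exactly 0, and an optional (#+1)/(M+1) estimator is
   provided for −log10 displays.
5. **Meta-analysis.** External per-variant p-values (chrom, pos, id, p)
   are assigned to windows by position; records duplicating an
   internally tested (chrom, position) are dropped — the
   sequencing-derived p-value wins — and the rest are appended to the
   window's set before G.  Under each permutation the external p-values
   are resampled from Uniform(0,1), because the external genotypes are
   not available to permute.  This is a declared approximation: it is
   exact for null external sources (their p-values are uniform) and
   conservative bookkeeping for informative ones (the observed merged G
   is compared against a null that re-randomises the external
   contribution).  Results carry an `n_external` flag.

## Numerical choices

- K at t = 1 (always reached at rank j = L) uses the analytic limit
  K(1,x) = −log x with the 0·log 0 = 0 convention; the piecewise
  definition taken literally would send every window to +∞.
- p-values of exactly 0 (possible in principle from degenerate inputs)
  are clamped to a floor of 1e-15 before the divergence, and the
  clamping is logged.  The +∞ branch (x = 0 with t > 0) is represented
  by `math.inf`, compares greater than any finite statistic, and is
  never fed into downstream arithmetic.
- log(t/x) is computed as log t − log x, and log((1−t)/(1−x)) via
  `log1p`, for stability at extreme ratios.
- Ties among sorted p-values need no special handling; the first
  maximising rank is reported.
- Dosages within 0.01 of [0, 2] are clamped into range (imputation
  files carry numeric spill); values further out are an error.
- Zero-variance (e.g. monomorphic) columns are flagged untestable and
  excluded from the window's p-value set; a window with no testable
  column is reported `untested`, never as p = 1.
- Missing genotypes: the default drops, per window, every sample with a
  missing call in that window; per-variant mean imputation is available.

## Synthetic data: what it emulates and what it does not

The generator targets the statistical regime of a sequencing-based
association study of unrelated individuals, not any particular cohort:

- **Genotypes.** Two latent-Gaussian haplotypes per sample; within a
  window the latent process is AR(1) with autocorrelation `ld_rho`
  (default 0.5) and is thresholded at the normal quantile of each
  variant's target MAF.  Marginal allele frequencies therefore match
  their targets in expectation while neighbouring variants are
  positively correlated — a local-LD caricature adequate for testing a
  method whose null distribution is permutation-based (the permutation
  test is valid under any LD).
- **MAF spectrum.** A mixture: a fraction (default 0.7) of variants
  drawn uniformly from a rare range (default [0.001, 0.05)) and the rest
  from a common range ([0.05, 0.5]).
- **Phenotype.** y = Σ β·g_k + ε with Gaussian noise (default unit SD);
  all rare causal effects share one (positive) sign, emulating the
  predominantly deleterious direction of missense rare alleles — the
  regime in which genotype-sum collapsing concentrates signal.
- **Replication.** Genotypes are drawn once per scenario; phenotype
  noise is redrawn per replicate (default 200 replicates, sample size
  default 142), mirroring the fixed-genotype / replicated-phenotype
  design of workshop-style simulation studies.

Not emulated: pedigree structure and relatedness, ascertainment,
realistic recombination-driven LD decay, genotyping error, allele
frequency/effect-size coupling beyond the rare/common split, and
population stratification.  Passing tests therefore demonstrate the
statistical behaviour of the method (calibration, the direction of
power effects), not performance guarantees on any real cohort.

## Evaluation experiments and problem sizes

All tests and the acceptance script run seeded scenarios sized to
finish in seconds on one core; the sizes below are the package's chosen
study conditions.

- **Type-I error.** Null scenario (effect 0): n = 200, 200 windows × 30
  variants, M = 200, 5 phenotype replicates → 1,000 window tests.  The
  empirical FPR at α ∈ {0.01, 0.05, 0.10} is compared to the exact
  binomial 95% interval centred at the *discrete null rate* of the k/M
  estimator, (⌊αM⌋+1)/(M+1): under exchangeability the observed
  statistic is uniform among the M+1 ranks, so P(p ≤ α) equals that
  value (0.0547 at α = 0.05, M = 200), not α itself.  Centring the band
  at nominal α would build a known bias into the check.
- **Null p-value law.** 500 null windows (n = 150, 10 variants each,
  M = 100): every empirical p lies on {0, 1/M, …, 1} and their mean is
  within 0.5 ± 0.03 (the exact null mean is 0.5; the band is ~2.3
  standard errors plus slack for tie-induced drift).
- **Collapsing gain.** The regime in which burden coding is expected to
  help is strong per-allele effects at very low frequency: 8
  same-direction causal rare variants per true window, MAF ∈
  [0.001, 0.01], β = 0.5, n = 500 — per-variant z ≈ 1, individually
  undetectable, while the summed burden of a causal-dense window is
  clearly testable.  Windows hold 10 variants (90% rare), 20 of 40
  windows are causal, 5 replicates, M = 200.  With individually strong
  signals (e.g. β = 0.3 at MAF ≈ 0.03, per-variant z ≈ 2) collapsing
  buys nothing and can dilute — that parameterisation was rejected at
  design time for contradicting the weak-signal premise.
- **Meta gain.** Base scan at modest power (β = 0.15, n = 300, 8 rare
  causal per true window) merged with an independent synthetic
  array-style cohort (n = 500, 3 common sites per window, causal in the
  true windows).  Power is compared at α ∈ {0.01, 0.05}.

## Known limitations

- Analytic (non-permutation) p-values for the Berk–Jones statistic are
  not provided; very small empirical p-values require large M.
- The per-variant tests assume unrelated individuals; no kinship or
  mixed-model adjustment.
- Binary traits with covariates fit one null GLM per permutation, which
  is markedly slower than the closed-form paths.
- The uniform-resampling permutation null for merged external p-values
  is an approximation (exact only for null external sources).
- The collapsing scheme is unweighted genotype summation; MAF- or
  annotation-weighted burden scores are out of scope.
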