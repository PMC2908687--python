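# Methods

## Scores

All assays reduce to two band intensities per sample (arbitrary
densitometry units, background already subtracted); only ratios are used,
so every score is scale-invariant.

* **M/P and P/M methylation ratios.** After methylation-sensitive digestion,
  only methylated (uncleaved) alleles amplify, so band intensity is
  proportional to the methylated fraction of each allele.  The ratio of the
  presumed less-methylated parental allele to the more-methylated one is 0
  for strictly monoallelic methylation and 1 for symmetric biallelic
  methylation.  Parental origin is an *assumption* (the less-methylated
  allele taken as maternal at IGF2/H19, paternal at IGF2R, following the
  pedigree-validated population pattern), recorded as a flag on each
  record, never inferred.  Table-level conversion (`compute_ratios`) takes
  min/max, constraining values to [0, 1]; the scalar `allelic_ratio`
  preserves values above 1 for callers with real orientation information,
  because clipping would destroy evidence of noise or imprint loss.
* **X-inactivation score** = upper band / (upper + lower).  Which allele
  runs "upper" is a gel artifact, so the score is left unfolded; its
  population distribution is symmetric about 0.5 and group means may fall
  slightly below 0.5.
* **Digestion control**: on homozygotes, efficiency = cleaved/(cleaved +
  uncleaved); assays pass at ≥ 0.99 by default.
* **Total-methylation consistency**: if all paternal alleles are methylated
  and a fraction *m* = M/P of maternal alleles gained methylation, a
  non-allele-resolved bisulfite assay should report (1 + *m*)/2 ≥ 50%
  methylation.  The map is restricted to *m* ∈ [0, 1] where the model is
  defined.
* **Loss of imprinting**: called when the major:minor allelic expression
  ratio is strictly below 3:1; exactly 3:1 is not called (strict
  inequality), a silent minor allele is never called.

## Founder-cell estimation

Model: a tissue sample descends from *N* founder cells whose epiallele
states are independent Bernoulli(*p*) draws; the sample's score is the
founder fraction *k/N*, so Var = *p*(1 − *p*)/*N*.  *p* = 0.5 for
X-inactivation; *p* = 0.1 for maternal IGF2/H19 DMR methylation (the
observed population frequency of appreciable maternal methylation, and
close to the placental group means); for the DMR flavor *p* may instead be
taken from the observed group mean (`p=None`).

* `moment_n` returns *p*(1 − *p*)/Var unrounded — the printed reference
  estimates (9.33, 8.15, …) are clearly unrounded moment values.
* `fit_n_distribution` scans integer *N* (default 1..100) and minimizes a
  distance between the empirical score distribution and the binomial score
  pmf: default χ² on 10 equal-width bins over [0, 1] (candidates placing
  zero mass where observations fall are rejected outright); alternatively a
  discrete-correct Kolmogorov–Smirnov distance whose supremum is evaluated
  at the jump points of *both* step CDFs — evaluating only at observed
  scores systematically favors interleaving supports and mis-ranks
  candidates.  Ties break toward smaller *N*.  Optional Gaussian
  measurement noise can be convolved into the candidates (default 0; the
  clonal model itself has none, and the truncation mass is assigned to the
  boundary bins to mirror the generator).
* Degenerate inputs: zero-variance scores make the moment estimator
  unbounded (error) and the fit monotone in *N* (pinned to `n_max` with a
  NaN metric and a warning).  Scores outside [0, 1] are excluded from the
  fit with a warning but kept in the moment estimate, where variance is
  still defined.
* `sample_variance` uses ddof = 1 by default; at the pooled sample sizes
  involved (hundreds of placenta sections) ddof is empirically
  indistinguishable, but it is exposed as a parameter.  Constant input
  returns exactly 0.0 (bypassing floating-point residue, so degeneracy
  detection is reliable).
* Pooling: all five placenta sections of all individuals in a group are
  pooled as independent draws.  A per-individual-first aggregation would
  model persistent founder states within an individual; the pooled
  treatment matches the variance arithmetic the estimators assume, and the
  generator draws each section independently for the same reason.

## Synthetic cohorts

`CohortConfig` defaults are the emulated study conditions: 45 in vitro and
56 in vivo individuals; cord blood, cord, five placenta sections; founder
counts 8 (in vitro) vs 10 (in vivo); p_dmr = 0.1, p_xi = 0.5; no
densitometry noise; qPCR technical noise ct_sd = 0.1; group fold effects on
expression set to the published fold-change table (e.g. placental IGF2
0.52).  Sex is Bernoulli(0.5) per individual and X-inactivation is scored
in females only.  Ct values are per-gene baselines (25 for targets, 20 for
the housekeeping gene — arbitrary, since only ΔCt differences matter) plus
noise; the in vitro group's target baselines are shifted by −log2(fold) so
the ΔΔCt method recovers the configured folds in expectation, and the
housekeeping gene is unaffected by group.  All randomness flows from the
single config seed, making cohorts byte-identical across runs.

What the generator does **not** emulate: bisulfite conversion error, PCR
amplification bias, gel saturation, correlated founder states across
tissues of one individual, biological expression variance beyond the
technical Ct noise, and family structure.  Passing tests therefore
demonstrate correctness of the estimators *under the clonal-sampling
model*, not robustness to every artifact of real densitometry or qPCR data.

## Group statistics

* Rank-sum test: exact mode enumerates all C(n, n₁) rank assignments
  (midranks for ties; two-sided p = probability of a rank sum at least as
  far from its null mean as observed), feasible to combined n = 20; the
  normal approximation (tie-corrected, continuity-corrected) delegates to
  scipy's Mann–Whitney implementation and is the default in summary tables.
* Variance equality: Brown–Forsythe (Levene with median centering) by
  default — robust to the skewed ratio distributions; a classical two-sided
  F test is available for comparison.  No published variance-test p-values
  are treated as reproducible, since the underlying per-sample data are not
  public.
* ΔΔCt: per-sample ΔCt = Ct(target) − Ct(housekeeping), group-mean
  difference ΔΔCt, fold = 2^−ΔΔCt for in vitro relative to in vivo; p from
  a two-sided Welch t-test on per-sample ΔCt (the equal-variance assumption
  is not imposed).  Samples without a housekeeping measurement are dropped
  with a warning; internally-constant groups with different means get p = 0
  rather than a NaN from the t statistic.
* No multiple-testing correction is applied anywhere: each table cell is
  reported at raw α, matching how such cohort tables are presented.

## Problem sizes and tolerances

Validation simulations use 10,000 scores per setting for the
parameter-recovery grid (N ∈ {5, 10, 20} × p ∈ {0.1, 0.5}, 100 replicates),
100 seeds at the study's own sample sizes for the group-ordering check, and
1,000 replicates for the variance-test calibration — sizes at which
Monte-Carlo error is small relative to the asserted margins while the whole
suite stays fast.  Closed-form identities (pmf normalization, moment/pmf
round trip) are asserted to 1e−12 / relative 1e−9.

## Known limitations

* The moment estimator is biased high when measurement noise inflates the
  variance; no noise deconvolution is attempted for it (the fit can model
  noise explicitly).
* Founder estimates carry no confidence intervals; seeded-replicate spread
  is the only dispersion measure offered, mirroring the point-estimate
  nature of the method.
* When founder states are strongly correlated across sections of one
  individual, pooled variance underestimates the within-individual
  component and the effective N is no longer the per-section founder count;
  the estimators are honest only under the independence assumption stated
  above.
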