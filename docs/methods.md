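# Methods

This note documents the models and procedures implemented in `panoptikit`,
the synthetic data they are tested on, and the numerical and design choices
made where more than one defensible option existed.

## 1. Preprocessing (`panoptikit.io`)

Expression tables are genes × samples with unique gene symbols; rows without
a symbol are dropped and duplicate symbols collapsed by row mean. Quantile
normalization follows the classic microarray algorithm: each sample's sorted
values are replaced by the cross-sample mean of order statistics, and tied
values within a sample receive the mean of the reference values across their
tied block. The transform is idempotent and equalizes column means to
machine precision (both are tested). The log2 transform uses `log2(x +
offset)` with offset 1 for count-like input and 0 for data already on a
positive continuous scale; the choice is a config flag because upstream
pipelines differ. Gene-symbol harmonization is a user-supplied mapping table
(uppercasing otherwise); there are no live symbol-service lookups, so runs
are reproducible offline.

## 2. Stratification and scoring (`panoptikit.scoring`)

**Consensus clustering.** Per resample, a fraction (default 0.8, all genes
kept) of samples is drawn without replacement and Ward-clustered (Euclidean;
Ward requires it) into k groups; the consensus entry for a sample pair is
the number of times they co-clustered divided by the number of times both
were drawn. Final labels come from complete-linkage clustering of
`1 − consensus` cut at k. The default 5000 resamples is the analysis
setting; tests and the acceptance script use 60–200, which is where the
consensus matrix stabilizes at the tested cohort sizes.

**Cluster count.** k ∈ [3, 6] maximizing the Calinski–Harabasz index of the
consensus-derived partition, evaluated on signature expression (samples as
points). Evaluating the index on the consensus-matrix rows instead is
available behind a flag; expression space is the default because the index
is defined for point clouds, and the consensus matrix geometry depends on
the resampling depth.

**High/medium/low.** The cluster with the highest mean signature expression
is "high", the lowest "low", all others "medium". Exact ties are broken
toward the larger cluster with a warning; an all-tied labeling is an error.

**Enrichment.** Two single-sample statistics are implemented from their
definitions (no wrapper):

- `gsva`: per gene, a Gaussian-kernel ECDF across samples (bandwidth =
  per-gene SD / 4) evaluated at each sample's own value; per sample, genes
  are ordered by that statistic and walked with weight `|p/2 − position|^τ`
  (τ = 1) for set genes against a uniform step for non-set genes; the score
  is the maximum positive walk deviation minus the maximum negative one.
- `ssgsea`: per sample, genes ordered by within-sample rank, set-gene weight
  `rank^α` (α = 0.25); the score is the integrated walk difference, range-
  normalized across samples by default. This variant is used per cell for
  single-cell data.

Constant genes are excluded with a warning (their kernel bandwidth is zero).
Both walks are verified against independently coded brute-force
implementations to 1e-10.

## 3. Survival analysis (`panoptikit.survival`)

Follow-up under 1 day is removed and times beyond 10 years (3650 days;
365 days/year) are administratively censored. Kaplan–Meier curves, the
log-rank test and the scaled-Schoenfeld proportional-hazards diagnostic go
through lifelines. `cox_fit` is a Newton–Raphson maximizer of the partial
likelihood written here because both Efron and Breslow tie conventions are
needed (lifelines implements Efron only, and the Breslow variant admits a
closed-form check on a 4-subject toy); it is cross-checked against lifelines
on random data and satisfies the score equation to 1e-8 at convergence.
Coefficients beyond |β| > 15 trigger a monotone-likelihood warning and are
reported unconverged.

The stratum comparison fits a univariate Cox model on the high-vs-low
indicator for the hazard ratio and takes its primary p-value from the
log-rank test (the Wald p is also reported, since a "χ² test" can denote
either). Screening keeps cohorts with p < 0.05, N1 + N2 > 100 and at least
one event in each stratum; failures are logged with reasons rather than
silently dropped. The PH-test global statistic sums per-covariate
chi-squares (df = number of covariates); this ignores cross-covariate
covariance and is labeled a screening approximation. Clinical covariates
are one-hot encoded dropping the first level, with stage/grade parsed as
ordered integers when possible.

## 4. Marker selection (`panoptikit.markers`)

**Moderated DE.** Per-gene two-group linear models with empirical-Bayes
variance shrinkage: the prior (d0, s0²) is moment-matched on the
log-variance distribution (trigamma inversion by Newton), the posterior
variance is the d0/d-weighted blend, and the moderated t has d0 + d degrees
of freedom. The implementation reproduces Bioconductor limma's `lmFit`/
`eBayes` output to ~1e-8 on a fixture (tested via Rscript). With too few
usable variances the code falls back to no shrinkage with a warning.
Markers are *primary* if differential between high and low strata,
*secondary* if (not primary and) differential versus normals in either
stratum, else *excluded*. Thresholds default to BH-adjusted p < 0.05 and
|log2 FC| > 0.5, both configurable.

**Stability selection.** Elastic-net Cox paths come from scikit-survival's
coordinate descent (penalty `λ[α‖β‖₁ + (1−α)‖β‖₂²/2]`, mixing α = 0.5 by
default, α = 1 available for LASSO ablations; covariates standardized
internally and coefficients reported on that scale). Each of the 100 runs
re-randomizes an event-stratified 5-fold split, scores every λ on the grid
by mean held-out Harrell's C, and selects the genes with nonzero full-data
coefficients at the winning λ (no 1-SE rule — the selection criterion is the
cross-validated concordance itself). Selection frequency ≥ 0.5 (inclusive)
marks a gene stable; the run with the best cross-validated concordance
provides the "best" linear model.

**Forest importance.** scikit-survival's random survival forest (log-rank
splits), hyperparameters (`n_estimators`, `max_features`,
`min_samples_leaf`) chosen by cross-validated concordance over a small grid.
Permutation importance is evaluated on an event-stratified 30% holdout the
forest never saw: in-sample permutation importance is biased upward for
every covariate an overfit forest touches, which would make pure-noise genes
look informative. Point estimates and 95% percentile intervals come from
subsample replicates of the holdout (ratio 0.632, default 100 replicates);
ranks break ties by the lower confidence bound.

**Intersection.** Top = {univariate BH-adjusted p < 0.05} ∩ {stable, with
mean penalized coefficient sign matching the univariate direction} ∩
{forest rank ≤ 10}. A stable gene whose penalized sign opposes its
univariate hazard direction is excluded — correlated signatures produce such
sign flips, and a marker whose direction depends on the model is not a
usable target. An empty intersection is legal and logged.

## 5. Evaluation (`panoptikit.evaluation`)

Harrell's C counts a pair as evaluable when the earlier time is an event,
concordant when that subject has the higher risk, and 1/2 for tied risks;
it equals exhaustive pair enumeration exactly (tested on 100 random
instances). The time-dependent AUC is the IPCW cumulative-case /
dynamic-control estimator (scikit-survival), which collapses to the
Mann–Whitney AUC without censoring; the incident/dynamic variant is not
implemented. Train/test splits (default 80/20) and CV folds are
event-stratified so small test sets cannot end up event-free. External
cohorts are z-scored per gene before scoring; model genes missing from a
cohort are imputed at the post-z-score mean (0) with the count reported, and
validation refuses when more than half the model genes are absent. Forest
risk scores are the ensemble cumulative hazard summed over the event-time
grid; linear scores are x·β.

## 6. Synthetic cohorts (`panoptikit.synthetic`)

The generator emulates what the analysis assumes about a quantile-normalized
log2 cohort, with ground truth for every stage:

- signature gene value = baseline + loading · (δ · σ) · level + shared
  factor + independent noise, with latent level ∈ {−1, 0, +1} balanced and
  shuffled (all three strata always exist when δ > 0);
- background genes are independent of the level; matched "normal" samples
  sit at the gene baselines, with an optional tumor-baseline offset planting
  differential-expression truth;
- survival is exponential with hazard `h0 · exp(x·β)` on centered
  expression (proportional hazards by construction) and independent
  exponential censoring whose rate is solved numerically to hit the
  requested censoring fraction;
- external cohorts are fresh draws from the same latent model, per-gene
  affine-distorted and optionally missing genes;
- single-cell counts are negative-binomial with per-cell lognormal library
  sizes and a per-type multiplicative activity factor on signature-gene
  means.

Default conditions: noise SD σ = 1 (log2 units), group shift δ = 2 noise-SDs
per level, baseline hazard 5e-4 events/day (median survival ≈ 3.8 years at
baseline), censoring fraction 0.6 (typical of overall-survival cohorts).
The shared-factor SD is 0.35: the factor lies along the same signature axis
as the group shift, so its variance is bounded by requiring the three strata
to remain separable at δ = 2 (within-stratum SD along the discriminant is
√(τ² + σ²/27)); 0.35 keeps within-signature correlation clearly positive
(mean pairwise r ≈ 0.11 at δ = 0) while respecting that bound. Survival
times are exponential rather than Weibull because that is the simplest model
satisfying proportional hazards.

What the generator does **not** emulate: batch effects, copy-number or
mutational structure, realistic count-depth distributions for bulk data,
probe-level microarray artifacts, or cell-type mixtures within a sample.
Passing the planted-recovery tests therefore shows the pipeline is correct
and calibrated under its own assumptions, not that those assumptions hold in
any particular public cohort.

## 7. Problem sizes in tests and the acceptance script

The analysis defaults (5000 consensus resamples, 100 penalized runs,
100 importance replicates) are the package settings; tests and
`scripts/acceptance.py` run the same code at reduced sizes chosen where the
monitored quantities have stabilized: 60–200 consensus resamples, 100 runs
× 5 folds on a 20-point λ grid for stability selection, 25 importance
replicates, cohorts of n = 120–600. Stochastic checks state their tolerance
in units of the quantity's own sampling spread (e.g. the null
cross-validated concordance is averaged over 20 independent cohorts because
a single cohort's 5-fold mean has spread ≈ 0.045).

## 8. Known limitations

- The PH global test is a sum of marginal chi-squares, not the joint test.
- `gsva` scores are not exactly invariant to shifting a single sample
  (the kernel-CDF step is gene-relative); global shifts are exact no-ops,
  and `ssgsea` is exactly rank-invariant per sample.
- The elastic-net coefficient paths are reported on the standardized scale;
  mapping back to expression units is left to the caller.
- Single-cell support is deliberately minimal (normalization, variable
  genes, per-cell scoring, per-type summaries); embeddings, clustering and
  label transfer are out of scope.
- The packaged signature uses TNFRSF1A as its TNF-receptor sensor entry;
  TNFRSF10-family death receptors are not part of the 27-gene set.
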