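# panoptikit

Pancancer survival analysis of an inflammatory cell-death gene program.
`panoptikit` stratifies bulk expression cohorts by a 27-gene PANoptosis
signature (sensors/upstream regulators, adaptors and effectors of the
integrated pyroptosis/apoptosis/necroptosis pathway), scores every sample by
single-sample enrichment, tests the prognostic impact of the signature-high
versus signature-low strata, and distills a minimal "Top" set of prognostic
genes by requiring agreement of three survival models. It is written for
computational biologists who want the whole chain — preprocessing,
clustering, scoring, survival screening, marker selection, validation — as a
tested, seedable library rather than a collection of one-off scripts.

## The method

**Stratification.** Samples are consensus-clustered on the signature genes:
5000 subsampled Ward clusterings (0.8 sample fraction) build a pairwise
co-clustering frequency matrix; complete-linkage clustering of
`1 − consensus` yields the final partition, with the cluster count `k ∈ [3,6]`
chosen by the Calinski–Harabasz index. The cluster with the highest mean
signature expression is *high*, the lowest *low*, the rest *medium*.

**Scoring.** The per-sample PANoptosis score is a single-sample enrichment
statistic: a weighted Kolmogorov–Smirnov random walk over genes ranked by a
Gaussian-kernel expression CDF (`gsva`), or by within-sample expression rank
with weight `rank^α` (`ssgsea`, also used per cell for single-cell data).

**Screening.** After follow-up cleaning (< 1 day removed, censored at 10
years), high vs low strata are compared by log-rank test and a Cox hazard
ratio. Cohorts qualify when p < 0.05, N1 + N2 > 100 and both strata have
events.

**Marker selection.** Signature genes are classed *primary* (differential
between high and low strata), *secondary* (differential versus normal
tissue) or *excluded*, using moderated t-statistics with empirical-Bayes
variance shrinkage (BH-adjusted p < 0.05, |log2 FC| > 0.5). Surviving genes
enter three survival models:

1. univariate Cox per gene (BH-adjusted Wald p),
2. elastic-net Cox (`λ[α‖β‖₁ + (1−α)‖β‖₂²/2]`, α = 0.5) run 100 times with
   fresh 5-fold splits, the penalty chosen per run by cross-validated
   Harrell's C — genes selected in ≥ 50% of runs are *stable*,
3. a random survival forest with hyperparameters from cross-validated
   concordance and held-out permutation importance with subsampled
   confidence intervals.

The **Top gene set** is the intersection: univariate-significant, stable with
a penalized coefficient sign matching the univariate direction, and within
the top-10 forest importances. Models built on the Top set are evaluated on
a held-out 20% split and on external cohorts by Harrell's C and
IPCW time-dependent AUC (external cohorts are z-scored per gene, which makes
linear risk scores invariant to per-gene affine platform shifts).

The elastic net, repeated runs, and the forest are deliberate: signature
genes are correlated, and a single L1 fit picks an arbitrary representative
of each correlated block per seed. Running the penalized model many times
turns that instability into a measurable selection frequency.

## Worked example

Everything runs on synthetic cohorts with planted ground truth; no downloads
are needed. The generator plants a 3-level latent activity factor on the
signature, a shared correlation factor, and exponential survival with chosen
log-hazard coefficients on declared genes.

```python
from panoptikit import PANoptosisModel, PipelineParams, packaged_signature, synthetic

sig = packaged_signature()                      # the 27-gene signature
cohort = synthetic.generate_bulk_cohort(
    400, 300, sig, delta=1.0,
    true_beta={g: 0.5 for g in sig.genes[:4]},  # plant ADAR, AIM2, MEFV, NLRC4
    tumor_shift=1.0, seed=7,
)
params = PipelineParams(n_resamples=200, n_runs=25, rfs_replicates=25)
model = PANoptosisModel(cohort.expression, cohort.survival, signature=sig,
                        normals=cohort.normals, params=params, cohort="SYN-DEMO")
print(model.fit(seed=1).summary())
```

```
======================================================================
PANoptosis signature survival analysis
======================================================================
clusters (consensus, k by Calinski-Harabasz): k = 3
stratum sizes: high=158, medium=96, low=146
high vs low: HR = 10.931 (6.628-18.028), log-rank p = 6.51e-30 (N1 = 158, N2 = 146)
screened in: True
marker classes: excluded=300, primary=27
stable genes (freq >= 0.5 over 25 runs): 5
Top gene set (4):
  MEFV       detrimental
  NLRC4      detrimental
  AIM2       detrimental
  ADAR       detrimental
held-out validation: CI = 0.821 (n = 80, events = 32); AUC(t): 1y=0.901, 2y=0.956, 3y=0.907, 5y=0.896
======================================================================
```

The cohort was built with detrimental activity planted on four genes; the
consensus clustering finds the three planted strata (`k = 3`), the high
stratum carries the expected excess hazard (`HR > 1`), and the three-model
intersection returns exactly the four planted genes with the correct
direction. The held-out concordance (0.82) and time-dependent AUCs measure
how well the Top-set risk score discriminates on samples the models never
saw.

A `panoptikit` CLI exposes each stage (`simulate`, `ingest`, `cluster`,
`score`, `survival`, `select`, `validate`, `sc-score`) and `run` executes a
full YAML-configured pipeline into a report bundle with checksums.

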