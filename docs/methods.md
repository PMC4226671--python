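# Methods

This note documents the models, algorithms, parameter choices and numerical
decisions behind `dmrsurv`, and what the synthetic-data generators do and do
not emulate.

## Study design being modelled

The pipeline mirrors a three-step methylation prognosis study in preoperatively
treated rectal cancer: an 11-sample tumor/mucosa CpG-island array screen, a
61-patient quantitative test cohort, and independent 71- and 42-patient
validation cohorts. Disease-free survival (DFS) is measured in months from
surgery; relapse or metastasis is the event, other deaths are censored. The
good-prognosis group is the *hyper*methylated one — the generators plant the
signal in that direction and the classifier learns the direction from the
Kaplan–Meier curves rather than assuming it.

## Synthetic-data generators

The generators are first-class, tested code; their defaults define the study
conditions used throughout the test suite and the acceptance script.

**Probe map.** CpG islands are tiled with 45–60 bp probes. Within an island,
consecutive probes are separated by an end-to-start gap drawn from a range
whose maximum is capped at 500 bp, so an island is a single coherent region
for the DMR caller; islands are ≥ 10 kb apart. Default geometry used in
recovery experiments: 4 chromosomes × 250 islands × 3–8 probes (~5,500
probes) — a scaled-down analogue of a 199k-probe, 27.8k-island array chosen so
the whole chain runs in seconds while keeping ≈ 5.5 probes/island and the
same top-5% selection semantics.

**Array cohorts.** True per-probe M-values are Normal(0, `noise_sd`); probes
of a planted island gain `+effect` in every carrier sample. Carriers are the
good-prognosis samples, which are simultaneously ypN-negative and responders,
so recovery can be scored through any clinical surrogate category. Channel
intensities are back-computed so that `log2((tumor_fg−bg)/(normal_fg−bg))`
equals the true M exactly, at an average log2-intensity of
`a_level + jitter`, jitter ~ Normal(0, 2.0). The 2.0-log2-unit intensity
spread matters: rank-invariant probe selection presupposes the wide dynamic
range real two-color arrays have; with a narrow range, probe-level channel
noise dominates the ranks and the invariant set degenerates. Backgrounds are
small constants (30); channel physics (dye bias, spatial artifacts,
saturation) is deliberately not modelled — the preprocessing chain is
exercised, not stress-tested.

**Methylation panels.** Per-CpG fractions are Beta-distributed with
concentration 30 (sd ≈ 0.08 at mean 0.5, plausible for amplicon-level
averages). Default panel: 10 prognostic regions of one CpG each (good-group
mean shifted +0.30 from a 0.35 baseline) among 100 null CpGs grouped into
2-CpG regions. Missingness is MCAR at 10% — below the 60% exclusion bar, so
samples survive the filter; no informative-missingness mechanism is modelled.

**Survival.** Event times are exponential with hazard
`0.006 · exp(log(4) · [bad])` per month and administrative censoring at 60
months. The baseline gives a good-group 36-month DFS of ≈ 0.81 and roughly
30–45% events per cohort, matching the reporting range such studies print.
Age, gender and ultrasound nodal status (uN) are drawn independently of
outcome, so the analysis-of-deviance comparison isolates the grouping's
contribution.

What passing tests therefore show: the pipeline recovers planted signals of
realistic size under MCAR missingness, exchangeable covariates and
proportional hazards. What they do not show: robustness to batch effects,
informative censoring, assay transfer (fresh-frozen → FFPE) or non-MCAR
missingness, none of which the generators emulate.

## Array preprocessing

**NormExp.** Net intensity (fg − bg) is modelled as exponential signal (mean
α) plus normal noise (μ, σ²). Parameters are estimated per array by exact
maximum likelihood — the convolution density is available in closed form —
with Nelder–Mead started from both a method-of-moments fit and a lower-tail
fit. Pure moments estimation is kept only as an initializer: on heavy-tailed
signal distributions it attributes signal skew to the normal component and
the posterior-mean correction then shrinks genuine fold-changes toward 1.
Each probe is replaced by E[signal | observed], computed with a log-scale
Mills ratio so far-left tails stay finite, plus the offset (default 50, which
damps low-intensity M-value variance). Degenerate (zero-variance) inputs
raise an estimation error.

**LOESS.** A locally linear curve of M on A (span 0.3) is fitted on the
reference probes only — the rank-invariant set, optionally merged with an
explicit negative-control list — and its value at every probe's A is
subtracted. Outside the reference A-range the curve is held flat. At equal A,
M differences between probes are preserved exactly.

**Rank-invariant probes.** A probe qualifies when its within-sample tumor and
normal intensity ranks differ by less than `tolerance·N` in *every* sample
(ties broken by probe index). The default tolerance is 5% of probes. For
short, noisy co-hybridization series (the 11-array screening setting with
probe-level channel noise of 0.5 M-units) the all-samples intersection at 5%
is near-empty, and 10% is used; the choice only moves the LOESS reference
set, not the statistics downstream.

**Between-array scaling.** Each array's M is multiplied by
(global median of per-array median |M|) / (that array's median |M|); A is
centred at its per-array median, scaled identically, and re-centred. The map
is idempotent. An array with median |M| = 0 is an error — this is why the
noise-free recovery property is asserted for the chain without the scaling
step (and with plain background subtraction, since NormExp's estimated
background shift is nonzero by construction).

## DMR calling

Regions are maximal probe runs with `next.start − prev.end ≤ 500` bp
(inclusive; the gap is sequence distance, not start-to-start, because probe
lengths vary 45–60 bp); single-probe runs are discarded. Per array the top
`round(0.05·N)` hypermethylated probes are selected, ties at the threshold
broken by probe index so the set is reproducible. A region is supported in a
sample when it contains two top probes separated by at most one consecutive
non-top probe; it becomes a DMR for a sample group when supported in all, or
all but one, of the group's arrays ("representative arrays" are read as the
arrays of the clinical category group under test). Within each of the four
categories (ypN+, ypN−, responder, non-responder) DMRs are ranked by support
count, then mean M over the supporting probes × samples, then region id — the
ranking key is this package's choice, as no canonical criterion exists — and
the top five are kept; duplicates across categories collapse into one region
carrying all its labels. Only hypermethylation is scanned by default (the
tumor-vs-mucosa direction); the support primitive is direction-agnostic if
fed top-hypomethylated sets.

The chromosome-distribution test is a goodness-of-fit of per-chromosome DMR
counts against expected proportions equal to per-chromosome probe fractions:
chi-square with an asymptotic p when all expected counts are ≥ 5, otherwise a
Monte-Carlo p from multinomial draws (`(1 + #{sim ≥ obs}) / (n_mc + 1)`,
deterministic given the seed). This is a reasonable stand-in; the exact test
used in the original analyses of such data is not specified anywhere.

## Survival statistics

The Cox model maximises the Efron-tied partial likelihood by damped Newton
iteration from β = 0, with step-halving and a gradient tolerance of 1e-8
scaled by the log-likelihood magnitude (float cancellation in the risk-set
cumulative sums bounds the attainable gradient norm on larger cohorts;
a Newton step below 1e-10 relative size is likewise treated as converged).
Covariates are centred for conditioning — the partial likelihood is invariant.
Constant covariates, zero events, singular information and non-convergence
are errors, not warnings. Hazard ratios are `exp(β)` with Wald 95% intervals;
per-covariate p-values are Wald tests. The log-rank statistic uses the
hypergeometric variance over distinct event times (G groups → quadratic form
in the first G−1 components of O−E, df = G−1); on tie-free data it equals the
Cox score test at β = 0, which the suite asserts to 1e-6. The analysis of
deviance is `2·(ll_full − ll_reduced)` clipped at zero against chi-square
with the parameter-count difference; nestedness and identical complete-case
samples are enforced. Kaplan–Meier estimation is the product-limit form with
optional Greenwood variance. Everything here is deterministic.

lifelines implements the same models and serves as the independent
cross-check in the test suite (coefficients, standard errors and
log-likelihoods to ≤ 1e-5 on tied data); it is never on the execution path.

## Classifier

CpGs pass the filter when their univariate Cox Wald p against DFS is below α
(default 0.05, complete cases per CpG, no multiple-testing correction — by
design, matching the screening character of the step). Patients missing more
than 60% of CpG units are excluded first (strict inequality: exactly 60% is
retained). Clustering is agglomerative Ward on Euclidean distances, with
per-CpG median imputation used *only* for the distance computation; the
dendrogram is cut at its root into two groups ("main branches" = the
2-cluster cut). Centroids are per-cluster per-CpG means of observed values.
The cluster with the higher mean methylation is named "high"; prognosis
labels come from comparing the clusters' Kaplan–Meier curves by restricted
mean survival over the shared follow-up. Transfer uses root-mean-square
distance over each patient's observed signature CpGs (≥ 40% observed
required), so differing missingness is comparable; exact ties — within float
noise, 1e-12 — go to the high cluster, a documented arbitrary choice. With no
missing values this reduces to ordinary Euclidean nearest-centroid. Cohort
reports carry the log-rank p, the bad-vs-good hazard ratio with 95% CI, the
analysis-of-deviance p for age + gender + uN + grouping vs. the model without
the grouping, and the overlap between the cohort's own DFS-correlated CpGs
and the training signature. Any second classifier's labels can be added to
the full Cox model and tested the same way (nested-model comparison), which
covers signature-vs-prior-panel combination analyses generically.

## Verification quantities and problem sizes

`scripts/acceptance.py --seed <s> --out <json>` recomputes, from freshly
generated data:

- exact agreement of `build_regions` / `segment_supported` with brute-force
  references on 1,000 random instances of ≤ 100 probes;
- planted-DMR sensitivity and precision through the full array chain
  (11 samples, 30 planted regions, effect 2.0 M-units, noise sd 0.5);
- the Cox log-HR estimate at n = 500 (true HR 4) and Wald 95% CI coverage
  over 500 replicates;
- the log-rank null rejection rate at n = 200 over 500 replicates, and the
  gap to a 10,000-draw permutation oracle on a 40-patient cohort;
- the Kolmogorov–Smirnov distance from uniformity of 500 null
  analysis-of-deviance p-values;
- end-to-end classifier transfer power on n = 71 and n = 42 validation
  cohorts over 100 seeds, the type-I rate against no-signal (HR = 1)
  validation cohorts, and the median estimated hazard ratio;
- filter exactness against direct recounts, and byte-identical CLI reruns.

These sizes were chosen as the package's standard verification workload; the
whole script completes in a few minutes on a single core.

## Known limitations

- No dye-swap designs, spatial artifact correction or multi-batch adjustment.
- No time-varying covariates, stratified or penalized Cox, competing risks.
- The chromosome-distribution p-value is a stand-in for an unspecified test.
- Cancer-specific survival is supported only through the event-indicator
  definition of the survival table; no CSS-specific behaviour is asserted.
- Nearest-centroid transfer assumes the validation assay measures the same
  CpG units on the same scale as training; no cross-assay calibration.
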