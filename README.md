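# dmrsurv

DMR discovery on CpG-island tiling arrays and a survival-filtered DNA-methylation
prognosis classifier, with synthetic ground-truth cohorts for every stage.

## The problem

In locally advanced rectal cancer (and similar settings), a pre-therapeutic
biomarker is needed to separate patients likely to relapse from those who will
do well on standard chemoradiotherapy. One established design is a three-step
methylation study:

1. **Screening** — a small set of tumor/normal-mucosa pairs is co-hybridized to
   a CpG-island tiling array; recurrently hypermethylated probe regions
   (differentially methylated regions, DMRs) are called against clinical
   surrogate categories (post-therapy nodal status ypN±, therapy response).
2. **Testing** — candidate DMRs are re-measured in a larger cohort with a
   quantitative assay yielding per-CpG methylation fractions; CpGs correlated
   with disease-free survival (DFS) are kept, the patients are clustered on
   them, and the two main dendrogram branches become good/bad prognosis groups.
3. **Validation** — further cohorts are assigned to those groups by
   nearest-centroid distance, and the split is checked by log-rank testing and
   Cox modelling.

`dmrsurv` implements that entire pipeline as a tested Python library. Because
studies of this design rarely deposit patient-level data, the package ships
first-class synthetic-data generators that plant known DMRs and a known
proportional-hazards structure, so every stage can be verified against ground
truth.

## Methods at a glance

- **Array preprocessing** — NormExp background correction (posterior mean of
  the exponential signal under a normal+exponential convolution, fitted per
  array by maximum likelihood; offset 50), M/A computation
  (`M = log2(T/N)`, `A = ½·log2(T·N)`), within-array LOESS normalization of M
  on A fitted on rank-invariant probes (optionally merged with negative
  controls), and between-array scaling to a common median |M|.
- **DMR calling** — stepwise criteria: (i) candidate regions are maximal probe
  runs with inter-probe gaps ≤ 500 bp; (ii) per array only the top 5%
  hypermethylated probes count; (iii) a region is supported by ≥ 2 vicinal top
  probes allowing a single-probe gap; (iv) a DMR must recur in all, or all but
  one, arrays of its category group. The top five DMRs per category are kept,
  and a chi-square / Monte-Carlo test checks the chromosome distribution
  against the per-chromosome probe supply.
- **Survival engine** — Cox proportional hazards via Newton-maximised Efron
  partial likelihood, hazard ratios with Wald 95% CIs, log-rank tests with
  hypergeometric variance, Kaplan–Meier curves, and likelihood-ratio
  ("analysis of deviance") comparison of nested Cox models.
- **Classifier** — per-CpG univariate Cox filter at p < 0.05 (no multiplicity
  correction, by design), Ward/Euclidean clustering cut at the two main
  branches, prognosis labels from the Kaplan–Meier comparison, and
  missingness-aware nearest-centroid transfer (root-mean-square distance over
  each patient's observed CpGs; patients with > 60% missing CpGs, or < 40% of
  the signature observed, are excluded).

## Worked example

`examples/05_train_and_validate_classifier.py` runs the full three-cohort
workflow on synthetic data (10 prognostic CpGs among 100 null ones, true
bad-vs-good hazard ratio 4):

```
training (n=61): 9 CpGs passed the DFS Cox filter at p < 0.05
  clusters: {'bad': 32, 'good': 29} (high-methylation cluster -> good prognosis)
  log-rank p = 0.0278, HR = 2.20, 95% CI = [1.07, 4.52]
  analysis of deviance (age+gender+uN with vs without clustering): p = 0.0223

validation (n=71): assigned 71 patients {'good': 36, 'bad': 35}
  log-rank p = 0.0001, HR = 3.81, 95% CI = [1.83, 7.91]
  4 of the cohort's own DFS-correlated CpGs overlap the training signature

validation (n=42): assigned 42 patients {'good': 21, 'bad': 21}
  log-rank p = 0.0000, HR = 8.03, 95% CI = [2.65, 24.32]
  5 of the cohort's own DFS-correlated CpGs overlap the training signature
```

Reading the output: at n = 61 the per-CpG screen has moderate power, so the
9 surviving CpGs are a mix of planted prognostic units and uncorrected-5%
false positives — yet the clustering still splits the cohort into a hyper-
and a hypomethylated branch along the planted signal, the hypermethylated
branch shows better survival, and nearest-centroid transfer reproduces a
significant good/bad split in both independent cohorts, with hazard-ratio
estimates scattering around the planted value of 4. (Both larger validation
analyses in `scripts/acceptance.py` quantify this: transfer power ≥ 80% over
100 seeds.)

The other example scripts cover simulation (`01`), array preprocessing (`02`),
DMR calling with the chromosome-distribution test (`03`) and the survival
statistics on their own (`04`).

## Command line

A thin CLI wraps the library for file-based use:

```bash
dmrsurv simulate arrays --seed 11 --outdir sim/       # probe map + channels + truth
dmrsurv simulate panel  --seed 5  --outdir panel/     # methylation + survival + truth
dmrsurv preprocess --intensities sim/intensities.tsv --outdir norm/
dmrsurv call-dmrs  --m-matrix norm/M.tsv --probe-map sim/probe_map.tsv \
                   --samples sim/samples.tsv --outdir dmrs/
dmrsurv validate-matrix panel/methylation.tsv
dmrsurv train    --matrix panel/methylation.tsv --survival panel/survival.tsv \
                 --model-out model.json --report-out train.json
dmrsurv validate --matrix other/methylation.tsv --survival other/survival.tsv \
                 --model model.json --report-out val.json
```

All commands are deterministic: rerunning with the same seed and configuration
produces byte-identical files.

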