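"""Simulate the three synthetic inputs every downstream stage consumes.

Builds a CpG-island probe map, an 11-sample two-channel array screening
cohort with 30 planted hypermethylated regions, and a 61-patient
quantitative methylation panel with survival linked to a planted hazard
structure (bad-vs-good HR = 4).
"""

import numpy as np

import dmrsurv as ds

probe_map = ds.generate_probe_map(seed=3, n_chrom=4, islands_per_chrom=250,
                                  probes_per_island=(3, 8))
print(f"probe map: {len(probe_map)} probes on {probe_map['chrom'].nunique()} "
      f"chromosomes, {probe_map['island_id'].nunique()} islands")

cohort = ds.generate_array_cohort(probe_map, n_samples=11, n_planted=30,
                                  effect=2.0, noise_sd=0.5, seed=11)
carriers = cohort.category_samples("responder")
print(f"array cohort: {len(cohort.samples)} tumor/mucosa co-hybridizations, "
      f"{len(cohort.truth)} planted regions carried by {len(carriers)} samples")
# the emitted truth lets tests score recovery: carrier-vs-rest M difference
diffs = []
for info in cohort.truth.values():
    sub = cohort.true_m[info["probe_ids"]]
    rest = [s for s in cohort.sample_ids if s not in info["carriers"]]
    diffs.append(sub.loc[info["carriers"]].mean().mean() - sub.loc[rest].mean().mean())
print(f"mean planted M shift recovered from truth: {np.mean(diffs):.3f} "
      f"(generator effect was 2.0)")

panel = ds.default_panel()  # 10 prognostic CpGs among 100 null ones
matrix, survival, labels = ds.generate_methylation_cohort(panel, n_patients=61,
                                                          seed=5)
print(f"methylation panel: {matrix.shape[0]} CpG units x {matrix.shape[1]} "
      f"patients, {matrix.isna().to_numpy().mean():.1%} missing, "
      f"{int(survival['event'].sum())} DFS events, "
      f"{(labels == 'good').sum()} good / {(labels == 'bad').sum()} bad prognosis")
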