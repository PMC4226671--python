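"""Stepwise differentially-methylated-region (DMR) calling on CpG-island arrays.

The caller follows four criteria applied to normalized per-sample M-values:

(i)   candidate *regions* are maximal runs of more than one probe in which
      consecutive probes are separated by at most ``max_gap`` bp (inclusive);
(ii)  per sample, only the top ``fraction`` (default 5%) hypermethylated
      probes are considered;
(iii) a region is *supported* in a sample when it contains at least two
      vicinal top probes, allowing a gap of a single non-top probe;
(iv)  a region becomes a recurrent DMR for a sample group when it is
      supported in all, or all except one, of the group's arrays.

Per clinical surrogate category the top-k DMRs are kept (support count,
then mean M over the supporting probes/samples, then region id), and a
chromosome-distribution goodness-of-fit test checks that called DMRs are
not simply tracking the per-chromosome probe supply.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Region",
    "DMR",
    "build_regions",
    "select_top_probes",
    "segment_supported",
    "call_recurrent_dmrs",
    "rank_select_dmrs",
    "chromosome_enrichment",
    "discover_dmrs",
    "write_dmrs",
]

CATEGORIES = ["ypN+", "ypN-", "responder", "non-responder"]


@dataclass(frozen=True)
class Region:
    """A coherent stretch of >= 2 probes (0-based half-open coordinates)."""

    region_id: str
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.probe_ids) < 2:
            raise ValueError("a region needs more than one probe")
        if self.end <= self.start:
            raise ValueError("region end must exceed start")


@dataclass
class DMR:
    """A recurrent hypermethylated region with its sample support."""

    region: Region
    supporting_samples: tuple[str, ...]
    support_segments: dict[str, tuple[int, int]]  # sample -> probe index span
    rank_score: float
    categories: list[str] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.supporting_samples)


def _validate_probe_map(probe_map: pd.DataFrame) -> None:
    for chrom, sub in probe_map.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise ValueError(f"probe map not sorted by start on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping probes on {chrom}")


def build_regions(probe_map: pd.DataFrame, max_gap: int = 500) -> list[Region]:
    """Criterion (i): maximal probe runs with inter-probe gaps <= max_gap.

    The gap is the sequence distance ``next.start − prev.end`` and the bound
    is inclusive.  Runs of a single probe are discarded.  Probes must be
    sorted and non-overlapping within each chromosome.
    """
    _validate_probe_map(probe_map)
    regions: list[Region] = []
    for chrom, sub in probe_map.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        run_start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or starts[i] - ends[i - 1] > max_gap:
                if i - run_start >= 2:
                    regions.append(
                        Region(
                            region_id=f"{chrom}:{starts[run_start]}-{ends[i - 1]}",
                            chrom=str(chrom),
                            start=int(starts[run_start]),
                            end=int(ends[i - 1]),
                            probe_ids=tuple(ids[run_start:i]),
                        )
                    )
                run_start = i
    return regions


def select_top_probes(M_sample: pd.Series, fraction: float = 0.05) -> set[str]:
    """Criterion (ii): the round(fraction*N) most hypermethylated probes.

    Ties at the threshold are broken by probe (index) order, so the set is
    identical on every run.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = M_sample.to_numpy(dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("M-values must be finite")
    k = int(round(fraction * len(m)))
    k = max(k, 1)
    order = np.argsort(-m, kind="stable")  # stable: ties keep probe order
    return set(M_sample.index[order[:k]])


def segment_supported(region: Region, top_set: set[str]) -> bool:
    """Criterion (iii): >= 2 vicinal top probes, allowing one non-top gap."""
    span = _support_span(region, top_set)
    return span is not None


def _support_span(region: Region, top_set: set[str]) -> tuple[int, int] | None:
    """Probe-index span of the supporting segment, or None if unsupported.

    Two top probes are vicinal when separated by at most one consecutive
    non-top probe, i.e. their positions in the region differ by <= 2.
    """
    pos = [i for i, p in enumerate(region.probe_ids) if p in top_set]
    if len(pos) < 2:
        return None
    # chains of top probes in which consecutive members are vicinal
    chains: list[list[int]] = [[pos[0]]]
    for a, b in zip(pos, pos[1:]):
        if b - a <= 2:
            chains[-1].append(b)
        else:
            chains.append([b])
    chains = [c for c in chains if len(c) >= 2]
    if not chains:
        return None
    longest = max(chains, key=len)
    return (longest[0], longest[-1])


def call_recurrent_dmrs(
    regions: list[Region],
    per_sample_top_sets: dict[str, set[str]],
    sample_group: list[str],
    M: pd.DataFrame | None = None,
    min_support: str | int = "all-but-one",
) -> list[DMR]:
    """Criterion (iv): regions supported in all, or all but one, group arrays.

    ``min_support`` is ``"all-but-one"`` (default), ``"all"`` or an integer.
    ``M`` (samples × probes) is used for the ranking score: the mean M over
    the region's probes in the supporting samples; without it the score is
    the support count.
    """
    if not sample_group:
        raise ValueError("empty sample group")
    g = len(sample_group)
    if g < 2:
        raise ValueError("sample group needs at least 2 arrays")
    if min_support == "all-but-one":
        need = g - 1
    elif min_support == "all":
        need = g
    else:
        need = int(min_support)
    dmrs: list[DMR] = []
    for region in regions:
        segs: dict[str, tuple[int, int]] = {}
        for s in sample_group:
            span = _support_span(region, per_sample_top_sets[s])
            if span is not None:
                segs[s] = span
        if len(segs) >= need:
            supporting = tuple(s for s in sample_group if s in segs)
            if M is not None:
                score = float(
                    M.loc[list(supporting), list(region.probe_ids)].to_numpy().mean()
                )
            else:
                score = float(len(supporting))
            dmrs.append(
                DMR(
                    region=region,
                    supporting_samples=supporting,
                    support_segments=segs,
                    rank_score=score,
                )
            )
    return dmrs


def rank_select_dmrs(dmrs_per_category: dict[str, list[DMR]], k: int = 5) -> list[DMR]:
    """Top-k DMRs per clinical category, merged across categories.

    Within a category DMRs are ranked by (support desc, rank_score desc,
    region_id asc); the union is returned with category labels, collapsing
    a region selected in several categories into one DMR carrying all its
    labels.  Categories with fewer than k DMRs contribute what they have.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    chosen: dict[str, DMR] = {}
    for category, dmrs in dmrs_per_category.items():
        ranked = sorted(
            dmrs, key=lambda d: (-d.support, -d.rank_score, d.region.region_id)
        )
        for d in ranked[:k]:
            rid = d.region.region_id
            if rid in chosen:
                chosen[rid].categories.append(category)
            else:
                kept = DMR(
                    region=d.region,
                    supporting_samples=d.supporting_samples,
                    support_segments=dict(d.support_segments),
                    rank_score=d.rank_score,
                    categories=[category],
                )
                chosen[rid] = kept
    return sorted(chosen.values(), key=lambda d: d.region.region_id)


def chromosome_enrichment(
    dmrs: list[DMR],
    probe_map: pd.DataFrame,
    n_mc: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Goodness-of-fit of per-chromosome DMR counts against probe supply.

    Expected proportions are the per-chromosome probe fractions.  Returns
    the chi-square statistic and a p-value: Monte-Carlo (multinomial draws)
    whenever any expected count is below 5, asymptotic otherwise.
    """
    if not dmrs:
        raise ValueError("no DMRs to test")
    if n_mc < 100:
        raise ValueError("n_mc must be at least 100")
    chroms = list(probe_map["chrom"].unique())
    probe_counts = probe_map["chrom"].value_counts().reindex(chroms).to_numpy(dtype=float)
    p = probe_counts / probe_counts.sum()
    observed = np.zeros(len(chroms))
    chrom_pos = {c: i for i, c in enumerate(chroms)}
    for d in dmrs:
        observed[chrom_pos[d.region.chrom]] += 1
    n = observed.sum()
    expected = n * p
    statistic = float(((observed - expected) ** 2 / expected).sum())
    if expected.min() >= 5:
        pval = float(stats.chi2.sf(statistic, df=len(chroms) - 1))
    else:
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(int(n), p, size=n_mc)
        sim = ((draws - expected) ** 2 / expected).sum(axis=1)
        pval = float((1 + np.sum(sim >= statistic - 1e-12)) / (n_mc + 1))
    return statistic, pval


def discover_dmrs(
    M: pd.DataFrame,
    probe_map: pd.DataFrame,
    category_samples: dict[str, list[str]],
    max_gap: int = 500,
    fraction: float = 0.05,
    k: int = 5,
    min_support: str | int = "all-but-one",
    direction: str = "hyper",
) -> list[DMR]:
    """End-to-end stepwise DMR discovery over clinical categories.

    ``category_samples`` maps category label (e.g. ypN+/ypN-/responder/
    non-responder) to the sample ids of that group.  ``direction`` selects
    the scan for hypermethylation (default) or, by negating M, for
    hypomethylation.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    if direction == "hypo":
        M = -M
    regions = build_regions(probe_map, max_gap=max_gap)
    top_sets = {s: select_top_probes(M.loc[s], fraction) for s in M.index}
    per_cat = {
        cat: call_recurrent_dmrs(regions, top_sets, samples, M=M, min_support=min_support)
        for cat, samples in category_samples.items()
        if len(samples) >= 2
    }
    return rank_select_dmrs(per_cat, k=k)


def write_dmrs(dmrs: list[DMR], bed_path, json_path=None) -> None:
    """Write DMRs as BED (chrom, start, end, region_id, support) plus a JSON
    sidecar with support, categories and rank scores."""
    with open(bed_path, "w") as fh:
        for d in dmrs:
            r = d.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{d.support}\n")
    if json_path is not None:
        payload = [
            {
                "region_id": d.region.region_id,
                "chrom": d.region.chrom,
                "start": d.region.start,
                "end": d.region.end,
                "probe_ids": list(d.region.probe_ids),
                "supporting_samples": list(d.supporting_samples),
                "support_segments": {s: list(v) for s, v in d.support_segments.items()},
                "rank_score": d.rank_score,
                "categories": d.categories,
            }
            for d in dmrs
        ]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
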