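"""Stepwise DMR criteria, top-k selection and the chromosome enrichment test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dmrsurv as ds
from dmrsurv.dmr import DMR, Region

from conftest import brute_force_regions, brute_force_segment


def pm_from_coords(coords, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [c[0] for c in coords],
            "end": [c[1] for c in coords],
            "probe_id": [f"p{i}" for i in range(len(coords))],
            "island_id": "i1",
        }
    )


class TestBuildRegions:
    def test_gap_rule_and_singleton_discard(self):
        pm = pm_from_coords([(0, 60), (460, 520), (5000, 5060)])
        regions = ds.build_regions(pm, max_gap=500)
        assert len(regions) == 1
        assert regions[0].probe_ids == ("p0", "p1")
        assert (regions[0].start, regions[0].end) == (0, 520)

    def test_gap_exactly_500_is_merged(self):
        pm = pm_from_coords([(0, 60), (560, 620), (1121, 1180)])
        regions = ds.build_regions(pm, max_gap=500)
        # 560-60 = 500 (merged, inclusive bound); 1121-620 = 501 (split)
        assert len(regions) == 1
        assert regions[0].probe_ids == ("p0", "p1")

    def test_unsorted_or_overlapping_rejected(self):
        with pytest.raises(ValueError):
            ds.build_regions(pm_from_coords([(100, 160), (0, 60)]))
        with pytest.raises(ValueError):
            ds.build_regions(pm_from_coords([(0, 60), (50, 110)]))

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 60))
            gaps = rng.integers(0, 1200, n)
            coords, pos = [], 0
            for g in gaps:
                length = int(rng.integers(45, 61))
                coords.append((pos, pos + length))
                pos += length + int(g)
            pm = pm_from_coords(coords)
            max_gap = int(rng.integers(100, 900))
            got = [
                (r.chrom, r.start, r.end, r.probe_ids)
                for r in ds.build_regions(pm, max_gap)
            ]
            assert got == brute_force_regions(pm, max_gap)

    def test_bed_round_trip_identity(self, tmp_path, probe_map_small):
        regions = ds.build_regions(probe_map_small)
        dmrs = [
            DMR(region=r, supporting_samples=("S1", "S2"),
                support_segments={}, rank_score=1.0)
            for r in regions
        ]
        from dmrsurv.dmr import write_dmrs

        bed = tmp_path / "dmrs.bed"
        write_dmrs(dmrs, bed)
        back = pd.read_csv(bed, sep="\t", header=None,
                           names=["chrom", "start", "end", "name", "score"])
        assert list(back["start"]) == [r.start for r in regions]
        assert list(back["end"]) == [r.end for r in regions]


class TestTopProbes:
    def test_count_is_rounded_fraction(self):
        rng = np.random.default_rng(0)
        m = pd.Series(rng.normal(size=20_000),
                      index=[f"p{i}" for i in range(20_000)])
        assert len(ds.select_top_probes(m, 0.05)) == 1000

    def test_tiny_fraction_keeps_the_max(self):
        m = pd.Series([0.1, 5.0, -2.0] + [0.0] * 17,
                      index=[f"p{i}" for i in range(20)])
        assert ds.select_top_probes(m, 0.05) == {"p1"}

    def test_ties_broken_by_probe_index(self):
        m = pd.Series([1.0, 2.0, 2.0, 2.0, 0.0],
                      index=[f"p{i}" for i in range(5)])
        got = ds.select_top_probes(m, 0.4)  # k = 2 of 5
        order = sorted(range(5), key=lambda i: (-m.iloc[i], i))
        assert got == {f"p{i}" for i in order[:2]}
        # repeated runs identical
        assert all(ds.select_top_probes(m, 0.4) == got for _ in range(5))

    def test_fraction_bounds(self):
        m = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            ds.select_top_probes(m, 0.0)
        with pytest.raises(ValueError):
            ds.select_top_probes(m, 1.5)


def region_of(n):
    return Region(region_id="r", chrom="chr1", start=0, end=100 * n,
                  probe_ids=tuple(f"p{i}" for i in range(n)))


class TestSegmentSupported:
    @pytest.mark.parametrize(
        "pattern, expected",
        [((1, 1), True), ((1, 0, 1), True), ((1, 0, 0, 1), False),
         ((0, 1, 1, 0), True), ((1, 0, 0, 0, 1, 0, 1), True)],
    )
    def test_examples(self, pattern, expected):
        r = region_of(len(pattern))
        top = {f"p{i}" for i, t in enumerate(pattern) if t}
        assert ds.segment_supported(r, top) is expected

    def test_exhaustive_against_oracle(self):
        for n in range(2, 11):
            r = region_of(n)
            for pattern in itertools.product([0, 1], repeat=n):
                top = {f"p{i}" for i, t in enumerate(pattern) if t}
                assert ds.segment_supported(r, top) == brute_force_segment(pattern)


class TestRecurrentCalling:
    def _setup(self, support_pattern):
        """support_pattern[s] = whether sample s supports the region."""
        region = region_of(2)
        samples = [f"S{i}" for i in range(len(support_pattern))]
        tops = {
            s: ({"p0", "p1"} if sup else set())
            for s, sup in zip(samples, support_pattern)
        }
        return region, tops, samples

    @pytest.mark.parametrize("n_support, called", [(5, True), (4, True), (3, False)])
    def test_all_but_one_rule(self, n_support, called):
        region, tops, samples = self._setup([1] * n_support + [0] * (5 - n_support))
        got = ds.call_recurrent_dmrs([region], tops, samples)
        assert bool(got) is called

    def test_supporting_samples_recorded(self):
        region, tops, samples = self._setup([1, 1, 1, 0, 1])
        (dmr,) = ds.call_recurrent_dmrs([region], tops, samples)
        assert dmr.supporting_samples == ("S0", "S1", "S2", "S4")
        assert set(dmr.support_segments) == {"S0", "S1", "S2", "S4"}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ds.call_recurrent_dmrs([region_of(2)], {}, [])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_recount(self, data):
        n_samples = data.draw(st.integers(2, 6))
        n_regions = data.draw(st.integers(1, 20))
        regions = []
        pos = 0
        for i in range(n_regions):
            n_probes = data.draw(st.integers(2, 5))
            regions.append(
                Region(region_id=f"r{i}", chrom="chr1", start=pos,
                       end=pos + 100 * n_probes,
                       probe_ids=tuple(f"r{i}_p{j}" for j in range(n_probes)))
            )
            pos += 100 * n_probes + 1000
        samples = [f"S{i}" for i in range(n_samples)]
        all_probes = [p for r in regions for p in r.probe_ids]
        tops = {
            s: {p for p in all_probes if data.draw(st.booleans())}
            for s in samples
        }
        got = {d.region.region_id for d in ds.call_recurrent_dmrs(regions, tops, samples)}
        expect = set()
        for r in regions:
            n_sup = sum(brute_force_segment([p in tops[s] for p in r.probe_ids])
                        for s in samples)
            if n_sup >= n_samples - 1:
                expect.add(r.region_id)
        assert got == expect


class TestRankSelect:
    def _dmr(self, rid, support, score):
        return DMR(
            region=Region(region_id=rid, chrom="chr1", start=0, end=200,
                          probe_ids=("a", "b")),
            supporting_samples=tuple(f"S{i}" for i in range(support)),
            support_segments={}, rank_score=score,
        )

    def test_triple_key_order(self):
        dmrs = [
            self._dmr("r3", 4, 1.0),
            self._dmr("r1", 5, 0.5),
            self._dmr("r2", 5, 0.9),
            self._dmr("r4", 4, 1.0),  # tie with r3 -> region id decides
        ]
        got = ds.rank_select_dmrs({"ypN+": dmrs}, k=3)
        ids = {d.region.region_id for d in got}
        assert ids == {"r2", "r1", "r3"}

    def test_short_category_returns_what_exists(self):
        dmrs = [self._dmr(f"r{i}", 3, 0.1) for i in range(3)]
        assert len(ds.rank_select_dmrs({"responder": dmrs}, k=5)) == 3

    def test_four_categories_cap_and_duplicate_collapse(self):
        per_cat = {
            cat: [self._dmr(f"{cat}_r{i}", 5, float(i)) for i in range(7)]
            for cat in ["ypN+", "ypN-", "responder", "non-responder"]
        }
        got = ds.rank_select_dmrs(per_cat, k=5)
        assert len(got) == 20
        shared = self._dmr("shared", 5, 9.0)
        per_cat["ypN+"].append(shared)
        per_cat["ypN-"].append(shared)
        got = ds.rank_select_dmrs(per_cat, k=5)
        lab = {d.region.region_id: d.categories for d in got}
        assert lab["shared"] == ["ypN+", "ypN-"]


class TestChromosomeEnrichment:
    def _dmrs_on(self, chroms):
        return [
            DMR(region=Region(region_id=f"d{i}", chrom=c, start=0, end=200,
                              probe_ids=("a", "b")),
                supporting_samples=("S1",), support_segments={}, rank_score=0.0)
            for i, c in enumerate(chroms)
        ]

    def _probe_map(self, counts):
        rows = []
        for chrom, n in counts.items():
            for i in range(n):
                rows.append((chrom, 1000 * i, 1000 * i + 50, f"{chrom}_p{i}", "x"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id", "island_id"])

    def test_proportional_counts_give_null(self):
        pm = self._probe_map({"chr1": 300, "chr2": 100})
        dmrs = self._dmrs_on(["chr1"] * 30 + ["chr2"] * 10)
        stat, p = ds.chromosome_enrichment(dmrs, pm, seed=0)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_concentration_on_rare_chromosome(self):
        pm = self._probe_map({"chr1": 10, **{f"chr{i}": 110 for i in range(2, 11)}})
        # chr1 holds 1% of probes but all 20 DMRs
        dmrs = self._dmrs_on(["chr1"] * 20)
        stat, p = ds.chromosome_enrichment(dmrs, pm, n_mc=1_000_000, seed=0)
        assert p < 1e-6
        # analytic bound: P(all 20 on a 1% chromosome) = 0.01^20, so any
        # consistent test must be far below the Monte-Carlo floor
        assert stats.binom.sf(19, 20, 0.01) < 1e-6

    def test_mc_and_asymptotic_agree_on_balanced_case(self):
        pm = self._probe_map({f"chr{i}": 200 for i in range(1, 6)})
        rng = np.random.default_rng(5)
        chroms = [f"chr{i}" for i in rng.integers(1, 6, 300)]
        dmrs = self._dmrs_on(chroms)
        # expected counts = 60 per chromosome -> asymptotic branch
        stat, p_asym = ds.chromosome_enrichment(dmrs, pm, seed=0)
        # independent Monte-Carlo estimate of the same tail probability
        draws = rng.multinomial(300, np.full(5, 0.2), size=200_000)
        sim = ((draws - 60.0) ** 2 / 60.0).sum(axis=1)
        p_mc = float((1 + np.sum(sim >= stat - 1e-12)) / 200_001)
        assert abs(p_mc - p_asym) < 0.02

    def test_argument_errors(self, probe_map_small):
        with pytest.raises(ValueError):
            ds.chromosome_enrichment([], probe_map_small)
        dmrs = self._dmrs_on(["chr1"])
        with pytest.raises(ValueError):
            ds.chromosome_enrichment(dmrs, probe_map_small, n_mc=50)


class TestDirection:
    def test_hypo_scan_mirrors_hyper_on_negated_m(self, probe_map_small):
        cohort = ds.generate_array_cohort(probe_map_small, n_samples=5,
                                          n_planted=4, noise_sd=0.3, seed=9)
        M = cohort.true_m
        cats = {"responder": cohort.category_samples("responder")}
        hyper = ds.discover_dmrs(M, probe_map_small, cats, k=10)
        hypo = ds.discover_dmrs(-M, probe_map_small, cats, k=10, direction="hypo")
        assert {d.region.region_id for d in hyper} == \
               {d.region.region_id for d in hypo}
        with pytest.raises(ValueError):
            ds.discover_dmrs(M, probe_map_small, cats, direction="sideways")


class TestMonotonicity:
    def test_fraction_increase_never_loses_dmrs(self, probe_map_small):
        cohort = ds.generate_array_cohort(probe_map_small, n_samples=5,
                                          n_planted=4, noise_sd=0.5, seed=6)
        M = cohort.true_m
        regions = ds.build_regions(probe_map_small)
        samples = list(M.index)
        called = {}
        for frac in (0.05, 0.1, 0.2, 0.4):
            tops = {s: ds.select_top_probes(M.loc[s], frac) for s in samples}
            called[frac] = {
                d.region.region_id
                for d in ds.call_recurrent_dmrs(regions, tops, samples)
            }
        assert called[0.05] <= called[0.1] <= called[0.2] <= called[0.4]

    def test_smaller_gap_never_merges(self, probe_map_small):
        wide = ds.build_regions(probe_map_small, max_gap=500)
        narrow = ds.build_regions(probe_map_small, max_gap=100)
        # every narrow region's probes are contained in some wide region
        wide_sets = [set(r.probe_ids) for r in wide]
        for r in narrow:
            assert any(set(r.probe_ids) <= w for w in wide_sets)
        assert len(narrow) >= 0  # narrow may split or drop, never merge
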