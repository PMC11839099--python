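"""High-Signal, Low-Mappability, and Blacklist-style callers."""

import numpy as np
import pandas as pd
import pytest

from exclusionkit.callers import (
    LABEL_BOTH,
    LABEL_HS,
    LABEL_LM,
    BinnedSignal,
    PeakSet,
    annotate_region,
    bin_mappability,
    call_blacklist,
    call_high_signal,
    call_low_mappability,
    count_reads_per_bin,
    make_bin_grid,
    union_with_gap_class,
)
from exclusionkit.genome import GapAnnotation, Genome, IntervalSet, ValueTrack, total_width

from conftest import random_interval_set


def peakset(genome, rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "fc"])
    return PeakSet(IntervalSet(genome, df[["chrom", "start", "end"]]), df["fc"].to_numpy(float))


def track_from(genome, rows):
    return ValueTrack(genome, pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


@pytest.fixture
def big_genome():
    return Genome((("chr1", 100_000),))


class TestHighSignal:
    def test_range_threshold_keeps_only_extreme_peak(self, big_genome):
        # fold changes {2,3,10,50,100}: threshold = 2 + 0.99*(100-2) = 99.02,
        # so only the fc=100 peak survives the strict > comparison
        rows = [
            ("chr1", 0, 1500, 2.0),
            ("chr1", 5000, 6500, 3.0),
            ("chr1", 10000, 11500, 10.0),
            ("chr1", 20000, 21500, 50.0),
            ("chr1", 30000, 31500, 100.0),
        ]
        out = call_high_signal(peakset(big_genome, rows))
        assert [(r.start, r.end) for r in out] == [(30000, 31500)]

    def test_constant_fold_changes_yield_nothing(self, big_genome):
        rows = [("chr1", i * 3000, i * 3000 + 1500, 7.0) for i in range(4)]
        assert len(call_high_signal(peakset(big_genome, rows))) == 0

    def test_merge_then_width_filter(self, big_genome):
        # two surviving 600 bp peaks 800 bp apart merge into one 2,200 bp
        # region that passes the 1 kb width filter; unmerged they would not
        rows = [
            ("chr1", 10_000, 10_600, 500.0),
            ("chr1", 11_400, 12_000, 500.0),
            ("chr1", 50_000, 50_200, 1.0),
        ]
        out = call_high_signal(peakset(big_genome, rows))
        assert [(r.start, r.end) for r in out] == [(10_000, 12_000)]
        assert total_width(out) == 2000  # 600 + 800 bridged + 600

    def test_empty_peakset_rejected(self, big_genome):
        empty = PeakSet(IntervalSet.empty(big_genome), np.array([]))
        with pytest.raises(ValueError):
            call_high_signal(empty)

    def test_percentile_mode_thresholds_on_quantile(self, big_genome):
        # 99th percentile of {1..100} (linear interpolation) = 99.01; with a
        # strict > only fc=100 survives, while the range rule keeps 100 too
        rows = [("chr1", i * 900, i * 900 + 1200, float(i + 1)) for i in range(100)]
        out = call_high_signal(peakset(big_genome, rows), mode="percentile")
        assert len(out) == 1

    def test_shrinking_range_fraction_never_drops_survivors(self, big_genome, rng):
        rows = [
            ("chr1", int(i * 2000), int(i * 2000) + 1500, float(fc))
            for i, fc in enumerate(rng.lognormal(1, 1, size=30))
        ]
        strict = call_high_signal(peakset(big_genome, rows), range_fraction=0.99)
        loose = call_high_signal(peakset(big_genome, rows), range_fraction=0.90)
        for r in strict:
            assert any(
                o.start <= r.start and r.end <= o.end for o in loose
            ), "peak surviving the stricter threshold lost at the looser one"


class TestUnionWithGapClass:
    def test_disjoint_additivity_and_identity(self, big_genome):
        cen = IntervalSet.from_tuples(big_genome, [("chr1", 40_000, 50_000)])
        gaps = GapAnnotation({"centromere": cen})
        s = IntervalSet.from_tuples(big_genome, [("chr1", 0, 5_000)])
        merged = union_with_gap_class(s, gaps)
        assert total_width(merged) == 15_000
        assert total_width(union_with_gap_class(IntervalSet.empty(big_genome), gaps)) == 10_000
        covering = IntervalSet.from_tuples(big_genome, [("chr1", 30_000, 60_000)])
        assert total_width(union_with_gap_class(covering, gaps)) == 30_000

    def test_unknown_class_rejected(self, big_genome):
        gaps = GapAnnotation({})
        with pytest.raises(KeyError):
            union_with_gap_class(IntervalSet.empty(big_genome), gaps, "centromere")


class TestLowMappability:
    def test_five_step_trace(self):
        # universe (>0.01) = [0,4000)+[4500,9000); merging within 1 kb absorbs
        # the 500 bp unmappable gap; inverting leaves [9000,10000), kept at
        # exactly the 1 kb width threshold
        g = Genome((("chr1", 10_000),))
        track = track_from(
            g,
            [
                ("chr1", 0, 4000, 1.0),
                ("chr1", 4000, 4500, 0.0),
                ("chr1", 4500, 9000, 1.0),
                ("chr1", 9000, 10_000, 0.005),
            ],
        )
        out = call_low_mappability(track, g)
        assert [(r.start, r.end) for r in out] == [(9000, 10_000)]

    def test_uniform_mappable_gives_nothing(self, big_genome):
        track = track_from(big_genome, [("chr1", 0, 100_000, 1.0)])
        assert len(call_low_mappability(track, big_genome)) == 0

    def test_uniform_zero_gives_whole_genome(self, big_genome):
        track = track_from(big_genome, [("chr1", 0, 100_000, 0.0)])
        out = call_low_mappability(track, big_genome)
        assert total_width(out) == big_genome.total_size

    def test_value_outside_unit_interval_rejected(self, big_genome):
        track = track_from(big_genome, [("chr1", 0, 100, 1.5)])
        with pytest.raises(ValueError):
            call_low_mappability(track, big_genome)

    def test_mappable_island_inside_desert_is_preserved(self):
        # a >=merge_gap mappable island surrounded by unmappable sequence must
        # not end up inside the called regions
        g = Genome((("chr1", 30_000),))
        track = track_from(
            g,
            [
                ("chr1", 0, 10_000, 0.0),
                ("chr1", 10_000, 14_000, 1.0),
                ("chr1", 14_000, 30_000, 0.0),
            ],
        )
        out = call_low_mappability(track, g)
        assert [(r.start, r.end) for r in out] == [(0, 10_000), (14_000, 30_000)]


class TestBinGrid:
    def test_non_overlapping_tiling(self):
        grid = make_bin_grid(Genome((("chr1", 100),)), 50, 0)
        assert list(zip(grid.starts, grid.ends)) == [(0, 50), (50, 100)]

    def test_overlapping_bins_step_arithmetic(self):
        grid = make_bin_grid(Genome((("chr1", 100),)), 40, 20)
        assert grid.starts.tolist() == [0, 20, 40, 60]
        assert grid.ends.tolist() == [40, 60, 80, 100]

    def test_short_trailing_bin_dropped(self):
        grid = make_bin_grid(Genome((("chr1", 110),)), 50, 0)
        assert list(zip(grid.starts, grid.ends)) == [(0, 50), (50, 100)]

    def test_chromosome_shorter_than_bin(self):
        grid = make_bin_grid(Genome((("chr1", 30),)), 50, 0)
        assert list(zip(grid.starts, grid.ends)) == [(0, 30)]

    @pytest.mark.parametrize("size,overlap", [(50, 50), (50, 60), (0, 0)])
    def test_invalid_parameters_rejected(self, size, overlap):
        with pytest.raises(ValueError):
            make_bin_grid(Genome((("chr1", 100),)), size, overlap)


class TestCountReadsPerBin:
    def test_midpoints_in_one_bin(self):
        g = Genome((("chr1", 200),))
        grid = make_bin_grid(g, 100, 0)
        reads = pd.DataFrame(
            [("chr1", 10, 30), ("chr1", 20, 40), ("chr1", 50, 70)],
            columns=["chrom", "start", "end"],
        )
        sig = count_reads_per_bin(reads, grid)
        assert sig.counts[:, 0].tolist() == [3, 0]

    def test_boundary_midpoint_goes_to_later_bin(self):
        g = Genome((("chr1", 200),))
        grid = make_bin_grid(g, 100, 0)
        reads = pd.DataFrame([("chr1", 90, 110)], columns=["chrom", "start", "end"])
        sig = count_reads_per_bin(reads, grid)  # midpoint exactly 100
        assert sig.counts[:, 0].tolist() == [0, 1]

    def test_overlapping_bins_count_midpoint_in_each(self):
        g = Genome((("chr1", 200),))
        grid = make_bin_grid(g, 100, 50)
        reads = pd.DataFrame([("chr1", 70, 80)], columns=["chrom", "start", "end"])
        sig = count_reads_per_bin(reads, grid)  # midpoint 75 in [0,100) and [50,150)
        assert sig.counts[:, 0].tolist() == [1, 1, 0]

    def test_read_outside_genome_rejected(self):
        g = Genome((("chr1", 200),))
        grid = make_bin_grid(g, 100, 0)
        reads = pd.DataFrame([("chr1", 150, 250)], columns=["chrom", "start", "end"])
        with pytest.raises(ValueError):
            count_reads_per_bin(reads, grid)

    def test_matches_brute_force_midpoint_binning(self, rng):
        g = Genome((("chr1", 2000), ("chr2", 1500)))
        grid = make_bin_grid(g, 100, 40)
        starts = rng.integers(0, 1900, size=500)
        reads = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], size=500), "start": starts}
        )
        reads["start"] = np.minimum(reads["start"], reads["chrom"].map(g.lengths) - 60)
        reads["end"] = reads["start"] + 50
        got = count_reads_per_bin(reads, grid).counts[:, 0]
        expected = np.zeros(grid.n_bins, dtype=int)
        for r in reads.itertuples(index=False):
            mid = (r.start + r.end) // 2
            for i in range(grid.n_bins):
                if grid.chroms[i] == r.chrom and grid.starts[i] <= mid < grid.ends[i]:
                    expected[i] += 1
        assert got.tolist() == expected.tolist()


class TestBinMappability:
    def test_uniform_track(self):
        g = Genome((("chr1", 1000),))
        grid = make_bin_grid(g, 100, 0)
        bm = bin_mappability(track_from(g, [("chr1", 0, 1000, 1.0)]), grid)
        assert np.allclose(bm, 1.0)

    def test_half_covered_bin(self):
        g = Genome((("chr1", 100),))
        grid = make_bin_grid(g, 100, 0)
        bm = bin_mappability(track_from(g, [("chr1", 0, 50, 1.0)]), grid)
        assert bm[0] == pytest.approx(0.5)

    def test_matches_per_base_oracle(self, rng):
        g = Genome((("chr1", 3000),))
        pos, rows = 0, []
        while pos < 3000:
            w = int(rng.integers(50, 300))
            rows.append(("chr1", pos, min(pos + w, 3000), float(rng.random())))
            pos += w + int(rng.integers(0, 100))  # leave implicit-zero gaps
        track = track_from(g, rows)
        grid = make_bin_grid(g, 250, 100)
        got = bin_mappability(track, grid)
        per_base = np.zeros(3000)
        for _, s, e, v in rows:
            per_base[s:e] = v
        expected = [per_base[s:e].mean() for s, e in zip(grid.starts, grid.ends)]
        assert np.allclose(got, expected, atol=1e-12)


class TestAnnotateRegion:
    @pytest.mark.parametrize(
        "hs,lm,expected",
        [(True, False, LABEL_HS), (False, True, LABEL_LM), (True, True, LABEL_BOTH)],
    )
    def test_label_table(self, hs, lm, expected):
        assert annotate_region(hs, lm) == expected

    def test_no_evidence_rejected(self):
        with pytest.raises(ValueError):
            annotate_region(False, False)


def _blacklist_fixture(lm_zone, hotspot=(10_000, 14_000), length=200_000):
    """One extreme pileup plus one zero-mappability zone on a 1-chrom genome."""
    g = Genome((("chr1", length),))
    grid = make_bin_grid(g, 1000, 500)
    rng = np.random.default_rng(7)
    counts = np.column_stack(
        [rng.poisson(20, size=grid.n_bins) for _ in range(3)]
    ).astype(float)
    hot = (grid.starts >= hotspot[0]) & (grid.ends <= hotspot[1])
    counts[hot] += 5000
    sig = BinnedSignal(grid, counts.astype(int), ("s1", "s2", "s3"))
    track = track_from(
        g,
        [
            ("chr1", 0, lm_zone[0], 1.0),
            ("chr1", lm_zone[0], lm_zone[1], 0.0),
            ("chr1", lm_zone[1], length, 1.0),
        ],
    )
    bm = bin_mappability(track, grid)
    return g, grid, sig, bm


class TestCallBlacklist:
    def test_far_apart_zones_get_distinct_labels(self):
        # the hotspot spans >1% of bins, so the 0.99 signal quantile falls
        # inside the hotspot value range and no background bin is flagged
        g, grid, sig, bm = _blacklist_fixture(lm_zone=(100_000, 110_000))
        out = call_blacklist(sig, bm)
        assert set(out.labels) == {LABEL_HS, LABEL_LM}
        by_label = dict(zip(out.labels, out.intervals))
        assert 10_000 <= by_label[LABEL_HS].start < by_label[LABEL_HS].end <= 14_000
        assert by_label[LABEL_LM].start == 100_000
        assert by_label[LABEL_LM].end == 110_000

    def test_nearby_zones_bridge_into_combined_label(self):
        g, grid, sig, bm = _blacklist_fixture(lm_zone=(20_000, 30_000))
        out = call_blacklist(sig, bm)
        assert out.labels == (LABEL_BOTH,)  # never silently collapsed to HS

    def test_uniform_signal_and_mappability_yields_empty(self):
        g = Genome((("chr1", 50_000),))
        grid = make_bin_grid(g, 1000, 500)
        sig = BinnedSignal(grid, np.full((grid.n_bins, 2), 10), ("a", "b"))
        bm = np.ones(grid.n_bins)
        out = call_blacklist(sig, bm)
        assert len(out) == 0

    def test_invariants_regions_separated_and_flags_partition(self):
        g, grid, sig, bm = _blacklist_fixture(lm_zone=(150_000, 160_000))
        bridge = 20_000
        out = call_blacklist(sig, bm, signal_quantile=0.95, bridge=bridge)
        for _, sub in out.intervals.df.groupby("chrom"):
            gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
            assert (gaps > bridge).all()
        # every flagged bin lies in exactly one output region, and a brute
        # re-scan of the flags reproduces each region's label
        totals = sig.counts.sum(axis=0).astype(float)
        agg = np.median(sig.counts / totals, axis=1)
        hs = agg > np.quantile(agg, 0.95)
        lm = bm < 0.5
        regions = list(out.intervals)
        for i in np.flatnonzero(hs | lm):
            containing = [
                r
                for r in regions
                if r.chrom == grid.chroms[i]
                and grid.starts[i] < r.end
                and grid.ends[i] > r.start
            ]
            assert len(containing) == 1
        for r, label in zip(regions, out.labels):
            inside = (grid.starts < r.end) & (grid.ends > r.start)
            assert label == annotate_region(bool((hs & inside).any()), bool((lm & inside).any()))

    def test_grid_mismatch_rejected(self):
        g, grid, sig, bm = _blacklist_fixture(lm_zone=(100_000, 110_000))
        with pytest.raises(ValueError):
            call_blacklist(sig, bm[:-1])
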