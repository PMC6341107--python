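"""Peak stitching, super-enhancer ranking, unions, blacklist filtering and
differential classification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hijackscan import peaks
from hijackscan.coverage import DensityTrack
from hijackscan.intervals import GenomicInterval
from hijackscan.peaks import MergedRegion, Peak

LENGTHS = {"chr4s": 64_000}


def make_track(values, bin_size=32, chrom="chr4s"):
    lengths = {chrom: len(values) * bin_size}
    track = DensityTrack.zeros(lengths, bin_size)
    track.data[chrom] = np.asarray(values, dtype=float)
    return track


def peak(start, end, signal=1.0, chrom="chr4s"):
    return Peak(interval=GenomicInterval(chrom, start, end), signal=signal)


class TestDetect:
    def test_flat_track_empty(self):
        assert peaks.detect_enriched_regions(make_track([0] * 100)) == []

    def test_planted_region_recovered(self, rng):
        bg = rng.poisson(5, size=500).astype(float)
        bg[200:240] = rng.poisson(50, size=40)
        track = make_track(bg)
        found = peaks.detect_enriched_regions(track, fold_threshold=4.0)
        assert len(found) == 1
        p = found[0]
        assert abs(p.interval.start // 32 - 200) <= 2
        assert abs(p.interval.end // 32 - 240) <= 2
        assert p.interval.contains_point(p.summit)

    def test_subthreshold_gap_splits_runs(self):
        values = [1] * 20 + [100, 100, 1, 100, 100] + [1] * 20
        found = peaks.detect_enriched_regions(
            make_track(values), fold_threshold=4.0, min_bins=2
        )
        assert len(found) == 2


class TestBlacklist:
    def test_overlap_rules(self):
        blacklist = [GenomicInterval("chr4s", 1_000, 2_000)]
        inside = peak(1_200, 1_400)
        one_bp = peak(1_999, 2_500)  # 1-bp overlap at the boundary
        clear = peak(2_000, 2_500)  # touches but does not overlap
        kept = peaks.filter_blacklist([inside, one_bp, clear], blacklist)
        assert kept == [clear]

    def test_empty_blacklist_is_identity(self):
        ps = [peak(0, 10), peak(100, 200)]
        assert peaks.filter_blacklist(ps, []) == ps


class TestStitch:
    def test_distance_exactly_gap_merges(self):
        out = peaks.stitch_regions([peak(0, 500), peak(13_000, 13_500)])
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (0, 13_500)

    def test_distance_one_over_gap_splits(self):
        out = peaks.stitch_regions([peak(0, 500), peak(13_001, 13_500)])
        assert len(out) == 2

    def test_chain_is_transitively_closed(self):
        # A-B and B-C within gap, A-C not: still one region
        out = peaks.stitch_regions(
            [peak(0, 100), peak(12_000, 12_100), peak(24_000, 24_100)]
        )
        assert len(out) == 1

    def test_aggregate_signal_is_length_weighted(self):
        out = peaks.stitch_regions([peak(0, 100, 2.0), peak(200, 500, 3.0)])
        assert out[0].signal == pytest.approx(2.0 * 100 + 3.0 * 300)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 2_000), st.integers(1, 100)),
            min_size=1,
            max_size=15,
        ),
        st.integers(0, 300),
    )
    def test_matches_union_find_oracle(self, spec, gap):
        ps = [peak(s * 10, s * 10 + l) for s, l in spec]
        out = peaks.stitch_regions(ps, gap=gap)
        # union-find oracle over the pairwise <=gap relation
        parent = list(range(len(ps)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                if ps[i].interval.gap_to(ps[j].interval) <= gap:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(ps))})
        assert len(out) == n_components
        # idempotence: re-stitching the merged regions changes nothing
        again = peaks.stitch_regions(
            [Peak(interval=r.interval, signal=1.0) for r in out], gap=gap
        )
        assert [r.interval for r in again] == [r.interval for r in out]


class TestSuperEnhancers:
    def _regions(self, signals):
        return [
            MergedRegion(
                interval=GenomicInterval("chr4s", i * 1_000, i * 1_000 + 100),
                constituents=[],
                signal=s,
            )
            for i, s in enumerate(signals)
        ]

    def test_top_five_percent_of_forty(self, rng):
        regions = self._regions(rng.uniform(1, 100, size=40))
        out = peaks.call_super_enhancers(regions)
        assert sum(r.is_super_enhancer for r in out) == 2
        flagged = {r.rank for r in out if r.is_super_enhancer}
        assert flagged == {1, 2}

    def test_minimum_one_rule(self):
        out = peaks.call_super_enhancers(self._regions(range(1, 11)))
        assert sum(r.is_super_enhancer for r in out) == 1
        assert [r for r in out if r.is_super_enhancer][0].signal == 10

    def test_tie_at_cutoff_prefers_earlier_start(self):
        regions = self._regions([5.0] * 30)
        out = peaks.call_super_enhancers(regions)
        flagged = [r for r in out if r.is_super_enhancer]
        assert len(flagged) == 1
        assert flagged[0].interval.start == 0

    def test_empty_input(self):
        assert peaks.call_super_enhancers([]) == []


class TestUnion:
    def test_overlapping_merge(self):
        out = peaks.union_regions([[peak(0, 10)], [peak(5, 20)]])
        assert out == [GenomicInterval("chr4s", 0, 20)]

    def test_disjoint_unchanged(self):
        out = peaks.union_regions([[peak(0, 10), peak(50, 60)]])
        assert [(r.start, r.end) for r in out] == [(0, 10), (50, 60)]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.lists(
                st.tuples(st.integers(0, 490), st.integers(1, 30)),
                max_size=10,
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_matches_per_bp_mark_and_sweep(self, sets):
        peak_sets = [[peak(s, s + l) for s, l in grp] for grp in sets]
        out = peaks.union_regions(peak_sets)
        marked = np.zeros(600, dtype=bool)
        for grp in sets:
            for s, l in grp:
                marked[s : s + l] = True
        padded = np.concatenate(([False], marked, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        expected = [
            GenomicInterval("chr4s", int(a), int(b))
            for a, b in zip(edges[::2], edges[1::2])
        ]
        assert out == expected


class TestDifferential:
    def _tracks(self, tumor_values, normal_values):
        return (
            [make_track(v) for v in tumor_values],
            make_track(normal_values),
        )

    @pytest.mark.parametrize(
        "tumor,normal,eps,expected_ratio,expected_label",
        [
            (8.0, 2.0, 0.0, 2.0, "up"),
            (1.0, 4.0, 0.0, -2.0, "down"),
            (4.0, 0.0, 0.25, np.log2(17), "up"),
            (4.0, 2.0, 0.0, 1.0, "neutral"),
        ],
    )
    def test_ratio_arithmetic(self, tumor, normal, eps, expected_ratio,
                              expected_label):
        tumors, norm = self._tracks([[tumor] * 10], [normal] * 10)
        region = GenomicInterval("chr4s", 0, 320)
        (d,) = peaks.classify_differential([region], tumors, norm, eps=eps)
        assert d.log2_ratio == pytest.approx(expected_ratio)
        assert d.label == expected_label

    def test_classes_partition_regions(self, rng):
        values = rng.poisson(4, size=(3, 200)).astype(float)
        tumors, norm = self._tracks(list(values[:2]), values[2])
        regions = [
            GenomicInterval("chr4s", s, s + 320) for s in range(0, 6_000, 640)
        ]
        out = peaks.classify_differential(regions, tumors, norm)
        assert len(out) == len(regions)
        assert all(d.label in ("up", "down", "neutral") for d in out)

    def test_region_outside_track_rejected(self):
        tumors, norm = self._tracks([[1.0] * 10], [1.0] * 10)
        with pytest.raises(ValueError, match="outside"):
            peaks.classify_differential(
                [GenomicInterval("chr4s", 0, 99_999)], tumors, norm
            )

    def test_noise_free_planted_recovery(self):
        # planted 4x and 0.25x regions on a flat background of 8
        normal = np.full(400, 8.0)
        tumor = normal.copy()
        tumor[50:80] *= 4.0
        tumor[200:230] *= 0.25
        tumors, norm = self._tracks([tumor, tumor], normal)
        regions = [
            GenomicInterval("chr4s", 50 * 32, 80 * 32),
            GenomicInterval("chr4s", 200 * 32, 230 * 32),
            GenomicInterval("chr4s", 300 * 32, 330 * 32),
        ]
        labels = [
            d.label
            for d in peaks.classify_differential(regions, tumors, norm, eps=0.0)
        ]
        assert labels == ["up", "down", "neutral"]
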