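"""Translocation filtering, pattern classification and derived-locus
reconstruction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hijackscan import rearrangements as rr
from hijackscan.intervals import GenomicInterval


def call(pos_a, strand_a="-", pos_b=499_400, strand_b="-", quality=300,
         support=20, sample="TX001"):
    return rr.TranslocationCall(
        sample=sample,
        a=rr.Breakend("chr4s", pos_a, strand_a),
        b=rr.Breakend("chr9s", pos_b, strand_b),
        quality=quality,
        support=support,
    )


class TestFilter:
    @pytest.mark.parametrize(
        "quality,support,kept",
        [
            (255, 15, True),  # both thresholds inclusive
            (254, 100, False),
            (300, 14, False),
            (1000, 80, True),
        ],
    )
    def test_thresholds(self, quality, support, kept):
        out = rr.filter_translocations([call(1_000, quality=quality,
                                             support=support)])
        assert bool(out) is kept

    def test_pure_predicate_and_idempotent(self):
        calls = [call(1, quality=q, support=s)
                 for q, s in [(255, 15), (0, 0), (999, 14)]]
        out = rr.filter_translocations(calls)
        assert all(c in calls for c in out)
        assert rr.filter_translocations(out) == out


@pytest.fixture(scope="module")
def annotation(locus):
    return locus.annotation()


class TestClassify:
    def test_intron_beats_everything(self, locus, annotation):
        intron = locus.fdcsp_intron1
        pc = rr.classify_pattern(call(intron.start + 10), annotation)
        assert pc.pattern == "pattern3"
        assert "intron" in pc.evidence

    def test_ctcf_window_outside_genes(self, annotation):
        w = annotation.ctcf_pair_window
        pc = rr.classify_pattern(call(w.start + 5), annotation)
        assert pc.pattern == "pattern1"

    def test_triple_gene_span(self, annotation):
        w = annotation.triple_gene_span
        pc = rr.classify_pattern(call(w.midpoint), annotation)
        assert pc.pattern == "pattern2"

    def test_elsewhere_is_other(self, annotation):
        pc = rr.classify_pattern(call(10), annotation)
        assert pc.pattern == "other"

    @pytest.mark.parametrize(
        "offset,near", [(600, True), (1, True), (601, False), (0, False)]
    )
    def test_acceptor_proximity_flag(self, locus, annotation, offset, near):
        c = call(10, pos_b=locus.acceptor_tss - offset)
        assert rr.classify_pattern(c, annotation).acceptor_near_tss is near

    def test_missing_annotation_named(self, annotation):
        broken = rr.LocusAnnotation(
            donor_chrom=annotation.donor_chrom,
            ctcf_pair_window=annotation.ctcf_pair_window,
            triple_gene_span=None,
            intragenic_intervals=annotation.intragenic_intervals,
            acceptor_chrom=annotation.acceptor_chrom,
            tss=annotation.tss,
        )
        with pytest.raises(ValueError, match="triple_gene_span"):
            rr.classify_pattern(call(10), broken)

    def test_planted_cohort_recovered(self, locus, annotation):
        from hijackscan import synthetic

        cohort = [1] * 4 + [2] * 10 + [3]
        calls, truth = synthetic.generate_translocations(
            locus, patterns=cohort, n_noise=5, seed=11
        )
        kept = rr.filter_translocations(calls)
        assert len(kept) == 15
        assert {c.sample for c in calls} - {c.sample for c in kept} == {
            s for s, lab in truth.pattern_labels.items() if lab == "noise"
        }
        for c in kept:
            got = rr.classify_pattern(c, annotation).pattern
            assert got == truth.pattern_labels[c.sample]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 999_999))
    def test_total_and_deterministic(self, annotation, pos):
        a = rr.classify_pattern(call(pos), annotation)
        b = rr.classify_pattern(call(pos), annotation)
        assert a.pattern == b.pattern
        assert a.pattern in ("pattern1", "pattern2", "pattern3", "other")
        # precedence: containment in the intron always yields pattern3
        if any(iv.contains_point(pos)
               for iv in annotation.intragenic_intervals):
            assert a.pattern == "pattern3"


def oracle_distance(donor_pos, donor_strand, feature, acc_pos, tss):
    """Brute-force oracle: enumerate retained donor base pairs, map each to
    its distance from the junction, take the feature's minimum."""
    span = np.arange(feature.start, feature.end)
    if donor_strand == "+":
        retained = span[span < donor_pos]
        offsets = donor_pos - retained - 1  # bp adjacent to junction -> 0
        # edge-based convention measures from the feature edge, i.e. the
        # gap between feature and breakpoint
        edge = donor_pos - retained.max() - 1 if retained.size else None
    else:
        retained = span[span >= donor_pos]
        edge = retained.min() - donor_pos if retained.size else None
    if edge is None:
        return None
    return abs(tss - acc_pos) + edge


class TestReconstruct:
    def test_worked_example_distance(self):
        # acceptor breakend 600 bp upstream of the TSS; donor enhancer whose
        # near edge is 90,000 bp from the breakpoint on the retained side
        tss = 500_000
        enhancer = GenomicInterval("chr4s", 290_000, 292_000, name="E")
        c = call(382_000, "+", pos_b=tss - 600, strand_b="-")
        derived = rr.reconstruct_derived_locus(c, [enhancer], tss,
                                               "chr4s", "chr9s")
        assert derived.junction_to_tss == 600
        assert derived.features[0].distance_to_tss == 90_600

    def test_lost_side_features_excluded(self):
        tss = 500_000
        kept = GenomicInterval("chr4s", 300_000, 301_000, name="kept")
        lost = GenomicInterval("chr4s", 100_000, 101_000, name="lost")
        c = call(250_000, "-", pos_b=tss - 600, strand_b="-")
        derived = rr.reconstruct_derived_locus(c, [kept, lost], tss,
                                               "chr4s", "chr9s")
        assert [f.name for f in derived.features] == ["kept"]

    def test_straddling_feature_clipped_to_zero_distance(self):
        tss = 500_000
        straddle = GenomicInterval("chr4s", 249_000, 251_000, name="s")
        c = call(250_000, "-", pos_b=tss - 100, strand_b="-")
        derived = rr.reconstruct_derived_locus(c, [straddle], tss,
                                               "chr4s", "chr9s")
        assert derived.features[0].distance_to_tss == 100  # junction offset only

    def test_tss_lost_raises(self):
        c = call(250_000, "-", pos_b=400_000, strand_b="+")  # left retained
        with pytest.raises(ValueError, match="TSS not on derived"):
            rr.reconstruct_derived_locus(
                c, [], 500_000, "chr4s", "chr9s"
            )

    def test_mirror_symmetry(self, rng):
        L = 1_000_000
        tss = 500_000
        for _ in range(50):
            n = rng.integers(1, 6)
            starts = rng.integers(0, L - 400, size=n)
            feats = [
                GenomicInterval("chr4s", int(s), int(s) + int(rng.integers(50, 300)),
                                name=f"f{i}")
                for i, s in enumerate(starts)
            ]
            pos = int(rng.integers(1, L - 1))
            acc = int(rng.integers(1, tss))
            fwd = rr.reconstruct_derived_locus(
                call(pos, "+", pos_b=acc, strand_b="-"), feats, tss,
                "chr4s", "chr9s",
            )
            mirrored = [
                GenomicInterval("chr4s", L - f.end, L - f.start, name=f.name)
                for f in feats
            ]
            rev = rr.reconstruct_derived_locus(
                call(L - pos, "-", pos_b=acc, strand_b="-"), mirrored, tss,
                "chr4s", "chr9s",
            )
            assert sorted((f.name, f.distance_to_tss) for f in fwd.features) == \
                sorted((f.name, f.distance_to_tss) for f in rev.features)

    def test_matches_bruteforce_coordinate_oracle(self, rng):
        L = 1_000_000
        tss = 500_000
        for _ in range(100):
            s = int(rng.integers(0, L - 400))
            feat = GenomicInterval("chr4s", s, s + int(rng.integers(1, 300)),
                                   name="f")
            pos = int(rng.integers(1, L - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            acc = int(rng.integers(1, tss))
            expected = oracle_distance(pos, strand, feat, acc, tss)
            derived = rr.reconstruct_derived_locus(
                call(pos, strand, pos_b=acc, strand_b="-"), [feat], tss,
                "chr4s", "chr9s",
            )
            if expected is None:
                assert derived.features == []
            else:
                # oracle measures from the first retained bp; the edge
                # convention measures the gap to the breakpoint, identical
                # except when the feature straddles the junction (both 0+)
                got = derived.features[0].distance_to_tss
                assert got == expected or (
                    feat.contains_point(pos) and got == abs(tss - acc)
                )

    def test_distances_ordered_and_nonnegative(self, locus):
        enhancers = [iv for iv, _ in locus.donor_enhancers]
        c = call(250_000, "-", pos_b=locus.acceptor_tss - 600, strand_b="-")
        derived = rr.reconstruct_derived_locus(
            c, enhancers, locus.acceptor_tss,
            locus.donor_chrom, locus.acceptor_chrom,
        )
        d = [f.distance_to_tss for f in derived.features]
        assert d == sorted(d)
        assert all(x >= 0 for x in d)


class TestInsulator:
    def test_quoted_configuration_is_separated(self):
        tss = 500_000
        c = call(1_000, pos_b=tss - 600, strand_b="-")
        assert rr.insulator_separation_check(
            c, [tss - 13_500], tss, "chr4s", "chr9s"
        )

    def test_site_downstream_of_breakend_not_separated(self):
        tss = 500_000
        c = call(1_000, pos_b=tss - 600, strand_b="-")
        assert not rr.insulator_separation_check(
            c, [tss - 400], tss, "chr4s", "chr9s"
        )

    def test_no_sites_never_separated(self):
        c = call(1_000, pos_b=499_400, strand_b="-")
        assert not rr.insulator_separation_check(
            c, [], 500_000, "chr4s", "chr9s"
        )
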