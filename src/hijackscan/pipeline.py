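"""End-to-end demonstration pipeline on synthetic data.

Runs every stage — simulation, coverage, peak/super-enhancer calling,
differential classification, consensus TAD boundaries, motif scanning
and orientation, translocation filtering/classification, derived-locus
reconstruction, quantification and cohort scoring — and returns a flat
summary of the headline numbers. Used by ``hijackscan report`` and the
reproduction script.
"""
from __future__ import annotations

import numpy as np

from . import coverage, motifs, peaks, quantify, rearrangements, synthetic, tads
from .intervals import GenomicInterval


def run_demo(seed: int = 1, chip_depth: int = 60_000) -> dict:
    rng_seed = int(seed)
    locus = synthetic.generate_locus(seed=rng_seed)
    summary: dict[str, float | int | str] = {}

    # --- coverage + peaks ------------------------------------------------
    tag_sets = [
        synthetic.generate_chip_tags(locus, "normal", depth=chip_depth + 13_000,
                                     seed=rng_seed + 10),
        synthetic.generate_chip_tags(locus, "tumor", depth=chip_depth,
                                     seed=rng_seed + 11),
        synthetic.generate_chip_tags(locus, "tumor", depth=chip_depth + 7_000,
                                     seed=rng_seed + 12),
    ]
    tag_sets = coverage.downsample_to_min(tag_sets, seed=rng_seed + 13)
    tracks = [
        coverage.bin_density(
            coverage.extend_tags(t, locus.chrom_lengths), locus.chrom_lengths
        )
        for t in tag_sets
    ]
    normal_track, tumor_tracks = tracks[0], tracks[1:]
    called = peaks.detect_enriched_regions(tumor_tracks[0], fold_threshold=3.0)
    regions = peaks.stitch_regions(called)
    regions = peaks.call_super_enhancers(regions)
    summary["n_peaks"] = len(called)
    summary["n_stitched_regions"] = len(regions)
    summary["n_super_enhancers"] = sum(r.is_super_enhancer for r in regions)

    union = peaks.union_regions(
        [peaks.detect_enriched_regions(t, fold_threshold=3.0) for t in tracks]
    )
    diff = peaks.classify_differential(union, tumor_tracks, normal_track)
    summary["n_union_regions"] = len(union)
    summary["n_up_regions"] = sum(d.label == "up" for d in diff)
    summary["n_down_regions"] = sum(d.label == "down" for d in diff)

    # --- consensus TAD boundaries ---------------------------------------
    bsets, btruth = synthetic.generate_boundary_calls(
        locus, n_samples=29, jitter_sd=5_000, drop_rate=0.1, seed=rng_seed + 20
    )
    counts = tads.bin_boundary_counts(bsets, locus.chrom_lengths)
    consensus = tads.call_consensus_boundaries(counts)
    truth_positions = [
        (c, p) for c, v in btruth.boundary_positions.items() for p in v
    ]
    recovered = sum(
        any(b.chrom == c and abs(b.position - p) <= tads.TAD_BIN_SIZE
            for b in consensus)
        for c, p in truth_positions
    )
    summary["n_consensus_boundaries"] = len(consensus)
    summary["tad_truth_recovered_frac"] = recovered / len(truth_positions)

    # --- motifs ----------------------------------------------------------
    pwm = motifs.build_pwm(motifs.load_builtin_pfm("ctcf"), name="CTCF_synthetic")
    motifs.calibrate_threshold(pwm)
    seqs, struth = synthetic.generate_genome_sequences(locus, seed=rng_seed + 30)
    hits = motifs.scan(seqs[locus.donor_chrom], pwm, chrom=locus.donor_chrom)
    site_peaks = [
        GenomicInterval(locus.donor_chrom, max(0, pos - 250), pos + 250)
        for pos, _ in locus.donor_ctcf_sites
    ]
    oriented = motifs.annotate_ctcf_orientation(site_peaks, hits)
    pairs = motifs.convergent_pairs(oriented)
    summary["n_ctcf_hits_donor"] = len(hits)
    summary["n_convergent_ctcf_pairs"] = len(pairs)

    nbre = motifs.build_pwm(motifs.load_builtin_pfm("nbre"), name="NBRE_synthetic")
    motifs.calibrate_threshold(nbre)
    fg, _ = synthetic.motif_region_set(50, 500, nbre.consensus, 0.8,
                                       seed=rng_seed + 31)
    bg, _ = synthetic.motif_region_set(200, 500, nbre.consensus, 0.05,
                                       seed=rng_seed + 32)
    fg_frac, bg_frac, pval = motifs.motif_enrichment(fg, bg, nbre)
    summary["nbre_fg_fraction"] = fg_frac
    summary["nbre_bg_fraction"] = bg_frac
    summary["nbre_enrichment_p"] = pval

    # --- rearrangements --------------------------------------------------
    cohort = [1] * 4 + [2] * 10 + [3]
    calls, ttruth = synthetic.generate_translocations(
        locus, patterns=cohort, n_noise=5, seed=rng_seed + 40
    )
    kept = rearrangements.filter_translocations(calls)
    ann = locus.annotation()
    labels = {c.sample: rearrangements.classify_pattern(c, ann).pattern
              for c in kept}
    correct = sum(
        labels[s] == ttruth.pattern_labels[s] for s in labels
    )
    summary["n_calls_pass_filter"] = len(kept)
    summary["pattern_recovery_frac"] = correct / len(kept)

    pat1 = [c for c in kept if ttruth.pattern_labels[c.sample] == "pattern1"][0]
    derived = rearrangements.reconstruct_derived_locus(
        pat1,
        [iv for iv, _ in locus.donor_enhancers],
        locus.acceptor_tss,
        locus.donor_chrom,
        locus.acceptor_chrom,
    )
    summary["n_hijacked_enhancers"] = len(derived.features)
    if derived.features:
        summary["nearest_enhancer_to_tss_bp"] = derived.features[0].distance_to_tss
    summary["insulator_separated"] = bool(
        rearrangements.insulator_separation_check(
            pat1, [locus.acceptor_ctcf_site], locus.acceptor_tss,
            locus.donor_chrom, locus.acceptor_chrom,
        )
    )

    # --- quantification + cohorts ---------------------------------------
    counts_m, models, fish, qtruth = synthetic.generate_counts_and_fish(
        locus, seed=rng_seed + 50
    )
    expr = quantify.compute_fpkm_tpm(counts_m, models)
    tumor_cols = [c for c in counts_m.columns if c.startswith("T")]
    normal_cols = [c for c in counts_m.columns if c.startswith("N")]
    lfc = quantify.log2_fold_change(expr["tpm"], tumor_cols, normal_cols)
    summary["tpm_included_sum"] = float(
        expr["tpm"].loc[expr["included"]].sum(axis=0).iloc[0]
    )
    summary["oncogene_log2fc"] = float(lfc["NR4A3_s"])

    fish_cases = [
        quantify.FishCase(r.case_id, r.group, r.n_cells, r.n_aberrant)
        for r in fish.itertuples()
    ]
    calls_tbl = fish.assign(
        status=[quantify.score_fish_case(c) for c in fish_cases]
    )
    synth_summary = quantify.cohort_summary(calls_tbl)
    acicc = synth_summary.set_index("group").loc["AciCC"]
    summary["synthetic_fish_positive_pct"] = int(acicc["percent"])

    fish_tbl, ihc_tbl = synthetic.printed_cohort_tables()
    fish_summary = quantify.cohort_summary(fish_tbl).set_index("group")
    ihc_summary = quantify.cohort_summary(ihc_tbl).set_index("group")
    summary["fish_positive_pct"] = int(fish_summary.loc["AciCC", "percent"])
    summary["fish_other_positive_pct"] = int(fish_summary.loc["other", "percent"])
    summary["ihc_positive_pct"] = int(ihc_summary.loc["AciCC", "percent"])
    return summary
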