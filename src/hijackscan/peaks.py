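"""Peak handling: enrichment detection, blacklist filtering, ROSE-style
super-enhancer stitching and ranking, union regions, and differential
log2-density classification of tumor versus normal tracks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .coverage import DensityTrack
from .intervals import GenomicInterval, sort_key

STITCH_GAP = 12_500
SUPER_ENHANCER_TOP_FRAC = 0.05
DIFFERENTIAL_LFC = 2.0
DIFFERENTIAL_EPS = 0.25


@dataclass
class Peak:
    interval: GenomicInterval
    signal: float
    summit: int | None = None
    source_sample: str | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("peak signal must be non-negative")
        if self.summit is not None and not self.interval.contains_point(self.summit):
            raise ValueError("summit outside peak interval")


@dataclass
class MergedRegion:
    interval: GenomicInterval
    constituents: list[Peak]
    signal: float
    is_super_enhancer: bool = False
    rank: int | None = None


@dataclass
class DifferentialRegion:
    interval: GenomicInterval
    tumor_means: list[float]
    normal_mean: float
    log2_ratio: float
    label: str  # up | down | neutral


def detect_enriched_regions(
    track: DensityTrack, fold_threshold: float = 4.0, min_bins: int = 2
) -> list[Peak]:
    """Simple enrichment detector over a binned density track.

    Calls maximal runs of at least ``min_bins`` consecutive bins whose
    count reaches ``fold_threshold`` times the genome-wide median of
    nonzero bins. Peak signal is the mean bin count over the run and the
    summit is the center of the (first) maximal bin. This deliberately
    simple detector closes the synthetic-data loop; it makes no claim to
    model-based peak calling.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if min_bins < 1:
        raise ValueError("min_bins must be >= 1")
    nonzero = np.concatenate(
        [arr[arr > 0] for arr in track.data.values()]
        or [np.empty(0)]
    )
    if nonzero.size == 0:
        return []
    threshold = fold_threshold * float(np.median(nonzero))
    bs = track.bin_size
    peaks: list[Peak] = []
    for chrom, arr in track.data.items():
        mask = arr >= threshold
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for s, e in zip(edges[::2], edges[1::2]):  # runs [s, e) in bins
            if e - s < min_bins:
                continue
            run = arr[s:e]
            peak_max = int(s + np.argmax(run))
            start = int(s * bs)
            end = int(min(e * bs, track.chrom_lengths[chrom]))
            summit = min(peak_max * bs + bs // 2, end - 1)
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    signal=float(run.mean()),
                    summit=summit,
                )
            )
    return peaks


def filter_blacklist(
    peaks: list[Peak], blacklist: list[GenomicInterval]
) -> list[Peak]:
    """Drop peaks overlapping any blacklisted interval by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return [
        p
        for p in peaks
        if not trees.get(p.interval.chrom, IntervalTree()).overlap(
            p.interval.start, p.interval.end
        )
    ]


def stitch_regions(peaks: list[Peak], gap: int = STITCH_GAP) -> list[MergedRegion]:
    """Single-linkage stitching of peaks within ``gap`` bp of each other.

    The inter-peak distance is the gap between the end of one interval and
    the start of the next (end-exclusive); a distance equal to ``gap``
    still merges. The merged interval is the hull of its constituents and
    its aggregate signal is the length-weighted sum of constituent signals.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    regions: list[MergedRegion] = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: sort_key(p.interval))
        cluster: list[Peak] = []
        cluster_end = None
        for p in chrom_peaks:
            if cluster and p.interval.start - cluster_end > gap:
                regions.append(_close_cluster(cluster))
                cluster = []
                cluster_end = None
            cluster.append(p)
            cluster_end = max(cluster_end or 0, p.interval.end)
        if cluster:
            regions.append(_close_cluster(cluster))
    return regions


def _close_cluster(cluster: list[Peak]) -> MergedRegion:
    start = min(p.interval.start for p in cluster)
    end = max(p.interval.end for p in cluster)
    signal = sum(p.signal * p.interval.length for p in cluster)
    return MergedRegion(
        interval=GenomicInterval(cluster[0].interval.chrom, start, end),
        constituents=list(cluster),
        signal=signal,
    )


def call_super_enhancers(
    regions: list[MergedRegion], top_frac: float = SUPER_ENHANCER_TOP_FRAC
) -> list[MergedRegion]:
    """Rank merged regions by aggregate signal and flag the top fraction.

    Exactly ``max(1, floor(top_frac * N))`` regions are flagged as super
    enhancers; ties are broken by (signal desc, chrom, start asc). Ranks
    are 1-based, 1 = strongest. Returns the input regions (mutated in
    place) in their original order.
    """
    if not regions:
        return []
    order = sorted(
        range(len(regions)),
        key=lambda i: (
            -regions[i].signal,
            regions[i].interval.chrom,
            regions[i].interval.start,
        ),
    )
    n_flag = max(1, math.floor(top_frac * len(regions)))
    for rank, i in enumerate(order, start=1):
        regions[i].rank = rank
        regions[i].is_super_enhancer = rank <= n_flag
    return regions


def union_regions(
    peak_sets: list[list[Peak]],
) -> list[GenomicInterval]:
    """Minimal set of disjoint intervals covering every peak in any sample.

    Overlapping and directly adjacent (0-gap) inputs are merged. These
    "extended regions" are the comparison units for differential density.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    ivs = sorted(
        (p.interval for peaks in peak_sets for p in peaks), key=sort_key
    )
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def classify_differential(
    regions: list[GenomicInterval],
    tumor_tracks: list[DensityTrack],
    normal_track: DensityTrack,
    lfc: float = DIFFERENTIAL_LFC,
    eps: float = DIFFERENTIAL_EPS,
) -> list[DifferentialRegion]:
    """Classify regions by log2 fold change of average fragment density.

    For each region the average bin density is computed per sample; the
    tumor statistic is the arithmetic mean over tumor samples; the ratio
    is ``log2((tumor + eps) / (normal + eps))``. Regions with ratio
    ``>= lfc`` are "up" (in tumors), ``<= -lfc`` are "down", the rest are
    "neutral". Tracks must share binning and be depth-normalized.
    """
    out: list[DifferentialRegion] = []
    for region in regions:
        tumor_means = [
            t.region_mean(region.chrom, region.start, region.end)
            for t in tumor_tracks
        ]
        normal_mean = normal_track.region_mean(
            region.chrom, region.start, region.end
        )
        t = float(np.mean(tumor_means))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = float(np.log2(t + eps) - np.log2(normal_mean + eps))
        if not math.isnan(ratio) and ratio >= lfc:
            label = "up"
        elif not math.isnan(ratio) and ratio <= -lfc:
            label = "down"
        else:
            label = "neutral"
        out.append(
            DifferentialRegion(
                interval=region,
                tumor_means=tumor_means,
                normal_mean=normal_mean,
                log2_ratio=ratio,
                label=label,
            )
        )
    return out
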