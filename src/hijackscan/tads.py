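"""Consensus TAD-boundary calling from multiple per-sample boundary sets.

The genome is segmented into fixed 40-kb bins and, for each bin, the
number of samples having at least one boundary in that bin or one of its
direct neighbors is counted (each sample contributes at most once per
bin). Bins whose count strictly exceeds a threshold (default 2) seed a
boundary region which is extended bin by bin while the criterion holds;
the consensus boundary position is the region start plus half the region
length. The neighbor window is applied once, in the counting step.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import n_bins

TAD_BIN_SIZE = 40_000
MIN_EXCEED = 2


@dataclass
class BoundarySet:
    """Per-sample TAD boundary positions (bp), per chromosome."""

    sample: str
    positions: dict[str, list[int]]


@dataclass
class ConsensusBoundary:
    chrom: str
    start: int  # boundary region start (bp)
    end: int  # boundary region end (bp, exclusive)
    position: int  # start + (end - start) // 2

    def __post_init__(self) -> None:
        if self.position != self.start + (self.end - self.start) // 2:
            raise ValueError("position must be the region midpoint")


def bin_boundary_counts(
    sets: list[BoundarySet],
    chrom_lengths: dict[str, int],
    bin_size: int = TAD_BIN_SIZE,
) -> dict[str, np.ndarray]:
    """Per-bin count of samples with a boundary in the bin or its neighbors."""
    if not sets:
        raise ValueError("need at least one boundary set")
    counts = {
        c: np.zeros(n_bins(L, bin_size), dtype=int)
        for c, L in chrom_lengths.items()
    }
    for bset in sets:
        for chrom, positions in bset.positions.items():
            if chrom not in counts:
                raise ValueError(f"boundary on unknown chromosome {chrom!r}")
            nb = len(counts[chrom])
            present = np.zeros(nb, dtype=bool)
            pos = np.asarray(positions, dtype=np.int64)
            if pos.size:
                if (pos < 0).any() or (pos >= chrom_lengths[chrom]).any():
                    raise ValueError(f"boundary position outside {chrom}")
                present[pos // bin_size] = True
            # sample counts once per bin if any of {b-1, b, b+1} has a boundary
            smeared = present.copy()
            smeared[:-1] |= present[1:]
            smeared[1:] |= present[:-1]
            counts[chrom] += smeared
    return counts


def call_consensus_boundaries(
    counts: dict[str, np.ndarray],
    min_exceed: int = MIN_EXCEED,
    bin_size: int = TAD_BIN_SIZE,
) -> list[ConsensusBoundary]:
    """Maximal runs of bins with count strictly above ``min_exceed``.

    Scanning left to right, a qualifying bin opens a boundary region of
    that bin's extent, the region is extended by each subsequent
    qualifying bin, and closed when the criterion fails; the boundary
    position is the region midpoint (floor for odd lengths). "Exceeded"
    is strict: a count equal to ``min_exceed`` does not qualify.
    """
    out: list[ConsensusBoundary] = []
    for chrom in counts:
        mask = counts[chrom] > min_exceed
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for s, e in zip(edges[::2], edges[1::2]):
            start = int(s * bin_size)
            end = int(e * bin_size)
            out.append(
                ConsensusBoundary(
                    chrom=chrom,
                    start=start,
                    end=end,
                    position=start + (end - start) // 2,
                )
            )
    return out
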