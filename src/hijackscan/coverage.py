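"""Fragment-density tracks from aligned ChIP tags.

The 5'-ends of aligned reads ("tags") mark the ends of immunoprecipitated
fragments; tags are therefore extended in silico at their 3'-ends to the
library's average fragment length (default 200 bp, typical size-selected
range 150-250 bp), the genome is divided into fixed-width bins (default
32 bp), and each bin counts the fragments overlapping it. Tracks are
stored in bedGraph files. Multi-sample normalization is performed by
down-sampling every sample to the tag count of the smallest one.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TAG_COLUMNS = ["chrom", "pos", "strand"]
FRAGMENT_COLUMNS = ["chrom", "start", "end"]

DEFAULT_FRAGMENT_LENGTH = 200
DEFAULT_BIN_SIZE = 32


def n_bins(chrom_length: int, bin_size: int) -> int:
    return -(-chrom_length // bin_size)  # ceil division


@dataclass
class DensityTrack:
    """Per-chromosome fixed-width bin counts of extended fragments."""

    data: dict[str, np.ndarray]
    bin_size: int
    chrom_lengths: dict[str, int]
    total_fragments: int = 0

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            expected = n_bins(self.chrom_lengths[chrom], self.bin_size)
            if len(arr) != expected:
                raise ValueError(
                    f"{chrom}: track has {len(arr)} bins, expected {expected}"
                )

    @classmethod
    def zeros(
        cls, chrom_lengths: dict[str, int], bin_size: int = DEFAULT_BIN_SIZE
    ) -> "DensityTrack":
        data = {
            c: np.zeros(n_bins(L, bin_size), dtype=float)
            for c, L in chrom_lengths.items()
        }
        return cls(data=data, bin_size=bin_size, chrom_lengths=dict(chrom_lengths))

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Average bin count over the bins overlapping ``[start, end)``."""
        if chrom not in self.data:
            raise ValueError(f"region chromosome {chrom!r} not in track")
        if start < 0 or end > self.chrom_lengths[chrom] or end <= start:
            raise ValueError(
                f"region [{start}, {end}) outside track for {chrom}"
            )
        b0 = start // self.bin_size
        b1 = (end - 1) // self.bin_size
        return float(self.data[chrom][b0 : b1 + 1].mean())


def _validate_tags(tags: pd.DataFrame) -> None:
    missing = [c for c in TAG_COLUMNS if c not in tags.columns]
    if missing:
        raise ValueError(f"tag table missing columns {missing}")
    bad = set(tags["strand"].unique()) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand symbol(s) {sorted(bad)}")


def extend_tags(
    tags: pd.DataFrame,
    chrom_lengths: dict[str, int],
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
) -> pd.DataFrame:
    """Extend tag 5'-positions into fragment intervals of ``fragment_length``.

    A ``+`` tag at ``p`` becomes ``[p, p+L)``. A ``-`` tag's coordinate is
    its 5' end, i.e. the *rightmost* aligned base, so it becomes
    ``[p+1-L, p+1)``. Fragments are clipped to chromosome bounds.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be positive")
    if not 150 <= fragment_length <= 250:
        warnings.warn(
            f"fragment_length {fragment_length} outside the typical "
            "size-selected range 150-250 bp",
            stacklevel=2,
        )
    _validate_tags(tags)
    pos = tags["pos"].to_numpy(dtype=np.int64)
    fwd = (tags["strand"] == "+").to_numpy()
    start = np.where(fwd, pos, pos + 1 - fragment_length)
    end = np.where(fwd, pos + fragment_length, pos + 1)
    lengths = tags["chrom"].map(chrom_lengths)
    if lengths.isna().any():
        unknown = sorted(set(tags.loc[lengths.isna(), "chrom"]))
        raise ValueError(f"unknown chromosome(s) {unknown}")
    lim = lengths.to_numpy(dtype=np.int64)
    frags = pd.DataFrame(
        {
            "chrom": tags["chrom"].to_numpy(),
            "start": np.clip(start, 0, lim),
            "end": np.clip(end, 0, lim),
        }
    )
    return frags[frags["end"] > frags["start"]].reset_index(drop=True)


def bin_density(
    fragments: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> DensityTrack:
    """Count, per fixed-width bin, the fragments overlapping it.

    A fragment increments every bin it overlaps, so a 200-bp fragment
    spans seven or eight 32-bp bins.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    track = DensityTrack.zeros(chrom_lengths, bin_size)
    track.total_fragments = len(fragments)
    for chrom, grp in fragments.groupby("chrom", sort=False):
        if chrom not in chrom_lengths:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        start = grp["start"].to_numpy(dtype=np.int64)
        end = grp["end"].to_numpy(dtype=np.int64)
        if (start < 0).any() or (end > chrom_lengths[chrom]).any():
            raise ValueError(f"fragment outside bounds of {chrom}")
        b0 = start // bin_size
        b1 = (end - 1) // bin_size
        nb = len(track.data[chrom])
        diff = np.zeros(nb + 1, dtype=float)
        np.add.at(diff, b0, 1.0)
        np.add.at(diff, b1 + 1, -1.0)
        track.data[chrom] = np.cumsum(diff[:-1])
    return track


def downsample_to_min(
    samples: list[pd.DataFrame], seed: int
) -> list[pd.DataFrame]:
    """Down-sample every tag table to the smallest sample's tag count.

    Subsets are drawn uniformly without replacement; the minimum sample is
    returned unchanged. Deterministic under ``seed``.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to normalize")
    counts = [len(s) for s in samples]
    if min(counts) == 0:
        raise ValueError("cannot normalize against an empty sample")
    m = min(counts)
    rng = np.random.default_rng(seed)
    out = []
    for s, n in zip(samples, counts):
        if n == m:
            out.append(s.reset_index(drop=True))
        else:
            idx = np.sort(rng.choice(n, size=m, replace=False))
            out.append(s.iloc[idx].reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# bedGraph IO
#
# The on-disk dialect is standard 4-column bedGraph (0-based, half-open)
# preceded by comment headers carrying the bin size, total fragment count
# and chromosome lengths so that a track round-trips exactly. Zero bins
# are omitted; with merge_runs=True adjacent equal-value bins are
# run-length merged into one line.
# ---------------------------------------------------------------------------


def write_bedgraph(
    track: DensityTrack, path: str, merge_runs: bool = False, name: str = "density"
) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        fh.write(f"# bin_size={track.bin_size}\n")
        fh.write(f"# total_fragments={track.total_fragments}\n")
        for chrom, L in track.chrom_lengths.items():
            fh.write(f"# chrom_length {chrom} {L}\n")
        for chrom, arr in track.data.items():
            L = track.chrom_lengths[chrom]
            bs = track.bin_size
            if merge_runs:
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(
                            f"{chrom}\t{s * bs}\t{min(e * bs, L)}\t{_fmt(v)}\n"
                        )
            else:
                for b in np.flatnonzero(arr):
                    fh.write(
                        f"{chrom}\t{b * bs}\t{min((b + 1) * bs, L)}\t{_fmt(arr[b])}\n"
                    )


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_bedgraph(path: str) -> DensityTrack:
    bin_size = None
    total = 0
    chrom_lengths: dict[str, int] = {}
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("track"):
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("bin_size="):
                    bin_size = int(body.split("=", 1)[1])
                elif body.startswith("total_fragments="):
                    total = int(body.split("=", 1)[1])
                elif body.startswith("chrom_length"):
                    _, chrom, L = body.split()
                    chrom_lengths[chrom] = int(L)
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"malformed bedGraph line {lineno}: {line!r}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ValueError(
                    f"malformed bedGraph line {lineno}: {line!r}"
                ) from exc
    if bin_size is None or not chrom_lengths:
        raise ValueError("bedGraph lacks bin_size/chrom_length headers")
    track = DensityTrack.zeros(chrom_lengths, bin_size)
    track.total_fragments = total
    for chrom, start, end, value in rows:
        if chrom not in track.data:
            raise ValueError(f"bedGraph interval on unknown chromosome {chrom!r}")
        b0 = start // bin_size
        b1 = (end - 1) // bin_size
        track.data[chrom][b0 : b1 + 1] = value
    return track
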