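"""Plain-text readers and writers for the pipeline's tables.

All files are TSV/BED with ``#`` comment headers; every coordinate is
0-based (half-open for intervals), and SV tables state the breakend
strand convention in their header.
"""
from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .rearrangements import Breakend, TranslocationCall
from .tads import BoundarySet

SV_COLUMNS = [
    "chromA", "posA", "strandA", "chromB", "posB", "strandB",
    "quality", "support",
]


def _read_tsv(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def write_tags_tsv(tags: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# ChIP tag table: chrom, 5' position (0-based), strand\n")
        tags.to_csv(fh, sep="\t", index=False)


def read_tags_tsv(path: str) -> pd.DataFrame:
    return _read_tsv(path, dtype={"chrom": str, "pos": int, "strand": str})


def write_bed(intervals: list[GenomicInterval], path: str,
              extra: dict[str, list] | None = None) -> None:
    """BED with optional name column and extra columns appended in order."""
    with open(path, "w") as fh:
        fh.write("# BED, 0-based half-open\n")
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name or "."]
            if extra:
                fields += [str(v[i]) for v in extra.values()]
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                       name=name))
    return out


def write_boundary_bed(bset: BoundarySet, path: str) -> None:
    """One 1-bp interval line per boundary position."""
    ivs = [
        GenomicInterval(chrom, pos, pos + 1)
        for chrom, positions in sorted(bset.positions.items())
        for pos in positions
    ]
    write_bed(ivs, path)


def read_boundary_bed(path: str, sample: str) -> BoundarySet:
    positions: dict[str, list[int]] = {}
    for iv in read_bed(path):
        positions.setdefault(iv.chrom, []).append(iv.start)
    return BoundarySet(sample=sample,
                       positions={c: sorted(v) for c, v in positions.items()})


def write_sv_tsv(calls: list[TranslocationCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# translocation calls; positions 0-based\n")
        fh.write("# breakend strand: + = segment left of pos retained, "
                 "- = segment right of pos retained\n")
        fh.write("sample\t" + "\t".join(SV_COLUMNS) + "\n")
        for c in calls:
            fh.write("\t".join(str(x) for x in (
                c.sample, c.a.chrom, c.a.pos, c.a.strand,
                c.b.chrom, c.b.pos, c.b.strand, c.quality, c.support,
            )) + "\n")


def read_sv_tsv(path: str) -> list[TranslocationCall]:
    df = _read_tsv(path)
    return [
        TranslocationCall(
            sample=str(r["sample"]),
            a=Breakend(str(r["chromA"]), int(r["posA"]), str(r["strandA"])),
            b=Breakend(str(r["chromB"]), int(r["posB"]), str(r["strandB"])),
            quality=float(r["quality"]),
            support=int(r["support"]),
        )
        for _, r in df.iterrows()
    ]


def write_counts_tsv(counts: pd.DataFrame, models: pd.DataFrame,
                     path: str) -> None:
    """Counts with gene metadata columns (chrom, length, biotype) prepended."""
    merged = models[["chrom", "length", "biotype"]].join(counts)
    merged.index.name = "gene_id"
    with open(path, "w") as fh:
        fh.write("# read counts; metadata columns: chrom, length, biotype\n")
        merged.to_csv(fh, sep="\t")


def read_counts_tsv(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = _read_tsv(path, index_col="gene_id")
    meta = df[["chrom", "length", "biotype"]]
    counts = df.drop(columns=["chrom", "length", "biotype"])
    return counts, meta


def write_gene_models_tsv(models: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# GTF-lite gene models; tss 0-based\n")
        models.to_csv(fh, sep="\t")


def read_gene_models_tsv(path: str) -> pd.DataFrame:
    return _read_tsv(path, index_col="gene_id")


def write_fish_tsv(fish: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# FISH tallies: case_id, group, n_cells, n_aberrant\n")
        fish.to_csv(fh, sep="\t", index=False)


def read_fish_tsv(path: str) -> pd.DataFrame:
    return _read_tsv(path)


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
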