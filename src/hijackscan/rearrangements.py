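"""Translocation filtering, breakpoint-pattern classification, and
derived-chromosome reconstruction.

Breakend convention: strand ``+`` means the segment to the LEFT of the
breakend position is retained on the derived chromosome, ``-`` means the
segment to the RIGHT is retained. SV tables written by this package state
the convention in their header.

Donor breakends are classified into three recurrent patterns:

* pattern 1 — the breakend falls between a convergent (forward, reverse)
  CTCF site pair at a sub-TAD border;
* pattern 2 — the breakend falls within the span of the three most highly
  expressed salivary-gland genes of the donor cluster;
* pattern 3 — the breakend falls directly within the first intron of the
  FDCSP-like donor gene.

Precedence is 3 > 1 > 2 (most specific containment wins); anything else
is "other". Only the donor-side breakend is classified; proximity of the
acceptor breakend to the target TSS (within 600 bp upstream) is reported
as a separate flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval

MIN_QUALITY = 255
MIN_SUPPORT = 15
TSS_UPSTREAM_WINDOW = 600


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    strand: str  # '+': left of pos retained; '-': right of pos retained

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid breakend strand {self.strand!r}")

    def retains(self, pos: int) -> bool:
        """Whether coordinate ``pos`` lies on the retained segment."""
        return pos < self.pos if self.strand == "+" else pos >= self.pos


@dataclass
class TranslocationCall:
    sample: str
    a: Breakend  # donor-side breakend by convention of the SV table
    b: Breakend  # acceptor-side breakend
    quality: float
    support: int

    def __post_init__(self) -> None:
        if self.support < 0:
            raise ValueError("support must be non-negative")


@dataclass
class PatternCall:
    call: TranslocationCall
    pattern: str  # pattern1 | pattern2 | pattern3 | other
    evidence: str | None
    acceptor_near_tss: bool


@dataclass
class LocusAnnotation:
    """Donor/acceptor annotation needed for pattern classification."""

    donor_chrom: str
    ctcf_pair_window: GenomicInterval | None
    triple_gene_span: GenomicInterval | None
    intragenic_intervals: list[GenomicInterval] | None  # e.g. FDCSP-like intron 1
    acceptor_chrom: str
    tss: int
    upstream_window: int = TSS_UPSTREAM_WINDOW


def filter_translocations(
    calls: list[TranslocationCall],
    min_quality: float = MIN_QUALITY,
    min_support: int = MIN_SUPPORT,
) -> list[TranslocationCall]:
    """Keep calls with quality >= min_quality AND support >= min_support."""
    return [
        c for c in calls if c.quality >= min_quality and c.support >= min_support
    ]


def _donor_acceptor(
    call: TranslocationCall, donor_chrom: str, acceptor_chrom: str
) -> tuple[Breakend, Breakend]:
    ends = {call.a.chrom: call.a, call.b.chrom: call.b}
    if donor_chrom not in ends or acceptor_chrom not in ends:
        raise ValueError(
            f"call {call.sample} does not connect {donor_chrom} and {acceptor_chrom}"
        )
    return ends[donor_chrom], ends[acceptor_chrom]


def classify_pattern(
    call: TranslocationCall, annotation: LocusAnnotation
) -> PatternCall:
    """Assign the donor breakend to one of the three recurrent patterns."""
    for attr in ("ctcf_pair_window", "triple_gene_span", "intragenic_intervals"):
        if getattr(annotation, attr) is None:
            raise ValueError(f"missing annotation: {attr}")
    donor, acceptor = _donor_acceptor(
        call, annotation.donor_chrom, annotation.acceptor_chrom
    )
    pattern, evidence = "other", None
    for iv in annotation.intragenic_intervals:
        if iv.contains_point(donor.pos):
            pattern, evidence = "pattern3", iv.name or "intragenic"
            break
    if pattern == "other" and annotation.ctcf_pair_window.contains_point(donor.pos):
        pattern, evidence = "pattern1", annotation.ctcf_pair_window.name or "ctcf_pair"
    if pattern == "other" and annotation.triple_gene_span.contains_point(donor.pos):
        pattern, evidence = "pattern2", annotation.triple_gene_span.name or "triple_gene"
    near = 0 < annotation.tss - acceptor.pos <= annotation.upstream_window
    return PatternCall(
        call=call, pattern=pattern, evidence=evidence, acceptor_near_tss=near
    )


@dataclass
class DerivedFeature:
    name: str | None
    interval: GenomicInterval  # original donor coordinates
    distance_to_tss: int  # bp along the derived chromosome, upstream positive


@dataclass
class DerivedLocus:
    """Donor features ordered by distance to the acceptor TSS on the
    derived chromosome (junction-to-TSS offset included in distances)."""

    junction_to_tss: int
    features: list[DerivedFeature]


def reconstruct_derived_locus(
    call: TranslocationCall,
    donor_features: list[GenomicInterval],
    acceptor_tss: int,
    donor_chrom: str,
    acceptor_chrom: str,
) -> DerivedLocus:
    """Model the derived chromosome and each retained donor feature's
    distance to the acceptor TSS.

    The acceptor breakend must retain the segment containing the TSS;
    otherwise the fusion cannot regulate the target and an error is
    raised. A donor feature is retained if any part of it lies on the
    retained donor side; its distance is measured from the breakpoint to
    the feature edge nearest the junction (clipped to 0 for features
    straddling the breakpoint), plus the junction-to-TSS offset.
    """
    donor, acceptor = _donor_acceptor(call, donor_chrom, acceptor_chrom)
    if not acceptor.retains(acceptor_tss):
        raise ValueError("TSS not on derived chromosome")
    junction_to_tss = abs(acceptor_tss - acceptor.pos)
    feats: list[DerivedFeature] = []
    for iv in donor_features:
        if iv.chrom != donor_chrom:
            continue
        if donor.strand == "+":
            if iv.start >= donor.pos:
                continue  # entirely on the lost (right) side
            edge_dist = donor.pos - min(iv.end, donor.pos)
        else:
            if iv.end <= donor.pos:
                continue  # entirely on the lost (left) side
            edge_dist = max(iv.start, donor.pos) - donor.pos
        feats.append(
            DerivedFeature(
                name=iv.name,
                interval=iv,
                distance_to_tss=junction_to_tss + edge_dist,
            )
        )
    feats.sort(key=lambda f: (f.distance_to_tss, f.name or ""))
    return DerivedLocus(junction_to_tss=junction_to_tss, features=feats)


def insulator_separation_check(
    call: TranslocationCall,
    acceptor_ctcf_sites: list[int],
    tss: int,
    donor_chrom: str | None = None,
    acceptor_chrom: str | None = None,
) -> bool:
    """True iff the junction separates an upstream CTCF site from the TSS.

    The acceptor-side breakend separates insulator and promoter when a
    CTCF site lies upstream (left) of the breakend while the TSS lies
    downstream (right) — i.e. site and TSS end up on opposite sides of
    the junction.
    """
    if acceptor_chrom is not None and donor_chrom is not None:
        _, acceptor = _donor_acceptor(call, donor_chrom, acceptor_chrom)
    else:
        acceptor = call.b
    if tss <= acceptor.pos:
        return False
    return any(site < acceptor.pos for site in acceptor_ctcf_sites)
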