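"""Synthetic inputs with planted ground truth for every pipeline stage.

The generated world emulates an enhancer-hijacking configuration on two
synthetic chromosomes (named ``chr4s``/``chr9s`` to avoid confusion with
real genome builds):

* a donor locus carrying a salivary-gland-like gene cluster with
  clustered high-signal enhancer intervals, a convergent (forward,
  reverse) CTCF site pair at a sub-TAD border, a triple-gene span of the
  three most highly expressed cluster genes, and an FDCSP-like gene whose
  first intron hosts the rarest breakpoint pattern;
* an acceptor locus with a proto-oncogene-like TSS and a CTCF site
  13.5 kb upstream of it.

Noise models are the simplest matching the assumed statistical structure:
Poisson-uniform background for ChIP tags, negative binomial for read
counts, binomial for FISH cell tallies. Every generator is deterministic
under its seed and returns its planted truth alongside the data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval
from .motifs import build_pwm, load_builtin_pfm, reverse_complement
from .rearrangements import Breakend, LocusAnnotation, TranslocationCall

DONOR_CHROM = "chr4s"
ACCEPTOR_CHROM = "chr9s"
DEFAULT_CHROM_LENGTH = 1_000_000

BACKGROUND_PROBS = {"A": 0.30, "C": 0.20, "G": 0.20, "T": 0.30}


@dataclass
class SimulationConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            DONOR_CHROM: DEFAULT_CHROM_LENGTH,
            ACCEPTOR_CHROM: DEFAULT_CHROM_LENGTH,
        }
    )
    n_enhancers: int = 5
    enhancer_length: int = 2_000
    enhancer_fold_range: tuple[float, float] = (6.0, 15.0)
    n_extra_ctcf: int = 2  # beyond the fixed convergent pair


@dataclass
class Gene:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[GenomicInterval]

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start,
                                       name=f"{self.name}_intron{len(out) + 1}"))
        return out

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.name)


@dataclass
class LocusModel:
    donor_chrom: str
    acceptor_chrom: str
    chrom_lengths: dict[str, int]
    donor_enhancers: list[tuple[GenomicInterval, float]]
    donor_ctcf_sites: list[tuple[int, str]]  # (position, 'forward'|'reverse')
    donor_genes: list[Gene]
    acceptor_tss: int
    acceptor_ctcf_site: int
    acceptor_gene: Gene
    tumor_regions: list[tuple[GenomicInterval, float]]
    tad_boundaries: dict[str, list[int]]

    # --- named landmarks -------------------------------------------------
    @property
    def ctcf_pair_window(self) -> GenomicInterval:
        """Window between the convergent forward/reverse CTCF pair."""
        fwd = [p for p, o in self.donor_ctcf_sites if o == "forward"]
        rev = [p for p, o in self.donor_ctcf_sites if o == "reverse"]
        left = max(p for p in fwd if any(r > p for r in rev))
        right = min(r for r in rev if r > left)
        return GenomicInterval(self.donor_chrom, left, right, name="ctcf_pair")

    @property
    def triple_gene_span(self) -> GenomicInterval:
        genes = [g for g in self.donor_genes if g.name.startswith(("STATH", "HTN"))]
        return GenomicInterval(
            self.donor_chrom,
            min(g.start for g in genes),
            max(g.end for g in genes),
            name="triple_gene_span",
        )

    @property
    def fdcsp_intron1(self) -> GenomicInterval:
        (gene,) = [g for g in self.donor_genes if g.name.startswith("FDCSP")]
        return gene.introns[0]

    def annotation(self) -> LocusAnnotation:
        return LocusAnnotation(
            donor_chrom=self.donor_chrom,
            ctcf_pair_window=self.ctcf_pair_window,
            triple_gene_span=self.triple_gene_span,
            intragenic_intervals=[self.fdcsp_intron1],
            acceptor_chrom=self.acceptor_chrom,
            tss=self.acceptor_tss,
        )

    def validate(self) -> None:
        for iv, fold in self.donor_enhancers + self.tumor_regions:
            L = self.chrom_lengths[iv.chrom]
            if iv.start < 0 or iv.end > L:
                raise ValueError(
                    f"interval {iv.name or ''} [{iv.start}, {iv.end}) exceeds "
                    f"{iv.chrom} length {L}"
                )
            if fold <= 1:
                raise ValueError("enhancer intensity folds must exceed 1")
        for pos, _ in self.donor_ctcf_sites:
            if not 0 <= pos < self.chrom_lengths[self.donor_chrom]:
                raise ValueError(f"CTCF site {pos} outside donor chromosome")
        if self.triple_gene_span.overlaps(self.ctcf_pair_window):
            raise ValueError("triple-gene span overlaps the CTCF-pair window")


@dataclass
class PlantedTruth:
    pattern_labels: dict[str, str] = field(default_factory=dict)
    boundary_positions: dict[str, list[int]] = field(default_factory=dict)
    enriched_regions: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    motif_sites: list[tuple[str, int, str]] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)
    fish_status: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# locus
# ---------------------------------------------------------------------------

def _make_gene(name: str, chrom: str, start: int, spans: list[tuple[int, int]],
               strand: str = "+") -> Gene:
    exons = [GenomicInterval(chrom, start + a, start + b) for a, b in spans]
    return Gene(name=name, chrom=chrom, start=exons[0].start,
                end=exons[-1].end, strand=strand, exons=exons)


def generate_locus(
    config: SimulationConfig | None = None, seed: int = 0
) -> LocusModel:
    """Build the donor/acceptor locus model; deterministic under seed.

    Landmark positions are fixed fractions of the donor chromosome;
    enhancer placement and intensities, and extra CTCF sites, are drawn
    from the seeded generator.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    D = config.chrom_lengths.get(DONOR_CHROM)
    A = config.chrom_lengths.get(ACCEPTOR_CHROM)
    if D is None or A is None:
        raise ValueError(
            f"chrom_lengths must define {DONOR_CHROM} and {ACCEPTOR_CHROM}"
        )
    if D < 800_000 or A < 800_000:
        raise ValueError("chromosomes shorter than 800 kb cannot hold the locus")
    donor_genes = [
        _make_gene("STATH_s", DONOR_CHROM, 305_000,
                   [(0, 2_000), (26_000, 30_000)]),
        _make_gene("HTN3_s", DONOR_CHROM, 345_000,
                   [(0, 2_000), (26_000, 30_000)]),
        _make_gene("HTN1_s", DONOR_CHROM, 385_000,
                   [(0, 2_000), (26_000, 30_000)]),
        _make_gene("FDCSP_s", DONOR_CHROM, 500_000,
                   [(0, 2_000), (10_000, 12_000), (18_000, 20_000)]),
    ]
    ctcf = [(200_000, "forward"), (260_000, "reverse")]
    for _ in range(config.n_extra_ctcf):
        pos = int(rng.integers(600_000, D - 1_000))
        ctcf.append((pos, str(rng.choice(["forward", "reverse"]))))
    ctcf.sort()
    # enhancers: seeded, non-overlapping, inside the active donor region
    lo, hi = 150_000, 550_000
    eL = config.enhancer_length
    n = config.n_enhancers
    if n < 1:
        raise ValueError("need at least one enhancer")
    if n * (eL + 5_000) > hi - lo:
        raise ValueError("enhancer configuration exceeds the active region")
    anchors = np.sort(rng.choice((hi - lo - eL) // 5_000, size=n, replace=False))
    enhancers = []
    for k, a in enumerate(anchors):
        start = lo + int(a) * 5_000
        fold = float(rng.uniform(*config.enhancer_fold_range))
        enhancers.append(
            (GenomicInterval(DONOR_CHROM, start, start + eL, name=f"E{k + 1}"),
             fold)
        )
    acceptor_tss = 500_000
    acceptor_gene = _make_gene("NR4A3_s", ACCEPTOR_CHROM, acceptor_tss,
                               [(0, 2_000), (30_000, 40_000)])
    tumor_regions = [
        (GenomicInterval(ACCEPTOR_CHROM, acceptor_tss - 1_200,
                         acceptor_tss - 200, name="acceptor_upstream_peak"), 8.0),
        (GenomicInterval(DONOR_CHROM, 330_000, 331_500,
                         name="nbre_peak_1"), 6.0),
    ]
    model = LocusModel(
        donor_chrom=DONOR_CHROM,
        acceptor_chrom=ACCEPTOR_CHROM,
        chrom_lengths=dict(config.chrom_lengths),
        donor_enhancers=enhancers,
        donor_ctcf_sites=ctcf,
        donor_genes=donor_genes,
        acceptor_tss=acceptor_tss,
        acceptor_ctcf_site=acceptor_tss - 13_500,
        acceptor_gene=acceptor_gene,
        tumor_regions=tumor_regions,
        tad_boundaries={
            DONOR_CHROM: [200_000, 260_000, 440_000, 720_000],
            ACCEPTOR_CHROM: [240_000, 480_000, 760_000],
        },
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# ChIP tags
# ---------------------------------------------------------------------------

def generate_chip_tags(
    locus: LocusModel,
    condition: str = "normal",
    depth: int = 50_000,
    seed: int = 0,
    fragment_length: int = 200,
    enriched: list[tuple[GenomicInterval, float]] | None = None,
) -> pd.DataFrame:
    """Sample exactly ``depth`` tag records from the planted density model.

    The per-bp fragment-center rate is uniform on the background and
    multiplied by the planted fold within enriched intervals (the donor
    enhancers by default; tumor condition adds the tumor-only regions).
    Tags inherit the ChIP strand shift: forward tags sit half a fragment
    left of the center, reverse tags half a fragment right.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if condition not in ("normal", "tumor"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    regions = list(locus.donor_enhancers if enriched is None else enriched)
    if enriched is None and condition == "tumor":
        regions += locus.tumor_regions
    segs = []  # (chrom, start, end, rate)
    for chrom, L in locus.chrom_lengths.items():
        pts = {0, L}
        on_chrom = [(iv, f) for iv, f in regions if iv.chrom == chrom]
        for iv, _ in on_chrom:
            pts |= {iv.start, iv.end}
        bounds = sorted(pts)
        for s, e in zip(bounds, bounds[1:]):
            rate = 1.0
            for iv, f in on_chrom:
                if iv.start <= s and e <= iv.end:
                    rate *= f
            segs.append((chrom, s, e, rate))
    weights = np.array([(e - s) * r for _, s, e, r in segs])
    counts = rng.multinomial(depth, weights / weights.sum())
    shift = fragment_length // 2
    recs = []
    for (chrom, s, e, _), k in zip(segs, counts):
        if k == 0:
            continue
        centers = rng.integers(s, e, size=k)
        fwd = rng.integers(0, 2, size=k).astype(bool)
        pos = np.where(fwd, centers - shift, centers + shift - 1)
        pos = np.clip(pos, 0, locus.chrom_lengths[chrom] - 1)
        recs.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "strand": np.where(fwd, "+", "-"),
        }))
    tags = pd.concat(recs, ignore_index=True)
    return tags.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# TAD boundary calls
# ---------------------------------------------------------------------------

def generate_boundary_calls(
    locus: LocusModel,
    n_samples: int = 29,
    jitter_sd: float = 0.0,
    drop_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list, PlantedTruth]:
    """Per-sample boundary sets: planted positions plus integer jitter,
    with boundaries independently dropped at ``drop_rate``."""
    from .tads import BoundarySet

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_samples):
        positions: dict[str, list[int]] = {}
        for chrom, truth in locus.tad_boundaries.items():
            kept = []
            for pos in truth:
                if rng.random() < drop_rate:
                    continue
                p = pos + (int(round(rng.normal(0, jitter_sd))) if jitter_sd > 0 else 0)
                kept.append(int(np.clip(p, 0, locus.chrom_lengths[chrom] - 1)))
            positions[chrom] = sorted(kept)
        sets.append(BoundarySet(sample=f"hic{i + 1:02d}", positions=positions))
    truth = PlantedTruth(boundary_positions={
        c: list(v) for c, v in locus.tad_boundaries.items()
    })
    return sets, truth


# ---------------------------------------------------------------------------
# translocations
# ---------------------------------------------------------------------------

def generate_translocations(
    locus: LocusModel,
    patterns: list[int] | tuple[int, ...] = (1, 2, 3),
    n_noise: int = 0,
    seed: int = 0,
    p_near_tss: float = 2 / 3,
) -> tuple[list[TranslocationCall], PlantedTruth]:
    """One passing call per requested pattern id (repeats allowed) plus
    ``n_noise`` calls planted to fail the quality/support filter.

    The donor breakend falls in the pattern's defining region; the
    acceptor breakend falls within the 600-bp window directly upstream of
    the TSS with probability ``p_near_tss`` (default 2/3), otherwise
    further upstream. Donor strand is reverse (right side retained) for
    patterns 1 and 3; pattern 2 mixes orientations.
    """
    bad = set(patterns) - {1, 2, 3}
    if bad:
        raise ValueError(f"unknown pattern id(s) {sorted(bad)}")
    rng = np.random.default_rng(seed)
    ann = locus.annotation()
    tss = locus.acceptor_tss
    calls: list[TranslocationCall] = []
    truth = PlantedTruth()
    for i, pat in enumerate(patterns):
        if pat == 1:
            w = ann.ctcf_pair_window
            pos = int(rng.integers(w.start + 100, w.end - 100))
            donor_strand = "-"
        elif pat == 2:
            w = ann.triple_gene_span
            pos = int(rng.integers(w.start, w.end))
            donor_strand = "+" if rng.random() < 0.3 else "-"
        else:
            w = locus.fdcsp_intron1
            pos = int(rng.integers(w.start, w.end))
            donor_strand = "-"
        if rng.random() < p_near_tss:
            acc_pos = tss - int(rng.integers(1, 601))
        else:
            acc_pos = tss - int(rng.integers(601, 40_000))
        sample = f"TX{i + 1:03d}"
        calls.append(TranslocationCall(
            sample=sample,
            a=Breakend(locus.donor_chrom, pos, donor_strand),
            b=Breakend(locus.acceptor_chrom, acc_pos, "-"),
            quality=float(rng.integers(255, 1000)),
            support=int(rng.integers(15, 80)),
        ))
        truth.pattern_labels[sample] = f"pattern{pat}"
    for j in range(n_noise):
        mode = rng.integers(0, 3)
        quality = float(rng.integers(0, 255)) if mode != 1 else float(rng.integers(255, 1000))
        support = int(rng.integers(0, 15)) if mode != 0 else int(rng.integers(15, 80))
        sample = f"NS{j + 1:03d}"
        calls.append(TranslocationCall(
            sample=sample,
            a=Breakend(locus.donor_chrom,
                       int(rng.integers(0, locus.chrom_lengths[locus.donor_chrom])),
                       str(rng.choice(["+", "-"]))),
            b=Breakend(locus.acceptor_chrom,
                       int(rng.integers(0, locus.chrom_lengths[locus.acceptor_chrom])),
                       str(rng.choice(["+", "-"]))),
            quality=quality,
            support=support,
        ))
        truth.pattern_labels[sample] = "noise"
    return calls, truth


# ---------------------------------------------------------------------------
# expression counts and FISH tallies
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gene_panel(locus: LocusModel) -> pd.DataFrame:
    """Gene models (GTF-lite) for the synthetic quantification panel,
    including exclusion-rule exemplars on chrX/MT and rRNA/tRNA genes."""
    rows = [
        ("NR4A3_s", locus.acceptor_chrom, 4_000, "protein_coding",
         locus.acceptor_tss, "+"),
        ("TARGET1_s", locus.acceptor_chrom, 2_500, "protein_coding", 700_000, "+"),
        ("NBR_UP_s", locus.acceptor_chrom, 3_000, "protein_coding", 420_000, "-"),
        ("NBR_DN_s", locus.acceptor_chrom, 5_000, "protein_coding", 600_000, "+"),
    ]
    for g in locus.donor_genes:
        exonic = sum(e.length for e in g.exons)
        rows.append((g.name, g.chrom, exonic, "protein_coding", g.start, g.strand))
    rows += [
        ("GX1_s", "chrX", 3_000, "protein_coding", 100_000, "+"),
        ("GMT1_s", "chrMT", 1_000, "protein_coding", 5_000, "+"),
        ("RNA5S_s", locus.donor_chrom, 120, "rRNA", 50_000, "+"),
        ("TRNA1_s", locus.donor_chrom, 75, "tRNA", 60_000, "+"),
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "length", "biotype", "tss", "strand"]
    ).set_index("gene_id")


def generate_counts_and_fish(
    locus: LocusModel,
    n_tumor: int = 10,
    n_normal: int = 3,
    seed: int = 0,
    de_fold: float = 4.0,
    dispersion: float = 0.05,
    n_acicc: int = 28,
    n_other: int = 75,
    acicc_positive: int = 24,
    p_aberrant_pos: float = 0.60,
    p_aberrant_neg: float = 0.02,
    n_cells: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Negative-binomial count matrix with planted DE genes, plus a FISH
    cohort tally table drawn binomially around the planted status.

    Returns (counts, gene models, fish table, truth). DE genes (the
    oncogene-like acceptor gene and its downstream target) get
    ``de_fold``-times-higher means in tumor samples.
    """
    if n_tumor < 1 or n_normal < 1:
        raise ValueError("need at least one tumor and one normal sample")
    rng = np.random.default_rng(seed)
    models = gene_panel(locus)
    base = np.exp(rng.normal(5.0, 1.0, size=len(models)))
    de_genes = {"NR4A3_s": de_fold, "TARGET1_s": de_fold}
    samples = [f"T{i + 1:02d}" for i in range(n_tumor)] + [
        f"N{i + 1:02d}" for i in range(n_normal)
    ]
    data = {}
    for s in samples:
        mean = base.copy()
        if s.startswith("T"):
            for g, f in de_genes.items():
                mean[models.index.get_loc(g)] *= f
        data[s] = _nb_draw(rng, mean, dispersion)
    counts = pd.DataFrame(data, index=models.index)

    cases = []
    status = {}
    for i in range(n_acicc):
        cid = f"AciCC{i + 1:02d}"
        positive = i < acicc_positive
        status[cid] = positive
        p = p_aberrant_pos if positive else p_aberrant_neg
        cases.append((cid, "AciCC", n_cells, int(rng.binomial(n_cells, p))))
    for i in range(n_other):
        cid = f"Other{i + 1:02d}"
        status[cid] = False
        cases.append((cid, "other", n_cells,
                      int(rng.binomial(n_cells, p_aberrant_neg))))
    fish = pd.DataFrame(
        cases, columns=["case_id", "group", "n_cells", "n_aberrant"]
    )
    truth = PlantedTruth(de_genes=de_genes, fish_status=status)
    return counts, models, fish, truth


def printed_cohort_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic case tables matching the published cohort tallies.

    FISH: 29 tumor-entity cases of which 28 are evaluable and 24 carry a
    rearrangement, plus 75 other salivary-gland neoplasms, all negative.
    IHC: 29 tumor-entity cases, 28 with nuclear staining.
    """
    fish_rows = []
    for i in range(29):
        evaluable = i < 28
        fish_rows.append({
            "case_id": f"AciCC{i + 1:02d}",
            "group": "AciCC",
            "status": evaluable and i < 24,
            "evaluable": evaluable,
        })
    for i in range(75):
        fish_rows.append({
            "case_id": f"Other{i + 1:02d}",
            "group": "other",
            "status": False,
            "evaluable": True,
        })
    ihc_rows = [
        {"case_id": f"AciCC{i + 1:02d}", "group": "AciCC",
         "status": i < 28, "evaluable": True}
        for i in range(29)
    ]
    return pd.DataFrame(fish_rows), pd.DataFrame(ihc_rows)


# ---------------------------------------------------------------------------
# sequence
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator) -> str:
    bases = np.array(list("ACGT"))
    probs = [BACKGROUND_PROBS[b] for b in "ACGT"]
    return "".join(rng.choice(bases, size=length, p=probs))


def plant_word(seq: str, word: str, pos: int, strand: str = "+") -> str:
    w = word if strand == "+" else reverse_complement(word)
    if pos < 0 or pos + len(w) > len(seq):
        raise ValueError("planted word exceeds sequence bounds")
    return seq[:pos] + w + seq[pos + len(w):]


def generate_genome_sequences(
    locus: LocusModel, seed: int = 0
) -> tuple[dict[str, str], PlantedTruth]:
    """Background sequence for both chromosomes with the CTCF consensus
    planted at every CTCF site in its stated orientation."""
    rng = np.random.default_rng(seed)
    ctcf = build_pwm(load_builtin_pfm("ctcf"), name="CTCF_synthetic")
    word = ctcf.consensus
    seqs = {}
    truth = PlantedTruth()
    for chrom, L in locus.chrom_lengths.items():
        seqs[chrom] = random_sequence(L, rng)
    for pos, orientation in locus.donor_ctcf_sites:
        strand = "+" if orientation == "forward" else "-"
        seqs[locus.donor_chrom] = plant_word(
            seqs[locus.donor_chrom], word, pos, strand
        )
        truth.motif_sites.append((locus.donor_chrom, pos, strand))
    seqs[locus.acceptor_chrom] = plant_word(
        seqs[locus.acceptor_chrom], word, locus.acceptor_ctcf_site, "+"
    )
    truth.motif_sites.append((locus.acceptor_chrom, locus.acceptor_ctcf_site, "+"))
    return seqs, truth


def motif_region_set(
    n_regions: int,
    region_length: int,
    word: str,
    frac_with_motif: float,
    seed: int = 0,
) -> tuple[list[str], int]:
    """Background regions with the motif word planted in the first
    ``round(frac * n)`` of them; returns (sequences, n_planted)."""
    rng = np.random.default_rng(seed)
    n_with = round(frac_with_motif * n_regions)
    seqs = []
    for i in range(n_regions):
        s = random_sequence(region_length, rng)
        if i < n_with:
            pos = int(rng.integers(0, region_length - len(word) + 1))
            strand = str(rng.choice(["+", "-"]))
            s = plant_word(s, word, pos, strand)
        seqs.append(s)
    return seqs, n_with
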