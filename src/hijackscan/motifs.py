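"""Position weight matrices: construction, threshold calibration, scanning,
CTCF orientation annotation, and a simple exact enrichment test.

PWMs are built from position frequency (count) matrices with pseudocounts
proportional to a genomic background of A=T=30%, C=G=20% (approximate
human CG content of 40%). Score thresholds for a target false positive
rate are calibrated by dynamic programming over quantized position scores
(TFM-pvalue style), with the score range divided into a fixed number of
quantization steps (default 1e4) and an i.i.d. background sequence model.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.stats import binomtest

from .intervals import GenomicInterval

ALPHABET = "ACGT"
DEFAULT_BACKGROUND = np.array([0.30, 0.20, 0.20, 0.30])  # A C G T
DEFAULT_FPR = 1e-4
DEFAULT_PRECISION = 10_000

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    name: str
    matrix: np.ndarray  # (4, L) log2-odds, rows A C G T
    background: np.ndarray  # (4,)
    threshold: float | None = None
    # set by calibrate_threshold: the quantized position-score matrix and
    # integer threshold, so scanning reproduces the calibrated FPR exactly
    int_matrix: np.ndarray | None = None
    int_threshold: int | None = None

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    def score(self, word: str) -> float:
        codes = _CODE[np.frombuffer(word.encode(), dtype=np.uint8)]
        if (codes < 0).any():
            raise ValueError(f"word {word!r} contains non-ACGT characters")
        if len(codes) != self.length:
            raise ValueError("word length does not match PWM length")
        return float(self.matrix[codes, np.arange(self.length)].sum())


@dataclass
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float
    pwm_name: str


def read_pfm(path_or_text: str) -> np.ndarray:
    """Parse a whitespace-tabular position frequency matrix.

    Accepts 4 rows x L columns (rows A, C, G, T) or L rows x 4 columns;
    orientation is auto-detected (4x4 is taken as rows = letters).
    Lines starting with ``>`` or ``#`` and optional leading row labels
    (``A`` / ``A:`` / ``A |``) are tolerated.
    """
    if "\n" in path_or_text or "\t" in path_or_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line[0] in ">#":
            continue
        parts = line.replace(":", " ").replace("|", " ").replace("[", " ").replace("]", " ").split()
        if parts and parts[0].upper() in set(ALPHABET):
            parts = parts[1:]
        rows.append([float(x) for x in parts])
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2:
        raise ValueError("PFM is not a rectangular numeric table")
    if arr.shape[0] != 4:
        if arr.shape[1] == 4:
            arr = arr.T
        else:
            raise ValueError(f"PFM shape {arr.shape} has no axis of size 4")
    if (arr < 0).any():
        raise ValueError("PFM counts must be non-negative")
    return arr


def load_builtin_pfm(name: str) -> np.ndarray:
    """Load one of the bundled synthetic PFMs ('ctcf' or 'nbre')."""
    fname = f"{name}_synthetic.pfm"
    text = resources.files("hijackscan.data").joinpath(fname).read_text()
    return read_pfm(text)


def build_pwm(
    counts: np.ndarray,
    pseudocount_weight: float = 1.0,
    background: np.ndarray = DEFAULT_BACKGROUND,
    name: str = "pwm",
) -> PWM:
    """Log2-odds PWM from counts with background-proportional pseudocounts.

    Each column receives ``background * pseudocount_weight`` pseudocounts,
    e.g. column (A=10, C=0, G=0, T=0) with weight 1 yields
    P(A) = 10.3 / 11 before log-odds. Weight 0 gives the pure maximum
    likelihood estimate (and fails on zero-total columns).
    """
    counts = np.asarray(counts, dtype=float)
    background = np.asarray(background, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("counts must have 4 rows (A, C, G, T)")
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background probabilities must sum to 1")
    totals = counts.sum(axis=0) + pseudocount_weight
    if (totals <= 0).any():
        raise ValueError(
            "zero-total PFM column requires a positive pseudocount weight"
        )
    probs = (counts + background[:, None] * pseudocount_weight) / totals
    with np.errstate(divide="ignore"):  # zero cells (pure ML) -> -inf
        matrix = np.log2(probs / background[:, None])
    return PWM(name=name, matrix=matrix, background=background.copy())


def quantize_pwm(pwm: PWM, precision: int = DEFAULT_PRECISION):
    """Integer position scores on a grid of ``precision`` steps.

    Returns ``(int_matrix, delta)`` with ``int_matrix = round(matrix / delta)``
    and ``delta = (max_score - min_score) / precision``. Shared by the DP
    calibration and the exhaustive-enumeration oracle so both work on the
    identical grid.
    """
    if not np.isfinite(pwm.matrix).all():
        raise ValueError(
            "calibration requires finite log-odds; build the PWM with a "
            "positive pseudocount weight"
        )
    span = pwm.max_score - pwm.min_score
    if span <= 0:
        raise ValueError("degenerate PWM: all words score equally")
    delta = span / precision
    return np.rint(pwm.matrix / delta).astype(np.int64), delta


def score_distribution(
    int_matrix: np.ndarray, background: np.ndarray
) -> tuple[int, np.ndarray]:
    """Exact distribution of the integer word score under i.i.d. background.

    Returns ``(offset, probs)`` where ``probs[k]`` is the probability of
    integer score ``offset + k``.
    """
    mins = int_matrix.min(axis=0)
    maxs = int_matrix.max(axis=0)
    dist = np.array([1.0])
    for j in range(int_matrix.shape[1]):
        width = len(dist) + int(maxs[j] - mins[j])
        new = np.zeros(width)
        for a in range(4):
            sh = int(int_matrix[a, j] - mins[j])
            new[sh : sh + len(dist)] += background[a] * dist
        dist = new
    return int(mins.sum()), dist


def calibrate_threshold(
    pwm: PWM,
    fpr: float = DEFAULT_FPR,
    precision: int = DEFAULT_PRECISION,
) -> float:
    """Smallest score whose background exceedance probability is <= fpr.

    Computed exactly by dynamic programming over quantized position
    scores; ``fpr=1`` returns the minimal achievable score. The returned
    PWM carries the threshold on ``pwm.threshold`` as well.
    """
    if not 0 < fpr <= 1:
        raise ValueError("fpr must lie in (0, 1]")
    iq, delta = quantize_pwm(pwm, precision)
    offset, dist = score_distribution(iq, pwm.background)
    tail = np.minimum(np.cumsum(dist[::-1])[::-1], 1.0)  # guard roundoff > 1
    ok = np.flatnonzero((tail <= fpr) & (dist > 0))  # smallest achievable score
    k = int(ok[0]) if ok.size else len(dist)  # above max score if needed
    threshold = (offset + k) * delta
    pwm.threshold = float(threshold)
    pwm.int_matrix = iq
    pwm.int_threshold = offset + k
    return pwm.threshold


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    L = matrix.shape[1]
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    scores = matrix[np.clip(win, 0, 3), np.arange(L)].sum(axis=1)
    scores[np.any(win < 0, axis=1)] = -np.inf  # windows containing N
    return scores


def scan(
    sequence: str,
    pwm: PWM,
    threshold: float | None = None,
    chrom: str = "seq",
) -> list[MotifHit]:
    """Report all windows on both strands scoring at or above threshold.

    A minus-strand hit over window ``[i, i+L)`` is reported at that
    interval with strand ``-`` and the score of the reverse-complemented
    window. Windows containing ``N`` are skipped; matching is case
    insensitive. When the PWM carries a calibrated threshold, windows are
    selected on the calibration's quantized-score grid so the attained
    false positive rate matches the calibration exactly.
    """
    use_grid = threshold is None and pwm.int_threshold is not None
    if threshold is None:
        threshold = pwm.threshold
    if threshold is None:
        raise ValueError("no threshold given; run calibrate_threshold first")
    L = pwm.length
    if len(sequence) < L:
        return []
    codes = _CODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)].astype(
        np.int64
    )
    # reverse-complement scoring matrix: position j reads complement of base L-1-j
    rc_matrix = pwm.matrix[::-1, ::-1]
    hits: list[MotifHit] = []
    for strand, matrix in (("+", pwm.matrix), ("-", rc_matrix)):
        scores = _window_scores(codes, matrix)
        if use_grid:
            iq = pwm.int_matrix if strand == "+" else pwm.int_matrix[::-1, ::-1]
            int_scores = _window_scores(codes, iq.astype(float))
            passing = int_scores >= pwm.int_threshold
        else:
            passing = scores >= threshold
        for i in np.flatnonzero(passing):
            hits.append(
                MotifHit(
                    interval=GenomicInterval(chrom, int(i), int(i) + L),
                    strand=strand,
                    score=float(scores[i]),
                    pwm_name=pwm.name,
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


@dataclass
class OrientedSite:
    """A binding-site peak annotated with its best motif hit's strand."""

    peak: GenomicInterval
    strand: str | None  # None when the peak contains no hit
    best_hit: MotifHit | None = None


def annotate_ctcf_orientation(
    peaks: list[GenomicInterval], hits: list[MotifHit]
) -> list[OrientedSite]:
    """Annotate each peak with the strand of its best contained motif hit.

    Peaks without any fully contained hit stay unoriented. Output keeps
    genomic order (chrom, start).
    """
    out = []
    for peak in sorted(peaks, key=lambda p: (p.chrom, p.start)):
        contained = [
            h
            for h in hits
            if h.interval.chrom == peak.chrom
            and h.interval.start >= peak.start
            and h.interval.end <= peak.end
        ]
        if contained:
            best = max(contained, key=lambda h: h.score)
            out.append(OrientedSite(peak=peak, strand=best.strand, best_hit=best))
        else:
            out.append(OrientedSite(peak=peak, strand=None))
    return out


def convergent_pairs(
    sites: list[OrientedSite],
) -> list[tuple[OrientedSite, OrientedSite]]:
    """Adjacent site pairs with inverse (convergent) orientation.

    A pair is convergent iff the left site is forward and the right site
    reverse — the configuration whose loss upon rearrangement disrupts
    sub-TAD insulation. Unoriented sites (no motif hit) are skipped, so
    adjacency is among oriented sites.
    """
    ordered = sorted(
        (s for s in sites if s.strand is not None),
        key=lambda s: (s.peak.chrom, s.peak.start),
    )
    pairs = []
    for left, right in zip(ordered, ordered[1:]):
        if (
            left.peak.chrom == right.peak.chrom
            and left.strand == "+"
            and right.strand == "-"
        ):
            pairs.append((left, right))
    return pairs


def motif_enrichment(
    fg_seqs: list[str],
    bg_seqs: list[str],
    pwm: PWM,
    threshold: float | None = None,
) -> tuple[float, float, float]:
    """One-sided exact test of motif occurrence in foreground regions.

    A region "contains" the motif if scanning yields at least one hit.
    Returns ``(fg_fraction, bg_fraction, p_value)`` from a one-sided
    binomial test of the foreground hit-containing count against the
    background fraction. Background should be the complete set of
    extended regions the foreground was drawn from.
    """
    if not fg_seqs:
        raise ValueError("empty foreground region set")
    if not bg_seqs:
        raise ValueError("empty background region set")

    def frac(seqs: list[str]) -> float:
        return sum(bool(scan(s, pwm, threshold)) for s in seqs) / len(seqs)

    fg_frac = frac(fg_seqs)
    bg_frac = frac(bg_seqs)
    k = round(fg_frac * len(fg_seqs))
    p = binomtest(k, len(fg_seqs), min(max(bg_frac, 0.0), 1.0), alternative="greater").pvalue
    return fg_frac, bg_frac, float(p)
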