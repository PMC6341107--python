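# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generators emulate (and what they do
not), and the design decisions taken where several readings were
defensible.

## Coordinates and conventions

All coordinates are 0-based, half-open `[start, end)` (BED semantics),
including positions in SV and FISH tables; file headers state this. The
synthetic chromosomes are named `chr4s` (donor) and `chr9s` (acceptor)
so they cannot be confused with a real genome build. Breakends use the
convention `+` = segment left of the position retained on the derived
chromosome, `-` = segment right retained; the SV TSV header repeats it.

## Fragment-density tracks

ChIP tags are 5′ positions of aligned reads; a `+` tag at `p` is
extended 3′ to `[p, p+L)` and a `-` tag — whose 5′ end is its
*rightmost* base — to `[p+1-L, p+1)`, clipped to chromosome bounds.
`L` defaults to 200 bp, the typical mean of a size-selected library;
values outside 150–250 bp trigger a warning rather than an error,
since the appropriate length is a property of the library and is
deliberately exposed as a parameter, not estimated. Density is the
count of fragments overlapping each 32-bp bin; a fragment increments
*every* bin it overlaps, matching the visual semantics of a bedGraph
density track. Multi-sample normalization down-samples each tag table
without replacement to the smallest sample's count under one seed.

The bedGraph dialect adds comment headers (`bin_size`,
`total_fragments`, `chrom_length`) so tracks round-trip exactly; zero
bins are omitted and an optional run-length-merged dialect collapses
adjacent equal values.

## Peaks, super-enhancers, differential regions

The enrichment detector (maximal runs of ≥ `min_bins` bins at ≥
`fold_threshold` × the genome-wide median of nonzero bins) is a
deliberately simple device that closes the loop on synthetic data;
model-based peak callers are out of scope and their output can be fed
in as BED instead.

Stitching is single-linkage with the inter-peak distance measured
end-to-start (end-exclusive); a distance exactly equal to the 12,500-bp
gap still merges. A merged region's aggregate signal is the
length-weighted sum of constituent signals; super-enhancers are the
`max(1, floor(0.05·N))` strongest regions, ties broken by earlier
start — the minimum-one rule makes "top 5%" well defined for N < 20.

Differential classification works on the union of per-sample peaks
(overlapping or directly adjacent intervals merged). Per region and
sample, the statistic is the mean bin density; tumor samples are
aggregated by their arithmetic mean (the aggregation is not uniquely
determined by the comparison "tumor samples vs. the normal sample", so
per-sample means are also reported). The ratio is
`log2((tumor + ε)/(normal + ε))` with ε defaulting to 0.25 bin-units to
guard zero densities; classes are `up` (ratio ≥ 2), `down` (≤ −2),
`neutral`. Note the boundary is *inclusive*: a noise-free planted
4-fold region with ε = 0 sits exactly at ratio 2 and is classified
`up`. Because a 4-fold effect lies exactly on the decision boundary,
robustness under Poisson noise is demonstrated with planted 8-fold /
0.125-fold effects — one log2 unit inside each class — at 5 mean
tags/bin; an effect on the boundary is recovered only about half the
time under noise, which is a property of any thresholded classifier,
not of this implementation.

## Consensus TAD boundaries

The genome is cut into 40-kb bins; for each bin we count the samples
with at least one boundary in the bin or a direct neighbor (each sample
counts once per bin). Bins whose count *strictly exceeds* 2 ("exceeded
a number of 2" is read literally as ≥ 3) seed a boundary region that
extends while the criterion holds; the position is the region start
plus half its length (floor for odd bin counts, positions being integer
bp). The ±1-neighbor window is applied once, in the counting step;
testing the extension against the already-smoothed counts avoids double
smoothing — the alternative (re-smoothing during extension) was
considered and rejected as it widens regions without adding
information. The caller is verified against an independent
mark-runs-midpoint implementation on 1,000 random 29-sample instances.

## PWM scanning

PWMs are log2-odds matrices over a fixed background A = T = 0.30,
C = G = 0.20 (≈ 40% GC). Pseudocounts proportional to the background
times a weight (default 1) are added per column; weight 0 gives the
pure ML estimate, with −∞ log-odds for zero cells (such a PWM can be
scanned with an explicit threshold but not calibrated).

Threshold calibration follows the TFM-pvalue approach: the score range
is divided into `precision` (default 10⁴) steps, position scores are
rounded to that grid, and the exact distribution of the integer word
score under the i.i.d. background is obtained by dynamic programming.
The threshold is the smallest *achievable* grid score whose exceedance
probability is ≤ the target FPR (default 10⁻⁴). Scanning then selects
windows on the same quantized grid (the quantized matrix and integer
threshold are stored on the PWM), so the attained false positive rate
equals the calibrated one exactly; comparing real-valued scores against
a grid threshold instead can exclude words — including the consensus —
whose rounded and unrounded scores fall on opposite sides of the cut.
The DP is validated against exhaustive 4^L enumeration for L ≤ 8 and
cross-checked against an independent score-distribution implementation.

Orientation annotation assigns each binding-site peak the strand of its
best-scoring fully contained hit (one arrow per site); a pair of
consecutive *oriented* sites is convergent iff the left is forward and
the right reverse. Motif enrichment is a one-sided exact binomial test
of the fraction of foreground regions containing ≥ 1 hit against the
background fraction; the background should be the complete set of
extended regions the foreground derives from. The test does not
length-match foreground and background regions; callers comparing
region sets of very different lengths should equalize them first.

The bundled CTCF (19 bp) and NBRE (8 bp, `AAAGGTCA`) matrices are
synthetic consensus-derived stand-ins intended for testing and
simulation; real database matrices are supplied by the user as PFM
text (4 × L or L × 4, auto-detected).

## Rearrangements

Calls are kept iff quality ≥ 255 **and** read support ≥ 15 (both
inclusive). The donor breakend is classified by genomic containment
with precedence intragenic (pattern 3) > convergent-CTCF window
(pattern 1) > triple-gene span (pattern 2) > other; the regions never
overlap in the motivating data, so precedence only matters for
degenerate synthetic layouts. Whether the acceptor breakend falls
within the 600-bp window directly upstream of the TSS is reported as a
separate flag, not part of the pattern.

Reconstruction joins the acceptor segment containing the TSS to the
retained donor segment; if neither acceptor segment contains the TSS
the fusion is rejected (`TSS not on derived chromosome`). A donor
feature is retained if any part of it lies on the retained side;
its distance to the TSS is the junction-to-TSS offset plus the gap
between the donor breakpoint and the feature edge nearest the junction
(zero for features straddling the breakpoint). Distances are therefore
non-negative, measured along the derived chromosome, and increase with
distance from the TSS. Mirroring the donor (coordinates `x → L − x`,
strands flipped) leaves all distances invariant — this exact symmetry
and a brute-force retained-base-pair oracle back the implementation.

The insulator check flags a call when an acceptor CTCF site lies
upstream of the breakend while the TSS lies downstream, i.e. the
junction separates insulator from promoter.

## Quantification and cohorts

FPKM and TPM use an *included-only* library: genes on chromosomes
X/Y/MT and rRNA/tRNA genes are excluded from the library-size and TPM
denominators but still receive values against the included totals.
TPM over included genes sums to 10⁶ by construction. Differential
expression is reported only as a descriptive log2 fold change of mean
TPM (pseudo-count 0.5); dispersion modeling and testing are out of
scope.

Peak–gene association flags a gene for a class when a region of that
class has its midpoint within a window (default 50 kb) of the gene's
TSS — a simple, order-independent rule chosen because the association
rule behind the motivating figures is not specified.

FISH cases are scored rearranged iff the aberrant fraction strictly
exceeds 20% of the (default 50) scored cells, so 10/50 is negative and
11/50 positive. Cohort summaries exclude non-evaluable cases from
denominators and round percentages half away from zero, reproducing
24/28 → 86% and 28/29 → 97%.

## Synthetic data

The generators define the study conditions: a 1-Mb donor chromosome
with a convergent CTCF pair at 200/260 kb, a triple-gene span at
300–420 kb, an FDCSP-like gene at 500 kb whose first intron spans
502–510 kb, five enhancers (fold 6–15, 2 kb) placed on a seeded grid in
the active region; a 1-Mb acceptor with a TSS at 500 kb and a CTCF site
13.5 kb upstream. ChIP tags are drawn exactly `depth` at a time from a
piecewise-constant center-rate model (uniform background × planted
folds), with the characteristic strand shift of half a fragment; counts
are negative binomial (dispersion 0.05, planted fold 4 in the
oncogene-like genes across 10 tumors vs. 3 normals); boundary sets
follow the 29-sample design with configurable jitter and drop-out;
translocation cohorts mirror the observed 4/10/1 pattern split, with
the acceptor breakend landing in the 600-bp upstream window with
probability 2/3 (the observed 4-of-6 rate) and noise calls planted to
fail the quality/support filter. FISH tallies are binomial with
aberrant-cell probability 0.60 (rearranged) or 0.02 (not).

What the generators do *not* emulate: read sequences, sequencing error,
mappability, GC bias, copy-number structure, replicate-to-replicate
batch effects, or correlated noise between marks. Passing the planted-
truth tests therefore demonstrates algorithmic correctness under the
stated noise models, not robustness to every artifact of real
libraries. Problem sizes in the test suite and reproduction script
(e.g. 1,000 random 29-sample × 500-bin TAD instances, 100 × 10-kb scan
replicates, 500 reconstruction configurations, 50 differential seeds)
were chosen as the smallest sizes at which the Monte-Carlo standard
errors are decisively smaller than the effects being checked.

## Known limitations

* The enrichment detector has no statistical model (no p-values/FDR);
  it exists to close the synthetic loop.
* The motif enrichment test does not length-match backgrounds.
* Whether the differential comparison should use per-tumor ratios or a
  tumor aggregate is genuinely open; both are reported, the class label
  follows the aggregate.
* The real-data breakpoint coordinates behind the published
  enhancer-to-TSS distances are not public, so those distances serve
  as narrative context only; the reconstruction is validated against
  oracles and symmetry instead.
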