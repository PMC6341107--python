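"""Expression quantification, peak-gene association, and FISH cohort scoring.

FPKM/TPM use an "included-only" library size: genes on chromosomes X, Y
and MT and genes of rRNA/tRNA biotype are omitted from the library-size
and TPM denominators (they bias library size estimates), but still
receive values computed against the included-only totals.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .peaks import DifferentialRegion

EXCLUDED_CHROMS = frozenset(
    {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}
)
EXCLUDED_BIOTYPES = frozenset({"rRNA", "tRNA"})
FISH_CUTOFF = 0.20
FISH_CELLS = 50
ASSOCIATION_WINDOW = 50_000

MODEL_COLUMNS = ["chrom", "length", "biotype"]


@dataclass
class FishCase:
    case_id: str
    group: str
    n_cells: int = FISH_CELLS
    n_aberrant: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_aberrant <= self.n_cells:
            raise ValueError("need 0 <= n_aberrant <= n_cells")


def compute_fpkm_tpm(
    counts: pd.DataFrame,
    models: pd.DataFrame,
    excluded_chroms: frozenset[str] = EXCLUDED_CHROMS,
    excluded_biotypes: frozenset[str] = EXCLUDED_BIOTYPES,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Length- and depth-normalized expression with biased-gene exclusion.

    ``counts`` is genes x samples; ``models`` is indexed by gene id with
    columns chrom, length (exonic bp) and biotype. Returns a dict with
    'fpkm' and 'tpm' DataFrames, the per-sample 'library_size', and the
    boolean 'included' mask.
    """
    missing = counts.index.difference(models.index)
    if len(missing):
        raise ValueError(f"genes without models: {list(missing)[:5]}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    models = models.loc[counts.index]
    if (models["length"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    included = ~(
        models["chrom"].isin(excluded_chroms)
        | models["biotype"].isin(excluded_biotypes)
    )
    libsize = counts.loc[included].sum(axis=0).astype(float)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        raise ValueError(f"zero included library size for sample(s) {bad}")
    kb = models["length"].astype(float) / 1e3
    fpkm = counts.div(kb, axis=0).div(libsize / 1e6, axis=1)
    rate = counts.div(models["length"].astype(float), axis=0)
    tpm = rate.div(rate.loc[included].sum(axis=0), axis=1) * 1e6
    return {"fpkm": fpkm, "tpm": tpm, "library_size": libsize, "included": included}


def log2_fold_change(
    tpm: pd.DataFrame,
    tumor_samples: list[str],
    normal_samples: list[str],
    eps: float = 0.5,
) -> pd.Series:
    """Descriptive per-gene log2 fold change of mean TPM (tumor/normal).

    Plumbing only — no dispersion modeling or significance testing.
    """
    t = tpm[tumor_samples].mean(axis=1)
    n = tpm[normal_samples].mean(axis=1)
    return np.log2((t + eps) / (n + eps))


def associate_peaks_to_genes(
    diff_regions: list[DifferentialRegion],
    models: pd.DataFrame,
    window: int = ASSOCIATION_WINDOW,
) -> pd.DataFrame:
    """Flag genes with a differential region midpoint within ``window`` of
    their TSS, one boolean column per region class.

    ``models`` must carry 'chrom' and 'tss' columns.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    classes = ("up", "down", "neutral")
    flags = pd.DataFrame(
        False, index=models.index, columns=list(classes), dtype=bool
    )
    for region in diff_regions:
        mid = region.interval.midpoint
        near = (models["chrom"] == region.interval.chrom) & (
            (models["tss"] - mid).abs() <= window
        )
        flags.loc[near, region.label] = True
    return flags


def score_fish_case(case: FishCase, cutoff: float = FISH_CUTOFF) -> bool:
    """Rearranged iff the aberrant-cell fraction strictly exceeds cutoff.

    10/50 cells (exactly 20%) is negative; 11/50 (22%) is positive.
    """
    if case.n_cells == 0:
        raise ValueError(f"case {case.case_id}: no cells scored")
    return case.n_aberrant / case.n_cells > cutoff


def round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group positive counts and rounded percentages.

    ``table`` needs columns 'group' and boolean 'status'; an optional
    boolean 'evaluable' column excludes non-evaluable records from the
    denominator. Percentages are rounded half away from zero. Groups with
    no evaluable records are omitted with a warning.
    """
    df = table.copy()
    if "evaluable" not in df.columns:
        df["evaluable"] = True
    rows = []
    for group, grp in df.groupby("group", sort=True):
        ev = grp[grp["evaluable"].astype(bool)]
        if len(ev) == 0:
            warnings.warn(f"group {group!r} has no evaluable cases; omitted",
                          stacklevel=2)
            continue
        positive = int(ev["status"].astype(bool).sum())
        rows.append(
            {
                "group": group,
                "positive": positive,
                "evaluable": len(ev),
                "percent": round_half_away(100.0 * positive / len(ev)),
            }
        )
    return pd.DataFrame(rows, columns=["group", "positive", "evaluable", "percent"])
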