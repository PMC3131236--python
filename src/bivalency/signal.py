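"""Promoter-window signal quantification and the H3K4me3/H3K27me3 ratio.

The central statistic is the per-gene ratio of H3K4me3 to H3K27me3 reads in
a strand-oriented window around the TSS (default -3 kb .. +3 kb).  Counts
are depth-normalised to reads per million before the ratio; a pseudocount
keeps ratios finite when a window is empty.  The array-style enrichment
(background-corrected ChIP over background-corrected input, both globally
normalised) covers tiling-array data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bivalency.io import GeneAnnotation, ReadSet, norm_chrom

logger = logging.getLogger(__name__)

OVERLAP_RULES = ("any", "midpoint", "five_prime")


@dataclass(frozen=True)
class WindowSpec:
    """A promoter window: upstream/downstream extents in bp, strand-oriented.

    ``upstream`` is measured against the direction of transcription, so a
    (3000, 3000) spec is the symmetric -3 kb..+3 kb window and a
    (4000, 1000) spec is -4 kb..+1 kb regardless of strand.
    """

    upstream: int = 3000
    downstream: int = 3000
    oriented: bool = True

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be >= 0")
        if self.upstream + self.downstream <= 0:
            raise ValueError("window must have positive width")


@dataclass(frozen=True)
class BivalencyScore:
    """Per-gene window counts, RPM signals and the pseudocounted ratio."""

    gene_id: str
    k4_count: int
    k27_count: int
    k4_norm: float
    k27_norm: float
    pseudocount: float

    @property
    def ratio(self) -> float:
        return (self.k4_norm + self.pseudocount) / (self.k27_norm + self.pseudocount)

    @property
    def log2_ratio(self) -> float:
        return math.log2(self.ratio)


def tss_window(gene: GeneAnnotation, spec: WindowSpec) -> tuple[str, int, int]:
    """The half-open genomic interval of ``spec`` anchored at the gene's TSS.

    For a minus-strand gene (with ``oriented``) the window is reflected:
    upstream extends to higher coordinates.  Clipped at position 0.
    """
    if spec.oriented and gene.strand == "-":
        start, end = gene.tss - spec.downstream, gene.tss + spec.upstream
    else:
        start, end = gene.tss - spec.upstream, gene.tss + spec.downstream
    return (gene.chrom, max(start, 0), max(end, 0))


def count_reads_in_windows(
    reads: ReadSet,
    windows: list[tuple[str, int, int]],
    overlap_rule: str = "any",
) -> np.ndarray:
    """Count reads per window under ``overlap_rule``.

    ``any``: a read is counted in every window its interval overlaps
    (half-open).  ``midpoint``: counted where its integer midpoint falls.
    ``five_prime``: counted where its start coordinate falls.  Windows on
    chromosomes absent from the library get count 0 (logged).
    """
    if overlap_rule not in OVERLAP_RULES:
        raise ValueError(f"unknown overlap_rule {overlap_rule!r}; expected one of {OVERLAP_RULES}")

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in reads.reads:
        by_chrom.setdefault(norm_chrom(chrom), []).append((start, end))

    # per-chromosome sorted coordinate arrays for O(log n) window queries
    index: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for chrom, ivs in by_chrom.items():
        arr = np.asarray(ivs, dtype=np.int64)
        if overlap_rule == "any":
            starts = np.sort(arr[:, 0])
            ends = np.sort(arr[:, 1])
        elif overlap_rule == "midpoint":
            points = np.sort((arr[:, 0] + arr[:, 1]) // 2)
            starts = ends = points
        else:  # five_prime
            points = np.sort(arr[:, 0])
            starts = ends = points
        index[chrom] = (starts, ends, len(arr))

    counts = np.zeros(len(windows), dtype=np.int64)
    missing: set[str] = set()
    for i, (chrom, ws, we) in enumerate(windows):
        key = norm_chrom(chrom)
        if key not in index:
            missing.add(chrom)
            continue
        starts, ends, n = index[key]
        if overlap_rule == "any":
            # overlap iff start < we and end > ws; the two failure events
            # (end <= ws, start >= we) are disjoint, so subtract both from n
            n_left = np.searchsorted(ends, ws, side="right")
            n_right = n - np.searchsorted(starts, we, side="left")
            counts[i] = n - n_left - n_right
        else:
            counts[i] = np.searchsorted(starts, we, side="left") - np.searchsorted(
                starts, ws, side="left"
            )
    if missing:
        logger.info(
            "%d window(s) on chromosome(s) absent from %s library: %s",
            sum(1 for c, *_ in windows if c in missing), reads.mark, sorted(missing),
        )
    return counts


def normalize_rpm(count: float, library_size: int) -> float:
    """Reads-per-million: count x 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0 for RPM normalisation")
    return count * 1e6 / library_size


def bivalency_ratio(k4_norm: float, k27_norm: float, pseudocount: float) -> tuple[float, float]:
    """The pseudocounted K4/K27 ratio and its log2.

    ``ratio = (k4 + eps)/(k27 + eps)``; with eps = 0 both signals must be
    positive.  Satisfies ratio(a,b,eps) * ratio(b,a,eps) = 1.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and k27_norm == 0:
        raise ValueError("zero denominator with pseudocount 0; set a positive pseudocount")
    ratio = (k4_norm + pseudocount) / (k27_norm + pseudocount)
    return ratio, math.log2(ratio)


def default_pseudocount(k4: ReadSet, k27: ReadSet) -> float:
    """RPM equivalent of a single read in the smaller of the two libraries."""
    smaller = min(k4.library_size, k27.library_size)
    if smaller <= 0:
        raise ValueError("cannot derive a pseudocount from an empty library")
    return 1e6 / smaller


def score_genes(
    genes: list[GeneAnnotation],
    k4: ReadSet,
    k27: ReadSet,
    spec: WindowSpec = WindowSpec(),
    pseudocount: float | str = "auto",
    overlap_rule: str = "any",
    raw_counts: bool = False,
) -> pd.DataFrame:
    """Score every gene: window counts, RPM signals, ratio and log2 ratio.

    ``pseudocount="auto"`` uses the RPM equivalent of one read in the
    smaller library.  ``raw_counts=True`` skips depth normalisation and
    forms the ratio from raw read numbers (with pseudocount 1 read under
    ``auto``), reproducing a single-dataset raw-count convention.
    """
    windows = [tss_window(g, spec) for g in genes]
    k4_counts = count_reads_in_windows(k4, windows, overlap_rule)
    k27_counts = count_reads_in_windows(k27, windows, overlap_rule)

    if raw_counts:
        k4_norm = k4_counts.astype(float)
        k27_norm = k27_counts.astype(float)
        eps = 1.0 if pseudocount == "auto" else float(pseudocount)
    else:
        k4_norm = np.array([normalize_rpm(c, k4.library_size) for c in k4_counts])
        k27_norm = np.array([normalize_rpm(c, k27.library_size) for c in k27_counts])
        eps = default_pseudocount(k4, k27) if pseudocount == "auto" else float(pseudocount)

    ratios = np.empty(len(genes))
    log2_ratios = np.empty(len(genes))
    for i in range(len(genes)):
        ratios[i], log2_ratios[i] = bivalency_ratio(k4_norm[i], k27_norm[i], eps)

    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "is_allosome": [g.is_allosome for g in genes],
            "k4_count": k4_counts,
            "k27_count": k27_counts,
            "k4_norm": k4_norm,
            "k27_norm": k27_norm,
            "ratio": ratios,
            "log2_ratio": log2_ratios,
            "pseudocount": eps,
        }
    )


def array_enrichment(
    chip_signal: np.ndarray,
    input_signal: np.ndarray,
    background_chip: float = 0.0,
    background_input: float = 0.0,
    normalise: bool = True,
    floor: float = 1e-6,
) -> np.ndarray:
    """Tiling-array enrichment: background-corrected ChIP over input.

    Both tracks are background-subtracted (floored at ``floor``), globally
    normalised to a common median (when ``normalise``), then divided
    probe-wise.  The output is invariant to rescaling either track.
    """
    chip = np.asarray(chip_signal, dtype=float)
    inp = np.asarray(input_signal, dtype=float)
    if chip.shape != inp.shape:
        raise ValueError("chip and input tracks must have equal length")
    if background_chip < 0 or background_input < 0:
        raise ValueError("backgrounds must be >= 0")
    if not np.any(inp > 0):
        raise ValueError("input track is all zero")

    chip_c = np.maximum(chip - background_chip, floor)
    inp_c = np.maximum(inp - background_input, floor)
    if normalise:
        chip_c = chip_c / np.median(chip_c)
        inp_c = inp_c / np.median(inp_c)
    return chip_c / inp_c
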