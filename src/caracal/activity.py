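"""Peak-to-gene activity projection.

scATAC-seq quantifies accessibility at peaks, not genes. To score cells
against gene sets, the peak x cell count matrix is projected to a gene x
cell "gene activity" matrix: each gene is assigned a strand-aware window
(gene body extended upstream of the transcription start site), and the
counts of every peak overlapping that window are summed per cell.

Overlap is computed on 0-based half-open intervals; a peak overlapping
several gene windows contributes its full count to each of them. Gene sets
built from one projection method do not transfer to activity matrices built
with another (e.g. co-accessibility-based estimators), so sets should always
be built and applied on the same projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from intervaltree import IntervalTree

from .io import CountMatrix, GeneAnnotationRecord, parse_peak_name

logger = logging.getLogger("caracal")

DEFAULT_UPSTREAM_BP = 2000


@dataclass
class PeakInterval:
    """A peak's genomic interval (0-based half-open)."""

    peak_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.peak_id}: start {self.start} >= end {self.end}")


@dataclass
class GeneWindow:
    """The genomic window whose peaks are attributed to a gene."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"gene {self.gene}: negative window start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene}: start {self.start} >= end {self.end}")


def parse_peak_intervals(features: Sequence[str]) -> list[PeakInterval]:
    """Parse peak feature names into intervals, preserving order."""
    intervals = []
    for name in features:
        parsed = parse_peak_name(name)
        if parsed is None:
            raise ValueError(f"feature {name!r} does not parse as a peak (chrom:start-end)")
        intervals.append(PeakInterval(name, *parsed))
    return intervals


def build_gene_windows(
    annotations: Sequence[GeneAnnotationRecord],
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
) -> list[GeneWindow]:
    """Build one strand-aware window per gene.

    The gene body is extended ``upstream_bp`` bases upstream of the
    transcription start: on the + strand (and for unknown strand, treated
    as +) the window is [start - upstream_bp, end); on the - strand it is
    [start, end + upstream_bp). Starts are clipped at the chromosome
    origin. Duplicate gene names keep the longest annotation.
    """
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be non-negative")
    if not annotations:
        raise ValueError("empty annotation list")
    best: dict[str, GeneAnnotationRecord] = {}
    n_dups = 0
    for rec in annotations:
        prev = best.get(rec.gene_name)
        if prev is None:
            best[rec.gene_name] = rec
        else:
            n_dups += 1
            if rec.end - rec.start > prev.end - prev.start:
                best[rec.gene_name] = rec
    if n_dups:
        logger.warning("%d duplicate gene annotations resolved by keeping the longest", n_dups)
    windows = []
    for name, rec in best.items():
        if rec.strand == "-":
            start, end = rec.start, rec.end + upstream_bp
        else:
            start, end = rec.start - upstream_bp, rec.end
        windows.append(GeneWindow(name, rec.chrom, max(0, start), end))
    return windows


def compute_gene_activity(peaks: CountMatrix, windows: Sequence[GeneWindow]) -> CountMatrix:
    """Sum peak counts over each gene's window to get a gene x cell matrix.

    activity(g, c) = sum of counts(p, c) over peaks p overlapping window(g)
    on the same chromosome, with half-open overlap (p.start < w.end and
    w.start < p.end). A peak overlapping k windows contributes fully to all
    k genes; genes with no overlapping peak are kept as all-zero rows.
    """
    if peaks.feature_kind != "peak":
        raise ValueError("compute_gene_activity requires a peak-level CountMatrix")
    if not windows:
        raise ValueError("at least one gene window is required")
    intervals = parse_peak_intervals(peaks.features)

    trees: dict[str, IntervalTree] = {}
    for gi, w in enumerate(windows):
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, gi)

    rows: list[int] = []
    cols: list[int] = []
    for pi, p in enumerate(intervals):
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.start, p.end):
            rows.append(hit.data)
            cols.append(pi)
    assignment = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(windows), peaks.n_features),
    )
    values = assignment @ peaks.values
    if peaks.values.nnz and np.all(peaks.values.data == np.round(peaks.values.data)):
        values = values.astype(np.int64)
    return CountMatrix(
        features=[w.gene for w in windows],
        barcodes=list(peaks.barcodes),
        values=values,
        layer="raw",
        feature_kind="gene",
    )
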