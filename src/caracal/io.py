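"""Readers and writers for on-disk artifacts.

This module handles the file formats the pipeline consumes and produces:

* 10x-style Matrix Market count directories (``matrix.mtx[.gz]`` plus
  ``features.tsv[.gz]``/``genes.tsv[.gz]`` and ``barcodes.tsv[.gz]``),
* gene annotations in GTF or BED,
* weighted gene-set tables (a TSV dialect with per-gene weights; GMT is
  supported as an import-only convenience with unit weights),
* per-cell label tables and score matrices (CSV).

Peak features are named ``chrom:start-end`` (the ``chrom-start-end`` dialect
is also accepted). Peak coordinates embedded in feature names are treated as
0-based half-open, i.e. BED-style; GTF input is converted from 1-based
inclusive on read.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("caracal")

LAYERS = ("raw", "normalized", "scaled")
FEATURE_KINDS = ("gene", "peak")
DIRECTIONS = ("up", "down")

#: fraction of feature names that must parse as peaks for a matrix to be
#: classified as peak-level
PEAK_KIND_THRESHOLD = 0.9

# non-greedy chrom so "chr1-100-200" splits at the first separator that
# leaves two integer fields
_PEAK_NAME_RE = re.compile(r"^(.+?)[:\-](\d+)-(\d+)$")

GENE_SET_COLUMNS = ["cell_type", "direction", "gene", "weight"]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

def parse_peak_name(name: str) -> tuple[str, int, int] | None:
    """Parse a peak feature name into (chrom, start, end), or None.

    Accepts both ``chr1:100-200`` and ``chr1-100-200``. Coordinates are
    0-based half-open; names whose coordinates do not satisfy start < end
    are not peaks.
    """
    m = _PEAK_NAME_RE.match(name)
    if m is None:
        return None
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start >= end:
        return None
    return chrom, start, end


def _make_unique(names: Sequence[str], what: str) -> list[str]:
    """Disambiguate duplicate identifiers by suffixing ``.1``, ``.2``, ..."""
    seen: dict[str, int] = {}
    out: list[str] = []
    n_dups = 0
    for name in names:
        if name not in seen:
            seen[name] = 0
            out.append(name)
            continue
        n_dups += 1
        k = seen[name] + 1
        new = f"{name}.{k}"
        while new in seen:
            k += 1
            new = f"{name}.{k}"
        seen[name] = k
        seen[new] = 0
        out.append(new)
    if n_dups:
        logger.warning("%d duplicate %s identifiers disambiguated by suffixing", n_dups, what)
    return out


@dataclass
class CountMatrix:
    """Sparse feature x cell matrix with identifiers and a layer tag.

    ``values`` has shape (n_features, n_cells). The ``raw`` layer holds
    non-negative counts; ``normalized`` holds log-normalized values and
    ``scaled`` holds per-gene centered/scaled values (which may be negative).
    """

    features: list[str]
    barcodes: list[str]
    values: sp.spmatrix
    layer: str = "raw"
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        self.features = list(self.features)
        self.barcodes = list(self.barcodes)
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.features), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.barcodes)} barcodes"
            )
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature identifiers")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if self.layer == "raw" and self.values.nnz and self.values.data.min() < 0:
            raise ValueError("raw layer contains negative values")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.features)}

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()


@dataclass
class GeneAnnotationRecord:
    """One gene's genomic location (0-based half-open coordinates)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} >= end {self.end}")


@dataclass
class WeightedGeneSet:
    """A named, directional set of (gene, weight) pairs for one cell type."""

    cell_type: str
    direction: str
    members: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        self.members = [(str(g), float(w)) for g, w in self.members]
        genes = [g for g, _ in self.members]
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate genes in set {self.name}")
        for g, w in self.members:
            if not w > 0:
                raise ValueError(f"non-positive weight {w} for gene {g} in set {self.name}")

    @property
    def name(self) -> str:
        return f"{self.cell_type}:{self.direction}"

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.members], dtype=float)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# 10x-style Matrix Market directories
# ---------------------------------------------------------------------------

def _find_file(directory: Path, stems: Iterable[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / f"{stem}{suffix}"
            if p.is_file():
                return p
    raise FormatError(f"no file matching {list(stems)} (plain or .gz) in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id_column(path: Path) -> list[str]:
    """Read identifiers from a features/barcodes file.

    10x feature files may carry extra columns (id, name, type); the second
    column (the display name) is used when present, otherwise the first.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if df.shape[1] >= 2 and not df.iloc[:, 1].isna().any():
        return df.iloc[:, 1].tolist()
    return df.iloc[:, 0].tolist()


def infer_feature_kind(features: Sequence[str]) -> str:
    """Classify a feature list as 'peak' or 'gene' by parse rate."""
    if not features:
        return "gene"
    n_peaks = sum(parse_peak_name(f) is not None for f in features)
    return "peak" if n_peaks / len(features) >= PEAK_KIND_THRESHOLD else "gene"


def read_counts_10x(directory: str | Path) -> CountMatrix:
    """Read a 10x-style Matrix Market triplet directory as a raw CountMatrix.

    Feature kind is inferred from the feature names; duplicate identifiers
    are disambiguated by suffixing so the matrix shape is preserved.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    matrix_path = _find_file(directory, ["matrix.mtx"])
    features_path = _find_file(directory, ["features.tsv", "genes.tsv", "peaks.tsv"])
    barcodes_path = _find_file(directory, ["barcodes.tsv"])

    with (gzip.open(matrix_path, "rb") if matrix_path.suffix == ".gz" else open(matrix_path, "rb")) as fh:
        values = sp.csr_matrix(mmread(fh))
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    if values.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix {matrix_path.name} is {values.shape[0]}x{values.shape[1]} but "
            f"{len(features)} features and {len(barcodes)} barcodes were listed"
        )
    kind = infer_feature_kind(features)
    return CountMatrix(
        features=_make_unique(features, "feature"),
        barcodes=_make_unique(barcodes, "barcode"),
        values=values,
        layer="raw",
        feature_kind=kind,
    )


def write_counts_10x(m: CountMatrix, directory: str | Path) -> None:
    """Write a CountMatrix as an uncompressed Matrix Market triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    values = sp.coo_matrix(m.values)
    if m.layer == "raw" and np.all(values.data == np.round(values.data)):
        values = values.astype(np.int64)
    mmwrite(directory / "matrix.mtx", values)
    (directory / "features.tsv").write_text("".join(f"{f}\n" for f in m.features))
    (directory / "barcodes.tsv").write_text("".join(f"{b}\n" for b in m.barcodes))


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

_GTF_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')
_GTF_GENE_ID_BARE_RE = re.compile(r"gene_id\s+([^;\s]+)")
_GTF_GENE_NAME_RE = re.compile(r'gene_name "([^"]+)"')


def _parse_gtf(path: Path) -> list[GeneAnnotationRecord]:
    records: list[GeneAnnotationRecord] = []
    n_unknown_strand = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            m = _GTF_GENE_ID_RE.search(attrs) or _GTF_GENE_ID_BARE_RE.search(attrs)
            if m is None:
                raise FormatError(f"{path}: line {lineno}: gene record without gene_id")
            gene_id = m.group(1)
            name_m = _GTF_GENE_NAME_RE.search(attrs)
            gene_name = name_m.group(1) if name_m else gene_id
            # GTF is 1-based inclusive; convert to 0-based half-open
            start, end = start1 - 1, end1
            if strand not in ("+", "-"):
                n_unknown_strand += 1
                strand = "+"
            if start >= end:
                logger.warning("%s: line %d: dropping gene %s with empty interval", path, lineno, gene_id)
                continue
            records.append(GeneAnnotationRecord(gene_id, gene_name, chrom, start, end, strand))
    if n_unknown_strand:
        logger.warning("%d gene records with unknown strand treated as '+'", n_unknown_strand)
    return records


def _parse_bed(path: Path) -> list[GeneAnnotationRecord]:
    records: list[GeneAnnotationRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: BED gene records need >= 4 columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            if start >= end:
                logger.warning("%s: line %d: dropping record %s with empty interval", path, lineno, name)
                continue
            records.append(GeneAnnotationRecord(name, name, chrom, start, end, strand))
    return records


def read_gene_annotations(path: str | Path, format: str = "gtf") -> list[GeneAnnotationRecord]:
    """Read gene annotations from GTF or BED into 0-based half-open records."""
    path = Path(path)
    if format == "gtf":
        records = _parse_gtf(path)
    elif format == "bed":
        records = _parse_bed(path)
    else:
        raise ValueError(f"format must be 'gtf' or 'bed', got {format!r}")
    if not records:
        raise FormatError(f"{path}: zero usable gene records")
    return records


# ---------------------------------------------------------------------------
# weighted gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> list[WeightedGeneSet]:
    """Read weighted gene sets from the TSV dialect.

    The file must have header columns exactly ``cell_type, direction, gene,
    weight``. Rows are grouped by (cell_type, direction) preserving order of
    first appearance; member order within each set follows file order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"cell_type": str, "direction": str, "gene": str})
    if list(df.columns) != GENE_SET_COLUMNS:
        raise FormatError(
            f"{path}: expected header columns {GENE_SET_COLUMNS}, got {list(df.columns)}"
        )
    grouped: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rowno = i + 2  # 1-based, after the header line
        if row.direction not in DIRECTIONS:
            raise FormatError(f"{path}: row {rowno}: unknown direction {row.direction!r}")
        try:
            weight = float(row.weight)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {rowno}: unparseable weight {row.weight!r}") from exc
        if not weight > 0:
            raise FormatError(f"{path}: row {rowno}: non-positive weight {weight}")
        grouped.setdefault((row.cell_type, row.direction), []).append((row.gene, weight))
    sets = [WeightedGeneSet(ct, d, members) for (ct, d), members in grouped.items()]
    by_type: dict[str, dict[str, set[str]]] = {}
    for s in sets:
        by_type.setdefault(s.cell_type, {})[s.direction] = set(s.genes)
    for ct, dirs in by_type.items():
        shared = dirs.get("up", set()) & dirs.get("down", set())
        if shared:
            raise FormatError(
                f"{path}: cell type {ct}: genes in both up and down sets: {sorted(shared)[:5]}"
            )
    return sets


def write_gene_sets(sets: Sequence[WeightedGeneSet], path: str | Path) -> None:
    """Write weighted gene sets as TSV (round-trip stable with read_gene_sets)."""
    rows = [
        {"cell_type": s.cell_type, "direction": s.direction, "gene": g, "weight": repr(w)}
        for s in sets
        for g, w in s.members
    ]
    pd.DataFrame(rows, columns=GENE_SET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, direction: str = "up") -> list[WeightedGeneSet]:
    """Import GMT gene sets with unit weights (GMT carries no weights)."""
    sets = []
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT rows need name, description, genes")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(WeightedGeneSet(name, direction, [(g, 1.0) for g in genes]))
    return sets


# ---------------------------------------------------------------------------
# label tables and score matrices
# ---------------------------------------------------------------------------

LABEL_COLUMNS = ["barcode", "label", "top_score", "margin", "tie"]


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"barcode": str, "label": str})
    missing = [c for c in ("barcode", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing label columns {missing}")
    return df


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (barcode, label) text file into a mapping.

    A header row is optional; comma or tab delimiters are accepted.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (barcode, label)")
    first = str(df.iloc[0, 0]).strip().lower()
    if first in ("barcode", "cell", "cell_id"):
        df = df.iloc[1:]
    if df.empty:
        raise FormatError(f"{path}: no label rows")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_score_frame(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a cell x column score matrix as CSV with a ``barcode`` column."""
    scores.rename_axis("barcode").to_csv(path)


def read_score_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "barcode" not in df.columns:
        raise FormatError(f"{path}: missing 'barcode' column")
    return df.set_index("barcode")
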