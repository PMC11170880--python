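"""Cell-type scoring, labeling, multimodal integration and evaluation.

Each cell type carries an up-regulated and (optionally) a down-regulated
weighted gene set. The per-type score for a cell combines both directions:

    combined = up_score + (1 - down_score)

so a cell strongly enriched for the up-program and depleted of the
down-program approaches 2, and the combined score lives in [0, 2]. When a
down-set could not be built the down score is pinned to 1 (contributing 0)
and the type is flagged as up-only.

Cells are labeled with their top-scoring type; ATAC-derived scores can
gate RNA-derived scores by multiplying the RNA score with an indicator of
the ATAC score strictly exceeding its per-type median over all cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LABEL_COLUMNS, CountMatrix, WeightedGeneSet
from .vam import VamParameters, score_gene_sets

logger = logging.getLogger("caracal")

UNASSIGNED_LABEL = "unassigned"


@dataclass
class CellTypeScores:
    """Per-cell per-cell-type up, down and combined scores."""

    barcodes: list[str]
    cell_types: list[str]
    up: np.ndarray  # cells x types, in [0, 1]
    down: np.ndarray  # cells x types, in [0, 1]; 1 where the down-set is absent
    combined: np.ndarray  # cells x types, in [0, 2]
    up_only: set[str] = field(default_factory=set)

    def combined_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.combined, index=self.barcodes, columns=self.cell_types)

    def to_frame(self) -> pd.DataFrame:
        """Wide per-cell table with ``type:up``, ``type:down``, ``type:combined``."""
        data = {}
        for j, ct in enumerate(self.cell_types):
            data[f"{ct}:up"] = self.up[:, j]
            data[f"{ct}:down"] = self.down[:, j]
            data[f"{ct}:combined"] = self.combined[:, j]
        return pd.DataFrame(data, index=self.barcodes)


def combine_up_down(up, down):
    """Combine direction scores: up + (1 - down), elementwise, in [0, 2]."""
    up = np.asarray(up, dtype=float)
    down = np.asarray(down, dtype=float)
    if np.any((up < 0) | (up > 1)) or np.any((down < 0) | (down > 1)):
        raise ValueError("direction scores must lie in [0, 1]")
    out = up + (1.0 - down)
    return float(out) if out.ndim == 0 else out


def score_cell_types(
    m: CountMatrix,
    sets: Sequence[WeightedGeneSet],
    params: VamParameters,
) -> CellTypeScores:
    """Score every cell for every cell type from its up/down gene sets.

    Every cell type must have a non-empty up-set; empty sets are treated
    as absent. Missing down-sets pin the down score at 1.
    """
    by_type: dict[str, dict[str, WeightedGeneSet]] = {}
    for s in sets:
        if len(s) == 0:
            logger.warning("ignoring empty gene set %s", s.name)
            continue
        if s.direction in by_type.setdefault(s.cell_type, {}):
            raise ValueError(f"duplicate {s.direction}-set for cell type {s.cell_type}")
        by_type[s.cell_type][s.direction] = s
    if not by_type:
        raise ValueError("no non-empty gene sets supplied")
    missing_up = [ct for ct, d in by_type.items() if "up" not in d]
    if missing_up:
        raise ValueError(f"cell types without an up-regulated set: {sorted(missing_up)}")

    cell_types = sorted(by_type)
    scorable = [by_type[ct][d] for ct in cell_types for d in ("up", "down") if d in by_type[ct]]
    vam = score_gene_sets(m, scorable, params)
    col = {name: j for j, name in enumerate(vam.set_names)}

    n = m.n_cells
    up = np.empty((n, len(cell_types)))
    down = np.ones((n, len(cell_types)))
    up_only = set()
    for j, ct in enumerate(cell_types):
        up[:, j] = vam.scores[:, col[f"{ct}:up"]]
        if f"{ct}:down" in col:
            down[:, j] = vam.scores[:, col[f"{ct}:down"]]
        else:
            up_only.add(ct)
            logger.warning("cell type %s scored from its up-set only", ct)
    combined = combine_up_down(up, down)
    return CellTypeScores(
        barcodes=list(m.barcodes),
        cell_types=cell_types,
        up=up,
        down=down,
        combined=combined,
        up_only=up_only,
    )


def assign_labels(scores: CellTypeScores, min_score: float = 0.0) -> pd.DataFrame:
    """Label each cell with its top-scoring cell type.

    Exact ties resolve to the lexicographically smallest type and are
    flagged; cells whose top score falls below ``min_score`` are labeled
    'unassigned'. Returns a table with columns barcode, label, top_score,
    margin, tie.
    """
    if not scores.cell_types:
        raise ValueError("no cell types to assign")
    combined = scores.combined
    order = np.argsort(scores.cell_types)  # lexicographic tie preference
    types_sorted = [scores.cell_types[i] for i in order]
    c = combined[:, order]
    best = np.argmax(c, axis=1)  # first occurrence = lexicographically smallest
    top = c[np.arange(c.shape[0]), best]
    ties = (c == top[:, None]).sum(axis=1) > 1
    if c.shape[1] > 1:
        part = np.partition(c, -2, axis=1)
        second = part[:, -2]
    else:
        second = top
    margin = top - second
    rows = []
    for i, b in enumerate(scores.barcodes):
        label = types_sorted[best[i]]
        if top[i] < min_score:
            label = UNASSIGNED_LABEL
        rows.append((b, label, float(top[i]), float(margin[i]), bool(ties[i])))
    return pd.DataFrame(rows, columns=LABEL_COLUMNS)


def integrate_scores(
    rna_scores: pd.DataFrame,
    atac_scores: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gate RNA-derived scores by ATAC-derived scores.

    out(i, j) = rna(i, j) * [atac(i, j) > median_j], where median_j is the
    median ATAC score of cell type j over all cells. The inequality is
    strict: scores exactly at the median gate to zero. Returns the gated
    matrix and the per-type medians.
    """
    if set(rna_scores.index) != set(atac_scores.index):
        raise ValueError("RNA and ATAC score matrices cover different barcodes")
    if set(rna_scores.columns) != set(atac_scores.columns):
        raise ValueError("RNA and ATAC score matrices cover different cell types")
    atac = atac_scores.reindex(index=rna_scores.index, columns=rna_scores.columns)
    medians = atac.median(axis=0)
    gated = rna_scores * (atac.gt(medians, axis=1)).astype(float)
    return gated, medians


@dataclass
class EvaluationReport:
    """Label agreement between predictions and a reference labeling."""

    confusion: pd.DataFrame  # truth labels (rows) x predicted labels (columns)
    agreement: float
    n_shared: int
    n_only_predicted: int
    n_only_truth: int


def evaluate_labels(predicted: pd.DataFrame, truth: Mapping[str, str]) -> EvaluationReport:
    """Compare a label table to reference labels over shared barcodes.

    The confusion matrix spans the union of both label vocabularies;
    agreement is the fraction of shared cells whose predicted label equals
    the reference label. Cells present on only one side are excluded and
    counted.
    """
    pred_map = dict(zip(predicted["barcode"], predicted["label"]))
    shared = [b for b in pred_map if b in truth]
    if not shared:
        raise ValueError("no barcodes shared between predictions and reference labels")
    n_only_pred = len(pred_map) - len(shared)
    n_only_truth = len(truth) - len(shared)
    if n_only_pred or n_only_truth:
        logger.info(
            "evaluation excludes %d predicted-only and %d reference-only cells",
            n_only_pred, n_only_truth,
        )
    t = pd.Series([truth[b] for b in shared], name="truth")
    p = pd.Series([pred_map[b] for b in shared], name="predicted")
    vocab = sorted(set(t) | set(p))
    confusion = (
        pd.crosstab(t, p)
        .reindex(index=vocab, columns=vocab, fill_value=0)
        .astype(int)
    )
    agreement = float((t.values == p.values).mean())
    return EvaluationReport(
        confusion=confusion,
        agreement=agreement,
        n_shared=len(shared),
        n_only_predicted=n_only_pred,
        n_only_truth=n_only_truth,
    )
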