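"""Quality filtering, log-normalization, variable-feature selection, scaling.

The preprocessing mirrors the standard single-cell workflow: cells are
filtered on total counts and detected-feature counts, features on the
number of cells expressing them; counts are library-size log-normalized
(ln(1 + v * scale_factor / total)); the most variable features are chosen
by binned-dispersion z-score; and selected features can be centered and
scaled per gene with clipping.

Gene-set scoring downstream operates on the normalized layer by default
(the scoring distance is anchored at zero, which centering would destroy);
the scaled layer exists for visualization-style workflows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix

logger = logging.getLogger("caracal")

DEFAULT_SCALE_FACTOR = 1e4
DEFAULT_N_VARIABLE = 2000
DEFAULT_CLIP = 10.0
N_DISPERSION_BINS = 20


@dataclass
class FilterReport:
    """Cell/feature counts before and after a filtering step."""

    cells_in: int
    cells_kept: int
    features_in: int
    features_kept: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cells_kept > self.cells_in or self.features_kept > self.features_in:
            raise ValueError("kept counts exceed input counts")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def filter_cells(
    m: CountMatrix,
    min_counts: int | None = None,
    max_counts: int | None = None,
    min_features: int | None = None,
) -> tuple[CountMatrix, FilterReport]:
    """Keep cells by total counts and number of detected features."""
    if m.layer != "raw":
        raise ValueError("filter_cells expects the raw layer")
    values = m.values.copy()
    values.eliminate_zeros()
    totals = np.asarray(values.sum(axis=0)).ravel()
    n_feats = values.getnnz(axis=0)
    keep = np.ones(m.n_cells, dtype=bool)
    if min_counts is not None:
        keep &= totals >= min_counts
    if max_counts is not None:
        keep &= totals <= max_counts
    if min_features is not None:
        keep &= n_feats >= min_features
    if not keep.any():
        raise ValueError("all cells removed; review the filtering thresholds")
    kept_idx = np.flatnonzero(keep)
    out = CountMatrix(
        features=list(m.features),
        barcodes=[m.barcodes[i] for i in kept_idx],
        values=m.values[:, kept_idx],
        layer="raw",
        feature_kind=m.feature_kind,
    )
    report = FilterReport(
        cells_in=m.n_cells,
        cells_kept=int(keep.sum()),
        features_in=m.n_features,
        features_kept=m.n_features,
        thresholds={"min_counts": min_counts, "max_counts": max_counts, "min_features": min_features},
    )
    logger.info("filter_cells kept %d/%d cells", report.cells_kept, report.cells_in)
    return out, report


def filter_features(m: CountMatrix, min_cells: int) -> tuple[CountMatrix, FilterReport]:
    """Keep features with nonzero counts in at least ``min_cells`` cells."""
    if m.layer != "raw":
        raise ValueError("filter_features expects the raw layer")
    values = m.values.copy()
    values.eliminate_zeros()
    n_cells_per_feat = values.getnnz(axis=1)
    keep = n_cells_per_feat >= min_cells
    if not keep.any():
        raise ValueError("all features removed; review min_cells")
    kept_idx = np.flatnonzero(keep)
    out = CountMatrix(
        features=[m.features[i] for i in kept_idx],
        barcodes=list(m.barcodes),
        values=m.values[kept_idx, :],
        layer="raw",
        feature_kind=m.feature_kind,
    )
    report = FilterReport(
        cells_in=m.n_cells,
        cells_kept=m.n_cells,
        features_in=m.n_features,
        features_kept=int(keep.sum()),
        thresholds={"min_cells": min_cells},
    )
    logger.info("filter_features kept %d/%d features", report.features_kept, report.features_in)
    return out, report


def log_normalize(m: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR) -> CountMatrix:
    """Library-size normalize and natural-log transform.

    v -> ln(1 + v * scale_factor / T) where T is the cell's total count.
    All-zero cells map to all zeros.
    """
    if m.layer != "raw":
        raise ValueError("log_normalize expects the raw layer")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.cell_totals()
    factors = np.zeros_like(totals, dtype=float)
    nonzero = totals > 0
    factors[nonzero] = scale_factor / totals[nonzero]
    values = m.values.astype(float) @ sp.diags(factors)
    values = values.log1p()
    return CountMatrix(
        features=list(m.features),
        barcodes=list(m.barcodes),
        values=values,
        layer="normalized",
        feature_kind=m.feature_kind,
    )


def _row_mean_var(values: sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and unbiased sample variance across cells."""
    n = values.shape[1]
    mean = np.asarray(values.mean(axis=1)).ravel()
    sq = np.asarray(values.multiply(values).sum(axis=1)).ravel()
    if n > 1:
        var = (sq - n * mean**2) / (n - 1)
    else:
        var = np.zeros_like(mean)
    return mean, np.maximum(var, 0.0)


def select_variable_features(m: CountMatrix, n: int = DEFAULT_N_VARIABLE) -> list[str]:
    """Rank features by binned-dispersion z-score and return the top ``n``.

    Features with positive variance are binned into up to 20 equal-occupancy
    bins by mean normalized value; within each bin the dispersion
    (variance / mean) is z-scored. The bin count shrinks for small inputs so
    every bin has at least ~20 members. Ties are broken by feature order.
    """
    if m.layer != "normalized":
        raise ValueError("select_variable_features expects the normalized layer")
    if n < 1:
        raise ValueError("n must be >= 1")
    mean, var = _row_mean_var(m.values)
    candidates = np.flatnonzero((var > 0) & (mean > 0))
    if candidates.size == 0:
        return []
    dispersion = var[candidates] / mean[candidates]
    k = candidates.size
    n_bins = int(np.clip(k // N_DISPERSION_BINS, 1, N_DISPERSION_BINS))
    order = np.argsort(mean[candidates], kind="stable")
    ranks = np.empty(k, dtype=int)
    ranks[order] = np.arange(k)
    bins = (ranks * n_bins) // k
    z = np.zeros(k)
    for b in range(n_bins):
        in_bin = bins == b
        d = dispersion[in_bin]
        sd = d.std()
        if sd > 0:
            z[in_bin] = (d - d.mean()) / sd
    top = np.argsort(-z, kind="stable")[: min(n, k)]
    return [m.features[candidates[i]] for i in top]


def scale_center(m: CountMatrix, features: list[str], clip: float = DEFAULT_CLIP) -> CountMatrix:
    """Restrict to ``features`` and center/scale each gene to mean 0, sd 1.

    Zero-variance genes become all-zero rows; values are clipped to
    [-clip, clip].
    """
    if m.layer != "normalized":
        raise ValueError("scale_center expects the normalized layer")
    if not features:
        raise ValueError("empty feature list")
    index = m.feature_index()
    missing = [f for f in features if f not in index]
    if missing:
        raise ValueError(f"features not in matrix: {missing[:5]}")
    idx = [index[f] for f in features]
    X = np.asarray(m.values[idx, :].todense(), dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True) if X.shape[1] > 1 else np.zeros_like(mean)
    X = X - mean
    nonconstant = (sd > 0).ravel()
    X[nonconstant] /= sd[nonconstant]
    X[~nonconstant] = 0.0
    np.clip(X, -clip, clip, out=X)
    return CountMatrix(
        features=list(features),
        barcodes=list(m.barcodes),
        values=sp.csr_matrix(X),
        layer="scaled",
        feature_kind=m.feature_kind,
    )
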