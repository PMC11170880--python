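"""Synthetic cell-type-structured gene-activity data with planted programs.

The generator draws a gene x cell matrix of negative-binomial counts in
which each cell type carries a planted program: its up-marker genes have
their mean multiplied by ``effect_fold`` and its down-marker genes divided
by it, all other genes sit at the baseline. Marker sets are disjoint
across types and directions, so the planted truth doubles as a reference
answer for gene-set recovery and end-to-end labeling tests.

With ``peak_mode`` the generator also emits a consistent peak-level
matrix: every gene gets 1-3 synthetic peaks placed wholly inside its
activity window (gene body + 2 kb upstream on a synthetic chromosome with
non-overlapping windows), and each cell's gene count is distributed among
the gene's peaks multinomially. Summing peak counts back over the default
windows therefore reproduces the activity matrix exactly.

The negative binomial is parameterized by mean mu and dispersion (size) r
with variance mu + mu^2 / r, the standard over-dispersed model for sparse,
noisy single-cell counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, GeneAnnotationRecord, WeightedGeneSet

logger = logging.getLogger("caracal")

#: gene body length and spacing on the synthetic chromosome (peak_mode)
_GENE_BODY_BP = 5000
_GENE_SPACING_BP = 10000
_UPSTREAM_BP = 2000
_PEAK_WIDTH_BP = 500
_PEAK_STRIDE_BP = 1500


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic dataset."""

    n_cell_types: int = 3
    cells_per_type: int = 200
    n_genes: int = 2000
    n_up_markers: int = 100
    n_down_markers: int = 100
    effect_fold: float = 4.0
    baseline_mean: float = 2.0
    dispersion: float = 2.0
    peak_mode: bool = False
    seed: int = 7
    #: seed for the marker-gene assignment; None reuses ``seed``. Replicates
    #: of one population share structure_seed but differ in seed.
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.cells_per_type < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        needed = self.n_cell_types * (self.n_up_markers + self.n_down_markers)
        if needed > self.n_genes:
            raise ValueError(
                f"disjoint marker sets need {needed} genes but only {self.n_genes} available"
            )


@dataclass
class SimulatedDataset:
    """A generated dataset plus its ground truth."""

    activity: CountMatrix
    truth_labels: dict[str, str]
    planted: list[WeightedGeneSet]
    annotations: list[GeneAnnotationRecord]
    peaks: CountMatrix | None = None
    config: SimulationConfig | None = None


FIXTURES: Mapping[str, SimulationConfig] = {
    # fast unit-test fixture; peak_mode exercises the projection round-trip
    "tiny": SimulationConfig(
        n_cell_types=2, cells_per_type=20, n_genes=50,
        n_up_markers=8, n_down_markers=8, effect_fold=4.0,
        baseline_mean=2.0, dispersion=2.0, peak_mode=True, seed=42,
    ),
    # pure noise: no planted structure, for null-calibration checks
    "null": SimulationConfig(
        n_cell_types=4, cells_per_type=500, n_genes=500,
        n_up_markers=50, n_down_markers=50, effect_fold=1.0,
        baseline_mean=2.0, dispersion=2.0, peak_mode=False, seed=11,
    ),
    # the default study conditions for recovery and end-to-end tests
    "benchmark": SimulationConfig(
        n_cell_types=3, cells_per_type=200, n_genes=2000,
        n_up_markers=100, n_down_markers=100, effect_fold=4.0,
        baseline_mean=2.0, dispersion=2.0, peak_mode=False, seed=7,
    ),
}


def _synthetic_annotations(gene_names: list[str]) -> list[GeneAnnotationRecord]:
    records = []
    for g, name in enumerate(gene_names):
        start = _UPSTREAM_BP + g * _GENE_SPACING_BP
        records.append(
            GeneAnnotationRecord(name, name, "chrS", start, start + _GENE_BODY_BP, "+")
        )
    return records


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset under ``config`` (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    n_types, n_cells_per, n_genes = config.n_cell_types, config.cells_per_type, config.n_genes
    n_cells = n_types * n_cells_per
    gene_names = [f"G{g:05d}" for g in range(n_genes)]
    type_names = [f"type{t}" for t in range(n_types)]
    barcodes = [f"cell{t}_{i:04d}" for t in range(n_types) for i in range(n_cells_per)]
    cell_type_of = np.repeat(np.arange(n_types), n_cells_per)

    # disjoint marker assignment over a seeded permutation of the genes;
    # the structural seed is separate so replicates can share their planted
    # programs while redrawing counts
    struct_seed = config.seed if config.structure_seed is None else config.structure_seed
    perm = np.random.default_rng(struct_seed).permutation(n_genes)
    up_markers, down_markers = [], []
    cursor = 0
    for _ in range(n_types):
        up_markers.append(perm[cursor : cursor + config.n_up_markers])
        cursor += config.n_up_markers
        down_markers.append(perm[cursor : cursor + config.n_down_markers])
        cursor += config.n_down_markers

    # per-type mean matrix: baseline times fold^{+1/-1/0}
    mu = np.full((n_genes, n_types), config.baseline_mean)
    for t in range(n_types):
        mu[up_markers[t], t] *= config.effect_fold
        mu[down_markers[t], t] /= config.effect_fold

    r = config.dispersion
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    for t in range(n_types):
        cols = cell_type_of == t
        mu_t = mu[:, t][:, None]
        p = r / (r + mu_t)
        counts[:, cols] = rng.negative_binomial(r, p, size=(n_genes, int(cols.sum())))

    activity = CountMatrix(
        features=gene_names,
        barcodes=barcodes,
        values=sp.csr_matrix(counts),
        layer="raw",
        feature_kind="gene",
    )
    truth = {b: type_names[cell_type_of[i]] for i, b in enumerate(barcodes)}
    # planted sets carry the generative effect as weight; under a null
    # (effect_fold == 1) unit weights keep the sets well-formed
    w = float(np.log2(config.effect_fold)) if config.effect_fold > 1 else 1.0
    planted = []
    for t, name in enumerate(type_names):
        planted.append(WeightedGeneSet(name, "up", [(gene_names[g], w) for g in sorted(up_markers[t])]))
        planted.append(WeightedGeneSet(name, "down", [(gene_names[g], w) for g in sorted(down_markers[t])]))
    annotations = _synthetic_annotations(gene_names)

    peaks = None
    if config.peak_mode:
        peaks = _emit_peaks(counts, gene_names, barcodes, annotations, rng)
    return SimulatedDataset(
        activity=activity,
        truth_labels=truth,
        planted=planted,
        annotations=annotations,
        peaks=peaks,
        config=config,
    )


def _emit_peaks(
    counts: np.ndarray,
    gene_names: list[str],
    barcodes: list[str],
    annotations: list[GeneAnnotationRecord],
    rng: np.random.Generator,
) -> CountMatrix:
    """Distribute each gene's counts multinomially over 1-3 in-window peaks."""
    peak_names: list[str] = []
    blocks: list[np.ndarray] = []
    for g, rec in enumerate(annotations):
        window_start = rec.start - _UPSTREAM_BP
        k = int(rng.integers(1, 4))
        for j in range(k):
            s = window_start + j * _PEAK_STRIDE_BP
            peak_names.append(f"{rec.chrom}:{s}-{s + _PEAK_WIDTH_BP}")
        pvals = np.full(k, 1.0 / k)
        split = rng.multinomial(counts[g], pvals)  # cells x k
        blocks.append(split.T)  # k x cells
    values = sp.csr_matrix(np.vstack(blocks))
    return CountMatrix(
        features=peak_names,
        barcodes=list(barcodes),
        values=values,
        layer="raw",
        feature_kind="peak",
    )


def make_fixture(name: str) -> SimulatedDataset:
    """Generate one of the named fixtures: 'tiny', 'null' or 'benchmark'."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return simulate_dataset(FIXTURES[name])


def benchmark_replicate(seed: int) -> SimulatedDataset:
    """The benchmark population re-sampled under a different seed.

    The planted programs (marker assignment) are shared with the
    'benchmark' fixture; only the count noise is redrawn.
    """
    base = FIXTURES["benchmark"]
    return simulate_dataset(replace(base, seed=seed, structure_seed=base.seed))
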