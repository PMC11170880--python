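"""Differential gene activity and weighted gene-set construction.

Cell-type signatures are built from a labeled reference gene-activity
matrix by one-vs-rest differential testing: for each cell type, every
gene is compared between the type's cells and all remaining cells with a
two-sided Wilcoxon rank-sum (Mann-Whitney) test, and a log2 fold-change is
computed on back-transformed normalized means. The up-regulated set is the
``n_genes`` genes with the largest positive log2FC, the down-regulated set
the ``n_genes`` most negative; each member is weighted by |log2FC|.

The default set size of 100 genes per direction is deliberately generous:
projected gene activity is noisier and sparser than measured expression,
so larger sets buy robustness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import CountMatrix, WeightedGeneSet

logger = logging.getLogger("caracal")

DEFAULT_N_GENES = 100
DEFAULT_MIN_PCT = 0.01
EXACT_MAX_GROUP = 8  # exact null enumeration when min group size <= this


@dataclass
class DifferentialActivityRecord:
    """One gene's one-vs-rest differential-activity result."""

    gene: str
    cell_type: str
    log2fc: float
    p_value: float
    adj_p_value: float
    pct_in: float
    pct_out: float


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _exact_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by dynamic programming over midranks.

    Midranks are doubled so all arithmetic is integral; the distribution of
    the doubled rank-sum over all equally likely group assignments is built
    by subset-sum convolution. The two-sided p-value is the probability of
    a |U - nm/2| deviation at least as large as observed (the permutation
    distribution of U is symmetric about nm/2).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(np.int64)
    obs_sum2 = int(ranks2[:n1].sum())
    # 2*U1 = (doubled rank-sum of x) - n1*(n1+1)
    dev_obs = abs(obs_sum2 - n1 * (n1 + 1) - n1 * n2)

    total2 = int(ranks2.sum())
    # counts[k, s] = number of size-k subsets of the pooled doubled ranks
    # summing to s; float64 is exact below 2^53
    counts = np.zeros((n1 + 1, total2 + 1))
    counts[0, 0] = 1.0
    for r in ranks2:
        # descending k so each pooled value is used at most once per subset
        for k in range(n1 - 1, -1, -1):
            counts[k + 1, r:] += counts[k, : total2 + 1 - r]
    dist = counts[n1]
    sums = np.arange(total2 + 1)
    dev = np.abs(sums - n1 * (n1 + 1) - n1 * n2)
    n_extreme = dist[dev >= dev_obs].sum()
    n_total = dist.sum()
    u1 = (obs_sum2 - n1 * (n1 + 1)) / 2.0
    return u1, min(1.0, float(n_extreme / n_total))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks.

    Returns (U statistic of ``x``, two-sided p-value). When the smaller
    group has more than 8 observations the tie-corrected normal
    approximation with continuity correction is used; otherwise the exact
    permutation null is enumerated (ties handled via midranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return x.size * y.size / 2.0, 1.0
    if min(x.size, y.size) > EXACT_MAX_GROUP:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return float(res.statistic), float(res.pvalue)
    return _exact_mwu(x, y)


# ---------------------------------------------------------------------------
# one-vs-rest differential activity
# ---------------------------------------------------------------------------

def differential_activity(
    m: CountMatrix,
    labels: Mapping[str, str],
    target: str,
    min_pct: float = DEFAULT_MIN_PCT,
) -> list[DifferentialActivityRecord]:
    """One-vs-rest differential activity of ``target`` cells vs all others.

    log2FC = log2((mean(expm1(v_in)) + 1) / (mean(expm1(v_out)) + 1)) on
    normalized values; p-values from the Wilcoxon rank-sum test, Bonferroni
    adjusted over tested genes. Genes are tested only when nonzero in at
    least ``min_pct`` of either group.
    """
    if m.layer != "normalized":
        raise ValueError("differential_activity expects the normalized layer")
    labeled = [i for i, b in enumerate(m.barcodes) if b in labels]
    if not labeled:
        raise ValueError("no barcodes shared between matrix and labels")
    cell_labels = np.array([labels[m.barcodes[i]] for i in labeled])
    if len(set(cell_labels)) < 2:
        raise ValueError("differential testing needs at least two distinct labels")
    if target not in set(cell_labels):
        raise ValueError(f"target cell type {target!r} not present in labels")

    X = np.asarray(m.values[:, labeled].todense(), dtype=float)
    in_mask = cell_labels == target
    Xin, Xout = X[:, in_mask], X[:, ~in_mask]
    n_in, n_out = Xin.shape[1], Xout.shape[1]

    pct_in = (Xin > 0).mean(axis=1)
    pct_out = (Xout > 0).mean(axis=1)
    tested = np.flatnonzero((pct_in >= min_pct) | (pct_out >= min_pct))
    if tested.size == 0:
        return []

    mean_in = np.expm1(Xin[tested]).mean(axis=1)
    mean_out = np.expm1(Xout[tested]).mean(axis=1)
    log2fc = np.log2((mean_in + 1) / (mean_out + 1))

    if min(n_in, n_out) > EXACT_MAX_GROUP:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                Xin[tested],
                Xout[tested],
                axis=1,
                alternative="two-sided",
                method="asymptotic",
                use_continuity=True,
            )
        pvals = np.asarray(res.pvalue, dtype=float)
        constant = np.ptp(X[tested], axis=1) == 0
        pvals[constant | ~np.isfinite(pvals)] = 1.0
    else:
        pvals = np.array([wilcoxon_rank_sum(Xin[g], Xout[g])[1] for g in tested])

    n_tested = tested.size
    adj = np.minimum(1.0, pvals * n_tested)
    return [
        DifferentialActivityRecord(
            gene=m.features[g],
            cell_type=target,
            log2fc=float(log2fc[k]),
            p_value=float(pvals[k]),
            adj_p_value=float(adj[k]),
            pct_in=float(pct_in[g]),
            pct_out=float(pct_out[g]),
        )
        for k, g in enumerate(tested)
    ]


# ---------------------------------------------------------------------------
# gene-set construction
# ---------------------------------------------------------------------------

def build_cell_type_gene_sets(
    records_by_type: Mapping[str, Sequence[DifferentialActivityRecord]],
    n_genes: int = DEFAULT_N_GENES,
    weight_scale: str = "log2fc",
) -> list[WeightedGeneSet]:
    """Build up/down weighted gene sets from differential-activity records.

    Per cell type the up-set holds the ``n_genes`` largest positive-log2FC
    genes and the down-set the ``n_genes`` most negative; weights are
    |log2FC| (or the raw fold-change 2**|log2FC| with
    ``weight_scale='fc'``). Ties in log2FC break by smaller p-value, then
    lexicographic gene id. Types with fewer qualifying genes get smaller
    sets (with a warning); a direction with no qualifying genes yields an
    empty set, which the scoring layer treats as absent.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if weight_scale not in ("log2fc", "fc"):
        raise ValueError("weight_scale must be 'log2fc' or 'fc'")
    sets: list[WeightedGeneSet] = []
    for cell_type, records in records_by_type.items():
        for direction in ("up", "down"):
            if direction == "up":
                qualifying = [r for r in records if r.log2fc > 0]
            else:
                qualifying = [r for r in records if r.log2fc < 0]
            qualifying.sort(key=lambda r: (-abs(r.log2fc), r.p_value, r.gene))
            chosen = qualifying[:n_genes]
            if not chosen:
                logger.warning("cell type %s: no %s-regulated genes; empty set", cell_type, direction)
            elif len(chosen) < n_genes:
                logger.warning(
                    "cell type %s: only %d %s-regulated genes (requested %d)",
                    cell_type, len(chosen), direction, n_genes,
                )
            members = []
            for r in chosen:
                w = abs(r.log2fc) if weight_scale == "log2fc" else 2 ** abs(r.log2fc)
                members.append((r.gene, w))
            sets.append(WeightedGeneSet(cell_type, direction, members))
    return sets


def build_gene_sets_from_reference(
    m: CountMatrix,
    labels: Mapping[str, str],
    n_genes: int = DEFAULT_N_GENES,
    min_pct: float = DEFAULT_MIN_PCT,
    weight_scale: str = "log2fc",
) -> list[WeightedGeneSet]:
    """Run one-vs-rest differential activity for every label and build sets."""
    present = sorted({labels[b] for b in m.barcodes if b in labels})
    records = {
        ct: differential_activity(m, labels, ct, min_pct=min_pct) for ct in present
    }
    return build_cell_type_gene_sets(records, n_genes=n_genes, weight_scale=weight_scale)
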