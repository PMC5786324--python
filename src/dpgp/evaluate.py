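"""Scoring of clusterings and of predictive credible intervals.

Rand and Adjusted Rand indices are computed from the contingency-table closed
form (Hubert-Arabie adjustment).  Held-out time-point evaluation scores the
proportion of true values covered by the 95% predictive band of each gene's
assigned cluster, together with a permutation baseline in which the
gene-to-cluster map is shuffled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gp import DataError
from .io import ExpressionMatrix
from .sampler import DPConfig, run_sampler
from .simulate import SimulatedDataset, heldout_column, holdout_middle_timepoints
from .summarize import (ClusteringResult, build_psm, cluster_credible_bands,
                        inclusion_probabilities, select_map_partition)

logger = logging.getLogger("dpgp")


def _labels(p) -> np.ndarray:
    """Accept a Partition, array or sequence of labels."""
    a = getattr(p, "assignments", p)
    return np.asarray(a)


# ---------------------------------------------------------------------------
# Rand / Adjusted Rand indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairCounts:
    """Pairwise agreement counts between two partitions of N elements."""

    a: int        # pairs together in both
    b: int        # pairs apart in both
    N: int

    @property
    def total_pairs(self) -> int:
        return self.N * (self.N - 1) // 2


def _contingency(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    _, i1 = np.unique(p1, return_inverse=True)
    _, i2 = np.unique(p2, return_inverse=True)
    table = np.zeros((i1.max() + 1, i2.max() + 1), dtype=np.int64)
    np.add.at(table, (i1, i2), 1)
    return table

def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) // 2


def pair_counts(p1, p2) -> PairCounts:
    """Exact pair agreement counts from the contingency table."""
    p1, p2 = _labels(p1), _labels(p2)
    if p1.shape != p2.shape:
        raise DataError("partitions must cover identical element sets")
    N = p1.size
    table = _contingency(p1, p2)
    a = int(_comb2(table).sum())
    same1 = int(_comb2(table.sum(axis=1)).sum())
    same2 = int(_comb2(table.sum(axis=0)).sum())
    total = N * (N - 1) // 2
    b = total - same1 - same2 + a
    return PairCounts(a, b, N)


def rand_index(p1, p2) -> float:
    """RI = (a + b) / C(N, 2): fraction of element pairs on which the two
    partitions agree."""
    pc = pair_counts(p1, p2)
    if pc.total_pairs == 0:
        return 1.0
    return (pc.a + pc.b) / pc.total_pairs


def adjusted_rand_index(p1, p2) -> float:
    """Chance-corrected Rand index (Hubert-Arabie).

    (RI - E[RI]) / (max(RI) - E[RI]) with the expectation under the
    hypergeometric model and max realized as the average of the two marginal
    pair sums.  Equals 1 iff the partitions are identical up to relabeling;
    ~0 for independent partitions.
    """
    p1, p2 = _labels(p1), _labels(p2)
    if p1.shape != p2.shape:
        raise DataError("partitions must cover identical element sets")
    table = _contingency(p1, p2)
    n = p1.size
    sum_ij = float(_comb2(table.astype(float)).sum())
    sum_i = float(_comb2(table.sum(axis=1).astype(float)).sum())
    sum_j = float(_comb2(table.sum(axis=0).astype(float)).sum())
    total = n * (n - 1) / 2.0
    if total == 0:
        return 1.0
    expected = sum_i * sum_j / total
    max_index = 0.5 * (sum_i + sum_j)
    if max_index == expected:  # both all-singletons or both one block: identical
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


# ---------------------------------------------------------------------------
# Credible-interval coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageReport:
    """Coverage of held-out points by the assigned clusters' bands."""

    coverage: float
    n_points: int
    level: float
    covered: np.ndarray          # per-gene indicator
    baseline: np.ndarray | None = None   # permutation-baseline coverages


def ci_coverage(bands: dict, heldout: np.ndarray, labels, time_index: int,
                level: float = 0.95) -> CoverageReport:
    """Proportion of held-out values inside [lower, upper] at ``time_index``.

    ``bands`` maps cluster label -> (mean, lower, upper) over the grid;
    ``labels`` maps each gene to its assigned cluster.
    """
    labels = _labels(labels)
    heldout = np.asarray(heldout, dtype=float)
    if labels.size != heldout.size:
        raise DataError("held-out values and labels must align")
    missing = set(np.unique(labels)) - set(bands)
    if missing:
        raise DataError(f"genes assigned to clusters without bands: {sorted(missing)}")
    lo = np.array([bands[l][1][time_index] for l in labels])
    hi = np.array([bands[l][2][time_index] for l in labels])
    covered = (lo <= heldout) & (heldout <= hi)
    return CoverageReport(float(covered.mean()), int(covered.size), level, covered)


def permuted_coverage_baseline(bands: dict, heldout: np.ndarray, labels,
                               time_index: int, n_perm: int = 1000,
                               rng: np.random.Generator | None = None,
                               level: float = 0.95) -> np.ndarray:
    """Empirical coverage distribution after shuffling the gene->cluster map
    ``n_perm`` times (default 1000).  With a single cluster the baseline
    equals the true coverage exactly."""
    if rng is None:
        rng = np.random.default_rng()
    labels = _labels(labels)
    heldout = np.asarray(heldout, dtype=float)
    lo = np.array([bands[l][1][time_index] for l in labels])
    hi = np.array([bands[l][2][time_index] for l in labels])
    out = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels.size)
        out[i] = float(((lo[perm] <= heldout) & (heldout <= hi[perm])).mean())
    return out


# ---------------------------------------------------------------------------
# Held-out time-point pipeline
# ---------------------------------------------------------------------------

@dataclass
class HoldoutResult:
    """Outcome of clustering a data set with one middle time point masked."""

    report: CoverageReport
    result: ClusteringResult
    time_index: int
    heldout: np.ndarray


def holdout_coverage(ds: SimulatedDataset, holdout_index: int, config: DPConfig,
                     level: float = 0.95, n_perm: int = 0,
                     rng: np.random.Generator | None = None) -> HoldoutResult:
    """Mask one middle time point, cluster the remaining data, and score the
    95% predictive bands of the selected clusters on the held-out values."""
    masked, heldout = holdout_middle_timepoints(ds, holdout_index)
    col = heldout_column(ds, holdout_index)
    trace = run_sampler(masked.matrix, config)
    result = select_map_partition(trace, masked.matrix, config)
    psm = build_psm(trace)
    inclusion_probabilities(result, psm)
    bands = cluster_credible_bands(result, level=level)
    report = ci_coverage(bands, heldout, result.partition, col, level=level)
    if n_perm > 0:
        report.baseline = permuted_coverage_baseline(
            bands, heldout, result.partition, col, n_perm=n_perm, rng=rng,
            level=level)
    return HoldoutResult(report, result, col, heldout)
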