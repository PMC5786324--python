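"""Synthetic benchmark generator for GP mixture clustering.

Each data set is produced by the model's own generative process: cluster mean
trajectories are drawn from a zero-mean GP with squared-exponential kernel,
and member trajectories are drawn around their cluster mean with covariance
equal to the GP posterior covariance of the mean plus the marginal (noise)
variance — or from a heavy-tailed multivariate t (df = 2 by default) with the
same scale matrix.  Ground-truth labels are kept alongside the matrix.

A table of 31 benchmark archetypes spans the study ranges (cluster counts
10-100, signal variance 0.5-3, marginal variance 0.01-1, length scale 0.5-3);
it lives in ``archetypes.json`` so individual entries can be revised without
a code change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .gp import (DataError, KernelHyperparams, ParameterError, TimeGrid,
                 gram_matrix, jittered_cholesky)
from .io import ExpressionMatrix

DEFAULT_GRID = TimeGrid(np.arange(8.0))


@dataclass(frozen=True)
class SimulationSpec:
    """Generating parameters for one benchmark data-set archetype.

    ``sizes`` is either a single genes-per-cluster count or an explicit
    per-cluster list.  Defaults are the moderate setting used throughout the
    desk-scale benchmarks: 20 clusters of 25 genes on 8 evenly spaced time
    points, length scale 1, signal variance 1, marginal variance 0.05.
    """

    n_clusters: int = 20
    sizes: int | tuple[int, ...] = 25
    grid: TimeGrid = field(default_factory=lambda: DEFAULT_GRID)
    length_scale: float = 1.0
    signal_variance: float = 1.0
    marginal_variance: float = 0.05
    error_model: str = "gaussian"
    df: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ParameterError("n_clusters must be >= 1")
        sizes = self.cluster_sizes()
        if any(s < 1 for s in sizes):
            raise ParameterError("all cluster sizes must be >= 1")
        for name in ("length_scale", "signal_variance", "marginal_variance"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if self.error_model not in ("gaussian", "student_t"):
            raise ParameterError("error_model must be 'gaussian' or 'student_t'")
        if self.error_model == "student_t" and not self.df > 0:
            raise ParameterError("df must be positive")

    def cluster_sizes(self) -> list[int]:
        if np.isscalar(self.sizes):
            return [int(self.sizes)] * self.n_clusters
        sizes = [int(s) for s in self.sizes]
        if len(sizes) != self.n_clusters:
            raise ParameterError("sizes list must have n_clusters entries")
        return sizes

    @property
    def hyperparams(self) -> KernelHyperparams:
        return KernelHyperparams(self.length_scale, self.signal_variance,
                                 self.marginal_variance)


@dataclass
class SimulatedDataset:
    """A generated matrix together with its ground truth."""

    matrix: ExpressionMatrix
    truth: np.ndarray             # per-gene true cluster label
    cluster_means: np.ndarray     # n_clusters x T generating means
    spec: SimulationSpec


def _posterior_scale_matrix(spec: SimulationSpec) -> np.ndarray:
    """Member scatter around the cluster mean: K* + sigma^2 I, with K* the GP
    posterior covariance of the mean at the generating hyperparameters."""
    hp = spec.hyperparams
    K = gram_matrix(spec.grid, hp, include_noise=False)
    A = K + hp.noise_variance * np.eye(spec.grid.T)
    Kstar = K - K @ np.linalg.solve(A, K)
    return Kstar + hp.noise_variance * np.eye(spec.grid.T)


def simulate_dataset(spec: SimulationSpec, seed: int | None = None) -> SimulatedDataset:
    """Draw one data set from the generative model; deterministic under seed."""
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    sizes = spec.cluster_sizes()
    T = spec.grid.T
    K = gram_matrix(spec.grid, spec.hyperparams, include_noise=False)
    Lmean = jittered_cholesky(K, context="(generating kernel)")
    Lmem = jittered_cholesky(_posterior_scale_matrix(spec), context="(member scatter)")
    heavy = spec.error_model == "student_t"

    means = np.empty((spec.n_clusters, T))
    rows, labels = [], []
    for h, n_h in enumerate(sizes):
        mu = Lmean @ rng.standard_normal(T)
        if heavy:  # scale-mixture construction of the multivariate t
            mu = mu / np.sqrt(rng.chisquare(spec.df) / spec.df)
        means[h] = mu
        Z = Lmem @ rng.standard_normal((T, n_h))
        if heavy:
            Z = Z / np.sqrt(rng.chisquare(spec.df, size=n_h) / spec.df)
        rows.append(mu[None, :] + Z.T)
        labels.extend([h] * n_h)
    values = np.vstack(rows)
    gene_ids = np.array([f"gene_{i:04d}" for i in range(values.shape[0])], dtype=object)
    matrix = ExpressionMatrix(gene_ids, spec.grid, values)
    return SimulatedDataset(matrix, np.asarray(labels, dtype=int), means, spec)


# ---------------------------------------------------------------------------
# Held-out middle time points
# ---------------------------------------------------------------------------

def middle_timepoints(T: int) -> list[int]:
    """The four centered column indices (0-based) of a grid with T >= 6."""
    if T < 6:
        raise DataError("held-out evaluation needs at least 6 time points")
    start = (T - 4) // 2
    return list(range(start, start + 4))


def holdout_middle_timepoints(ds: SimulatedDataset, index: int) -> tuple[SimulatedDataset, np.ndarray]:
    """Mask one of the four middle time points for every gene.

    ``index`` in 0..3 selects which middle column is held out.  Returns the
    masked data set (same grid, the column set to NaN) and the vector of
    held-out true values for coverage scoring.
    """
    middles = middle_timepoints(ds.matrix.T)
    if not 0 <= index < len(middles):
        raise DataError(f"holdout index must be in 0..{len(middles) - 1}")
    col = middles[index]
    values = ds.matrix.values.copy()
    heldout = values[:, col].copy()
    values[:, col] = np.nan
    masked = ExpressionMatrix(ds.matrix.gene_ids.copy(), ds.matrix.grid,
                              values, ds.matrix.standardized)
    return SimulatedDataset(masked, ds.truth.copy(), ds.cluster_means.copy(), ds.spec), heldout


def heldout_column(ds: SimulatedDataset, index: int) -> int:
    """Grid column (0-based) corresponding to holdout ``index``."""
    return middle_timepoints(ds.matrix.T)[index]


# ---------------------------------------------------------------------------
# Benchmark archetypes
# ---------------------------------------------------------------------------

def _load_archetype_table() -> dict:
    with resources.files("dpgp").joinpath("archetypes.json").open() as fh:
        return json.load(fh)


def _varied_sizes(n_clusters: int, total_genes: int) -> tuple[int, ...]:
    """Widely varied cluster sizes: a geometric series normalized to the
    target gene total, with every cluster at least one gene."""
    raw = np.geomspace(1.0, 10.0, n_clusters)
    sizes = np.maximum(1, np.round(raw / raw.sum() * total_genes).astype(int))
    # adjust the largest cluster so the total matches exactly
    sizes[-1] += total_genes - sizes.sum()
    return tuple(int(s) for s in sizes)


def benchmark_archetype(archetype_id: int, seed: int | None = None) -> SimulationSpec:
    """The generating spec for benchmark family 1..31.

    Families 1-5 vary the cluster-size distribution (10-100 clusters over 500
    genes); families 6-31 vary one generating hyperparameter at a time over
    the study ranges.  The table is versioned in ``archetypes.json``.
    """
    table = _load_archetype_table()
    entry = table.get(str(archetype_id))
    if entry is None:
        raise ParameterError(f"unknown archetype id {archetype_id} (valid: 1..{len(table)})")
    sizes = entry["genes_per_cluster"]
    if sizes == "varied":
        sizes = _varied_sizes(entry["n_clusters"], entry["total_genes"])
    return SimulationSpec(
        n_clusters=entry["n_clusters"],
        sizes=sizes,
        length_scale=entry["length_scale"],
        signal_variance=entry["signal_variance"],
        marginal_variance=entry["marginal_variance"],
        error_model=entry.get("error_model", "gaussian"),
        seed=seed,
    )
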