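"""Post-processing of the Gibbs trace.

Turns the thinned sequence of sampled partitions into a posterior similarity
matrix (PSM), a selected clustering (MAP by default), per-gene cluster
inclusion probabilities, and per-cluster posterior mean trajectories with
predictive credible bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gp import (ClusterModel, DataError, KernelHyperparams, ParameterError,
                 gp_posterior_update, optimize_hyperparams)
from .io import FLOAT_FORMAT, ExpressionMatrix
from .sampler import DPConfig, Partition, SamplerTrace

logger = logging.getLogger("dpgp")


# ---------------------------------------------------------------------------
# Posterior similarity matrix
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSimilarityMatrix:
    """P x P co-clustering frequencies across Q Gibbs samples."""

    S: np.ndarray
    Q: int
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise DataError("PSM must be square")
        if not np.allclose(S, S.T):
            raise DataError("PSM must be symmetric")
        if not np.allclose(np.diag(S), 1.0):
            raise DataError("PSM diagonal must be exactly 1")
        if S.min() < -1e-12 or S.max() > 1 + 1e-12:
            raise DataError("PSM entries must lie in [0, 1]")
        self.S = S


def build_psm(trace: SamplerTrace) -> PosteriorSimilarityMatrix:
    """S[j, j'] = fraction of samples in which genes j and j' co-cluster.

    Label-switching-proof by construction: only equality of labels within a
    sample is used, never the labels themselves.
    """
    if trace.Q < 1:
        raise DataError("empty trace: no samples to summarize")
    A = trace.assignments
    S = np.zeros((trace.P, trace.P))
    for q in range(trace.Q):
        S += A[q][:, None] == A[q][None, :]
    S /= trace.Q
    return PosteriorSimilarityMatrix(S, trace.Q, trace.gene_ids)


# ---------------------------------------------------------------------------
# Selecting a single clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSummary:
    """Refreshed GP state of one selected cluster."""

    label: int
    hyperparams: KernelHyperparams
    mean: np.ndarray
    posterior_cov: np.ndarray
    members: np.ndarray
    size: int


@dataclass
class ClusteringResult:
    """A selected partition with per-cluster summaries and gene inclusion
    probabilities."""

    partition: Partition
    criterion: str = "map"
    sample_index: int | None = None
    log_posterior: float = np.nan
    summaries: dict[int, ClusterSummary] = field(default_factory=dict)
    inclusion: np.ndarray | None = None
    gene_ids: np.ndarray | None = None


def _refresh_summaries(partition: Partition, data: ExpressionMatrix,
                       config: DPConfig) -> dict[int, ClusterSummary]:
    """Recompute posterior mean/covariance and hyperparameters per cluster of
    the selected partition (fresh optimization from the initialization)."""
    summaries = {}
    init_hp = config.hyperpriors.initial_hyperparams()
    for label in np.unique(partition.assignments):
        idx = np.flatnonzero(partition.assignments == label)
        Ym, Mm = data.values[idx], data.mask[idx]
        hp = optimize_hyperparams(Ym, data.grid, init_hp, config.hyperpriors,
                                  mask=Mm,
                                  include_prior=config.include_prior_in_objective,
                                  maxiter=config.optimizer_maxiter)
        mu, Kstar = gp_posterior_update(Ym, data.grid, hp, Mm, label=int(label))
        summaries[int(label)] = ClusterSummary(int(label), hp, mu, Kstar,
                                               idx, idx.size)
    return summaries


def select_map_partition(trace: SamplerTrace, data: ExpressionMatrix | None = None,
                         config: DPConfig | None = None,
                         criterion: str = "map") -> ClusteringResult:
    """Select a single clustering from the trace.

    ``criterion='map'`` (default) takes the sampled partition with the
    maximal log posterior, earliest sample winning ties;
    ``criterion='least_squares'`` takes the sample whose binary co-clustering
    matrix is closest to the PSM.  When the data and configuration are
    supplied, cluster summaries are refreshed on the selected partition.
    """
    if trace.Q < 1:
        raise DataError("empty trace")
    if criterion == "map":
        q = int(np.argmax(trace.log_posteriors))  # argmax returns first max: earliest wins
    elif criterion == "least_squares":
        S = build_psm(trace).S
        errs = [np.mean(((trace.assignments[i][:, None] == trace.assignments[i][None, :]) - S) ** 2)
                for i in range(trace.Q)]
        q = int(np.argmin(errs))
    else:
        raise ParameterError(f"unknown selection criterion {criterion!r}")
    partition = Partition(trace.assignments[q].copy())
    result = ClusteringResult(partition, criterion=criterion, sample_index=q,
                              log_posterior=float(trace.log_posteriors[q]),
                              gene_ids=trace.gene_ids)
    if data is not None:
        if config is None:
            config = trace.config
        result.summaries = _refresh_summaries(partition, data, config)
    return result


def inclusion_probabilities(result: ClusteringResult,
                            psm: PosteriorSimilarityMatrix) -> np.ndarray:
    """Per-gene probability of belonging to its selected cluster.

    For gene j in cluster h: the mean PSM entry between j and the other
    members of h (uniform weights).  Genes in singleton clusters get
    probability 1 by convention.
    """
    c = result.partition.assignments
    P = c.size
    if psm.S.shape[0] != P:
        raise DataError("result and PSM cover different gene sets")
    probs = np.ones(P)
    for label in np.unique(c):
        idx = np.flatnonzero(c == label)
        if idx.size < 2:
            continue
        sub = psm.S[np.ix_(idx, idx)]
        probs[idx] = (sub.sum(axis=1) - 1.0) / (idx.size - 1)
    result.inclusion = probs
    return probs


# ---------------------------------------------------------------------------
# Credible bands
# ---------------------------------------------------------------------------

def cluster_credible_bands(result: ClusteringResult, level: float = 0.95,
                           two_sd: bool = False) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-cluster (mean, lower, upper) predictive bands over the grid.

    The band is mu_h +/- z(level) * sqrt(diag(K_h*) + sigma_h^2): a predictive
    interval for a member trajectory, combining the posterior uncertainty of
    the cluster mean with the marginal noise.  ``two_sd=True`` uses z = 2
    (the plotting convention of mean +/- 2 SD) instead of the exact quantile.
    """
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    if not result.summaries:
        raise DataError("cluster summaries missing: select the partition with data")
    z = 2.0 if two_sd else float(norm.ppf(0.5 + level / 2.0))
    bands = {}
    for label, s in result.summaries.items():
        sd = np.sqrt(np.diag(s.posterior_cov) + s.hyperparams.noise_variance)
        bands[label] = (s.mean.copy(), s.mean - z * sd, s.mean + z * sd)
    return bands


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_clustering(result: ClusteringResult, path) -> None:
    """Three-column table: gene id, cluster label, inclusion probability."""
    ids = result.gene_ids if result.gene_ids is not None else np.arange(result.partition.P)
    incl = result.inclusion if result.inclusion is not None else np.full(result.partition.P, np.nan)
    df = pd.DataFrame({"gene": ids, "cluster": result.partition.assignments,
                       "inclusion_probability": incl})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_psm(psm: PosteriorSimilarityMatrix, path) -> None:
    """Square tab-delimited PSM with gene ids as row/column headers."""
    ids = psm.gene_ids if psm.gene_ids is not None else np.arange(psm.S.shape[0])
    df = pd.DataFrame(psm.S, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.4f", index_label="gene")


def write_cluster_bands(result: ClusteringResult, grid_times: np.ndarray, path,
                        level: float = 0.95) -> None:
    """Long table: cluster, time, mean, lower, upper."""
    bands = cluster_credible_bands(result, level=level)
    rows = []
    for label in sorted(bands):
        mean, lo, hi = bands[label]
        for t, m, l, u in zip(grid_times, mean, lo, hi):
            rows.append((label, t, m, l, u))
    df = pd.DataFrame(rows, columns=["cluster", "time", "mean", "lower", "upper"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
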