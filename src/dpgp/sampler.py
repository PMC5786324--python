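"""Dirichlet process mixture inference by Gibbs sampling (Neal's Algorithm 8).

Genes start in singleton clusters and are reassigned one at a time; the prior
over assignments is the Chinese restaurant process with concentration alpha
(default 1), realized with m auxiliary empty clusters per sweep whose mean
functions are drawn from the GP prior.  The first 48% of iterations form two
equal burn-in phases: phase 1 keeps the kernel hyperparameters frozen at
their initialization (unit signal variance and length scale, noise at the
inverse-gamma prior mode) and re-applies the GP smoothing update of the
member average each iteration; phase 2 additionally re-optimizes the
hyperparameters (type-II ML) every iteration.  After burn-in the
chain is thinned: parameters are updated and the assignment vector recorded
every s-th iteration (s = 3 by default).

The fast likelihood path ("fDPGP") applies when all genes are observed on an
identical grid: a single Cholesky factorization of K_h + sigma_h^2 I per
cluster is reused for every gene evaluated against that cluster in a sweep.
The general path groups genes by missingness pattern and caches one
factorization per pattern, so it degenerates to the fast path (and is
numerically identical to it) on complete data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .gp import (ClusterModel, DataError, HyperpriorConfig, KernelHyperparams,
                 ParameterError, TimeGrid, gram_matrix, jittered_cholesky,
                 member_mean, gp_posterior_update, optimize_hyperparams)
from .io import ExpressionMatrix

logger = logging.getLogger("dpgp")


# ---------------------------------------------------------------------------
# Configuration and state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DPConfig:
    """Sampler configuration.

    ``alpha`` is the DP concentration (larger -> more clusters, expected
    count ~ alpha * log P); ``m`` the number of auxiliary empty clusters
    regenerated before each sweep; ``thin`` the post-burn-in sampling
    interval.  ``fast_mode`` asserts the complete-data precondition of the
    fast likelihood path.  ``prior_only`` disables the likelihood entirely so
    the sampler targets the bare CRP (used for prior diagnostics).
    """

    alpha: float = 1.0
    m: int = 4
    thin: int = 3
    max_iterations: int = 1000
    burnin_fraction: float = 0.48
    seed: int | None = None
    fast_mode: bool = False
    check_convergence: bool = False
    prior_only: bool = False
    random_order: bool = False
    hyperpriors: HyperpriorConfig = field(default_factory=HyperpriorConfig)
    include_prior_in_objective: bool = True
    optimizer_maxiter: int = 40
    tol_psm: float = 1e-3
    tol_lik: float = 1e-3
    convergence_window: int = 20

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ParameterError("alpha must be positive")
        if self.m < 1 or self.thin < 1:
            raise ParameterError("m and thin must be >= 1")
        if not 0 < self.burnin_fraction < 1:
            raise ParameterError("burnin_fraction must be in (0, 1)")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")

    @property
    def n_burnin(self) -> int:
        return int(round(self.burnin_fraction * self.max_iterations))

    @property
    def n_samples(self) -> int:
        return (self.max_iterations - self.n_burnin) // self.thin


@dataclass
class Partition:
    """Cluster-assignment vector; labels are arbitrary hashable ints."""

    assignments: np.ndarray

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)

    @property
    def P(self) -> int:
        return self.assignments.size

    def sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.assignments, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    @property
    def n_clusters(self) -> int:
        return np.unique(self.assignments).size


@dataclass
class SamplerState:
    """Mutable sampler state: partition, live cluster models, bookkeeping."""

    partition: Partition
    clusters: dict[int, ClusterModel]
    iteration: int = 0
    phase: str = "burnin1"
    log_posterior: float = math.nan
    next_label: int = 0


@dataclass
class SamplerTrace:
    """Thinned sequence of sampled partitions with posterior scores."""

    assignments: np.ndarray        # Q x P
    log_posteriors: np.ndarray     # Q
    gene_ids: np.ndarray
    grid: TimeGrid
    config: DPConfig
    diagnostics: dict = field(default_factory=dict)
    final_state: SamplerState | None = None

    @property
    def Q(self) -> int:
        return self.assignments.shape[0]

    @property
    def P(self) -> int:
        return self.assignments.shape[1]


# ---------------------------------------------------------------------------
# CRP prior and assignment weights
# ---------------------------------------------------------------------------

def crp_prior_probs(target_gene: int, partition: Partition, config: DPConfig
                    ) -> tuple[dict[int, float], np.ndarray]:
    """CRP assignment probabilities for one gene given all others.

    Existing cluster h receives n_{h,-j} / (alpha + n - 1); each of the m
    auxiliary slots receives (alpha/m) / (alpha + n - 1).  The returned masses
    sum to one.
    """
    c = partition.assignments
    n = c.size
    denom = config.alpha + n - 1
    keep = np.ones(n, dtype=bool)
    keep[target_gene] = False
    labels, counts = np.unique(c[keep], return_counts=True)
    existing = {int(l): cnt / denom for l, cnt in zip(labels, counts)}
    aux = np.full(config.m, (config.alpha / config.m) / denom)
    return existing, aux


def assignment_log_weights(y: np.ndarray, candidates, config: DPConfig,
                           mask: np.ndarray | None = None) -> np.ndarray:
    """Unnormalized log weights for one gene over candidate clusters.

    ``candidates`` is a sequence of ``(count, model)`` pairs where ``count``
    is the cluster's current size excluding the gene (auxiliary slots use
    ``None`` and get prior mass alpha/m).  Sampling from the normalized
    weights is done in log space (Gumbel-max), so the weights may be shifted
    by any constant.
    """
    y = np.asarray(y, dtype=float)
    if mask is None:
        mask = np.isfinite(y)
    log_aux = math.log(config.alpha / config.m)
    out = np.empty(len(candidates))
    for i, (count, model) in enumerate(candidates):
        prior = log_aux if count is None else math.log(count)
        out[i] = prior + model.log_likelihood(y, mask)
    return out


def sample_from_log_weights(log_w: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an index proportional to exp(log_w) via the Gumbel-max trick."""
    log_w = np.asarray(log_w, dtype=float)
    finite = np.isfinite(log_w)
    if not finite.any():
        raise ParameterError("all assignment weights are -inf")
    g = rng.gumbel(size=log_w.size)
    return int(np.argmax(np.where(finite, log_w + g, -np.inf)))


# ---------------------------------------------------------------------------
# Fast per-gene likelihood (fDPGP path)
# ---------------------------------------------------------------------------

def fast_gene_log_likelihood(y: np.ndarray, cluster: ClusterModel) -> float:
    """Per-gene Gaussian log density reusing the cluster's cached factor.

    Requires fully observed data on the shared grid; with missing entries the
    general ``gp_log_marginal_likelihood`` path must be used instead.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError("missing data present: use the general likelihood path")
    return cluster.log_likelihood(y, np.ones(y.size, dtype=bool))


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------

def _mask_groups(mask: np.ndarray):
    """Unique missingness patterns and the gene rows sharing each of them."""
    patterns, inverse = np.unique(np.asarray(mask, dtype=bool), axis=0,
                                  return_inverse=True)
    return [(patterns[p], np.flatnonzero(inverse == p))
            for p in range(patterns.shape[0])]


def _loglik_columns(models, data: ExpressionMatrix, groups) -> np.ndarray:
    """P x C matrix of per-gene log likelihoods under each candidate model."""
    P = data.P
    out = np.empty((P, len(models)))
    for c, model in enumerate(models):
        for pattern, rows in groups:
            out[rows, c] = model.log_likelihood_many(data.values[rows], pattern)
    return out


def _make_aux_models(grid: TimeGrid, init_hp: KernelHyperparams, L0: np.ndarray,
                     m: int, rng: np.random.Generator) -> list[ClusterModel]:
    """m empty clusters with mean functions drawn from the GP prior
    N(0, K0 + sigma0^2 I) and initialization kernel parameters."""
    models = []
    for _ in range(m):
        mean = L0 @ rng.standard_normal(grid.T)
        models.append(ClusterModel(grid, init_hp, mean=mean))
    return models


# ---------------------------------------------------------------------------
# One Gibbs sweep (Neal Algorithm 8)
# ---------------------------------------------------------------------------

def gibbs_sweep(state: SamplerState, data: ExpressionMatrix, config: DPConfig,
                rng: np.random.Generator, aux_models=None, groups=None) -> SamplerState:
    """Reassign every gene once, in index order (or a random order).

    A gene sitting in a singleton cluster keeps its cluster's parameters as
    one of the m auxiliary slots for its own draw (one fresh slot is displaced
    so the total new-cluster prior mass stays alpha); clusters emptied by a
    move are removed.  Likelihood columns are computed once per sweep per
    candidate model, reusing each model's cached factorization.
    """
    if groups is None:
        groups = _mask_groups(data.mask)
    if aux_models is None:
        init_hp = config.hyperpriors.initial_hyperparams()
        L0 = jittered_cholesky(gram_matrix(data.grid, init_hp, include_noise=True))
        aux_models = _make_aux_models(data.grid, init_hp, L0, config.m, rng)

    labels = list(state.clusters)
    models = [state.clusters[l] for l in labels] + list(aux_models)
    n_exist = len(labels)
    C = len(models)
    P = data.P

    # capacity for clusters born during the sweep (each consumed auxiliary
    # slot is replenished immediately so exactly m empty clusters stay
    # available for every gene update, as Algorithm 8 requires)
    cap = C + P
    lik = np.empty((P, cap))
    if config.prior_only:
        lik[:, :C] = 0.0
    else:
        lik[:, :C] = _loglik_columns(models, data, groups)

    counts = np.zeros(cap)
    col_of_label = {l: i for i, l in enumerate(labels)}
    cols = np.array([col_of_label[l] for l in state.partition.assignments])
    for c in cols:
        counts[c] += 1
    alive = np.zeros(cap, dtype=bool)
    alive[:C] = True
    is_fresh = np.zeros(cap, dtype=bool)
    is_fresh[n_exist:C] = True

    init_hp = aux_models[0].hyperparams if aux_models else config.hyperpriors.initial_hyperparams()
    L0 = None

    def spawn_aux() -> None:
        """Append one fresh auxiliary slot (prior-seeded mean)."""
        nonlocal C, L0
        if L0 is None:
            L0 = jittered_cholesky(gram_matrix(data.grid, init_hp, include_noise=True))
        model = ClusterModel(data.grid, init_hp,
                             mean=L0 @ rng.standard_normal(data.grid.T))
        models.append(model)
        if config.prior_only:
            lik[:, C] = 0.0
        else:
            for pattern, rows in groups:
                lik[rows, C] = model.log_likelihood_many(data.values[rows], pattern)
        alive[C] = True
        is_fresh[C] = True
        C += 1

    log_aux = math.log(config.alpha / config.m)
    order = rng.permutation(P) if config.random_order else np.arange(P)

    for j in order:
        k = cols[j]
        counts[k] -= 1
        vacated = counts[k] == 0
        displaced = -1
        if vacated and not is_fresh[k]:
            fresh_alive = np.flatnonzero(alive[:C] & is_fresh[:C])
            if fresh_alive.size:
                displaced = int(fresh_alive[0])

        logw = np.full(C, -np.inf)
        occ = (counts[:C] > 0) & alive[:C]
        logw[occ] = np.log(counts[:C][occ])
        logw[alive[:C] & is_fresh[:C]] = log_aux
        if vacated:
            logw[k] = log_aux
            if displaced >= 0:
                logw[displaced] = -np.inf

        pick = sample_from_log_weights(logw + lik[j, :C], rng)
        counts[pick] += 1
        cols[j] = pick
        if vacated and pick != k:
            alive[k] = False  # dissolved cluster
        if is_fresh[pick]:
            is_fresh[pick] = False  # auxiliary slot becomes a real cluster
            spawn_aux()  # keep m empty clusters available

    # rebuild label map: surviving originals keep labels, born clusters get new ones
    next_label = state.next_label
    new_label_of_col: dict[int, int] = {}
    clusters: dict[int, ClusterModel] = {}
    for c in range(C):
        if counts[c] > 0:
            if c < n_exist and alive[c]:
                lab = labels[c]
            else:
                lab = next_label
                next_label += 1
            new_label_of_col[c] = lab
            models[c].label = lab
            models[c].size = int(counts[c])
            clusters[lab] = models[c]
    assignments = np.array([new_label_of_col[c] for c in cols])
    assert assignments.size == P

    return SamplerState(Partition(assignments), clusters,
                        iteration=state.iteration + 1, phase=state.phase,
                        next_label=next_label)


# ---------------------------------------------------------------------------
# Parameter updates and posterior score
# ---------------------------------------------------------------------------

def _update_clusters(state: SamplerState, data: ExpressionMatrix,
                     config: DPConfig, full: bool) -> None:
    """Refresh cluster means and posterior covariances from the current
    memberships; with ``full`` the kernel hyperparameters are re-optimized
    first, otherwise they stay frozen (burn-in phase 1)."""
    c = state.partition.assignments
    for label, model in state.clusters.items():
        idx = np.flatnonzero(c == label)
        model.size = idx.size
        Ym = data.values[idx]
        Mm = data.mask[idx]
        ybar, _ = member_mean(Ym, Mm)
        model.member_avg = ybar
        if config.prior_only:
            model.mean = ybar
            continue
        if full:
            hp = optimize_hyperparams(
                Ym, data.grid, model.hyperparams, config.hyperpriors, mask=Mm,
                include_prior=config.include_prior_in_objective,
                maxiter=config.optimizer_maxiter)
            model.set_hyperparams(hp)
        mu, Kstar = gp_posterior_update(Ym, data.grid, model.hyperparams, Mm,
                                        label=label)
        model.set_posterior(mu, Kstar)


def partition_log_posterior(partition: Partition, clusters: dict[int, ClusterModel],
                            data: ExpressionMatrix, config: DPConfig,
                            groups=None) -> float:
    """Unnormalized log posterior score of a partition.

    Sum of per-gene GP log likelihoods under their assigned clusters, the CRP
    exchangeable partition probability alpha^H * prod_h (n_h - 1)! *
    Gamma(alpha) / Gamma(alpha + P), and the hyperprior density of each
    cluster's kernel parameters.  Comparable only across partitions of the
    same data.
    """
    c = partition.assignments
    P = c.size
    if groups is None:
        groups = _mask_groups(data.mask)
    lik = 0.0
    if not config.prior_only:
        for pattern, rows in groups:
            for label, model in clusters.items():
                sub = rows[c[rows] == label]
                if sub.size:
                    lik += float(model.log_likelihood_many(data.values[sub], pattern).sum())
    sizes = np.array(list(partition.sizes().values()), dtype=float)
    H = sizes.size
    crp = (H * math.log(config.alpha) + gammaln(sizes).sum()
           + gammaln(config.alpha) - gammaln(config.alpha + P))
    prior = 0.0
    if not config.prior_only:
        prior = sum(config.hyperpriors.log_density(m.hyperparams)
                    for m in clusters.values())
    return lik + crp + prior


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def check_convergence(assignments: np.ndarray, log_posteriors: np.ndarray,
                      window: int = 20, tol_psm: float = 1e-3,
                      tol_lik: float = 1e-3) -> tuple[bool, dict]:
    """Convergence check on a (partial) trace.

    Criterion (i): the sliding-window mean of the squared distance between
    each new sample's binary co-clustering matrix and the running posterior
    similarity matrix falls below ``tol_psm``.  Criterion (ii): the sliding-
    window mean absolute change in log posterior falls below ``tol_lik`` times
    the magnitude of the current log posterior.  Both series are returned as
    diagnostics.  At least ``2 * window`` samples are required.
    """
    A = np.asarray(assignments)
    lp = np.asarray(log_posteriors, dtype=float)
    Q = A.shape[0]
    dists = []
    S = np.zeros((A.shape[1], A.shape[1])) if Q else None
    for q in range(Q):
        B = (A[q][:, None] == A[q][None, :]).astype(float)
        if q >= 1:
            dists.append(float(np.mean((B - S / q) ** 2)))
        S += B
    dists = np.asarray(dists)
    dlp = np.abs(np.diff(lp))
    diagnostics = {"psm_distance": dists, "delta_log_posterior": dlp}
    if Q < 2 * window or dists.size < window or dlp.size < window:
        return False, diagnostics
    psm_ok = float(dists[-window:].mean()) < tol_psm
    scale = max(1.0, abs(float(lp[-1])))
    lik_ok = float(dlp[-window:].mean()) < tol_lik * scale
    return bool(psm_ok and lik_ok), diagnostics


# ---------------------------------------------------------------------------
# The full sampler
# ---------------------------------------------------------------------------

def initial_state(data: ExpressionMatrix, config: DPConfig) -> SamplerState:
    """Each gene in its own cluster, parameterized by its own trajectory and
    the initialization kernel."""
    init_hp = config.hyperpriors.initial_hyperparams()
    clusters = {}
    for j in range(data.P):
        mean = np.where(data.mask[j], data.values[j], 0.0)
        model = ClusterModel(data.grid, init_hp, mean=mean, label=j)
        model.size = 1
        clusters[j] = model
    return SamplerState(Partition(np.arange(data.P)), clusters,
                        iteration=0, phase="burnin1", next_label=data.P)


def run_sampler(data: ExpressionMatrix, config: DPConfig) -> SamplerTrace:
    """Run the full MCMC schedule and return the thinned trace."""
    if config.fast_mode and not data.complete:
        raise DataError("fast mode requires fully observed data on a shared grid")
    if config.n_samples < 1:
        raise ParameterError(
            f"max_iterations={config.max_iterations} yields no post-burn-in "
            f"samples at thin={config.thin}")
    rng = np.random.default_rng(config.seed)
    groups = _mask_groups(data.mask)
    init_hp = config.hyperpriors.initial_hyperparams()
    L0 = jittered_cholesky(gram_matrix(data.grid, init_hp, include_noise=True))

    state = initial_state(data, config)
    # seed each singleton with its smoother update at the frozen init kernel
    # so the very first sweep already sees tight, discriminative clusters
    _update_clusters(state, data, config, full=False)
    n_burn = config.n_burnin
    phase1_end = n_burn // 2

    kept_assignments: list[np.ndarray] = []
    kept_lp: list[float] = []
    psm_sum = None
    psm_dists: list[float] = []
    converged_at = None

    for it in range(1, config.max_iterations + 1):
        if it <= phase1_end:
            phase = "burnin1"
        elif it <= n_burn:
            phase = "burnin2"
        else:
            phase = "sampling"
        state.phase = phase

        aux = _make_aux_models(data.grid, init_hp, L0, config.m, rng)
        state = gibbs_sweep(state, data, config, rng, aux_models=aux, groups=groups)
        state.phase = phase

        if phase == "burnin1":
            _update_clusters(state, data, config, full=False)
        elif phase == "burnin2":
            _update_clusters(state, data, config, full=True)
        else:
            if (it - n_burn) % config.thin == 0:
                _update_clusters(state, data, config, full=True)
                lp = partition_log_posterior(state.partition, state.clusters,
                                             data, config, groups=groups)
                state.log_posterior = lp
                kept_assignments.append(state.partition.assignments.copy())
                kept_lp.append(lp)
                # running PSM distance for the convergence diagnostics
                B = (kept_assignments[-1][:, None] == kept_assignments[-1][None, :]).astype(float)
                if psm_sum is None:
                    psm_sum = B.copy()
                else:
                    psm_dists.append(float(np.mean((B - psm_sum / (len(kept_assignments) - 1)) ** 2)))
                    psm_sum += B
                if config.check_convergence and converged_at is None:
                    ok, _ = check_convergence(
                        np.asarray(kept_assignments), np.asarray(kept_lp),
                        window=config.convergence_window,
                        tol_psm=config.tol_psm, tol_lik=config.tol_lik)
                    if ok:
                        converged_at = len(kept_assignments)
                        logger.info("convergence criteria met after %d samples "
                                    "(iteration %d)", converged_at, it)
                        break
        if it == phase1_end:
            logger.info("burn-in phase 1 complete (%d iterations, %d clusters)",
                        it, state.partition.n_clusters)
        elif it == n_burn:
            logger.info("burn-in phase 2 complete (%d iterations, %d clusters)",
                        it, state.partition.n_clusters)

    diagnostics = {
        "psm_distance": np.asarray(psm_dists),
        "delta_log_posterior": np.abs(np.diff(kept_lp)) if len(kept_lp) > 1 else np.array([]),
        "converged_at": converged_at,
        "n_burnin": n_burn,
        "phase1_end": phase1_end,
    }
    logger.info("sampling complete: %d samples, %d clusters in final state",
                len(kept_assignments), state.partition.n_clusters)
    return SamplerTrace(np.asarray(kept_assignments), np.asarray(kept_lp),
                        data.gene_ids.copy(), data.grid, config,
                        diagnostics=diagnostics, final_state=state)
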