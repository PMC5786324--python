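"""Gaussian process observation model for cluster trajectories.

Each cluster of trajectories is modeled as draws from a multivariate normal
with a cluster-specific mean function and covariance built from a squared
exponential (SE) kernel plus time-point-specific ("marginal") noise:

    y_j | cluster h  ~  N(mu_h, K_h + sigma_h^2 I)
    K_h[t, t']       =  tau_h^2 * exp(-(x_t - x_t')^2 / (2 * ell_h^2))

Hyperparameters carry log-normal priors on the length scale ``ell`` and the
signal standard deviation ``tau``, and an inverse-gamma prior on the noise
variance ``sigma^2``.  Missing observations are handled exactly by deleting
the corresponding rows/columns of the Gram matrix (GP marginalization), never
by imputation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.special import gammaln

logger = logging.getLogger("dpgp")

LOG_2PI = math.log(2.0 * math.pi)

# Cholesky jitter schedule: start at JITTER_INIT * mean(diag), double until
# JITTER_MAX * mean(diag), then give up.
JITTER_INIT = 1e-8
JITTER_MAX = 1e-2

# L-BFGS-B box bounds on log-hyperparameters (prevents overflow of exp).
LOG_HP_BOUND = 10.0


class ParameterError(ValueError):
    """A hyperparameter or configuration value is outside its domain."""


class NumericalError(RuntimeError):
    """A covariance factorization failed even after maximum jitter."""


class DataError(ValueError):
    """Input data violate a precondition (all-missing rows, non-finite values...)."""


# ---------------------------------------------------------------------------
# Time grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeGrid:
    """Ordered sampling times and their rescaled version.

    Times are divided by the mean inter-sample interval so that the mean
    consecutive difference of ``scaled_times`` is one unit.  This keeps the
    log-normal prior on the kernel length scale on a sensible scale regardless
    of the units (minutes, hours) of the original design.
    """

    times: np.ndarray
    scaled_times: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ParameterError("times must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(t)):
            raise ParameterError("times must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ParameterError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        if t.size > 1:
            scaled = t / np.diff(t).mean()
        else:
            scaled = t.copy()
        object.__setattr__(self, "scaled_times", scaled)

    @property
    def T(self) -> int:
        return self.times.size

    def __len__(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# Kernel hyperparameters and hyperpriors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelHyperparams:
    """SE-kernel hyperparameters: length scale, signal variance, noise variance."""

    length_scale: float = 1.0
    signal_variance: float = 1.0
    noise_variance: float = 1.0

    def __post_init__(self) -> None:
        for name in ("length_scale", "signal_variance", "noise_variance"):
            v = float(getattr(self, name))
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
            object.__setattr__(self, name, v)

    def as_log_array(self) -> np.ndarray:
        return np.log([self.length_scale, self.signal_variance, self.noise_variance])

    @staticmethod
    def from_log_array(x: np.ndarray) -> "KernelHyperparams":
        l, t2, s2 = np.exp(np.asarray(x, dtype=float))
        return KernelHyperparams(l, t2, s2)


@dataclass(frozen=True)
class HyperpriorConfig:
    """Priors on the kernel hyperparameters.

    * length scale:  ell ~ logN(0, 1)
    * signal s.d.:   tau ~ logN(0, 1)   (density on tau, not tau^2)
    * noise var:     sigma^2 ~ InverseGamma(alpha_ig, beta_ig)  (rate beta_ig)

    The inverse-gamma defaults (shape 12, rate 2) put the prior mode at
    2/13 ~= 0.154 on standardized expression; decreasing the shape (e.g. to 6
    for microarray data) allows greater within-cluster marginal variance.
    """

    alpha_ig: float = 12.0
    beta_ig: float = 2.0

    def __post_init__(self) -> None:
        if not (self.alpha_ig > 0 and self.beta_ig > 0):
            raise ParameterError("alpha_ig and beta_ig must be positive")

    @property
    def noise_prior_mode(self) -> float:
        return self.beta_ig / (self.alpha_ig + 1.0)

    def initial_hyperparams(self) -> KernelHyperparams:
        """Initialization: unit signal variance, unit length scale, noise at
        the mode of its inverse-gamma prior."""
        return KernelHyperparams(1.0, 1.0, self.noise_prior_mode)

    def log_density(self, hp: KernelHyperparams) -> float:
        """Joint log hyperprior density at ``hp``."""
        ll = math.log(hp.length_scale)
        lt = 0.5 * math.log(hp.signal_variance)  # log tau
        s2 = hp.noise_variance
        lp = -0.5 * ll * ll - ll - 0.5 * LOG_2PI          # logN(0,1) on ell
        lp += -0.5 * lt * lt - lt - 0.5 * LOG_2PI         # logN(0,1) on tau
        lp += (self.alpha_ig * math.log(self.beta_ig) - gammaln(self.alpha_ig)
               - (self.alpha_ig + 1.0) * math.log(s2) - self.beta_ig / s2)
        return lp


# ---------------------------------------------------------------------------
# Kernel and Gram matrix
# ---------------------------------------------------------------------------

def se_kernel(t1: float, t2: float, hp: KernelHyperparams) -> float:
    """Squared-exponential covariance between two (scaled) time points."""
    d = float(t1) - float(t2)
    return hp.signal_variance * math.exp(-d * d / (2.0 * hp.length_scale ** 2))


def gram_matrix(grid: TimeGrid, hp: KernelHyperparams, include_noise: bool = False) -> np.ndarray:
    """Gram matrix of the SE kernel on the grid, optionally plus sigma^2 I."""
    x = grid.scaled_times
    d = x[:, None] - x[None, :]
    K = hp.signal_variance * np.exp(-(d * d) / (2.0 * hp.length_scale ** 2))
    if include_noise:
        K = K + hp.noise_variance * np.eye(grid.T)
    return K


def jittered_cholesky(A: np.ndarray, context: str = "") -> np.ndarray:
    """Lower Cholesky factor of A, adding diagonal jitter if needed.

    Jitter starts at 1e-8 * mean(diag A) and doubles until 1e-2 * mean(diag A);
    beyond that a NumericalError is raised.
    """
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        pass
    scale = float(np.mean(np.diag(A)))
    if not (scale > 0 and math.isfinite(scale)):
        scale = 1.0
    jitter = JITTER_INIT * scale
    eye = np.eye(A.shape[0])
    while jitter <= JITTER_MAX * scale:
        try:
            L = np.linalg.cholesky(A + jitter * eye)
            logger.debug("cholesky required jitter %.3e %s", jitter, context)
            return L
        except np.linalg.LinAlgError:
            jitter *= 2.0
    raise NumericalError(f"covariance factorization failed after maximum jitter {context}".strip())


def _chol_logpdf(resid: np.ndarray, L: np.ndarray) -> float:
    """Multivariate normal log density of ``resid`` with covariance LL^T."""
    z = solve_triangular(L, resid, lower=True)
    k = resid.shape[0]
    return float(-0.5 * z @ z - np.log(np.diag(L)).sum() - 0.5 * k * LOG_2PI)


# ---------------------------------------------------------------------------
# Marginal likelihood with missingness
# ---------------------------------------------------------------------------

def gp_log_marginal_likelihood(
    y: np.ndarray,
    mean: np.ndarray,
    grid: TimeGrid,
    hp: KernelHyperparams,
    mask: np.ndarray | None = None,
) -> float:
    """Log density of the observed entries of ``y`` under N(mean, K + sigma^2 I).

    Missing time points (NaN in ``y`` or False in ``mask``) are marginalized
    exactly by row/column deletion of the covariance.
    """
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if y.shape != (grid.T,) or mean.shape != (grid.T,):
        raise DataError("y and mean must be defined on the full grid")
    if mask is None:
        mask = np.isfinite(y)
    else:
        mask = np.asarray(mask, dtype=bool)
        if not np.all(np.isfinite(y[mask])):
            raise DataError("non-finite values among observed entries")
    if not mask.any():
        raise DataError("all time points missing")
    obs = np.flatnonzero(mask)
    K = gram_matrix(grid, hp, include_noise=False)
    A = K[np.ix_(obs, obs)] + hp.noise_variance * np.eye(obs.size)
    L = jittered_cholesky(A)
    return _chol_logpdf(y[obs] - mean[obs], L)


# ---------------------------------------------------------------------------
# Posterior mean/covariance update
# ---------------------------------------------------------------------------

def member_mean(Y: np.ndarray, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise average of member trajectories over observed entries.

    Returns ``(ybar, obs_cols)`` where ``obs_cols`` marks time points with at
    least one observation; ``ybar`` is zero where nothing is observed.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if mask is None:
        mask = np.isfinite(Y)
    counts = mask.sum(axis=0)
    obs_cols = counts > 0
    ybar = np.zeros(Y.shape[1])
    with np.errstate(invalid="ignore"):
        s = np.where(mask, Y, 0.0).sum(axis=0)
    ybar[obs_cols] = s[obs_cols] / counts[obs_cols]
    return ybar, obs_cols


def gp_posterior_update(
    Y: np.ndarray,
    grid: TimeGrid,
    hp: KernelHyperparams,
    mask: np.ndarray | None = None,
    label=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the cluster mean function.

    The GP smoother is applied to the element-wise member average ``ybar``:

        mu*  = K (K + sigma^2 I)^{-1} ybar
        K*   = K - K (K + sigma^2 I)^{-1} K

    evaluated on the full grid (missing columns are predicted from the
    observed ones).  The diagonal of K* never exceeds the diagonal of K.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] < 1:
        raise DataError("at least one member trajectory required")
    ybar, obs_cols = member_mean(Y, mask)
    if not obs_cols.any():
        raise DataError("no observed entries in member set")
    obs = np.flatnonzero(obs_cols)
    K = gram_matrix(grid, hp, include_noise=False)
    A = K[np.ix_(obs, obs)] + hp.noise_variance * np.eye(obs.size)
    try:
        L = jittered_cholesky(A)
    except NumericalError as exc:
        raise NumericalError(f"{exc} (cluster {label})") from exc
    z = solve_triangular(L, ybar[obs], lower=True)
    w = solve_triangular(L.T, z, lower=False)
    mu = K[:, obs] @ w
    V = solve_triangular(L, K[obs, :], lower=True)
    Kstar = K - V.T @ V
    # numerical guard: posterior variance is non-negative by construction
    d = np.diag(Kstar).copy()
    np.fill_diagonal(Kstar, np.maximum(d, 0.0))
    return mu, Kstar


# ---------------------------------------------------------------------------
# Type-II maximum likelihood (optionally MAP-II) hyperparameter updates
# ---------------------------------------------------------------------------

def penalized_objective(
    x: np.ndarray,
    grid: TimeGrid,
    priors: HyperpriorConfig,
    ybar: np.ndarray,
    obs: np.ndarray,
    counts: np.ndarray,
    rss: float,
    n_resid: int,
    include_prior: bool,
) -> float:
    """Negative (penalized) cluster marginal likelihood on log-hyperparameters.

    The members of a cluster share one latent mean function drawn from
    GP(0, K) and deviate from it with independent N(0, sigma^2) noise at each
    observed point.  Integrating the mean out, the joint density of all
    member observations factorizes exactly into the density of the
    per-time-point observed means ``ybar`` (noise sigma^2 / n_t) and the
    within-cluster residual sum of squares:

        log p = log N(ybar_obs | 0, K_oo + sigma^2 D)
                - rss / (2 sigma^2) - (n_resid / 2) log(2 pi sigma^2) + const

    with D = diag(1 / n_t) and n_resid = (total observed entries) - (observed
    time points).  This is the likelihood whose direct evaluation would cost
    O((MT)^3) on the stacked member vector; the decomposition reduces it to a
    single T x T factorization per evaluation.
    """
    ell, tau2, sig2 = np.exp(x)
    hp = KernelHyperparams(ell, tau2, sig2)
    xg = grid.scaled_times[obs]
    d = xg[:, None] - xg[None, :]
    A = tau2 * np.exp(-(d * d) / (2.0 * ell * ell)) + np.diag(sig2 / counts)
    try:
        L = jittered_cholesky(A)
    except NumericalError:
        return np.inf
    total = _chol_logpdf(ybar[obs], L)
    total += -0.5 * rss / sig2 - 0.5 * n_resid * (math.log(sig2) + LOG_2PI)
    if include_prior:
        total += priors.log_density(hp)
    return -total


def optimize_hyperparams(
    Y: np.ndarray,
    grid: TimeGrid,
    init: KernelHyperparams,
    priors: HyperpriorConfig | None = None,
    mask: np.ndarray | None = None,
    include_prior: bool = True,
    maxiter: int = 40,
) -> KernelHyperparams:
    """Maximize the (hyperprior-penalized) cluster marginal likelihood by L-BFGS-B.

    The search is over log-transformed hyperparameters with box bounds
    exp(+/-10); a single start from ``init`` keeps the update cheap enough to
    interleave with Gibbs sweeps.  If the optimizer fails to improve on the
    starting point the initial values are retained and a warning is logged
    (the sampler must never abort on a failed update).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] < 1:
        raise DataError("nonempty member set required")
    if priors is None:
        priors = HyperpriorConfig()
    if mask is None:
        mask = np.isfinite(Y)
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    if not mask.any(axis=1).all():
        raise DataError("every member must have at least one observed time point")
    ybar, obs_cols = member_mean(Y, mask)
    obs = np.flatnonzero(obs_cols)
    counts = mask.sum(axis=0)[obs].astype(float)
    resid = np.where(mask, Y - ybar[None, :], 0.0)
    rss = float((resid ** 2).sum())
    n_resid = int(counts.sum()) - obs.size
    args = (grid, priors, ybar, obs, counts, rss, n_resid, include_prior)
    x0 = np.clip(init.as_log_array(), -LOG_HP_BOUND, LOG_HP_BOUND)
    f0 = penalized_objective(x0, *args)
    res = minimize(
        penalized_objective,
        x0,
        args=args,
        method="L-BFGS-B",
        bounds=[(-LOG_HP_BOUND, LOG_HP_BOUND)] * 3,
        options={"maxiter": maxiter},
    )
    if not np.isfinite(res.fun) or res.fun > f0 + 1e-9:
        logger.warning("hyperparameter update did not improve the objective; keeping current values")
        return init
    return KernelHyperparams.from_log_array(res.x)


# ---------------------------------------------------------------------------
# Cluster model container
# ---------------------------------------------------------------------------

class ClusterModel:
    """Per-cluster GP state used by the sampler.

    Holds the kernel hyperparameters, the mean function on the full grid and
    the covariance in force for member likelihoods: the prior Gram matrix K
    for freshly seeded (empty/auxiliary) clusters, and the updated posterior
    covariance K* once the cluster's parameters have been refreshed from its
    members.  A gene's likelihood under the cluster is

        N(y | mean, C + sigma^2 I)   with C = K* (updated) or K (seeded),

    restricted to the gene's observed time points.  Cholesky factors of the
    restricted covariance are cached per missingness pattern and invalidated
    when the hyperparameters or the covariance change; ``factor_computations``
    counts actual factorizations (one per pattern per parameter setting).
    """

    __slots__ = ("grid", "hyperparams", "mean", "posterior_cov", "size",
                 "member_avg", "_gram", "_factors", "factor_computations", "label")

    def __init__(self, grid: TimeGrid, hyperparams: KernelHyperparams,
                 mean: np.ndarray | None = None, label=None):
        self.grid = grid
        self.hyperparams = hyperparams
        self.mean = np.zeros(grid.T) if mean is None else np.asarray(mean, dtype=float)
        self.posterior_cov: np.ndarray | None = None
        self.size = 0
        self.member_avg: np.ndarray | None = None
        self.label = label
        self._gram: np.ndarray | None = None
        self._factors: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
        self.factor_computations = 0

    # -- caches ------------------------------------------------------------
    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = gram_matrix(self.grid, self.hyperparams, include_noise=False)
        return self._gram

    @property
    def covariance(self) -> np.ndarray:
        """Non-noise covariance in force: K* once updated, else the prior K."""
        return self.posterior_cov if self.posterior_cov is not None else self.gram()

    def set_hyperparams(self, hp: KernelHyperparams) -> None:
        self.hyperparams = hp
        self._gram = None
        self._factors.clear()

    def set_posterior(self, mean: np.ndarray, posterior_cov: np.ndarray) -> None:
        self.mean = np.asarray(mean, dtype=float)
        self.posterior_cov = np.asarray(posterior_cov, dtype=float)
        self._factors.clear()

    def factor(self, mask_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cached ``(obs_idx, L)`` for the given observation pattern."""
        mask_row = np.asarray(mask_row, dtype=bool)
        key = mask_row.tobytes()
        hit = self._factors.get(key)
        if hit is not None:
            return hit
        obs = np.flatnonzero(mask_row)
        if obs.size == 0:
            raise DataError("all time points missing")
        C = self.covariance
        A = C[np.ix_(obs, obs)] + self.hyperparams.noise_variance * np.eye(obs.size)
        L = jittered_cholesky(A, context=f"(cluster {self.label})")
        self.factor_computations += 1
        self._factors[key] = (obs, L)
        return obs, L

    # -- likelihoods -------------------------------------------------------
    def log_likelihood(self, y: np.ndarray, mask: np.ndarray | None = None) -> float:
        """Log density of one trajectory under this cluster's GP."""
        y = np.asarray(y, dtype=float)
        if mask is None:
            mask = np.isfinite(y)
        obs, L = self.factor(mask)
        return _chol_logpdf(y[obs] - self.mean[obs], L)

    def log_likelihood_many(self, Y: np.ndarray, mask_row: np.ndarray) -> np.ndarray:
        """Vectorized log density of several trajectories sharing one pattern."""
        obs, L = self.factor(mask_row)
        R = (np.atleast_2d(Y)[:, obs] - self.mean[obs]).T  # T' x n
        Z = solve_triangular(L, R, lower=True)
        k = obs.size
        return -0.5 * np.sum(Z * Z, axis=0) - np.log(np.diag(L)).sum() - 0.5 * k * LOG_2PI
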