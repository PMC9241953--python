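"""One-dimensional Gaussian mixture model fitted by expectation–maximization.

This is the scoring engine of the package: pooled log2 bait-normalized
spectral counts are modelled as a mixture of (by default two) Gaussians —
a large low-abundance background component and a small high-abundance
component of proteins genuinely in complex with the bait.  The posterior
probability of the high-mean component is the interaction score.

Model
-----
Observations x_1..x_n are i.i.d. from

    p(x) = sum_j w_j N(x; m_j, v_j),   sum_j w_j = 1,

with all parameters estimated by EM.  Responsibilities are computed in log
space for numerical stability; M-step variances are floored to avoid the
classical single-point collapse degeneracy.  The convergence criterion is
the absolute change in total log-likelihood.

The fit is canonicalised with means in ascending order, so component ``k-1``
is always the high-abundance component when ties are absent.  All
randomness (restart perturbations) flows from one recorded seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import FitError, InsufficientDataError, ValidationError

__all__ = ["FitConfig", "MixtureFit", "fit_gmm", "posterior", "select_high_component", "bic", "select_k"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FitConfig:
    """EM settings.

    k:          number of components (2 = background vs bound).
    tol:        convergence tolerance on |change in log-likelihood|.
    max_iter:   EM iteration cap per restart.
    var_floor:  lower bound on component variances (log2^2 units).
    n_restarts: random restarts beyond the deterministic quantile start.
    seed:       seed for the restart perturbations, recorded in the fit.
    init:       'quantile' (deterministic) or 'random' (seeded draws).
    """

    k: int = 2
    tol: float = 1e-8
    max_iter: int = 10000
    var_floor: float = 1e-6
    n_restarts: int = 5
    seed: int = 0
    init: str = "quantile"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.var_floor <= 0:
            raise ValidationError("var_floor must be positive")
        if self.init not in ("quantile", "random"):
            raise ValidationError("init must be 'quantile' or 'random'")


@dataclass(frozen=True)
class MixtureFit:
    """A fitted 1-D Gaussian mixture in canonical (ascending-means) form."""

    k: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    variances: tuple[float, ...]
    log_likelihood: float
    n_obs: int
    n_iter: int
    converged: bool
    seed: int
    log_likelihood_path: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValidationError("mixture weights must sum to 1")
        if any(not (0.0 < w <= 1.0) for w in self.weights):
            raise ValidationError("each weight must lie in (0, 1]")
        if any(v <= 0 for v in self.variances):
            raise ValidationError("variances must be positive")
        if list(self.means) != sorted(self.means):
            raise ValidationError("means must be stored in ascending order")

    def summary(self) -> str:
        """Plain-text key-value block for logging."""
        lines = [
            f"k\t{self.k}",
            f"n_obs\t{self.n_obs}",
            f"log_likelihood\t{self.log_likelihood:.6f}",
            f"n_iter\t{self.n_iter}",
            f"converged\t{str(self.converged).lower()}",
            f"seed\t{self.seed}",
        ]
        for j in range(self.k):
            lines.append(
                f"component_{j}\tweight={self.weights[j]:.6g}\t"
                f"mean={self.means[j]:.6g}\tvariance={self.variances[j]:.6g}"
            )
        return "\n".join(lines) + "\n"


def _log_component_densities(
    x: np.ndarray, weights: np.ndarray, means: np.ndarray, variances: np.ndarray
) -> np.ndarray:
    """log(w_j) + log N(x_i; m_j, v_j) as an (n, k) matrix."""
    x = x[:, None]
    return (
        np.log(weights)[None, :]
        - 0.5 * (_LOG_2PI + np.log(variances))[None, :]
        - 0.5 * (x - means[None, :]) ** 2 / variances[None, :]
    )


def _em_run(
    x: np.ndarray,
    means0: np.ndarray,
    weights0: np.ndarray,
    variances0: np.ndarray,
    config: FitConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list[float]]:
    means, weights, variances = means0.copy(), weights0.copy(), variances0.copy()
    n = x.size
    prev_ll = -np.inf
    ll_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        log_wd = _log_component_densities(x, weights, means, variances)
        log_norm = logsumexp(log_wd, axis=1)
        ll = float(log_norm.sum())
        ll_path.append(ll)
        resp = np.exp(log_wd - log_norm[:, None])  # (n, k) responsibilities
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < config.tol:
            converged = True
            break
        prev_ll = ll
        # M-step
        nj = resp.sum(axis=0)
        nj = np.maximum(nj, 1e-300)  # guard against an emptied component
        weights = nj / n
        means = resp.T @ x / nj
        variances = np.maximum(
            (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nj,
            config.var_floor,
        )
    return means, weights, variances, ll_path[-1], it, converged, ll_path


def _seed_means_weighted(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted (k-means++-style) seeding of component means.

    Subsequent means are drawn with probability proportional to squared
    distance from the nearest already-chosen mean, which reliably places a
    start inside small, well-separated clusters that quantile starts miss.
    """
    means = [float(rng.choice(x))]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.asarray(means)[None, :]) ** 2, axis=1)
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(x.size, 1.0 / x.size)
        means.append(float(rng.choice(x, p=probs)))
    return np.asarray(means)


def _initial_params(
    x: np.ndarray, config: FitConfig, rng: np.random.Generator, restart: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = config.k
    sd = float(np.std(x))
    if restart == 0 and config.init == "quantile":
        # component j starts at the (2j+1)/(2k) sample quantile
        q = (2 * np.arange(k) + 1) / (2 * k)
        means = np.quantile(x, q)
    elif restart == 1 and config.init == "quantile" and k >= 2:
        # upper-tail start: a minority high-abundance component is the
        # expected structure of pulldown data, so probe the 98th percentile
        q = np.append((2 * np.arange(k - 1) + 1) / (2 * (k - 1)) * 0.9, 0.98)
        means = np.quantile(x, q)
    else:
        means = _seed_means_weighted(x, k, rng)
        means = np.sort(means + rng.normal(0.0, max(sd, 1e-3) / 10.0, size=k))
    # moment-match each component to its nearest-mean cluster: a component
    # seeded in a small distant cluster must start tight, not at the pooled
    # variance, or the first E-step dissolves it into the bulk
    labels = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
    weights = np.empty(k)
    variances = np.empty(k)
    for j in range(k):
        members = x[labels == j]
        if members.size == 0:
            weights[j] = 1.0 / x.size
            variances[j] = max(sd**2, config.var_floor)
            continue
        weights[j] = members.size / x.size
        means[j] = members.mean()
        variances[j] = max(float(members.var()), config.var_floor)
    weights = weights / weights.sum()
    return np.asarray(means, dtype=float), weights, variances


def fit_gmm(observations: Sequence[float] | np.ndarray, config: FitConfig | None = None) -> MixtureFit:
    """Fit a k-component 1-D Gaussian mixture by EM with restarts.

    The deterministic quantile start is always run; ``n_restarts`` further
    runs perturb it with a seeded generator.  The highest-likelihood run
    wins and is returned in canonical ascending-means form.

    Raises
    ------
    InsufficientDataError
        if fewer than ``5 * k`` observations are supplied.
    FitError
        if all observations are identical (no mixture is identifiable).
    """
    if config is None:
        config = FitConfig()
    x = np.asarray(observations, dtype=float)
    if x.ndim != 1:
        raise ValidationError("observations must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValidationError("observations must be finite")
    if x.size < 5 * config.k:
        raise InsufficientDataError(
            f"need at least {5 * config.k} observations for k={config.k}, got {x.size}"
        )
    if np.ptp(x) == 0.0:
        raise FitError("all observations identical; mixture is degenerate")

    rng = np.random.default_rng(config.seed)
    best: tuple | None = None
    for restart in range(config.n_restarts + 1):
        means0, weights0, variances0 = _initial_params(x, config, rng, restart)
        result = _em_run(x, means0, weights0, variances0, config)
        if best is None or result[3] > best[3]:
            best = result
    means, weights, variances, ll, n_iter, converged, ll_path = best

    order = np.lexsort((-weights, means))  # ascending mean; ties: heavier first
    means, weights, variances = means[order], weights[order], variances[order]
    weights = weights / weights.sum()  # renormalise away float drift
    return MixtureFit(
        k=config.k,
        weights=tuple(float(w) for w in weights),
        means=tuple(float(m) for m in means),
        variances=tuple(float(v) for v in variances),
        log_likelihood=ll,
        n_obs=int(x.size),
        n_iter=n_iter,
        converged=converged,
        seed=config.seed,
        log_likelihood_path=tuple(ll_path),
    )


def posterior(fit: MixtureFit, x: float | np.ndarray) -> np.ndarray:
    """Component posteriors at ``x`` by Bayes' rule, computed in log space.

    For scalar ``x`` returns a length-k vector; for an array of shape (n,)
    returns an (n, k) matrix.  Rows sum to 1 within 1e-12.
    """
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    log_wd = _log_component_densities(
        arr, np.asarray(fit.weights), np.asarray(fit.means), np.asarray(fit.variances)
    )
    out = np.exp(log_wd - logsumexp(log_wd, axis=1)[:, None])
    return out[0] if np.isscalar(x) or np.asarray(x).ndim == 0 else out


def select_high_component(fit: MixtureFit) -> int:
    """Index of the high-abundance component: largest mean, ties broken by
    larger weight, then lowest index."""
    best = 0
    for j in range(1, fit.k):
        if fit.means[j] > fit.means[best] or (
            fit.means[j] == fit.means[best] and fit.weights[j] > fit.weights[best]
        ):
            best = j
    return best


def bic(fit: MixtureFit) -> float:
    """Bayesian information criterion: (3k - 1) ln(n) - 2 * log-likelihood.

    A k-component 1-D mixture has 3k - 1 free parameters (k - 1 weights,
    k means, k variances).  Lower is better.
    """
    return (3 * fit.k - 1) * math.log(fit.n_obs) - 2.0 * fit.log_likelihood


def select_k(
    observations: Sequence[float] | np.ndarray,
    candidates: Sequence[int] = (1, 2, 3),
    config: FitConfig | None = None,
) -> MixtureFit:
    """Fit each candidate k and return the fit with the lowest BIC."""
    if config is None:
        config = FitConfig()
    fits = []
    for k in candidates:
        try:
            fits.append(fit_gmm(observations, FitConfig(**{**config.__dict__, "k": k})))
        except InsufficientDataError:
            continue
    if not fits:
        raise InsufficientDataError("no candidate k is fittable on these observations")
    return min(fits, key=bic)
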