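"""Domain types and likelihood computations for the mixRHLP model.

The mixture of regressions with hidden logistic processes (mixRHLP) describes
multi-subject univariate time series observed on a shared time grid.  Each
subject i belongs to a latent cluster Z_i in {1..K} with mixing proportions
alpha_k.  Within cluster k, the latent regime H_ij at time t_j follows a
multinomial logistic model in time,

    P(H_ij = r | t_j, Z_i = k) = exp(w_kr0 + w_kr1 t_j) / sum_s exp(w_ks0 + w_ks1 t_j),

with the last regime as the zero-pinned reference class, and the observation
is Gaussian around a polynomial trend of order d,

    y_i(t_j) | H_ij = r, Z_i = k  ~  N(X_j beta_kr, sigma2_kr),

where X_j = (1, t_j, ..., t_j^d).  All probability arithmetic here is done in
log space with log-sum-exp; at several hundred time points per subject the
per-subject component densities underflow catastrophically in linear space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "TimeGrid",
    "PanelData",
    "ModelSpec",
    "Parameters",
    "design_matrix",
    "regime_log_probabilities",
    "regime_probabilities",
    "emission_logdensity",
    "component_loglik",
    "total_loglik",
    "posterior_cluster",
    "posterior_regime",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class InvalidParameterError(ValueError):
    """Raised when model parameters violate their invariants."""


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing time points shared by every subject in a panel."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("time grid needs at least two points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("time grid must be finite")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def n_times(self) -> int:
        return self.points.size

    @classmethod
    def unit(cls, n_times: int) -> "TimeGrid":
        """Equally spaced grid of ``n_times`` points spanning [0, 1] inclusive."""
        return cls(np.linspace(0.0, 1.0, n_times))


@dataclass
class PanelData:
    """Subject-by-time observation matrix with an observed-cell mask.

    ``values[i, j]`` is subject i's measurement at ``grid.points[j]``; cells
    with ``observed[i, j]`` False are missing (their values may be NaN).
    """

    grid: TimeGrid
    values: np.ndarray
    observed: np.ndarray | None = None
    subject_ids: Sequence | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.observed is None:
            self.observed = np.ones(self.values.shape, dtype=bool)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed mask shapes differ")
        if self.values.shape[1] != self.grid.n_times:
            raise ValueError("values do not conform to the time grid")
        if self.values.shape[0] < 1:
            raise ValueError("panel needs at least one subject")
        if not self.observed.any(axis=1).all():
            raise ValueError("every subject needs at least one observed cell")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise ValueError("observed values must be finite")
        if self.subject_ids is None:
            self.subject_ids = list(range(1, self.values.shape[0] + 1))
        elif len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.grid.n_times

    @property
    def complete(self) -> bool:
        return bool(self.observed.all())

    def require_complete(self) -> None:
        if not self.complete:
            raise ValueError(
                "panel contains missing cells; impute before likelihood evaluation"
            )


VARIANCE_STRUCTURES = ("heteroskedastic", "homoskedastic")


@dataclass(frozen=True, order=True)
class ModelSpec:
    """One candidate model: K clusters, R regimes, polynomial order d."""

    n_clusters: int
    n_regimes: int
    degree: int
    variance_structure: str = "heteroskedastic"

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_regimes < 1 or self.degree < 0:
            raise ValueError("need K >= 1, R >= 1, d >= 0")
        if self.variance_structure not in VARIANCE_STRUCTURES:
            raise ValueError(f"variance_structure must be one of {VARIANCE_STRUCTURES}")

    @property
    def homoskedastic(self) -> bool:
        return self.variance_structure == "homoskedastic"

    def to_dict(self) -> dict:
        return {
            "K": self.n_clusters,
            "R": self.n_regimes,
            "d": self.degree,
            "variance_structure": self.variance_structure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(d["K"], d["R"], d["d"], d.get("variance_structure", "heteroskedastic"))


@dataclass
class Parameters:
    """Full parameter set Theta = (alpha, omega, beta, sigma2).

    Shapes: ``alpha`` (K,), ``omega`` (K, R, 2), ``beta`` (K, R, d+1),
    ``sigma2`` (K, R).  The last regime is the reference class of the logistic
    model, so ``omega[k, -1, :] == 0`` for every cluster k.
    """

    alpha: np.ndarray
    omega: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    spec: ModelSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        K = self.alpha.size
        if self.omega.ndim != 3 or self.beta.ndim != 3 or self.omega.shape[0] != K:
            raise InvalidParameterError("omega/beta shape inconsistent with alpha")
        R = self.omega.shape[1]
        d = self.beta.shape[2] - 1
        if self.spec is None:
            self.spec = ModelSpec(K, R, d)
        if self.omega.shape != (K, R, 2):
            raise InvalidParameterError("omega must have shape (K, R, 2)")
        if self.beta.shape != (K, R, d + 1):
            raise InvalidParameterError("beta must have shape (K, R, d+1)")
        if self.sigma2.shape != (K, R):
            raise InvalidParameterError("sigma2 must have shape (K, R)")
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.alpha)) or np.any(self.alpha < -1e-12):
            raise InvalidParameterError("alpha must be finite and non-negative")
        if abs(self.alpha.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("alpha must sum to 1")
        if not np.all(np.isfinite(self.omega)):
            raise InvalidParameterError("omega must be finite")
        if np.any(self.omega[:, -1, :] != 0.0):
            raise InvalidParameterError("reference regime omega row must be zero")
        if not np.all(np.isfinite(self.beta)):
            raise InvalidParameterError("beta must be finite")
        if np.any(self.sigma2 <= 0) or not np.all(np.isfinite(self.sigma2)):
            raise InvalidParameterError("sigma2 must be positive and finite")

    @property
    def n_clusters(self) -> int:
        return self.alpha.size

    @property
    def n_regimes(self) -> int:
        return self.omega.shape[1]

    @property
    def degree(self) -> int:
        return self.beta.shape[2] - 1

    @property
    def sigma(self) -> np.ndarray:
        """Residual standard deviations, sqrt(sigma2)."""
        return np.sqrt(self.sigma2)

    def copy(self) -> "Parameters":
        return Parameters(
            self.alpha.copy(), self.omega.copy(), self.beta.copy(),
            self.sigma2.copy(), self.spec,
        )

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "omega": self.omega.tolist(),
            "beta": self.beta.tolist(),
            "sigma2": self.sigma2.tolist(),
            "spec": self.spec.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        spec = ModelSpec.from_dict(d["spec"]) if "spec" in d else None
        return cls(
            np.asarray(d["alpha"]), np.asarray(d["omega"]),
            np.asarray(d["beta"]), np.asarray(d["sigma2"]), spec,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Parameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def design_matrix(grid: TimeGrid | np.ndarray, degree: int) -> np.ndarray:
    """Vandermonde design matrix with rows X_j = (1, t_j, ..., t_j^d).

    The raw (non-orthogonalized) basis is used throughout so that reported
    coefficients are on the plain polynomial scale.
    """
    t = grid.points if isinstance(grid, TimeGrid) else np.asarray(grid, dtype=float)
    return np.vander(t, degree + 1, increasing=True)


def regime_log_probabilities(omega_k: np.ndarray, grid: TimeGrid | np.ndarray) -> np.ndarray:
    """Log of the multinomial-logistic regime probabilities, shape (N_t, R).

    Row j is the log-softmax of (w_r0 + w_r1 t_j) over regimes r; the row
    maximum is subtracted before exponentiating for stability.
    """
    omega_k = np.asarray(omega_k, dtype=float)
    if not np.all(np.isfinite(omega_k)):
        raise InvalidParameterError("omega must be finite")
    t = grid.points if isinstance(grid, TimeGrid) else np.asarray(grid, dtype=float)
    logits = omega_k[:, 0][None, :] + np.outer(t, omega_k[:, 1])  # (N_t, R)
    logits -= logits.max(axis=1, keepdims=True)
    return logits - logsumexp(logits, axis=1, keepdims=True)


def regime_probabilities(omega_k: np.ndarray, grid: TimeGrid | np.ndarray) -> np.ndarray:
    """Multinomial-logistic regime probabilities pi_kr(t_j), rows summing to 1."""
    return np.exp(regime_log_probabilities(omega_k, grid))


def emission_logdensity(y, mean, sigma2) -> np.ndarray:
    """Gaussian log density log N(y; mean, sigma2); broadcasts over arrays."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise InvalidParameterError("sigma2 must be positive")
    resid = np.asarray(y, dtype=float) - np.asarray(mean, dtype=float)
    return -0.5 * (_LOG2PI + np.log(sigma2) + resid * resid / sigma2)


def _pointwise_log_joint(values: np.ndarray, grid: TimeGrid, params: Parameters) -> np.ndarray:
    """log[pi_kr(t_j) N(y_ij; X_j beta_kr, sigma2_kr)], shape (N_p, N_t, K, R)."""
    K, R = params.n_clusters, params.n_regimes
    X = design_matrix(grid, params.degree)                       # (N_t, d+1)
    means = np.einsum("jd,krd->krj", X, params.beta)             # (K, R, N_t)
    ld = emission_logdensity(values[:, None, None, :], means[None], params.sigma2[None, :, :, None])
    logpi = np.stack([regime_log_probabilities(params.omega[k], grid) for k in range(K)])
    # ld is (N_p, K, R, N_t), logpi is (K, N_t, R); align both to (N_p, N_t, K, R)
    return ld.transpose(0, 3, 1, 2) + logpi.transpose(1, 0, 2)[None]


def pointwise_log_joint(data: PanelData, params: Parameters) -> np.ndarray:
    """Per-cell log joint of regime and emission, shape (N_p, N_t, K, R)."""
    data.require_complete()
    return _pointwise_log_joint(data.values, data.grid, params)


def component_loglik(y_i: np.ndarray, grid: TimeGrid, params: Parameters, k: int) -> float:
    """Log density of one subject's complete series under cluster k.

    Sum over time of log sum_r pi_kr(t_j) N(y(t_j); X_j beta_kr, sigma2_kr),
    each inner sum taken with log-sum-exp.
    """
    y_i = np.asarray(y_i, dtype=float)
    lp = _pointwise_log_joint(y_i[None, :], grid, params)[0, :, k, :]  # (N_t, R)
    return float(logsumexp(lp, axis=1).sum())


def component_logliks(data: PanelData, params: Parameters) -> np.ndarray:
    """Matrix of per-subject, per-cluster log component densities, (N_p, K)."""
    lp = pointwise_log_joint(data, params)
    return logsumexp(lp, axis=3).sum(axis=1)


def total_loglik(data: PanelData, params: Parameters) -> float:
    """Observed-data log-likelihood l(Theta) = sum_i log sum_k alpha_k p_k(y_i)."""
    ll = component_logliks(data, params)
    log_alpha = np.log(np.maximum(params.alpha, 1e-300))
    return float(logsumexp(ll + log_alpha[None, :], axis=1).sum())


def posterior_cluster(data: PanelData, params: Parameters) -> np.ndarray:
    """Posterior cluster probabilities tau_ik, shape (N_p, K); rows sum to 1."""
    ll = component_logliks(data, params)
    log_alpha = np.log(np.maximum(params.alpha, 1e-300))
    log_tau = ll + log_alpha[None, :]
    log_tau -= logsumexp(log_tau, axis=1, keepdims=True)
    return np.exp(log_tau)


def posterior_regime(y_i: np.ndarray, grid: TimeGrid, params: Parameters, k: int) -> np.ndarray:
    """Posterior regime probabilities under cluster k, shape (N_t, R).

    Entry (j, r) is proportional to pi_kr(t_j) N(y(t_j); X_j beta_kr,
    sigma2_kr), normalized within each time point.
    """
    y_i = np.asarray(y_i, dtype=float)
    lp = _pointwise_log_joint(y_i[None, :], grid, params)[0, :, k, :]
    lp -= logsumexp(lp, axis=1, keepdims=True)
    return np.exp(lp)
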