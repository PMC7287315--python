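"""Maximum-likelihood estimation of the mixRHLP model via EM.

The E-step computes cluster responsibilities tau_ik and, within each cluster,
per-time-point regime responsibilities gamma_ijkr.  The M-step updates the
mixing proportions in closed form, the regression coefficients by weighted
least squares, the variances as weighted mean squared residuals (pooled when
homoskedastic), and the logistic regime coefficients by a Newton-Raphson /
IRLS inner loop on the weighted multinomial log-likelihood with fractional
targets.  Because each M-step maximizes (or at least never decreases, thanks
to step-halving) the expected complete-data log-likelihood, the observed-data
log-likelihood ascends monotonically.

The likelihood surface is multimodal; ``fit`` therefore runs several
independently initialized EM chains and keeps the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import (
    InvalidParameterError,
    ModelSpec,
    PanelData,
    Parameters,
    design_matrix,
    regime_log_probabilities,
)

__all__ = ["FitControls", "FitResult", "FitError", "fit", "initialize", "irls_logistic"]


class FitError(RuntimeError):
    """All EM starts failed."""


@dataclass(frozen=True)
class FitControls:
    """Knobs for the EM outer loop and the IRLS inner loop."""

    max_iter: int = 1000
    tol: float = 1e-8
    n_starts: int = 10
    irls_max_iter: int = 50
    irls_tol: float = 1e-8
    variance_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.irls_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("max_iter and n_starts must be >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclass
class FitResult:
    """Outcome of one (multi-start) EM fit."""

    params: Parameters
    loglik: float
    loglik_trace: np.ndarray
    cluster_posterior: np.ndarray
    converged: bool
    n_iter: int
    spec: ModelSpec
    n_params: int
    criteria: dict = field(default_factory=dict)
    start_logliks: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
            "cluster_posterior": np.asarray(self.cluster_posterior).tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "spec": self.spec.to_dict(),
            "n_params": self.n_params,
            "criteria": self.criteria,
            "start_logliks": list(self.start_logliks),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            params=Parameters.from_dict(d["params"]),
            loglik=d["loglik"],
            loglik_trace=np.asarray(d["loglik_trace"]),
            cluster_posterior=np.asarray(d["cluster_posterior"]),
            converged=d["converged"],
            n_iter=d["n_iter"],
            spec=ModelSpec.from_dict(d["spec"]),
            n_params=d["n_params"],
            criteria=d.get("criteria", {}),
            start_logliks=d.get("start_logliks", []),
        )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(
    data: PanelData,
    spec: ModelSpec,
    seed: int,
    strategy: str = "random_partition",
) -> Parameters:
    """Build starting Parameters from a rough partition of the data.

    ``random_partition`` assigns subjects uniformly at random to K clusters
    (repairing empty clusters); ``contiguous_segments`` orders subjects by
    their series mean and cuts the ordering into K consecutive groups.  Within
    each cluster, the time axis is split into R contiguous equal blocks and an
    OLS polynomial of order d is fitted per block to seed beta and sigma2.
    Logistic coefficients start at zero (uniform regime probabilities).
    Deterministic given ``seed``.
    """
    K, R, d = spec.n_clusters, spec.n_regimes, spec.degree
    n_p, n_t = data.n_subjects, data.n_times
    if K > n_p:
        raise ValueError("more clusters than subjects")
    rng = np.random.default_rng(seed)

    if strategy == "random_partition":
        z = rng.integers(0, K, size=n_p)
        for k in range(K):  # repair empty clusters
            if not np.any(z == k):
                z[rng.integers(0, n_p)] = k
    elif strategy == "contiguous_segments":
        order = np.argsort(data.values.mean(axis=1), kind="stable")
        z = np.empty(n_p, dtype=int)
        for k, chunk in enumerate(np.array_split(order, K)):
            z[chunk] = k
    else:
        raise ValueError(f"unknown initialization strategy {strategy!r}")

    X = design_matrix(data.grid, d)
    blocks = np.array_split(np.arange(n_t), R)
    beta = np.zeros((K, R, d + 1))
    sigma2 = np.ones((K, R))
    counts = np.bincount(z, minlength=K).astype(float)
    alpha = counts / counts.sum()
    for k in range(K):
        yk = data.values[z == k]
        for r, idx in enumerate(blocks):
            Xb = np.tile(X[idx], (yk.shape[0], 1))
            yb = yk[:, idx].ravel()
            coef, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
            beta[k, r] = coef
            resid = yb - Xb @ coef
            sigma2[k, r] = max(float(np.mean(resid**2)), 1e-6)
    omega = np.zeros((K, R, 2))
    return Parameters(alpha, omega, beta, sigma2, spec)


# ---------------------------------------------------------------------------
# IRLS for the logistic regime model
# ---------------------------------------------------------------------------

def _logistic_objective(omega: np.ndarray, counts: np.ndarray, t: np.ndarray) -> float:
    logpi = regime_log_probabilities(omega, t)
    return float(np.sum(counts * logpi))


def irls_logistic(
    counts: np.ndarray,
    grid,
    omega_init: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    max_halvings: int = 30,
) -> np.ndarray:
    """Fit multinomial logistic coefficients to fractional per-time targets.

    Maximizes sum_{j,r} counts[j, r] * log pi_r(t_j) over omega (shape (R, 2),
    last row pinned at zero) by Newton-Raphson with step-halving; the returned
    coefficients never have a worse objective than ``omega_init``.  ``counts``
    are non-negative regime responsibilities aggregated over subjects.
    """
    counts = np.asarray(counts, dtype=float)
    t = grid.points if hasattr(grid, "points") else np.asarray(grid, dtype=float)
    R = counts.shape[1]
    if R == 1:
        return np.zeros((1, 2))
    if np.any(counts < -1e-12):
        raise ValueError("responsibilities must be non-negative")
    U = np.column_stack([np.ones_like(t), t])       # (N_t, 2)
    omega = np.asarray(omega_init, dtype=float).copy()
    n_j = counts.sum(axis=1)                        # (N_t,)
    obj = _logistic_objective(omega, counts, t)
    n_free = R - 1

    for _ in range(max_iter):
        pi = np.exp(regime_log_probabilities(omega, t))      # (N_t, R)
        # gradient for free regimes r = 0..R-2
        g = np.einsum("jr,jc->rc", counts[:, :n_free] - n_j[:, None] * pi[:, :n_free], U)
        grad = g.ravel()
        if np.linalg.norm(grad, ord=np.inf) < tol:
            break
        # Hessian of the log-likelihood (negative definite)
        H = np.zeros((2 * n_free, 2 * n_free))
        UU = np.einsum("jc,jd->jcd", U, U)                   # (N_t, 2, 2)
        for r in range(n_free):
            for s in range(n_free):
                w = n_j * pi[:, r] * ((r == s) - pi[:, s])
                H[2 * r:2 * r + 2, 2 * s:2 * s + 2] = -np.einsum("j,jcd->cd", w, UU)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(2 * n_free), -grad)
        except np.linalg.LinAlgError:
            step = grad / max(n_j.sum(), 1.0)                # gradient fallback
        if not np.all(np.isfinite(step)):
            step = grad / max(n_j.sum(), 1.0)

        # step-halving: accept only non-decreasing objective
        accepted = False
        scale = 1.0
        for _h in range(max_halvings + 1):
            cand = omega.copy()
            cand[:n_free] += scale * step.reshape(n_free, 2)
            cand_obj = _logistic_objective(cand, counts, t)
            if np.isfinite(cand_obj) and cand_obj >= obj:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break
        improvement = cand_obj - obj
        omega, obj = cand, cand_obj
        if improvement < tol * (abs(obj) + 1.0):
            break
    return omega


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def _e_step(y: np.ndarray, X: np.ndarray, grid, params: Parameters):
    """Return (loglik, tau (N_p,K), gamma (N_p,N_t,K,R))."""
    K = params.n_clusters
    means = np.einsum("jd,krd->krj", X, params.beta)             # (K, R, N_t)
    resid = y[:, None, None, :] - means[None]                    # (N_p, K, R, N_t)
    s2 = params.sigma2[None, :, :, None]
    ld = -0.5 * (np.log(2 * np.pi * s2) + resid**2 / s2)
    logpi = np.stack([regime_log_probabilities(params.omega[k], grid) for k in range(K)])
    lp = ld.transpose(0, 3, 1, 2) + logpi.transpose(1, 0, 2)[None]   # (N_p, N_t, K, R)
    lse_r = logsumexp(lp, axis=3)                                # (N_p, N_t, K)
    comp_ll = lse_r.sum(axis=1)                                  # (N_p, K)
    log_tau = comp_ll + np.log(np.maximum(params.alpha, 1e-300))[None]
    norm = logsumexp(log_tau, axis=1)
    loglik = float(norm.sum())
    tau = np.exp(log_tau - norm[:, None])
    gamma = np.exp(lp - lse_r[..., None])
    return loglik, tau, gamma


def _m_step(
    y: np.ndarray,
    X: np.ndarray,
    grid,
    params: Parameters,
    tau: np.ndarray,
    gamma: np.ndarray,
    controls: FitControls,
) -> Parameters:
    K, R = params.n_clusters, params.n_regimes
    w = tau[:, None, :, None] * gamma                            # (N_p, N_t, K, R)
    alpha = tau.mean(axis=0)
    alpha = alpha / alpha.sum()

    beta = params.beta.copy()
    sigma2 = params.sigma2.copy()
    a = w.sum(axis=0)                                            # (N_t, K, R) weights per time
    b = np.einsum("ijkr,ij->jkr", w, y)                          # weighted y sums
    sq_acc = 0.0
    ridge = 1e-10 * np.eye(X.shape[1])
    for k in range(K):
        for r in range(R):
            a_j, b_j = a[:, k, r], b[:, k, r]
            tot = a_j.sum()
            if tot > 1e-12:
                G = X.T @ (a_j[:, None] * X) + ridge
                try:
                    beta[k, r] = np.linalg.solve(G, X.T @ b_j)
                except np.linalg.LinAlgError:
                    pass
            mean = X @ beta[k, r]
            sq = float(np.einsum("ij,ij->", w[:, :, k, r], (y - mean[None, :]) ** 2))
            sq_acc += sq
            if not params.spec.homoskedastic and tot > 1e-12:
                sigma2[k, r] = max(sq / tot, controls.variance_floor)
    if params.spec.homoskedastic:
        pooled = max(sq_acc / y.size, controls.variance_floor)
        sigma2[:] = pooled

    omega = params.omega.copy()
    for k in range(K):
        counts = w[:, :, k, :].sum(axis=0)                       # (N_t, R)
        omega[k] = irls_logistic(
            counts, grid, params.omega[k],
            max_iter=controls.irls_max_iter, tol=controls.irls_tol,
        )
    return Parameters(alpha, omega, beta, sigma2, params.spec)


def _em_single(data: PanelData, params: Parameters, controls: FitControls):
    y = data.values
    X = design_matrix(data.grid, params.degree)
    trace: list[float] = []
    converged = False
    tau = None
    ll = -np.inf
    for it in range(controls.max_iter):
        ll_new, tau, gamma = _e_step(y, X, data.grid, params)
        if not np.isfinite(ll_new):
            raise FloatingPointError("non-finite log-likelihood")
        trace.append(ll_new)
        if it > 0 and abs(ll_new - ll) / (abs(ll_new) + 1.0) < controls.tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
        params = _m_step(y, X, data.grid, params, tau, gamma, controls)
    return params, ll, np.asarray(trace), tau, converged, len(trace)


def fit(
    data: PanelData,
    spec: ModelSpec,
    controls: FitControls = FitControls(),
    init_params: Parameters | None = None,
    init_strategy: str = "random_partition",
) -> FitResult:
    """Fit the mixRHLP model by multi-start EM and keep the best start.

    ``data`` must be complete (impute first).  When ``init_params`` is given a
    single EM chain is run from those values (useful for truth-initialized
    recovery checks); otherwise ``controls.n_starts`` chains start from
    ``initialize`` with seeds derived from ``controls.seed``.
    """
    from .selection import count_parameters, information_criteria

    data.require_complete()
    starts: list[Parameters] = []
    if init_params is not None:
        starts = [init_params.copy()]
    else:
        for s in range(controls.n_starts):
            starts.append(
                initialize(data, spec, seed=controls.seed * 1_000_003 + s,
                           strategy=init_strategy)
            )

    best = None
    start_lls: list[float] = []
    for p0 in starts:
        try:
            out = _em_single(data, p0, controls)
        except (FloatingPointError, np.linalg.LinAlgError, InvalidParameterError) as exc:
            warnings.warn(f"EM start failed: {exc}")
            start_lls.append(float("nan"))
            continue
        start_lls.append(out[1])
        if best is None or out[1] > best[1]:
            best = out
    if best is None:
        raise FitError("all EM starts failed")

    params, ll, trace, tau, converged, n_iter = best
    q = count_parameters(spec)
    crit = information_criteria(ll, q, data.n_times, data.n_subjects)
    return FitResult(
        params=params,
        loglik=ll,
        loglik_trace=trace,
        cluster_posterior=tau,
        converged=converged,
        n_iter=n_iter,
        spec=spec,
        n_params=q,
        criteria=crit,
        start_logliks=start_lls,
    )
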