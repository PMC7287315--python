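"""Information criteria and grid search over candidate model specifications.

Criteria follow the penalized-likelihood form c = penalty(|Theta|, n) - 2 l_M
with effective sample size n = N_t * N_p (total number of observed cells):

    BIC   = log(n) q - 2 l_M
    saBIC = log((n + 2) / 24) q - 2 l_M        (Sclove's sample adjustment)
    AIC   = 2 q - 2 l_M
    AICc  = AIC + (2 q^2 + 2 q) / (n - q - 1)

The smallest value indicates the preferred model.  ``grid_search`` fits every
(K, R, d) combination — the canonical grid K, R in 1..4 and d in 1..2 yields
32 candidates — and ranks the surviving fits per criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .em import FitControls, FitError, FitResult, fit
from .model import ModelSpec, PanelData

__all__ = [
    "CRITERIA",
    "count_parameters",
    "information_criteria",
    "grid_search",
    "SelectionReport",
]

CRITERIA = ("BIC", "saBIC", "AIC", "AICc")

DEFAULT_KS = (1, 2, 3, 4)
DEFAULT_RS = (1, 2, 3, 4)
DEFAULT_DS = (1, 2)


def count_parameters(spec: ModelSpec) -> int:
    """Number of free parameters |Theta| of a model specification.

    (K-1) mixing proportions, 2K(R-1) logistic coefficients (the reference
    regime is pinned), KR(d+1) regression coefficients, and KR variances
    (one pooled variance when homoskedastic).
    """
    K, R, d = spec.n_clusters, spec.n_regimes, spec.degree
    n_var = 1 if spec.homoskedastic else K * R
    return (K - 1) + 2 * K * (R - 1) + K * R * (d + 1) + n_var


def information_criteria(loglik: float, n_params: int, n_times: int, n_subjects: int) -> dict:
    """BIC, saBIC, AIC and AICc from a maximized log-likelihood.

    AICc is NaN when its denominator n - q - 1 is non-positive.
    """
    n = n_times * n_subjects
    q = n_params
    aic = 2 * q - 2 * loglik
    denom = n - q - 1
    aicc = aic + (2 * q * q + 2 * q) / denom if denom > 0 else float("nan")
    return {
        "BIC": math.log(n) * q - 2 * loglik,
        "saBIC": math.log((n + 2) / 24.0) * q - 2 * loglik,
        "AIC": aic,
        "AICc": aicc,
    }


@dataclass
class SelectionReport:
    """Fits over a spec grid with per-criterion rankings."""

    fits: list
    failures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self._ranks: dict[str, dict[ModelSpec, int]] = {}
        for crit in CRITERIA:
            # sort by criterion value, ties broken by parsimony (K, R, d)
            keyed = sorted(
                self.fits,
                key=lambda f: (
                    f.criteria[crit] if f.criteria[crit] == f.criteria[crit] else float("inf"),
                    (f.spec.n_clusters, f.spec.n_regimes, f.spec.degree),
                ),
            )
            self._ranks[crit] = {f.spec: i + 1 for i, f in enumerate(keyed)}

    def rank_of(self, spec: ModelSpec, criterion: str) -> int:
        return self._ranks[criterion][spec]

    def best(self, criterion: str = "BIC", parsimony_window: int = 1) -> FitResult:
        """Winning fit for a criterion.

        With ``parsimony_window`` w > 1, the fit with the fewest parameters
        among the w smallest criterion values is returned (mirroring the
        practice of preferring the more parsimonious model among the top few).
        """
        order = sorted(self.fits, key=lambda f: self.rank_of(f.spec, criterion))
        window = order[: max(1, parsimony_window)]
        return min(window, key=lambda f: (f.n_params, self.rank_of(f.spec, criterion)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row = {
                "K": f.spec.n_clusters,
                "R": f.spec.n_regimes,
                "d": f.spec.degree,
                "variance_structure": f.spec.variance_structure,
                "loglik": f.loglik,
                "n_params": f.n_params,
                "converged": f.converged,
            }
            for crit in CRITERIA:
                row[crit] = f.criteria[crit]
                row[f"rank_{crit}"] = self.rank_of(f.spec, crit)
            rows.append(row)
        return pd.DataFrame(rows).sort_values("BIC").reset_index(drop=True)


def grid_search(
    data: PanelData,
    Ks=DEFAULT_KS,
    Rs=DEFAULT_RS,
    ds=DEFAULT_DS,
    variance_structure: str = "heteroskedastic",
    controls: FitControls = FitControls(),
) -> SelectionReport:
    """Fit every (K, R, d) combination and rank the fits per criterion.

    Individual fit failures are recorded in ``failures`` and do not abort the
    grid; an error is raised only if every fit fails.
    """
    fits, failures = [], []
    for K, R, d in product(Ks, Rs, ds):
        spec = ModelSpec(K, R, d, variance_structure)
        try:
            fits.append(fit(data, spec, controls))
        except (FitError, ValueError) as exc:
            failures.append((spec, str(exc)))
    if not fits:
        raise FitError("every fit in the grid failed")
    return SelectionReport(fits, failures)
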