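"""Data generation from the mixRHLP generative process.

``simulate`` draws multi-subject series on an equally spaced unit grid:
cluster membership from Categorical(alpha), a regime at each time point from
the logistic probabilities pi_{kr}(t_j), and the observation from the
regime's Gaussian polynomial emission.  ``apply_mcar`` masks cells completely
at random; ``impute_linear`` fills missing cells by linear interpolation in
time (nearest-value fill at the edges), matching the usual impute-then-fit
workflow for panel methods that require complete series.

``benchmark_parameters`` returns the two-cluster, three-regime, linear
(K=2, R=3, d=1) generating model used throughout the package's Monte Carlo
studies: well-separated cluster trends with crossing regime lines that are
hard to tell apart by eye, equal residual scale sigma across all clusters and
regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import Labeling
from .model import ModelSpec, PanelData, Parameters, TimeGrid, design_matrix, regime_probabilities

__all__ = [
    "SimOutput",
    "SimulationDesign",
    "simulate",
    "apply_mcar",
    "impute_linear",
    "benchmark_parameters",
    "synthetic_tablet_events",
]


@dataclass
class SimOutput:
    """A simulated panel plus everything needed to score a fit against truth."""

    data: PanelData        # post-missingness (masked cells NaN)
    complete: PanelData    # pre-missingness
    truth: Labeling
    params: Parameters
    seed: int


@dataclass(frozen=True)
class SimulationDesign:
    """Factor levels of the full factorial Monte Carlo design."""

    n_subjects_levels: tuple = (20, 60, 100)
    n_times_levels: tuple = (20, 160, 300)
    sigma_levels: tuple = (0.10, 0.15, 0.20)
    p_miss_levels: tuple = (0.0, 0.1, 0.2)
    n_runs: int = 200

    def conditions(self):
        for n_p in self.n_subjects_levels:
            for n_t in self.n_times_levels:
                for sigma in self.sigma_levels:
                    for p in self.p_miss_levels:
                        yield (n_p, n_t, sigma, p)


def benchmark_parameters(sigma: float = 0.10) -> Parameters:
    """Two-cluster, three-regime linear generating model for recovery studies.

    ``sigma`` is the common residual standard deviation (typical levels 0.10,
    0.15, 0.20).  Cluster 1 mixes three downward lines, cluster 2 three upward
    lines; the logistic coefficients make regime occupancy drift over the unit
    interval with the last regime as reference.
    """
    spec = ModelSpec(2, 3, 1, "heteroskedastic")
    alpha = np.array([0.5, 0.5])
    omega = np.array([
        [[-2.0, 3.0], [1.0, -2.5], [0.0, 0.0]],
        [[-1.0, 2.0], [0.5, -2.0], [0.0, 0.0]],
    ])
    beta = np.array([
        [[0.0, -1.5], [0.6, -0.9], [1.2, -0.3]],
        [[0.6, 0.3], [1.2, 0.9], [1.8, 1.5]],
    ])
    sigma2 = np.full((2, 3), float(sigma) ** 2)
    return Parameters(alpha, omega, beta, sigma2, spec)


def simulate(params: Parameters, n_subjects: int, n_times: int, seed: int) -> SimOutput:
    """Draw a complete panel from the generative model; deterministic per seed."""
    rng = np.random.default_rng(seed)
    grid = TimeGrid.unit(n_times)
    K, R = params.n_clusters, params.n_regimes
    X = design_matrix(grid, params.degree)
    means = np.einsum("jd,krd->krj", X, params.beta)       # (K, R, N_t)
    pis = np.stack([regime_probabilities(params.omega[k], grid) for k in range(K)])

    z = rng.choice(K, size=n_subjects, p=params.alpha)
    values = np.empty((n_subjects, n_times))
    regimes = np.empty((n_subjects, n_times), dtype=int)
    u = rng.random((n_subjects, n_times))
    noise = rng.standard_normal((n_subjects, n_times))
    cums = np.cumsum(pis, axis=2)                          # (K, N_t, R)
    cols = np.arange(n_times)
    for i in range(n_subjects):
        k = int(z[i])
        h = (u[i][:, None] > cums[k]).sum(axis=1)          # inverse-CDF draw
        regimes[i] = h
        values[i] = means[k, h, cols] + np.sqrt(params.sigma2[k, h]) * noise[i]

    panel = PanelData(grid, values)
    truth = Labeling(z + 1, regimes + 1)
    return SimOutput(data=panel, complete=panel, truth=truth, params=params, seed=seed)


def apply_mcar(
    data: PanelData, p_miss: float, seed: int, protect_endpoints: bool = True
) -> PanelData:
    """Mask each cell independently with probability ``p_miss`` (MCAR).

    With ``protect_endpoints`` (default) every subject's first and last grid
    points stay observed so that linear interpolation is defined everywhere
    without edge extrapolation; without it, edge gaps are later filled with
    the nearest observed value.
    """
    if not 0 <= p_miss < 1:
        raise ValueError("p_miss must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(data.values.shape) >= p_miss        # True = observed
    if protect_endpoints:
        mask[:, 0] = True
        mask[:, -1] = True
    # never leave a subject with fewer than two observed cells
    for i in range(mask.shape[0]):
        if mask[i].sum() < 2:
            mask[i, [0, -1]] = True
    values = np.where(mask, data.values, np.nan)
    return PanelData(data.grid, values, mask, data.subject_ids)


def impute_linear(data: PanelData) -> PanelData:
    """Fill missing cells by linear interpolation in time.

    Interior gaps are interpolated between the nearest observed neighbors;
    leading/trailing gaps take the nearest observed value.  Requires at least
    two observed cells per subject; returns a fully observed panel.
    """
    t = data.grid.points
    values = data.values.copy()
    for i in range(data.n_subjects):
        obs = data.observed[i]
        if obs.sum() < 2:
            raise ValueError(f"subject {data.subject_ids[i]} has fewer than 2 observed cells")
        if not obs.all():
            values[i, ~obs] = np.interp(t[~obs], t[obs], values[i, obs])
    return PanelData(data.grid, values, None, data.subject_ids)


def synthetic_tablet_events(
    n_subjects: int = 12,
    seed: int = 0,
    mean_events: int = 800,
    duration_range: tuple = (200.0, 820.0),
):
    """Synthetic emulation of irregular two-hand tablet trajectories.

    This generator is a stand-in for real hand-movement recordings: it is
    entirely synthetic and only mimics their structure for pipeline testing.
    Each subject produces irregularly spaced event times over a random session
    duration (seconds) with two positive channels (left/right hand heights).
    Subjects come in two behavioral groups that differ in how quickly the
    right/left ratio trajectory settles from ~1 (hands level) through a noisy
    exploration phase to the target ratio ~2, with occasional fallbacks.
    Returns a list of ``preprocess.EventSeries``.
    """
    from .preprocess import EventSeries

    rng = np.random.default_rng(seed)
    series = []
    for i in range(n_subjects):
        fast = i % 2 == 1                         # group: quick vs slow settlers
        duration = rng.uniform(*duration_range)
        n_ev = max(50, rng.poisson(mean_events))
        times = np.sort(rng.uniform(0.0, duration, size=n_ev))
        # silent gap to induce missing bins downstream
        gap_start = rng.uniform(0.2, 0.7)
        gap = (times / duration > gap_start) & (times / duration < gap_start + 0.05)
        times = times[~gap]
        s = times / duration
        settle = 0.25 if fast else 0.6            # fraction of session to settle
        phase = np.clip((s - 0.1) / max(settle, 1e-9), 0.0, 1.0)
        ratio = 1.0 + phase + rng.normal(0, 0.25 * (1 - phase) + 0.03, size=s.size)
        ratio = np.clip(ratio, 0.2, 4.0)
        left = np.clip(rng.uniform(2.0, 8.0) + rng.normal(0, 0.3, size=s.size), 0.5, None)
        right = ratio * left
        series.append(EventSeries(subject_id=i + 1, times=times,
                                  values=np.column_stack([left, right])))
    return series
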