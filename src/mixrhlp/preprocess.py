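"""Preprocessing of irregular multi-subject event streams onto a shared grid.

Real sensor streams arrive at subject-specific, irregular times.  The
pipeline implemented here builds the complete panel the model needs:

1. ``rescale_time`` maps each subject's session onto [0, 1] (proportional
   time since onset).
2. ``ratio_channel`` reduces a two-channel stream to the right/left ratio.
3. ``aggregate_bins`` averages events within ``n_bins`` equal intervals of
   [0, 1); bin b is assigned to grid point b/n_bins and events at exactly
   t = 1 to the final grid point, giving n_bins + 1 occasions.  Empty bins
   become missing cells.
4. ``winsorize_upper`` caps values above an upper quantile (outlier ratios
   from near-zero denominators).
5. ``simulate.impute_linear`` fills the remaining gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import PanelData, TimeGrid

__all__ = [
    "EventSeries",
    "rescale_time",
    "ratio_channel",
    "aggregate_bins",
    "build_panel",
    "winsorize_upper",
    "winsorize_panel",
]


@dataclass
class EventSeries:
    """One subject's raw event stream: increasing timestamps, 1-2 channels."""

    subject_id: object
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.times.ndim != 1 or self.values.shape[0] != self.times.size:
            raise ValueError("times and values lengths differ")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def rescale_time(series: EventSeries) -> EventSeries:
    """Map timestamps to [0, 1]: t' = (t - t_first) / (t_last - t_first)."""
    if series.times.size < 2:
        raise ValueError("need at least two events to rescale")
    span = series.times[-1] - series.times[0]
    if span <= 0:
        raise ValueError("zero-duration series cannot be rescaled")
    t = (series.times - series.times[0]) / span
    return EventSeries(series.subject_id, t, series.values.copy())


def ratio_channel(series: EventSeries, eps: float = 0.0) -> EventSeries:
    """Reduce (left, right) channels to right/left; drops non-positive-left events.

    Returns the single-channel series; the number of dropped events is stored
    on the result as ``n_dropped``.
    """
    if series.n_channels != 2:
        raise ValueError("ratio_channel needs exactly two channels (left, right)")
    left, right = series.values[:, 0], series.values[:, 1]
    keep = left > eps
    out = EventSeries(series.subject_id, series.times[keep], right[keep] / left[keep])
    out.n_dropped = int((~keep).sum())  # type: ignore[attr-defined]
    return out


def aggregate_bins(series: EventSeries, n_bins: int = 200):
    """Average a rescaled single-channel series within equal bins of [0, 1).

    Bin b in {0..n_bins-1} covers [b/n_bins, (b+1)/n_bins) and its mean is
    assigned to grid point b/n_bins; events at exactly t = 1 average into the
    final grid point, for n_bins + 1 occasions in total.  Empty bins yield
    missing cells.  Returns ``(grid, values, observed)`` with values NaN where
    unobserved.
    """
    if series.n_channels != 1:
        raise ValueError("aggregate a single-channel series")
    t, y = series.times, series.values[:, 0]
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("series must be rescaled to [0, 1] first")
    idx = np.minimum((t * n_bins).astype(int), n_bins)      # t==1 -> last point
    at_one = t == 1.0
    idx[at_one] = n_bins
    sums = np.bincount(idx, weights=y, minlength=n_bins + 1)
    counts = np.bincount(idx, minlength=n_bins + 1)
    observed = counts > 0
    values = np.full(n_bins + 1, np.nan)
    values[observed] = sums[observed] / counts[observed]
    grid = TimeGrid(np.linspace(0.0, 1.0, n_bins + 1))
    return grid, values, observed


def build_panel(series_list: Sequence[EventSeries], n_bins: int = 200) -> PanelData:
    """Aggregate many rescaled single-channel series onto one shared grid."""
    rows, masks, ids = [], [], []
    grid = None
    for s in series_list:
        grid, v, o = aggregate_bins(s, n_bins)
        rows.append(v)
        masks.append(o)
        ids.append(s.subject_id)
    return PanelData(grid, np.vstack(rows), np.vstack(masks), ids)


def winsorize_upper(values: np.ndarray, q: float = 0.95) -> np.ndarray:
    """Cap values above the q-quantile at the q-quantile (upper winsorization).

    The quantile uses linear interpolation between order statistics; NaNs are
    ignored when computing the quantile and passed through unchanged.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        return values.copy()
    cut = np.nanquantile(values[finite], q)
    out = values.copy()
    out[finite & (values > cut)] = cut
    return out


def winsorize_panel(data: PanelData, q: float = 0.95, scope: str = "pooled") -> PanelData:
    """Upper-winsorize a panel's observed cells.

    ``scope='pooled'`` computes one quantile over all observed cells in the
    sample; ``scope='subject'`` computes a quantile per subject row.
    """
    values = data.values.copy()
    obs = data.observed
    if scope == "pooled":
        cut = np.quantile(values[obs], q)
        hi = obs & (values > cut)
        values[hi] = cut
    elif scope == "subject":
        for i in range(data.n_subjects):
            row = values[i]
            cut = np.quantile(row[obs[i]], q)
            hi = obs[i] & (row > cut)
            row[hi] = cut
    else:
        raise ValueError("scope must be 'pooled' or 'subject'")
    return PanelData(data.grid, values, obs.copy(), data.subject_ids)
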