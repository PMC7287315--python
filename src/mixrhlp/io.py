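"""CSV I/O for panels and labelings.

Wide form: one row per subject, first column ``subject``, remaining columns
named by time value; empty cells are missing.  Long form: columns
``subject, time, value`` with missing cells simply absent (or value NaN).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import Labeling
from .model import PanelData, TimeGrid

__all__ = ["write_panel_csv", "read_panel_csv", "write_labels_csv"]


def write_panel_csv(data: PanelData, path) -> None:
    """Write a panel in wide form; unobserved cells are left empty."""
    values = np.where(data.observed, data.values, np.nan)
    df = pd.DataFrame(values, columns=[repr(float(t)) for t in data.grid.points])
    df.insert(0, "subject", list(data.subject_ids))
    df.to_csv(path, index=False)


def read_panel_csv(path) -> PanelData:
    """Read a panel from wide (subject + time columns) or long
    (subject,time,value) CSV form."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] == ["subject", "time", "value"] and df.shape[1] == 3:
        df.columns = ["subject", "time", "value"]
        wide = df.pivot_table(index="subject", columns="time", values="value", sort=True)
        grid = TimeGrid(np.asarray(wide.columns, dtype=float))
        values = wide.to_numpy()
        return PanelData(grid, values, ~np.isnan(values), list(wide.index))
    if cols[0] != "subject":
        raise ValueError("wide CSV must start with a 'subject' column")
    times = np.array([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return PanelData(TimeGrid(times), values, ~np.isnan(values), list(df.iloc[:, 0]))


def write_labels_csv(labels: Labeling, data: PanelData, path,
                     cluster_prob: np.ndarray | None = None,
                     regime_prob: np.ndarray | None = None) -> None:
    """Write MAP labels in long form (subject, time, cluster, regime, probs)."""
    rows = []
    for i, sid in enumerate(data.subject_ids):
        for j, t in enumerate(data.grid.points):
            row = {
                "subject": sid,
                "time": t,
                "cluster": int(labels.cluster[i]),
                "regime": int(labels.regime[i, j]),
            }
            if cluster_prob is not None:
                row["cluster_prob"] = float(cluster_prob[i, labels.cluster[i] - 1])
            if regime_prob is not None:
                row["regime_prob"] = float(regime_prob[i, j])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
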