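"""Delimited-table I/O for voxel time series and fits.

Voxel series travel as plain CSV: one row per (site, configuration),
columns ``site, configuration, t0000, t0001, ...``. The same dialect is
written by the synthetic generator and read back by the fitting CLI, and
accepts user-supplied recordings shaped the same way.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_voxels", "read_voxels", "write_truth", "read_truth"]


def write_voxels(data: dict[str, np.ndarray], path: str | Path) -> None:
    rows = []
    for config, arr in data.items():
        arr = np.atleast_2d(arr)
        for site, series in enumerate(arr):
            rows.append({"site": site, "configuration": config,
                         **{f"t{t:04d}": v for t, v in enumerate(series)}})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_voxels(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    tcols = sorted(c for c in df.columns if c.startswith("t") and c[1:].isdigit())
    if not tcols:
        raise ValueError("no time-point columns (t0000, ...) found")
    out = {}
    for config, grp in df.groupby("configuration"):
        grp = grp.sort_values("site")
        out[str(config)] = grp[tcols].to_numpy(dtype=float)
    return out


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
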