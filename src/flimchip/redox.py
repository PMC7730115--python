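"""Optical redox ratio maps and control normalization.

The optical redox ratio is the per-pixel NAD(P)H intensity divided by
the FAD intensity. Because absolute autofluorescence intensities depend
on the instrument, per-cell values are normalized to the mean of the
untreated (CTL) cells imaged at the same chamber position (proximal or
distal), so a treated group's normalized mean directly reads out the
fractional metabolic shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RedoxMap", "compute_redox_map", "normalize_to_control", "per_cell_redox"]


@dataclass
class RedoxMap:
    ratio: np.ndarray  # NaN where invalid
    mask: np.ndarray  # True where the ratio is defined


def compute_redox_map(nadph_intensity: np.ndarray, fad_intensity: np.ndarray) -> RedoxMap:
    """Elementwise NAD(P)H / FAD; zero-FAD pixels are masked, not infinite."""
    n = np.asarray(nadph_intensity, dtype=float)
    f = np.asarray(fad_intensity, dtype=float)
    if n.shape != f.shape:
        raise ValueError(f"channel shape mismatch: {n.shape} vs {f.shape}")
    mask = (f > 0) & np.isfinite(f) & np.isfinite(n)
    ratio = np.full(n.shape, np.nan)
    ratio[mask] = n[mask] / f[mask]
    return RedoxMap(ratio=ratio, mask=mask)


def per_cell_redox(
    nadph: np.ndarray,
    fad: np.ndarray,
    cytoplasm: np.ndarray,
    mode: str = "ratio_then_average",
) -> pd.Series:
    """Cytoplasm-level redox ratio per cell label.

    Default averages the per-pixel ratio over the cytoplasm
    (ratio-then-average); ``mode="sum_then_ratio"`` instead divides the
    summed channel intensities, which down-weights dim pixels.
    """
    labels = cytoplasm[cytoplasm > 0]
    if mode == "ratio_then_average":
        rmap = compute_redox_map(nadph, fad)
        vals = rmap.ratio[cytoplasm > 0]
        return pd.Series(vals).groupby(labels).mean()
    if mode == "sum_then_ratio":
        n = pd.Series(np.asarray(nadph, float)[cytoplasm > 0]).groupby(labels).sum()
        f = pd.Series(np.asarray(fad, float)[cytoplasm > 0]).groupby(labels).sum()
        return n / f.replace(0.0, np.nan)
    raise ValueError(f"unknown mode {mode!r}")


def normalize_to_control(
    cells: pd.DataFrame,
    value_col: str = "redox_ratio",
    condition_col: str = "condition",
    position_col: str = "position",
    control: str = "CTL",
) -> pd.Series:
    """Divide each cell's value by the CTL mean at the same position.

    After normalization the CTL group at every position has mean exactly
    1. Raises if any position present in the table has no CTL cells to
    normalize against.
    """
    for col in (value_col, condition_col, position_col):
        if col not in cells.columns:
            raise KeyError(f"missing column {col!r}")
    ctl = cells[cells[condition_col] == control]
    ctl_means = ctl.groupby(position_col)[value_col].mean()
    missing = sorted(set(cells[position_col]) - set(ctl_means.index))
    if missing:
        raise ValueError(
            f"no {control} cells for position(s) {missing}; cannot normalize"
        )
    return cells[value_col] / cells[position_col].map(ctl_means)
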