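"""Live/dead staining quantification.

Works on two-channel viability images (channel 0 = green / calcein-AM /
live, channel 1 = red / propidium iodide / dead): detect stained objects,
call each live or dead by its dominant channel, report per-region
percentages and axis intensity profiles, and measure the necrotic-core
extent — the contiguous dead-dominated stretch of the chamber ending at
the distal wall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .scene import ChamberGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "ViabilityOptions",
    "ViabilityResult",
    "classify_live_dead",
    "region_viability",
    "axis_profile",
    "necrotic_core_extent",
]


@dataclass
class ViabilityOptions:
    smooth_sigma: float = 1.0
    min_object_area_px: int = 4
    threshold_floor: float = 25.0  # ignore Otsu thresholds below this signal level
    split_touching: bool = True
    watershed_min_distance_px: int = 2
    area_based: bool = False  # percentages by object area instead of object count


@dataclass
class ViabilityResult:
    regions: pd.DataFrame  # region, n, live_percent, dead_percent, valid
    necrotic_core_fraction: float


def _detect_objects(total: np.ndarray, opts: ViabilityOptions) -> np.ndarray:
    sm = gaussian(total, opts.smooth_sigma, preserve_range=True)
    if np.unique(sm).size < 2:
        return np.zeros(total.shape, dtype=np.int32)
    thr = max(threshold_otsu(sm), opts.threshold_floor)
    mask = sm > thr
    labels, n = ndi.label(mask)
    if n == 0:
        return labels.astype(np.int32)
    if opts.split_touching:
        dist = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            dist, labels=labels, min_distance=opts.watershed_min_distance_px,
            exclude_border=False,
        )
        markers = np.zeros(total.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() > 0:
            labels = watershed(-dist, markers=markers, mask=mask)
    return labels.astype(np.int32)


def classify_live_dead(image: np.ndarray, opts: ViabilityOptions | None = None) -> pd.DataFrame:
    """Detect stained objects and call each live or dead.

    Objects are segmented on the channel sum (so a cell stained in either
    channel is one object), then classified by the larger
    background-subtracted mean of the two channels over the object
    footprint; exact ties are called dead (conservative). Returns a table
    with ``centroid_x_px``, ``centroid_y_px``, ``area_px``, ``class``.
    """
    opts = opts or ViabilityOptions()
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[0] != 2:
        raise ValueError("image must have shape (2, rows, cols)")
    green, red = img[0], img[1]
    labels = _detect_objects(green + red, opts)
    bg_green = float(np.median(green))
    bg_red = float(np.median(red))
    rows = []
    for prop in regionprops(labels):
        if prop.area < opts.min_object_area_px:
            continue
        sel = labels == prop.label
        g = float(green[sel].mean()) - bg_green
        r = float(red[sel].mean()) - bg_red
        cy, cx = prop.centroid
        rows.append(
            {
                "centroid_x_px": float(cx),
                "centroid_y_px": float(cy),
                "area_px": int(prop.area),
                "class": "live" if g > r else "dead",
            }
        )
    return pd.DataFrame(rows, columns=["centroid_x_px", "centroid_y_px", "area_px", "class"])


def region_viability(
    objects: pd.DataFrame,
    regions: dict[str, tuple[float, float]],
    pixel_size_um: float,
    area_based: bool = False,
) -> pd.DataFrame:
    """Percent live / dead per axis band.

    ``regions`` maps a label to an ``[x0_mm, x1_mm)`` band. Percentages
    are object-count based by default (``area_based=True`` weights by
    object area instead). Empty regions get ``n = 0`` with NaN
    percentages and ``valid = False`` rather than silent zeros.
    """
    rows = []
    x_mm = (
        (objects["centroid_x_px"].to_numpy() + 0.5) * pixel_size_um / 1000.0
        if len(objects)
        else np.array([])
    )
    for name, (x0, x1) in regions.items():
        if x1 <= x0:
            raise ValueError(f"region {name!r} is empty or reversed")
        sel = (x_mm >= x0) & (x_mm < x1)
        sub = objects[sel] if len(objects) else objects
        if len(sub) == 0:
            rows.append(
                {"region": name, "n": 0, "live_percent": np.nan,
                 "dead_percent": np.nan, "valid": False}
            )
            continue
        weights = (
            sub["area_px"].to_numpy(dtype=float)
            if area_based
            else np.ones(len(sub))
        )
        live_mask = (sub["class"] == "live").to_numpy()
        live = float(weights[live_mask].sum() / weights.sum() * 100.0)
        rows.append(
            {"region": name, "n": int(len(sub)), "live_percent": live,
             "dead_percent": 100.0 - live, "valid": True}
        )
    return pd.DataFrame(rows)


def axis_profile(image: np.ndarray, roi: tuple[int, int, int, int], n_bins: int) -> np.ndarray:
    """Mean intensity per axis bin within a rectangular ROI.

    ``roi`` is (row0, row1, col0, col1), half-open; the axis runs along
    columns (away from the lumen).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("axis_profile expects a single channel")
    r0, r1, c0, c1 = roi
    ny, nx = img.shape
    if not (0 <= r0 < r1 <= ny and 0 <= c0 < c1 <= nx):
        raise ValueError(f"roi {roi} outside the {img.shape} frame")
    if n_bins < 1 or n_bins > c1 - c0:
        raise ValueError("n_bins must be in [1, roi width]")
    sub = img[r0:r1, c0:c1]
    col_means = sub.mean(axis=0)
    edges = np.linspace(0, sub.shape[1], n_bins + 1).astype(int)
    return np.array([col_means[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])


def necrotic_core_extent(
    objects: pd.DataFrame,
    geometry: ChamberGeometry,
    n_bins: int = 20,
) -> float:
    """Fraction of chamber length occupied by the distal necrotic core.

    The axis is split into ``n_bins`` bands; a band is necrotic when its
    dead objects strictly outnumber its live objects. The extent is the
    longest contiguous necrotic run ending at the distal wall, as a
    fraction of chamber length. No objects at all yields 0 with a
    warning.
    """
    if len(objects) == 0:
        logger.warning("no objects; necrotic core extent undefined, returning 0")
        return 0.0
    x_mm = (objects["centroid_x_px"].to_numpy() + 0.5) * geometry.pixel_size_um / 1000.0
    dead = (objects["class"] == "dead").to_numpy()
    edges = np.linspace(0.0, geometry.width_mm, n_bins + 1)
    which = np.clip(np.digitize(x_mm, edges) - 1, 0, n_bins - 1)
    run = 0
    for b in range(n_bins - 1, -1, -1):
        in_bin = which == b
        n_dead = int(dead[in_bin].sum())
        n_live = int((~dead[in_bin]).sum())
        if n_dead > n_live:
            run += 1
        else:
            break
    return run / n_bins
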