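"""Milestone difference maps and hemisphere ROI splits.

Delta-StO2 maps subtract the saturation image at one treatment milestone from
another, per pixel, on the intersection of the two validity masks; the sign
convention is (later - earlier), so deoxygenation over the interval is
negative and reoxygenation positive.  A 3x3 median filter is available for
display only.  For asymmetric-dose experiments the tumor ROI can be split
into lateral halves about its own centroid column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .kinetics import ROIMask
from .unmixing import OximetryMaps

__all__ = [
    "DeltaMap",
    "delta_sto2",
    "display_median_filter",
    "split_roi_lateral",
    "reoxygenation_map",
]


@dataclass
class DeltaMap:
    """Signed per-pixel StO2 change (%) between two milestones."""

    delta: np.ndarray
    mask: np.ndarray
    t_from: float
    t_to: float


def delta_sto2(map_a: OximetryMaps, map_b: OximetryMaps) -> DeltaMap:
    """Element-wise StO2 difference ``map_b - map_a`` on the joint mask.

    Pixels valid at only one milestone are excluded (mask false) rather than
    treated as change from/to 0, which would fabricate +-100 % swings at the
    noise floor.
    """
    if map_a.sto2.shape != map_b.sto2.shape:
        raise ValidationError("milestone maps must share a shape")
    both = map_a.mask & map_b.mask
    delta = np.where(both, map_b.sto2 - map_a.sto2, 0.0)
    return DeltaMap(delta=delta, mask=both, t_from=map_a.t, t_to=map_b.t)


def display_median_filter(map2d: np.ndarray, size: int = 3) -> np.ndarray:
    """3x3 neighborhood median for display; edges by nearest replication.

    Display-only: never feeds statistics.
    """
    m = np.asarray(map2d, dtype=float)
    if m.shape[0] < size or m.shape[1] < size:
        raise ValidationError(f"map must be at least {size}x{size}")
    return ndimage.median_filter(m, size=size, mode="nearest")


def split_roi_lateral(
    roi: ROIMask, midline: int | None = None
) -> tuple[ROIMask, ROIMask]:
    """Split the ROI into left/right halves about its lateral centroid column.

    Columns strictly below the centroid go left, the rest right, so the halves
    partition the ROI exactly.  Passing ``midline`` splits at a fixed column
    (e.g. the image midline) instead.
    """
    mask = roi.mask
    cols = np.nonzero(mask)[1]
    centroid = float(midline) if midline is not None else cols.mean()
    col_idx = np.arange(mask.shape[1])
    left = mask & (col_idx[None, :] < centroid)
    right = mask & (col_idx[None, :] >= centroid)
    if not left.any() or not right.any():
        warnings.warn("degenerate ROI split: one half is empty", stacklevel=2)
    return (
        ROIMask(left, label=f"{roi.label}_left", allow_empty=True),
        ROIMask(right, label=f"{roi.label}_right", allow_empty=True),
    )


def reoxygenation_map(
    end_active: OximetryMaps, end_monitoring: OximetryMaps
) -> DeltaMap:
    """StO2 change from the end of active PDT to the end of monitoring.

    Positive values mark reoxygenating regions (vasculature that retained
    function after treatment); negative values mark continued deoxygenation.
    """
    return delta_sto2(end_active, end_monitoring)
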