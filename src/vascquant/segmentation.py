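"""Intensity-ratio segmentation of marker channels.

A pixel is positive when its intensity is at least ``ratio_k`` times the
local background estimate and at least the negative-control floor;
connected components below a physical size are removed as artifacts.
The background estimator is a median over a disk (default 50 um),
approximated on a downsampled grid when the disk would be very large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph
from skimage import transform as sktransform

from .imgio import BinaryMask

__all__ = [
    "SegmentationParams",
    "estimate_background",
    "segment_channel",
    "remove_small_objects_um2",
    "negative_control_floor",
]

# downsample before the median when the disk radius exceeds this many px
_MAX_MEDIAN_RADIUS_PX = 16


@dataclass
class SegmentationParams:
    background_radius_um: float = 50.0
    ratio_k: float = 2.0
    negcontrol_floor: float = 0.0
    min_object_area_um2: float = 10.0

    def __post_init__(self) -> None:
        if self.ratio_k <= 1:
            raise ValueError("ratio_k must be > 1")
        if self.background_radius_um <= 0:
            raise ValueError("background_radius_um must be > 0")
        if self.min_object_area_um2 < 0:
            raise ValueError("min_object_area_um2 must be >= 0")


def _disk_footprint(radius_px: int) -> np.ndarray:
    return skmorph.disk(radius_px)


def estimate_background(
    channel: np.ndarray, radius_um: float, resolution_um_per_px: float
) -> np.ndarray:
    """Per-pixel local background: median over a disk of ``radius_um``.

    Values are clamped at 1 so foreground/background ratios are always
    defined. Large disks are computed on a downsampled copy for speed
    (the background is smooth by construction, so this loses nothing the
    ratio test can see).
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty image")
    if channel.ndim != 2:
        raise ValueError("estimate_background expects a single 2D channel")
    radius_px = radius_um / resolution_um_per_px
    if radius_px < 1:
        radius_px = 1.0

    if radius_px <= _MAX_MEDIAN_RADIUS_PX:
        bg = ndimage.median_filter(
            channel.astype(np.float64), footprint=_disk_footprint(int(round(radius_px)))
        )
    else:
        factor = radius_px / _MAX_MEDIAN_RADIUS_PX
        small_shape = (
            max(int(round(channel.shape[0] / factor)), 4),
            max(int(round(channel.shape[1] / factor)), 4),
        )
        small = sktransform.resize(
            channel.astype(np.float64), small_shape, order=1, anti_aliasing=True
        )
        small_bg = ndimage.median_filter(
            small, footprint=_disk_footprint(_MAX_MEDIAN_RADIUS_PX)
        )
        bg = sktransform.resize(small_bg, channel.shape, order=1)
    return np.maximum(bg, 1.0)


def remove_small_objects_um2(
    mask: np.ndarray, min_area_um2: float, resolution_um_per_px: float
) -> np.ndarray:
    """Drop connected components with area strictly below ``min_area_um2``."""
    mask = np.asarray(mask, dtype=bool)
    if min_area_um2 <= 0 or not mask.any():
        return mask.copy()
    # keep components whose physical area is >= min_area_um2 (strict removal)
    structure = np.ones((3,) * mask.ndim, dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    areas_um2 = np.bincount(labels.ravel())[1:] * resolution_um_per_px**2
    keep = np.flatnonzero(areas_um2 >= min_area_um2) + 1
    return np.isin(labels, keep)


def negative_control_floor(control_channel: np.ndarray, q: float = 99.9) -> float:
    """Absolute floor from a negative-control image: its q-th percentile."""
    return float(np.percentile(np.asarray(control_channel), q))


def segment_channel(
    channel: np.ndarray,
    params: SegmentationParams,
    resolution_um_per_px: float,
    marker: str = "unknown",
) -> BinaryMask:
    """Segment one channel (2D, or 3D processed per-slice).

    positive <=> intensity >= ratio_k * local background
                 and intensity >= negcontrol_floor,
    then components smaller than ``min_object_area_um2`` are removed.
    """
    channel = np.asarray(channel)
    if channel.ndim == 3:
        slices = [
            segment_channel(channel[z], params, resolution_um_per_px, marker).pixels
            for z in range(channel.shape[0])
        ]
        pixels = np.stack(slices)
    elif channel.ndim == 2:
        bg = estimate_background(
            channel, params.background_radius_um, resolution_um_per_px
        )
        raw = (channel.astype(np.float64) >= params.ratio_k * bg) & (
            channel >= params.negcontrol_floor
        )
        pixels = remove_small_objects_um2(
            raw, params.min_object_area_um2, resolution_um_per_px
        )
    else:
        raise ValueError(f"expected 2D or 3D channel, got ndim={channel.ndim}")

    return BinaryMask(
        pixels=pixels,
        marker=marker,
        resolution_um_per_px=resolution_um_per_px,
        provenance={
            "background_radius_um": params.background_radius_um,
            "ratio_k": params.ratio_k,
            "negcontrol_floor": params.negcontrol_floor,
            "min_object_area_um2": params.min_object_area_um2,
        },
    )
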