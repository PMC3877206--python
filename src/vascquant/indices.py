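"""Surface-based marker indices and the object-based covered-vessel call.

Surface indices are staining areas divided by an ROI area: Ki-67, TUNEL,
EF5 and the perfusion markers over TT; endothelial TUNEL/ZO-1 over VS;
perivascular SMA/desmin are the stained PVS area divided by the VS area
(note: VS, not PVS, in the denominator).

A vessel counts as "covered" when a fraction of its own perivascular
shell is desmin+/SMA+ double-positive; the threshold is a free
parameter (the source methodology does not define "covered"
numerically), recorded in provenance.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .imgio import BinaryMask, GridMismatchError

__all__ = [
    "UndefinedIndexError",
    "surface_index",
    "endothelial_index",
    "perivascular_index",
    "per_vessel_shells",
    "covered_vessel_frequency",
]


class UndefinedIndexError(ZeroDivisionError):
    """Denominator region is empty; the index is undefined (never silently 0)."""


def _check_grids(*masks: BinaryMask | np.ndarray) -> None:
    shapes = {
        (m.pixels.shape if isinstance(m, BinaryMask) else np.asarray(m).shape)
        for m in masks
    }
    if len(shapes) > 1:
        raise GridMismatchError(f"masks on different grids: {sorted(shapes)}")


def _px(m: BinaryMask | np.ndarray) -> np.ndarray:
    return m.pixels if isinstance(m, BinaryMask) else np.asarray(m, dtype=bool)


def surface_index(
    marker: BinaryMask | np.ndarray,
    numerator_region: BinaryMask | np.ndarray,
    denominator_region: BinaryMask | np.ndarray,
) -> float:
    """area(marker ∩ numerator_region) / area(denominator_region).

    Dimensionless; can exceed 1 only when the numerator region is not a
    subset of the denominator region (as in the perivascular indices).
    """
    _check_grids(marker, numerator_region, denominator_region)
    denom = int(_px(denominator_region).sum())
    if denom == 0:
        raise UndefinedIndexError("denominator region is empty")
    num = int((_px(marker) & _px(numerator_region)).sum())
    return num / denom


def endothelial_index(marker: BinaryMask | np.ndarray, vs: BinaryMask | np.ndarray) -> float:
    """area(marker ∩ VS) / area(VS)."""
    return surface_index(marker, vs, vs)


def perivascular_index(
    marker: BinaryMask | np.ndarray,
    pvs: BinaryMask | np.ndarray,
    vs: BinaryMask | np.ndarray,
) -> float:
    """area(marker ∩ PVS) / area(VS)."""
    return surface_index(marker, pvs, vs)


def per_vessel_shells(
    vessel_labels: np.ndarray, pvs: BinaryMask | np.ndarray
) -> np.ndarray:
    """Assign every PVS pixel to its nearest labelled vessel.

    Returns a label raster over PVS pixels (0 elsewhere), so adjacent
    vessels never share shell pixels and per-object coverage is
    well-defined.
    """
    vessel_labels = np.asarray(vessel_labels)
    pvs_px = _px(pvs)
    if vessel_labels.shape != pvs_px.shape:
        raise GridMismatchError("vessel labels and PVS on different grids")
    if vessel_labels.max() == 0:
        return np.zeros_like(vessel_labels)
    _, (iy, ix) = ndimage.distance_transform_edt(
        vessel_labels == 0, return_indices=True
    )
    nearest = vessel_labels[iy, ix]
    shells = np.where(pvs_px, nearest, 0)
    return shells


def covered_vessel_frequency(
    vessel_labels: np.ndarray,
    desmin: BinaryMask | np.ndarray,
    sma: BinaryMask | np.ndarray,
    pvs: BinaryMask | np.ndarray,
    coverage_threshold: float = 0.10,
) -> float:
    """Percent of vessels whose own PVS shell is desmin+/SMA+ covered.

    covered <=> area(desmin ∩ sma ∩ shell_i) / area(shell_i) >= threshold.
    Vessels with an empty shell (fully surrounded by other vessels) count
    as uncovered.
    """
    vessel_labels = np.asarray(vessel_labels)
    n_vessels = int(vessel_labels.max())
    if n_vessels == 0:
        raise UndefinedIndexError("no vessel objects")
    _check_grids(vessel_labels, desmin, sma, pvs)
    shells = per_vessel_shells(vessel_labels, pvs)
    double = _px(desmin) & _px(sma)
    idx = np.arange(1, n_vessels + 1)
    shell_areas = ndimage.sum_labels(np.ones_like(shells), shells, idx)
    pos_areas = ndimage.sum_labels(double.astype(float), shells, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(shell_areas > 0, pos_areas / np.maximum(shell_areas, 1), 0.0)
    covered = int(np.count_nonzero(frac >= coverage_threshold))
    return 100.0 * covered / n_vessels
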