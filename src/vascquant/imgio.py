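"""Calibrated multi-channel image I/O and tabular result output.

Conventions used throughout the package (declared once, here):

* rasters are channel-first ``(C, Y, X)`` or ``(C, Z, Y, X)`` arrays of
  unsigned 16-bit intensities;
* pixel coordinates are 0-based with pixel centers at ``(i + 0.5) * res``;
* areas are ``pixel count x (um/px)^2``; every physical quantity leaving
  this package is in um / um^2 / mm^2, never in pixel units;
* calibration lives in a sidecar JSON next to the TIFF (TIFF resolution
  tags are honored when present but the sidecar wins).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "CalibrationError",
    "GridMismatchError",
    "INDEX_COLUMNS",
    "COMPARISON_COLUMNS",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_results",
]


class CalibrationError(ValueError):
    """Raised when physical calibration is missing or inconsistent."""


class GridMismatchError(ValueError):
    """Raised when two rasters that must share a pixel grid do not."""


@dataclass
class CalibratedImage:
    """Multi-channel raster with physical pixel size and channel names.

    Parameters
    ----------
    pixels
        ``(C, Y, X)`` or ``(C, Z, Y, X)`` array of uint16 intensities.
    resolution_um_per_px
        In-plane pixel size in micrometers (isotropic).
    channels
        Ordered marker names, one per channel.
    z_step_um
        Optional slice spacing for thick stacks.
    """

    pixels: np.ndarray
    resolution_um_per_px: float
    channels: list[str]
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (3, 4):
            raise ValueError(
                f"pixels must be (C, Y, X) or (C, Z, Y, X); got ndim={self.pixels.ndim}"
            )
        if self.pixels.shape[0] != len(self.channels):
            raise CalibrationError(
                f"{self.pixels.shape[0]} channels in raster but "
                f"{len(self.channels)} channel names"
            )
        if not (self.resolution_um_per_px and self.resolution_um_per_px > 0):
            raise CalibrationError("resolution_um_per_px must be > 0")
        if self.pixels.dtype != np.uint16:
            if self.pixels.min() < 0 or self.pixels.max() > 65535:
                raise ValueError("intensities outside 16-bit range")
            self.pixels = self.pixels.astype(np.uint16)

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        """Return the raster for channel ``name`` (``(Y, X)`` or ``(Z, Y, X)``)."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None
        return self.pixels[idx]

    def field_area_mm2(self) -> float:
        ny, nx = self.field_shape
        return ny * nx * self.resolution_um_per_px**2 / 1e6


@dataclass
class BinaryMask:
    """Boolean raster on the grid of its source image."""

    pixels: np.ndarray
    marker: str
    resolution_um_per_px: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if not (self.resolution_um_per_px and self.resolution_um_per_px > 0):
            raise CalibrationError("resolution_um_per_px must be > 0")

    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.resolution_um_per_px**2

    def same_grid(self, other: "BinaryMask | np.ndarray") -> None:
        other_shape = other.pixels.shape if isinstance(other, BinaryMask) else other.shape
        if self.pixels.shape != other_shape:
            raise GridMismatchError(
                f"grid mismatch: {self.pixels.shape} vs {other_shape}"
            )


# Stable column order for the per-image results table.
INDEX_COLUMNS = [
    "image_id",
    "group",
    "ki67_index",
    "tunel_index",
    "ef5_index",
    "hoechst_surface",
    "dextran10k_surface",
    "dextran2M_surface",
    "zo1_endothelial_index",
    "tunel_endothelial_index",
    "sma_perivascular_index",
    "desmin_perivascular_index",
    "covered_vessel_frequency",
    "mvd_per_mm2",
    "branch_per_mm",
    "skeleton_length_mm",
    "mean_diameter_um",
    "tortuosity",
    "pct_cells_beyond_100um",
]

COMPARISON_COLUMNS = [
    "metric",
    "group_a",
    "group_b",
    "n_a",
    "n_b",
    "test",
    "statistic",
    "p_value",
    "adjusted_p",
    "stars",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: CalibratedImage, path: str | Path) -> Path:
    """Write a multi-channel TIFF (channel-first pages) plus a sidecar JSON.

    Returns the sidecar path.
    """
    path = Path(path)
    tifffile.imwrite(path, image.pixels, photometric="minisblack")
    meta = {
        "resolution_um_per_px": image.resolution_um_per_px,
        "channels": list(image.channels),
        "z_step_um": image.z_step_um,
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_image(path: str | Path, meta: str | Path | None = None) -> CalibratedImage:
    """Read a calibrated multi-channel TIFF.

    ``meta`` is the sidecar JSON path; when omitted, ``<path>.json`` is
    tried. Missing calibration is an error — there is no silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]

    meta_path = Path(meta) if meta is not None else _sidecar_path(path)
    if not meta_path.exists():
        raise CalibrationError(
            f"no calibration sidecar for {path} (looked for {meta_path})"
        )
    info = json.loads(meta_path.read_text())
    if not info.get("resolution_um_per_px"):
        raise CalibrationError(f"missing/zero resolution_um_per_px in {meta_path}")
    channels = info.get("channels")
    if not channels:
        raise CalibrationError(f"missing channel names in {meta_path}")
    return CalibratedImage(
        pixels=pixels,
        resolution_um_per_px=float(info["resolution_um_per_px"]),
        channels=list(channels),
        z_step_um=info.get("z_step_um"),
    )


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit TIFF (0/255) with sidecar metadata."""
    path = Path(path)
    tifffile.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "marker": mask.marker,
                "resolution_um_per_px": mask.resolution_um_per_px,
                "provenance": mask.provenance,
            },
            indent=2,
            default=str,
        )
    )


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pixels = tifffile.imread(path) > 0
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise CalibrationError(f"no sidecar for mask {path}")
    info = json.loads(meta_path.read_text())
    return BinaryMask(
        pixels=pixels,
        marker=info.get("marker", "unknown"),
        resolution_um_per_px=float(info["resolution_um_per_px"]),
        provenance=info.get("provenance", {}),
    )


def write_results(
    index_table: pd.DataFrame,
    out_dir: str | Path,
    comparisons: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write results as deterministic UTF-8 CSV files.

    One row per image in ``indices.csv``; one row per statistical
    comparison in ``comparisons.csv``. Empty tables produce header-only
    files and a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    df = index_table.reindex(columns=[c for c in INDEX_COLUMNS if c in index_table.columns]
                             + [c for c in index_table.columns if c not in INDEX_COLUMNS])
    if df.empty:
        warnings.warn("index table is empty; writing header-only CSV", stacklevel=2)
        logger.warning("index table is empty")
    sort_cols = [c for c in ("group", "image_id") if c in df.columns]
    if sort_cols and not df.empty:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    path = out_dir / "indices.csv"
    df.to_csv(path, index=False, encoding="utf-8")
    written["indices"] = path

    if comparisons is not None:
        cdf = comparisons.reindex(
            columns=[c for c in COMPARISON_COLUMNS if c in comparisons.columns]
            + [c for c in comparisons.columns if c not in COMPARISON_COLUMNS]
        )
        if cdf.empty:
            warnings.warn("comparison table is empty; writing header-only CSV",
                          stacklevel=2)
        cpath = out_dir / "comparisons.csv"
        cdf.to_csv(cpath, index=False, encoding="utf-8")
        written["comparisons"] = cpath
    return written
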