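"""Config-driven orchestration: simulate/ingest -> segment -> ROIs ->
indices, distance profile, network metrics -> group statistics.

Per-image analysis is independent and order-insensitive; a failure on
one image is logged, the image skipped, and the run summary reports a
nonzero failure count. Every stage's parameters, the config hash, the
seed and library versions are recorded in the output bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .imgio import (
    BinaryMask,
    CalibratedImage,
    INDEX_COLUMNS,
    read_image,
    read_mask,
    write_image,
    write_results,
)
from .segmentation import SegmentationParams, negative_control_floor, segment_channel
from .roi_geometry import build_roi_set
from .indices import (
    UndefinedIndexError,
    covered_vessel_frequency,
    endothelial_index,
    perivascular_index,
    surface_index,
)
from .distance_profile import distance_profile, vessel_distance_map
from .vessel_network import label_vessels, network_metrics, skeletonize_vs
from .group_stats import kruskal_dunn, mann_whitney
from .synthetic_data import SceneSpec, render_channel, simulate_scene

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "RunResult", "analyze_image", "run_experiment"]

# channels the index table knows how to interpret
_SURFACE_MARKERS = {
    "Ki-67": "ki67_index",
    "TUNEL": "tunel_index",
    "EF5": "ef5_index",
    "Hoechst": "hoechst_surface",
    "dextran10k": "dextran10k_surface",
    "dextran2M": "dextran2M_surface",
}
_ENDOTHELIAL_MARKERS = {"ZO-1": "zo1_endothelial_index", "TUNEL": "tunel_endothelial_index"}
_PERIVASCULAR_MARKERS = {"SMA": "sma_perivascular_index", "desmin": "desmin_perivascular_index"}


class ConfigError(ValueError):
    pass


@dataclass
class RoiParams:
    tt_dilation_um: float = 10.0
    pvs_shell_um: float = 5.0
    gap_um: float = 5.0
    hypoxic_cutoff_um: float = 100.0
    vessel_min_area_um2: float = 10.0


@dataclass
class RunConfig:
    """Full description of one experiment run (synthetic or image mode)."""

    mode: str = "synthetic"  # "synthetic" | "images"
    # synthetic mode: {group label: {"n_scenes": int, "spec": {...overrides}}}
    groups: dict = field(default_factory=dict)
    # image mode
    input_dir: str | None = None
    group_assignment: dict = field(default_factory=dict)  # image id -> label
    exclusion_masks: dict = field(default_factory=dict)  # image id -> mask path
    # analysis parameters
    segmentation: dict = field(default_factory=dict)  # channel -> params dict
    roi: RoiParams = field(default_factory=RoiParams)
    coverage_threshold: float = 0.10
    branch_denominator: str = "skeleton"  # or "tissue"
    nuclear_channel: str = "DAPI"
    vessel_channel: str = "CD31"
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "images"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and not self.groups:
            raise ConfigError("synthetic mode needs at least one group")
        if self.mode == "images" and not self.input_dir:
            raise ConfigError("image mode needs input_dir")
        for ch in (self.nuclear_channel, self.vessel_channel):
            if ch not in self.segmentation:
                raise ConfigError(
                    f"missing segmentation parameters for channel {ch!r}"
                )
        if self.mode == "synthetic":
            for label, g in self.groups.items():
                if not label:
                    raise ConfigError("empty group label")
                if int(g.get("n_scenes", 0)) < 1:
                    raise ConfigError(f"group {label!r} needs n_scenes >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "roi" in d and isinstance(d["roi"], dict):
            d["roi"] = RoiParams(**d["roi"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        doc = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    index_table: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: pd.DataFrame
    profiles: dict
    failures: list
    log: dict


def _seg_params(config: RunConfig, channel: str) -> SegmentationParams:
    d = dict(config.segmentation.get(channel, config.segmentation.get("default", {})))
    return SegmentationParams(**d)


def synthetic_control_floors(
    spec: SceneSpec, channels: list[str], q: float = 99.9
) -> dict[str, float]:
    """Negative-control floors for a synthetic scene: render an empty mask
    with the scene's noise model and take its q-th percentile."""
    rng = np.random.default_rng(spec.seed + 987654321)
    blank = np.zeros(spec.shape, dtype=bool)
    control = render_channel(blank, spec, rng)
    floor = negative_control_floor(control, q)
    return {c: floor for c in channels}


def analyze_image(
    image: CalibratedImage,
    config: RunConfig,
    image_id: str = "image",
    group: str = "",
    exclusion: BinaryMask | None = None,
    floors: dict[str, float] | None = None,
) -> tuple[dict, object]:
    """Analyze one calibrated image; returns (index row, DistanceProfile)."""
    res = image.resolution_um_per_px
    floors = floors or {}

    def seg(channel_name: str) -> BinaryMask:
        params = _seg_params(config, channel_name)
        if channel_name in floors:
            params = dataclasses.replace(params, negcontrol_floor=floors[channel_name])
        raster = image.channel(channel_name)
        if raster.ndim == 3:
            raster = raster.max(axis=0)  # thin stacks: projection for 2D analyses
        return segment_channel(raster, params, res, marker=channel_name)

    masks: dict[str, BinaryMask] = {}
    for name in image.channels:
        masks[name] = seg(name)

    dapi = masks[config.nuclear_channel]
    cd31 = masks[config.vessel_channel]
    rois = build_roi_set(
        dapi,
        cd31,
        exclusion=exclusion,
        tt_dilation_um=config.roi.tt_dilation_um,
        pvs_shell_um=config.roi.pvs_shell_um,
        vs_min_object_area_um2=config.roi.vessel_min_area_um2,
    )

    row: dict = {c: float("nan") for c in INDEX_COLUMNS}
    row["image_id"] = image_id
    row["group"] = group

    for marker, col in _SURFACE_MARKERS.items():
        if marker in masks:
            row[col] = surface_index(masks[marker], rois.tt, rois.tt)
    if rois.vs.pixels.any():
        for marker, col in _ENDOTHELIAL_MARKERS.items():
            if marker in masks:
                row[col] = endothelial_index(masks[marker], rois.vs)
        for marker, col in _PERIVASCULAR_MARKERS.items():
            if marker in masks:
                row[col] = perivascular_index(masks[marker], rois.pvs, rois.vs)

    objects = label_vessels(rois.vs, config.roi.vessel_min_area_um2)
    tt_area_mm2 = rois.tt.area_um2() / 1e6
    if tt_area_mm2 > 0:
        row["mvd_per_mm2"] = objects.n_objects / tt_area_mm2
    if objects.n_objects > 0 and "desmin" in masks and "SMA" in masks:
        row["covered_vessel_frequency"] = covered_vessel_frequency(
            objects.labels,
            masks["desmin"],
            masks["SMA"],
            rois.pvs,
            config.coverage_threshold,
        )

    profile = None
    if rois.vs.pixels.any() and (dapi.pixels & rois.tt.pixels).any():
        dmap = vessel_distance_map(rois.vs, res)
        profile = distance_profile(dapi, rois.tt, dmap, gap_um=config.roi.gap_um)
        row["pct_cells_beyond_100um"] = profile.pct_beyond_100um

    if rois.vs.pixels.any():
        skel, graph = skeletonize_vs(rois.vs)
        nm = network_metrics(
            graph, skel, rois.vs, tissue_area_mm2=max(tt_area_mm2, 1e-12),
            objects=objects,
        )
        row["skeleton_length_mm"] = nm.skeleton_length_mm
        row["mean_diameter_um"] = nm.mean_diameter_um
        row["tortuosity"] = nm.tortuosity if nm.tortuosity is not None else float("nan")
        if config.branch_denominator == "tissue":
            row["branch_per_mm"] = nm.n_junctions / max(tt_area_mm2, 1e-12)
        else:
            row["branch_per_mm"] = nm.branch_per_mm
    return row, profile


def _iter_synthetic(config: RunConfig):
    """Yield (image_id, group, CalibratedImage, floors) deterministically."""
    counter = 0
    for label in config.groups:
        g = config.groups[label]
        overrides = dict(g.get("spec", {}))
        for i in range(int(g.get("n_scenes", 1))):
            spec = SceneSpec(**{**overrides, "seed": config.seed + counter})
            counter += 1
            image, gt = simulate_scene(spec)
            floors = synthetic_control_floors(spec, image.channels)
            yield f"{label}_{i:03d}", label, image, floors, gt


def _iter_images(config: RunConfig):
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise ConfigError(f"input_dir {input_dir} is not a directory")
    paths = sorted(p for p in input_dir.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff"))
    for p in paths:
        image_id = p.stem
        group = config.group_assignment.get(image_id, "")
        image = read_image(p)
        exclusion = None
        if image_id in config.exclusion_masks:
            exclusion = read_mask(config.exclusion_masks[image_id])
        yield image_id, group, image, {}, exclusion


def _sem(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(len(x)))


def run_experiment(config: RunConfig, write: bool = True) -> RunResult:
    """Run the full experiment described by ``config``.

    Deterministic given config + seed. Returns per-image indices,
    per-group mean +/- sem, and the statistical comparison table.
    """
    config.validate()
    rows: list[dict] = []
    profiles: dict = {}
    failures: list[dict] = []

    if config.mode == "synthetic":
        iterator = (
            (iid, grp, img, floors, None)
            for iid, grp, img, floors, _gt in _iter_synthetic(config)
        )
    else:
        iterator = (
            (iid, grp, img, floors, excl)
            for iid, grp, img, floors, excl in _iter_images(config)
        )

    for image_id, group, image, floors, exclusion in iterator:
        try:
            row, profile = analyze_image(
                image, config, image_id=image_id, group=group,
                exclusion=exclusion, floors=floors,
            )
            rows.append(row)
            if profile is not None:
                profiles[image_id] = profile
        except (UndefinedIndexError, ValueError) as exc:  # pragma: no cover
            logger.error("image %s failed: %s", image_id, exc)
            failures.append({"image_id": image_id, "error": str(exc)})

    index_table = pd.DataFrame(rows, columns=INDEX_COLUMNS)

    numeric_cols = [c for c in INDEX_COLUMNS if c not in ("image_id", "group")]
    summaries = []
    for label, sub in index_table.groupby("group", sort=True):
        entry = {"group": label, "n": len(sub)}
        for c in numeric_cols:
            vals = sub[c].to_numpy(dtype=float)
            entry[f"{c}_mean"] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
            entry[f"{c}_sem"] = _sem(vals)
        summaries.append(entry)
    group_summary = pd.DataFrame(summaries)

    comparisons = _compare_groups(index_table, numeric_cols)

    log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_images": len(rows),
        "n_failures": len(failures),
        "libraries": _library_versions(),
        "config": config.to_dict(),
    }
    result = RunResult(
        index_table=index_table,
        group_summary=group_summary,
        comparisons=comparisons,
        profiles=profiles,
        failures=failures,
        log=log,
    )
    if write:
        out_dir = Path(config.out_dir)
        write_results(index_table, out_dir, comparisons)
        group_summary.to_csv(out_dir / "group_summary.csv", index=False)
        _write_profiles(profiles, out_dir)
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return result


def _compare_groups(index_table: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    rows = []
    labels = sorted(set(index_table["group"]))
    if len(labels) < 2:
        return pd.DataFrame(rows)
    for metric in metrics:
        groups = []
        used_labels = []
        for label in labels:
            vals = index_table.loc[index_table["group"] == label, metric].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            if len(vals):
                groups.append(vals)
                used_labels.append(label)
        if len(groups) < 2:
            continue
        if len(groups) == 2:
            cmp = mann_whitney(groups[0], groups[1], metric=metric,
                               label_a=used_labels[0], label_b=used_labels[1])
            rows.append(dataclasses.asdict(cmp))
        else:
            overall, pairwise = kruskal_dunn(groups, used_labels, metric=metric)
            rows.append(dataclasses.asdict(overall))
            rows.extend(dataclasses.asdict(c) for c in pairwise)
    return pd.DataFrame(rows)


def _write_profiles(profiles: dict, out_dir: Path) -> None:
    if not profiles:
        return
    rows = []
    for image_id, prof in sorted(profiles.items()):
        for edge, pct in zip(prof.bin_edges_um, prof.percent_per_bin):
            rows.append({"image_id": image_id, "bin_lower_um": edge, "percent": pct})
    pd.DataFrame(rows).to_csv(out_dir / "distance_profiles.csv", index=False)


def _library_versions() -> dict:
    import numpy, scipy, skimage, pandas, networkx  # noqa

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }
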