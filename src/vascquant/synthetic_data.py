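"""Synthetic multi-channel fluorescence scenes with exact ground truth.

Generates tubular vessel networks, nuclei fields with per-marker
positivity, pericyte shells on a configurable fraction of vessels,
distance-thresholded hypoxia marking, perfusion channels, and a simple
PSF + Gaussian-noise rendering model. Every generated scene carries a
:class:`GroundTruth` whose metrics are computed exactly from the clean
masks and vessel geometry, so downstream measurements can be validated
against known answers.

Channel order of rendered scenes: DAPI, CD31, Ki-67, TUNEL, EF5, SMA,
desmin, Hoechst, dextran10k, dextran2M.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import draw as skdraw
from skimage import measure as skmeasure

from .imgio import CalibratedImage

__all__ = [
    "SceneSpec",
    "Segment",
    "VesselTree",
    "GroundTruth",
    "CHANNELS",
    "generate_vessel_network",
    "rasterize_scene",
    "true_metrics",
    "simulate_scene",
    "render_channel",
    "save_ground_truth",
    "load_ground_truth",
]

CHANNELS = [
    "DAPI",
    "CD31",
    "Ki-67",
    "TUNEL",
    "EF5",
    "SMA",
    "desmin",
    "Hoechst",
    "dextran10k",
    "dextran2M",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults emulate a tumor-like field: ~50 vessels/mm2, ~9.5 um mean
    vessel diameter, hypoxia positive beyond 100 um from the nearest
    perfused vessel.
    """

    field_width_um: float = 500.0
    field_height_um: float = 500.0
    resolution_um_per_px: float = 1.0
    n_stems: int = 12
    branch_prob: float = 0.02
    step_um: float = 5.0
    max_length_um: float = 250.0
    min_branch_length_um: float = 25.0
    turn_sd_rad: float = 0.15
    mean_diameter_um: float = 9.5
    diameter_sd_um: float = 1.5
    perfused_fraction: float = 0.8
    covered_fraction: float = 0.2
    pericyte_thickness_um: float = 3.0
    nuclei_density_per_mm2: float = 2000.0
    nucleus_radius_um: float = 3.5
    marker_fractions: dict = field(
        default_factory=lambda: {"Ki-67": 0.3, "TUNEL": 0.05}
    )
    hypoxia_distance_um: float = 100.0
    hoechst_halo_um: float = 2.0
    puncta_density_per_mm2: float = 200.0
    puncta_radius_um: float = 1.0
    stem_placement: str = "random"  # "random" or "grid"
    psf_sigma_um: float = 0.5
    noise_sd: float = 2000.0
    background_level: float = 200.0
    foreground_level: float = 20000.0
    seed: int = 0

    def validate(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field size must be positive")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be > 0")
        if self.mean_diameter_um <= 0:
            raise ValueError("mean_diameter_um must be > 0")
        if self.hypoxia_distance_um < 0:
            raise ValueError("hypoxia_distance_um must be >= 0")
        for name, frac in {
            "branch_prob": self.branch_prob,
            "perfused_fraction": self.perfused_fraction,
            "covered_fraction": self.covered_fraction,
            **{f"marker_fractions[{k}]": v for k, v in self.marker_fractions.items()},
        }.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {frac}")
        if self.stem_placement not in ("random", "grid"):
            raise ValueError(f"unknown stem_placement {self.stem_placement!r}")

    @property
    def shape(self) -> tuple[int, int]:
        ny = int(round(self.field_height_um / self.resolution_um_per_px))
        nx = int(round(self.field_width_um / self.resolution_um_per_px))
        return ny, nx

    def field_area_mm2(self) -> float:
        return self.field_width_um * self.field_height_um / 1e6

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        spec = cls(**d)
        spec.validate()
        return spec

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SceneSpec":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class Segment:
    """One centerline polyline with a constant radius."""

    points: np.ndarray  # (n, 2) um coordinates, columns (x, y)
    radius_um: float

    def length_um(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))


@dataclass
class VesselTree:
    """A connected vessel: a stem segment plus branch segments (a tree)."""

    id: int
    segments: list[Segment]
    perfused: bool
    covered: bool
    n_junctions: int = 0

    def total_length_um(self) -> float:
        return sum(s.length_um() for s in self.segments)

    def mean_diameter_um(self) -> float:
        """Length-weighted mean diameter over segments."""
        lengths = np.array([s.length_um() for s in self.segments])
        diams = np.array([2.0 * s.radius_um for s in self.segments])
        if lengths.sum() == 0:
            return float(diams.mean())
        return float(np.average(diams, weights=lengths))


@dataclass
class GroundTruth:
    """Exact truth for one scene: geometry, labels, clean masks, metrics."""

    trees: list[VesselTree]
    nuclei: list[dict]  # {"x_um", "y_um", "markers": {name: bool}}
    clean_masks: dict  # marker name -> bool array (Y, X)
    true_metrics: dict  # scalar oracle values


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean/sd."""
    if sd <= 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _draw_diameter(spec: SceneSpec, rng: np.random.Generator) -> float:
    mu, sigma = _lognormal_params(spec.mean_diameter_um, spec.diameter_sd_um)
    if sigma == 0:
        return spec.mean_diameter_um
    return float(rng.lognormal(mu, sigma))


def _stem_starts(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float, float, float] | None]]:
    """Stem start points plus per-stem walk bounds.

    Random placement gives unconstrained walks (trees may overlap; the
    ground truth reports merged components). Grid placement assigns each
    stem its own cell and confines the whole walk to that cell minus a
    tube-width margin, so trees are guaranteed disjoint and per-tree
    topology is exact ground truth.
    """
    n = spec.n_stems
    w, h = spec.field_width_um, spec.field_height_um
    if spec.stem_placement == "random":
        starts = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
        return starts, [None] * n
    ncols = int(math.ceil(math.sqrt(n * w / h)))
    nrows = int(math.ceil(n / ncols))
    cw, ch = w / ncols, h / nrows
    margin = (
        spec.mean_diameter_um / 2.0
        + 2.0 * spec.diameter_sd_um
        + spec.pericyte_thickness_um
        + 1.0
    )
    cells = [(i, j) for j in range(nrows) for i in range(ncols)][:n]
    jitter = 0.15
    pts, bounds = [], []
    for i, j in cells:
        px = (i + 0.5 + rng.uniform(-jitter, jitter)) * cw
        py = (j + 0.5 + rng.uniform(-jitter, jitter)) * ch
        pts.append((px, py))
        x0 = min(i * cw + margin, px)
        x1 = max((i + 1) * cw - margin, px)
        y0 = min(j * ch + margin, py)
        y1 = max((j + 1) * ch - margin, py)
        bounds.append((x0, x1, y0, y1))
    return np.asarray(pts), bounds


def generate_vessel_network(
    spec: SceneSpec, rng: np.random.Generator
) -> list[VesselTree]:
    """Grow ``spec.n_stems`` vessel trees by a persistent random walk.

    Each centerline advances in ``step_um`` steps with a small Gaussian
    heading perturbation; at every step a branch is spawned with
    probability ``branch_prob``. Walks stop at the field boundary or at
    ``max_length_um`` of total tree length. Perfused/covered flags are
    drawn per tree with the spec fractions. Deterministic given the rng
    state.
    """
    spec.validate()
    starts, walk_bounds = _stem_starts(spec, rng)
    trees: list[VesselTree] = []
    w, h = spec.field_width_um, spec.field_height_um

    for tid in range(spec.n_stems):
        box = walk_bounds[tid] or (0.0, w, 0.0, h)
        x0, x1, y0, y1 = box
        budget = spec.max_length_um
        # queue: (start point, heading, radius, parent index, arc at spawn)
        queue = [
            (
                starts[tid].copy(),
                rng.uniform(0, 2 * math.pi),
                _draw_diameter(spec, rng) / 2.0,
                None,
                0.0,
            )
        ]
        grown: list[tuple[Segment | None, int | None, float]] = []
        while queue and budget > 0:
            p, angle, radius, parent, spawn_arc = queue.pop(0)
            my_idx = len(grown)
            pts = [p.copy()]
            while budget > 0:
                angle += rng.normal(0.0, spec.turn_sd_rad)
                nxt = p + spec.step_um * np.array([math.cos(angle), math.sin(angle)])
                if not (x0 <= nxt[0] <= x1 and y0 <= nxt[1] <= y1):
                    break
                p = nxt
                pts.append(p.copy())
                budget -= spec.step_um
                if rng.random() < spec.branch_prob:
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    queue.append(
                        (
                            p.copy(),
                            angle + side * rng.normal(1.0, 0.2),
                            _draw_diameter(spec, rng) / 2.0,
                            my_idx,
                            (len(pts) - 1) * spec.step_um,
                        )
                    )
            seg = Segment(points=np.asarray(pts), radius_um=radius) \
                if len(pts) >= 2 else None
            grown.append((seg, parent, spawn_arc))
        # Drop (and do not count) branches that cannot form a clean
        # topological junction in the raster: branches shorter than
        # min_branch_length_um hide inside the parent tube, and branches
        # attached within ~a tube diameter of a parent end make a corner,
        # not a junction. Descendants of dropped branches go with them,
        # so the junction count is geometric ground truth.
        guard = max(2.0 * spec.step_um, 1.5 * spec.mean_diameter_um)
        dropped: set[int] = set()
        for i, (seg, parent, spawn_arc) in enumerate(grown):
            is_branch = parent is not None
            bad = seg is None or (
                is_branch and seg.length_um() < spec.min_branch_length_um
            )
            if is_branch and not bad:
                parent_seg = grown[parent][0]
                parent_len = parent_seg.length_um() if parent_seg is not None else 0.0
                if spawn_arc < guard or (parent_len - spawn_arc) < guard:
                    bad = True
            if bad or (parent in dropped):
                dropped.add(i)
        segments = [s for i, (s, _, _) in enumerate(grown)
                    if i not in dropped and s is not None]
        n_junctions = max(len(segments) - 1, 0)
        if not segments:
            # degenerate walk (boundary start); keep a minimal stub inward
            center = np.array([w / 2.0, h / 2.0])
            v = center - starts[tid]
            v /= max(np.hypot(*v), 1e-9)
            pts = np.array([starts[tid], starts[tid] + v * spec.step_um])
            segments = [Segment(points=pts, radius_um=_draw_diameter(spec, rng) / 2.0)]
            n_junctions = 0
        trees.append(
            VesselTree(
                id=tid,
                segments=segments,
                perfused=bool(rng.random() < spec.perfused_fraction),
                covered=bool(rng.random() < spec.covered_fraction),
                n_junctions=n_junctions,
            )
        )
    return trees


def _paint_tube(mask: np.ndarray, seg: Segment, res: float) -> None:
    """Stamp disks of ``seg.radius_um`` along the polyline into ``mask``."""
    r_px = seg.radius_um / res
    spacing = max(min(res, seg.radius_um / 2.0), res / 4.0)
    pts = seg.points
    shape = mask.shape
    for a, b in zip(pts[:-1], pts[1:]):
        d = np.hypot(*(b - a))
        n = max(int(math.ceil(d / spacing)), 1)
        for t in np.linspace(0.0, 1.0, n + 1):
            x, y = a + t * (b - a)
            rr, cc = skdraw.disk((y / res, x / res), r_px, shape=shape)
            mask[rr, cc] = True


def _paint_disks(
    mask: np.ndarray, centers_um: np.ndarray, radius_um: float, res: float
) -> None:
    for x, y in centers_um:
        rr, cc = skdraw.disk((y / res, x / res), radius_um / res, shape=mask.shape)
        mask[rr, cc] = True


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centers with min spacing 1.5 x radius."""
    n_target = int(round(spec.nuclei_density_per_mm2 * spec.field_area_mm2()))
    min_d2 = (1.5 * spec.nucleus_radius_um) ** 2
    placed: list[tuple[float, float]] = []
    arr = np.empty((0, 2))
    tries = 0
    max_tries = 60 * max(n_target, 1)
    while len(placed) < n_target and tries < max_tries:
        tries += 1
        x = rng.uniform(0, spec.field_width_um)
        y = rng.uniform(0, spec.field_height_um)
        if placed:
            d2 = (arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2
            if d2.min() < min_d2:
                continue
        placed.append((x, y))
        arr = np.asarray(placed)
    return arr if len(placed) else np.empty((0, 2))


def _dilate_um(mask: np.ndarray, radius_um: float, res: float) -> np.ndarray:
    """Euclidean dilation via distance transform of the complement."""
    if radius_um <= 0 or not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask) * res
    return d <= radius_um


def render_channel(
    clean: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render one clean mask into a noisy uint16 channel.

    clean * (foreground - background) + background, Gaussian PSF blur,
    additive Gaussian noise, clipped to the 16-bit range. With zero PSF
    and zero noise this is the identity rendering of the mask.
    """
    img = np.where(clean, spec.foreground_level, spec.background_level).astype(float)
    if spec.psf_sigma_um > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma_um / spec.resolution_um_per_px)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def rasterize_scene(
    trees: list[VesselTree], spec: SceneSpec, rng: np.random.Generator
) -> tuple[CalibratedImage, GroundTruth]:
    """Rasterize vessel trees into a rendered scene plus exact ground truth.

    Clean (noise-free) masks are stored in the GroundTruth before the
    PSF/noise rendering is applied.
    """
    spec.validate()
    res = spec.resolution_um_per_px
    ny, nx = spec.shape
    if min(spec.field_width_um, spec.field_height_um) < 2 * spec.nucleus_radius_um:
        raise ValueError("field too small to contain one nucleus")

    cd31 = np.zeros((ny, nx), dtype=bool)
    perfused = np.zeros_like(cd31)
    covered_tubes = np.zeros_like(cd31)
    for tree in trees:
        tree_mask = np.zeros_like(cd31)
        for seg in tree.segments:
            _paint_tube(tree_mask, seg, res)
        cd31 |= tree_mask
        if tree.perfused:
            perfused |= tree_mask
        if tree.covered:
            covered_tubes |= tree_mask

    # pericyte shell: ring of pericyte_thickness_um around covered tubes,
    # excluding all vessel lumens
    shell = _dilate_um(covered_tubes, spec.pericyte_thickness_um, res) & ~cd31

    centers = _place_nuclei(spec, rng)
    # distance of each nucleus center to the nearest perfused vessel surface
    if perfused.any():
        dist_perf = ndimage.distance_transform_edt(~perfused) * res
    else:
        dist_perf = np.full((ny, nx), np.inf)
    nuclei: list[dict] = []
    marker_flags = {m: np.zeros(len(centers), dtype=bool) for m in spec.marker_fractions}
    for m, frac in spec.marker_fractions.items():
        marker_flags[m] = rng.random(len(centers)) < frac
    ef5_flags = np.zeros(len(centers), dtype=bool)
    for i, (x, y) in enumerate(centers):
        iy = min(int(y / res), ny - 1)
        ix = min(int(x / res), nx - 1)
        ef5_flags[i] = dist_perf[iy, ix] > spec.hypoxia_distance_um
        nuclei.append(
            {
                "x_um": float(x),
                "y_um": float(y),
                "markers": {
                    **{m: bool(marker_flags[m][i]) for m in spec.marker_fractions},
                    "EF5": bool(ef5_flags[i]),
                },
            }
        )

    dapi = np.zeros_like(cd31)
    _paint_disks(dapi, centers, spec.nucleus_radius_um, res)
    clean: dict[str, np.ndarray] = {"DAPI": dapi, "CD31": cd31}
    for m in ("Ki-67", "TUNEL"):
        msk = np.zeros_like(cd31)
        flags = marker_flags.get(m, np.zeros(len(centers), dtype=bool))
        if len(centers):
            _paint_disks(msk, centers[flags], spec.nucleus_radius_um, res)
        clean[m] = msk
    ef5 = np.zeros_like(cd31)
    if len(centers):
        _paint_disks(ef5, centers[ef5_flags], spec.nucleus_radius_um, res)
    clean["EF5"] = ef5
    clean["SMA"] = shell
    clean["desmin"] = shell.copy()
    clean["Hoechst"] = _dilate_um(perfused, spec.hoechst_halo_um, res)

    # perfusion puncta inside perfused lumens (free parameter; the source
    # study gives no generative density for these markers)
    lumen_idx = np.flatnonzero(perfused.ravel())
    n_puncta = int(round(spec.puncta_density_per_mm2 * spec.field_area_mm2()))
    for name in ("dextran10k", "dextran2M"):
        msk = np.zeros_like(cd31)
        if len(lumen_idx) and n_puncta:
            chosen = rng.choice(lumen_idx, size=n_puncta, replace=True)
            yy, xx = np.unravel_index(chosen, (ny, nx))
            pts = np.column_stack([(xx + 0.5) * res, (yy + 0.5) * res])
            _paint_disks(msk, pts, spec.puncta_radius_um, res)
            msk &= perfused
        clean[name] = msk

    pixels = np.stack([render_channel(clean[c], spec, rng) for c in CHANNELS])
    image = CalibratedImage(
        pixels=pixels, resolution_um_per_px=res, channels=list(CHANNELS)
    )

    gt = GroundTruth(trees=trees, nuclei=nuclei, clean_masks=clean, true_metrics={})
    gt.true_metrics = _compute_true_metrics(gt, spec)
    return image, gt


def _compute_true_metrics(gt: GroundTruth, spec: SceneSpec) -> dict:
    res = spec.resolution_um_per_px
    cd31 = gt.clean_masks["CD31"]
    dapi = gt.clean_masks["DAPI"]
    area_mm2 = spec.field_area_mm2()
    # merged component count: overlapping trees count once
    n_components = int(skmeasure.label(cd31, connectivity=2).max())
    tt = _dilate_um(dapi, 10.0, res)
    tt_area = float(tt.sum()) * res**2
    metrics: dict[str, float] = {
        "n_trees": len(gt.trees),
        "n_components": n_components,
        "mvd_per_mm2": n_components / area_mm2,
        "mvd_per_mm2_tt": (n_components / (tt_area / 1e6)) if tt_area else float("nan"),
        "covered_vessel_fraction": (
            sum(t.covered for t in gt.trees) / len(gt.trees) if gt.trees else 0.0
        ),
        "junction_count": sum(t.n_junctions for t in gt.trees),
        "total_centerline_length_um": sum(t.total_length_um() for t in gt.trees),
        "tt_area_um2": tt_area,
    }
    lengths = np.array([t.total_length_um() for t in gt.trees])
    diams = np.array([t.mean_diameter_um() for t in gt.trees])
    if len(gt.trees):
        metrics["mean_diameter_um"] = float(
            np.average(diams, weights=np.maximum(lengths, 1e-9))
        )
    for marker, key in (
        ("Ki-67", "ki67_index"),
        ("TUNEL", "tunel_index"),
        ("EF5", "ef5_index"),
    ):
        if tt_area > 0:
            inter = float((gt.clean_masks[marker] & tt).sum()) * res**2
            metrics[key] = inter / tt_area
        else:
            metrics[key] = float("nan")
    n_nuc = len(gt.nuclei)
    metrics["n_nuclei"] = n_nuc
    if n_nuc:
        metrics["ef5_nucleus_fraction"] = (
            sum(n["markers"]["EF5"] for n in gt.nuclei) / n_nuc
        )
    return metrics


def true_metrics(gt: GroundTruth, spec: SceneSpec) -> dict:
    """Exact oracle values recomputed from the ground truth (not pixels
    of the rendered image). Keys mirror the measured quantities."""
    return _compute_true_metrics(gt, spec)


def simulate_scene(spec: SceneSpec) -> tuple[CalibratedImage, GroundTruth]:
    """Convenience: seeded generation + rasterization in one call."""
    rng = np.random.default_rng(spec.seed)
    trees = generate_vessel_network(spec, rng)
    return rasterize_scene(trees, spec, rng)


def save_ground_truth(gt: GroundTruth, json_path: str | Path, tiff_path: str | Path) -> None:
    """Serialize ground truth: JSON (trees, nuclei, metrics) + clean-mask TIFF."""
    doc = {
        "trees": [
            {
                "id": t.id,
                "perfused": t.perfused,
                "covered": t.covered,
                "n_junctions": t.n_junctions,
                "segments": [
                    {"radius_um": s.radius_um, "points": s.points.tolist()}
                    for s in t.segments
                ],
            }
            for t in gt.trees
        ],
        "nuclei": gt.nuclei,
        "true_metrics": gt.true_metrics,
        "mask_channels": list(gt.clean_masks.keys()),
    }
    Path(json_path).write_text(json.dumps(doc))
    stack = np.stack([gt.clean_masks[c] for c in gt.clean_masks]).astype(np.uint8)
    tifffile.imwrite(tiff_path, stack * 255, photometric="minisblack")


def load_ground_truth(json_path: str | Path, tiff_path: str | Path) -> GroundTruth:
    doc = json.loads(Path(json_path).read_text())
    stack = tifffile.imread(tiff_path) > 0
    if stack.ndim == 2:
        stack = stack[None]
    masks = {name: stack[i] for i, name in enumerate(doc["mask_channels"])}
    trees = [
        VesselTree(
            id=t["id"],
            perfused=t["perfused"],
            covered=t["covered"],
            n_junctions=t["n_junctions"],
            segments=[
                Segment(points=np.asarray(s["points"]), radius_um=s["radius_um"])
                for s in t["segments"]
            ],
        )
        for t in doc["trees"]
    ]
    return GroundTruth(
        trees=trees,
        nuclei=doc["nuclei"],
        clean_masks=masks,
        true_metrics=doc["true_metrics"],
    )
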