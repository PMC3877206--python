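import numpy as np
import pytest
from skimage import measure as skmeasure

from vascquant.synthetic_data import (
    CHANNELS,
    SceneSpec,
    generate_vessel_network,
    rasterize_scene,
    simulate_scene,
    true_metrics,
)


def _spec(**kw):
    base = dict(
        field_width_um=300.0,
        field_height_um=300.0,
        resolution_um_per_px=1.0,
        n_stems=4,
        nuclei_density_per_mm2=800.0,
        noise_sd=0.0,
        psf_sigma_um=0.0,
        seed=3,
    )
    base.update(kw)
    return SceneSpec(**base)


class TestSceneSpec:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(perfused_fraction=1.5).validate()

    def test_zero_resolution_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(resolution_um_per_px=0).validate()

    def test_zero_field_rejected(self):
        with pytest.raises(ValueError):
            generate_vessel_network(
                SceneSpec(field_width_um=0.0), np.random.default_rng(0)
            )

    def test_json_round_trip(self, tmp_path):
        spec = _spec(branch_prob=0.1)
        p = tmp_path / "spec.json"
        spec.save(p)
        assert SceneSpec.load(p) == spec

    def test_yaml_round_trip(self, tmp_path):
        spec = _spec()
        p = tmp_path / "spec.yaml"
        spec.save(p)
        assert SceneSpec.load(p) == spec


class TestGenerateVesselNetwork:
    def test_no_branching_when_prob_zero(self):
        spec = _spec(branch_prob=0.0)
        trees = generate_vessel_network(spec, np.random.default_rng(0))
        assert len(trees) == spec.n_stems
        for t in trees:
            assert t.n_junctions == 0
            assert len(t.segments) == 1  # a single polyline: 2 endpoints

    def test_determinism(self):
        spec = _spec(branch_prob=0.05)
        a = generate_vessel_network(spec, np.random.default_rng(9))
        b = generate_vessel_network(spec, np.random.default_rng(9))
        assert len(a) == len(b)
        for ta, tb in zip(a, b):
            assert ta.perfused == tb.perfused and ta.covered == tb.covered
            assert len(ta.segments) == len(tb.segments)
            for sa, sb in zip(ta.segments, tb.segments):
                np.testing.assert_array_equal(sa.points, sb.points)
                assert sa.radius_um == sb.radius_um

    def test_polylines_inside_field(self):
        spec = _spec(branch_prob=0.1, n_stems=8)
        for t in generate_vessel_network(spec, np.random.default_rng(1)):
            for s in t.segments:
                assert (s.points[:, 0] >= 0).all()
                assert (s.points[:, 0] <= spec.field_width_um).all()
                assert (s.points[:, 1] >= 0).all()
                assert (s.points[:, 1] <= spec.field_height_um).all()
                assert s.radius_um > 0

    def test_true_mvd_with_nonoverlapping_stems(self):
        # 50 stems on a 1 mm^2 field, grid-placed short walks: the
        # rasterized clean CD31 mask must have exactly 50 components
        spec = SceneSpec(
            field_width_um=1000.0,
            field_height_um=1000.0,
            resolution_um_per_px=2.0,
            n_stems=50,
            max_length_um=60.0,
            branch_prob=0.0,
            stem_placement="grid",
            nuclei_density_per_mm2=200.0,
            noise_sd=0.0,
            psf_sigma_um=0.0,
            seed=5,
        )
        rng = np.random.default_rng(spec.seed)
        trees = generate_vessel_network(spec, rng)
        _, gt = rasterize_scene(trees, spec, rng)
        n_comp = int(skmeasure.label(gt.clean_masks["CD31"], connectivity=2).max())
        assert n_comp == 50
        assert gt.true_metrics["mvd_per_mm2"] == pytest.approx(50.0)


class TestRasterizeScene:
    def test_ef5_positivity_by_distance_rule(self):
        spec = _spec(hypoxia_distance_um=60.0, perfused_fraction=1.0, n_stems=1)
        image, gt = simulate_scene(spec)
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~gt.clean_masks["CD31"]) * \
            spec.resolution_um_per_px
        for nuc in gt.nuclei:
            iy = min(int(nuc["y_um"] / spec.resolution_um_per_px), dist.shape[0] - 1)
            ix = min(int(nuc["x_um"] / spec.resolution_um_per_px), dist.shape[1] - 1)
            assert nuc["markers"]["EF5"] == (dist[iy, ix] > spec.hypoxia_distance_um)

    def test_no_coverage_means_empty_pericyte_masks(self):
        spec = _spec(covered_fraction=0.0)
        _, gt = simulate_scene(spec)
        assert not gt.clean_masks["SMA"].any()
        assert not gt.clean_masks["desmin"].any()

    def test_identity_rendering_without_noise_or_blur(self):
        spec = _spec(noise_sd=0.0, psf_sigma_um=0.0,
                     background_level=100.0, foreground_level=30000.0)
        image, gt = simulate_scene(spec)
        for i, name in enumerate(CHANNELS):
            expected = np.where(gt.clean_masks[name], 30000, 100).astype(np.uint16)
            np.testing.assert_array_equal(image.pixels[i], expected)

    def test_field_too_small_for_one_nucleus(self):
        spec = SceneSpec(field_width_um=4.0, field_height_um=4.0,
                         nucleus_radius_um=3.5, n_stems=1)
        with pytest.raises(ValueError, match="too small"):
            simulate_scene(spec)

    def test_scene_determinism_bit_identical(self):
        spec = _spec(noise_sd=500.0, psf_sigma_um=0.5)
        img1, gt1 = simulate_scene(spec)
        img2, gt2 = simulate_scene(spec)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        for name in CHANNELS:
            np.testing.assert_array_equal(gt1.clean_masks[name], gt2.clean_masks[name])
        assert gt1.true_metrics == gt2.true_metrics

    def test_nuclei_min_spacing(self):
        spec = _spec(nuclei_density_per_mm2=2000.0)
        _, gt = simulate_scene(spec)
        pts = np.array([[n["x_um"], n["y_um"]] for n in gt.nuclei])
        from scipy.spatial.distance import pdist

        assert pdist(pts).min() >= 1.5 * spec.nucleus_radius_um

    def test_each_nucleus_has_one_record_with_all_markers(self):
        _, gt = simulate_scene(_spec())
        for nuc in gt.nuclei:
            assert set(nuc["markers"]) == {"Ki-67", "TUNEL", "EF5"}

    def test_clean_cd31_is_union_of_tree_rasters(self):
        # conservation: every painted tube pixel is in the CD31 mask and
        # the CD31 mask contains nothing else
        spec = _spec(n_stems=3, branch_prob=0.05)
        rng = np.random.default_rng(spec.seed)
        trees = generate_vessel_network(spec, rng)
        _, gt = rasterize_scene(trees, spec, rng)
        from vascquant.synthetic_data import _paint_tube

        union = np.zeros(spec.shape, bool)
        for t in trees:
            for s in t.segments:
                _paint_tube(union, s, spec.resolution_um_per_px)
        np.testing.assert_array_equal(union, gt.clean_masks["CD31"])


class TestTrueMetrics:
    def test_all_nuclei_ki67_positive(self):
        spec = _spec(marker_fractions={"Ki-67": 1.0, "TUNEL": 0.0})
        _, gt = simulate_scene(spec)
        from vascquant.roi_geometry import dilate_um

        tt = dilate_um(gt.clean_masks["DAPI"], 10.0, spec.resolution_um_per_px)
        expected = (gt.clean_masks["Ki-67"] & tt).sum() / tt.sum()
        assert gt.true_metrics["ki67_index"] == pytest.approx(expected)
        # Ki-67 mask equals DAPI mask when everything is positive
        np.testing.assert_array_equal(gt.clean_masks["Ki-67"], gt.clean_masks["DAPI"])

    def test_straight_single_tube_length_and_junctions(self):
        spec = _spec(n_stems=1, branch_prob=0.0, turn_sd_rad=0.0, max_length_um=100.0)
        rng = np.random.default_rng(2)
        trees = generate_vessel_network(spec, rng)
        t = trees[0]
        assert t.n_junctions == 0
        assert t.total_length_um() == pytest.approx(
            spec.step_um * (len(t.segments[0].points) - 1)
        )

    def test_covered_fraction_flag_counting(self):
        spec = _spec(n_stems=5)
        rng = np.random.default_rng(0)
        trees = generate_vessel_network(spec, rng)
        for i, t in enumerate(trees):
            t.covered = i < 2  # 2 covered of 5
        _, gt = rasterize_scene(trees, spec, rng)
        assert gt.true_metrics["covered_vessel_fraction"] == pytest.approx(0.4)

    def test_true_metrics_recomputable(self):
        spec = _spec()
        _, gt = simulate_scene(spec)
        again = true_metrics(gt, spec)
        assert again == gt.true_metrics


def test_hypoxia_monotone_in_perfused_density():
    """Mean true EF5+ nucleus fraction is non-increasing as perfused
    vessel density grows (averaged over seeds)."""
    densities = [1, 4, 10]
    means = []
    for n_stems in densities:
        fracs = []
        for seed in range(5):
            spec = SceneSpec(
                field_width_um=300.0,
                field_height_um=300.0,
                n_stems=n_stems,
                perfused_fraction=1.0,
                nuclei_density_per_mm2=500.0,
                hypoxia_distance_um=50.0,
                noise_sd=0.0,
                psf_sigma_um=0.0,
                stem_placement="grid",
                max_length_um=100.0,
                seed=seed,
            )
            _, gt = simulate_scene(spec)
            fracs.append(gt.true_metrics["ef5_nucleus_fraction"])
        means.append(np.mean(fracs))
    assert means[0] >= means[1] >= means[2]


def test_ground_truth_round_trip(tmp_path):
    from vascquant.synthetic_data import load_ground_truth, save_ground_truth

    spec = _spec(branch_prob=0.05)
    _, gt = simulate_scene(spec)
    save_ground_truth(gt, tmp_path / "gt.json", tmp_path / "gt.tif")
    back = load_ground_truth(tmp_path / "gt.json", tmp_path / "gt.tif")
    assert back.true_metrics == gt.true_metrics
    assert back.nuclei == gt.nuclei
    for name in gt.clean_masks:
        np.testing.assert_array_equal(back.clean_masks[name], gt.clean_masks[name])
    for ta, tb in zip(gt.trees, back.trees):
        assert ta.perfused == tb.perfused
        np.testing.assert_allclose(ta.segments[0].points, tb.segments[0].points)
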