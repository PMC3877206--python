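import math

import numpy as np
import pytest

from vascquant.distance_profile import (
    distance_profile,
    iterative_enlargement_oracle,
    smooth_profile,
    vessel_distance_map,
)

from conftest import disk_mask


class TestVesselDistanceMap:
    def test_adjacent_pixel_distance(self):
        vs = np.zeros((20, 20), bool)
        vs[10, 10] = True
        dmap = vessel_distance_map(vs, resolution_um_per_px=0.5)
        assert dmap[10, 11] == pytest.approx(0.5)
        assert dmap[10, 10] == 0.0

    def test_center_of_100um_gap(self):
        # two vertical walls 100 um apart (res 1 um/px)
        vs = np.zeros((50, 140), bool)
        vs[:, 19] = True
        vs[:, 120] = True
        dmap = vessel_distance_map(vs, 1.0)
        assert dmap[25, 70] == pytest.approx(50.0, abs=1.0)

    def test_all_vs_zero_everywhere(self):
        dmap = vessel_distance_map(np.ones((15, 15), bool), 1.0)
        assert dmap.max() == 0.0

    def test_empty_vs_raises(self):
        with pytest.raises(ValueError):
            vessel_distance_map(np.zeros((10, 10), bool), 1.0)


class TestDistanceProfile:
    def test_all_dapi_within_first_gap(self):
        vs = disk_mask((60, 60), (30, 30), 10)
        dapi = disk_mask((60, 60), (30, 30), 13) & ~vs  # ring within 3 px
        tt = np.ones((60, 60), bool)
        prof = distance_profile(dapi, tt, vessel_distance_map(vs, 1.0), gap_um=5)
        assert prof.percent_per_bin[0] == pytest.approx(100.0)
        assert prof.pct_beyond_100um == 0.0

    def test_analytic_ring_masses(self):
        # fully DAPI+ field, central vessel disk r=10 um: bin masses
        # proportional to annulus areas pi*((r+5k+5)^2 - (r+5k)^2)
        res = 0.5
        n = 600  # 300 um field
        vs = disk_mask((n, n), (n // 2, n // 2), 10 / res)
        dapi = np.ones((n, n), bool)
        tt = np.ones((n, n), bool)
        prof = distance_profile(dapi, tt, vessel_distance_map(vs, res), gap_um=5)
        total_um2 = n * n * res * res
        # bin 0 is the enlarged disk of radius 15 um
        assert prof.percent_per_bin[0] / 100 * total_um2 == pytest.approx(
            math.pi * 15**2, rel=0.02
        )
        for k in range(1, 10):  # rings fully inside the field
            r_in, r_out = 10 + 5 * k, 10 + 5 * (k + 1)
            expected = math.pi * (r_out**2 - r_in**2)
            measured = prof.percent_per_bin[k] / 100 * total_um2
            assert measured == pytest.approx(expected, rel=0.02), k

    def test_raw_bins_sum_to_100(self, rng):
        vs = rng.random((100, 100)) > 0.97
        dapi = rng.random((100, 100)) > 0.5
        tt = np.ones((100, 100), bool)
        prof = distance_profile(dapi, tt, vessel_distance_map(vs, 1.0))
        assert prof.percent_per_bin.sum() == pytest.approx(100.0, abs=1e-9)

    def test_smoothing_never_alters_raw_bins(self):
        raw = np.array([60.0, 30.0, 10.0, 0.0])
        smoothed = smooth_profile(raw)
        assert raw.tolist() == [60.0, 30.0, 10.0, 0.0]
        assert len(smoothed) == len(raw)
        assert smoothed.sum() != 0

    def test_no_dapi_in_tt_raises(self):
        vs = disk_mask((30, 30), (15, 15), 5)
        with pytest.raises(ValueError):
            distance_profile(np.zeros((30, 30), bool), np.ones((30, 30), bool),
                             vessel_distance_map(vs, 1.0))

    def test_vessel_addition_shifts_mass_down(self, rng):
        """pct_beyond_100um is non-increasing when VS grows."""
        dapi = rng.random((300, 300)) > 0.5
        tt = np.ones((300, 300), bool)
        vs1 = disk_mask((300, 300), (40, 40), 8)
        vs2 = vs1 | disk_mask((300, 300), (250, 250), 8)
        p1 = distance_profile(dapi, tt, vessel_distance_map(vs1, 1.0))
        p2 = distance_profile(dapi, tt, vessel_distance_map(vs2, 1.0))
        assert p2.pct_beyond_100um <= p1.pct_beyond_100um

    def test_exclude_vs_mass_option(self):
        vs = disk_mask((60, 60), (30, 30), 10)
        dapi = np.ones((60, 60), bool)
        tt = np.ones((60, 60), bool)
        dmap = vessel_distance_map(vs, 1.0)
        with_vs = distance_profile(dapi, tt, dmap, include_vs_bin0=True)
        without = distance_profile(dapi, tt, dmap, include_vs_bin0=False)
        assert without.percent_per_bin.sum() == pytest.approx(100.0)
        assert without.percent_per_bin[0] < with_vs.percent_per_bin[0]


class TestOracleEquivalence:
    def _random_scene(self, rng, n=256):
        vs = np.zeros((n, n), bool)
        for _ in range(rng.integers(1, 5)):
            c = rng.integers(20, n - 20, 2)
            vs |= disk_mask((n, n), tuple(c), rng.integers(4, 12))
        dapi = rng.random((n, n)) < 0.4
        return vs, dapi, np.ones((n, n), bool)

    @pytest.mark.parametrize("seed", range(6))
    def test_dual_implementation_agrees_exactly(self, seed):
        rng = np.random.default_rng(seed)
        vs, dapi, tt = self._random_scene(rng)
        prof_a = distance_profile(dapi, tt, vessel_distance_map(vs, 1.0),
                                  gap_um=5, max_um=100)
        prof_b = iterative_enlargement_oracle(vs, dapi, tt, gap_um=5,
                                              resolution_um_per_px=1.0, max_um=100)
        np.testing.assert_array_equal(prof_a.percent_per_bin, prof_b.percent_per_bin)
        assert prof_a.pct_beyond_100um == prof_b.pct_beyond_100um

    def test_empty_annulus_zero_in_both(self):
        vs = disk_mask((80, 80), (40, 40), 5)
        dapi = disk_mask((80, 80), (40, 40), 8)  # all mass within 3 px
        tt = np.ones((80, 80), bool)
        a = distance_profile(dapi, tt, vessel_distance_map(vs, 1.0), 5, max_um=50)
        b = iterative_enlargement_oracle(vs, dapi, tt, 5, resolution_um_per_px=1.0,
                                         max_um=50)
        assert a.percent_per_bin[3] == 0.0
        assert b.percent_per_bin[3] == 0.0

    def test_single_bin_degenerate(self):
        vs = disk_mask((40, 40), (20, 20), 10)
        dapi = vs.copy()
        tt = np.ones((40, 40), bool)
        a = distance_profile(dapi, tt, vessel_distance_map(vs, 1.0), 5, max_um=5)
        b = iterative_enlargement_oracle(vs, dapi, tt, 5, resolution_um_per_px=1.0,
                                         max_um=5)
        assert a.percent_per_bin[0] == 100.0
        assert b.percent_per_bin[0] == 100.0

    def test_oracle_at_half_um_resolution(self):
        rng = np.random.default_rng(99)
        vs, dapi, tt = self._random_scene(rng, n=200)
        a = distance_profile(dapi, tt, vessel_distance_map(vs, 0.5), 5, max_um=50)
        b = iterative_enlargement_oracle(vs, dapi, tt, 5, resolution_um_per_px=0.5,
                                         max_um=50)
        np.testing.assert_array_equal(a.percent_per_bin, b.percent_per_bin)
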