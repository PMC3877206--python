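import numpy as np
import pytest

from vascquant.imgio import BinaryMask
from vascquant.synthetic_data import SceneSpec, simulate_scene


def disk_mask(shape, center_yx, radius_px):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2 <= radius_px**2


def tube_mask(shape, p0, p1, radius_px):
    """Capsule between p0 and p1 (x, y pixel coords)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    L2 = float(d @ d)
    t = np.clip(((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / L2, 0, 1)
    return np.hypot(xx - (p0[0] + t * d[0]), yy - (p0[1] + t * d[1])) <= radius_px


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, blur-free scene with grid-placed stems (session-cached)."""
    spec = SceneSpec(
        seed=7,
        stem_placement="grid",
        max_length_um=150.0,
        noise_sd=0.0,
        psf_sigma_um=0.0,
        covered_fraction=0.4,
    )
    image, gt = simulate_scene(spec)
    return spec, image, gt


@pytest.fixture(scope="session")
def noisy_scene():
    """Scene rendered with the default noise model (SNR ~ 10)."""
    spec = SceneSpec(
        seed=11,
        stem_placement="grid",
        max_length_um=150.0,
        resolution_um_per_px=0.5,
        field_width_um=300.0,
        field_height_um=300.0,
        n_stems=5,
    )
    image, gt = simulate_scene(spec)
    return spec, image, gt


def bmask(pixels, res=1.0, marker="m"):
    return BinaryMask(pixels=np.asarray(pixels, bool), marker=marker,
                      resolution_um_per_px=res)
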