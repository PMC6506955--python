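import numpy as np
import pytest

from periplaque.config import RunConfig, ThresholdSpec
from periplaque.synthetic import NoiseSpec, PlaqueSpec, SceneSpec


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def noise_free() -> NoiseSpec:
    return NoiseSpec(photon_scale=0.0, read_sd=0.0, psf_sigma_um=0.3)


@pytest.fixture
def plaque_scene_spec(noise_free) -> SceneSpec:
    """Small Aβ+thioS scene, noise-free, for segmentation-level tests."""
    return SceneSpec(
        fov_um=(128.0, 128.0),
        pixel_size_um=0.5,
        channels=("abeta", "thios"),
        plaque=PlaqueSpec(count=6),
        noise=noise_free,
    )


@pytest.fixture
def half_contrast_config(plaque_scene_spec) -> RunConfig:
    """Fixed threshold at half the planted plaque contrast, light blur."""
    ps = plaque_scene_spec.plaque
    thr = ThresholdSpec("fixed_value", (ps.background + ps.abeta_core) / 2)
    return RunConfig().replace(blur_radius_um=0.5, thresholds={"abeta": thr})


def disk_image(shape, cy, cx, r_px, value, background=0.0):
    img = np.full(shape, background, dtype=float)
    yy, xx = np.indices(shape)
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2] = value
    return img
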