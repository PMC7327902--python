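import numpy as np
import pytest

from thinfil import imaging, synth


@pytest.fixture(scope="session")
def clean_render() -> synth.RenderConfig:
    """Noise-free, background-free rendering for exact-value tests."""
    return synth.RenderConfig(
        image_shape=(256, 256),
        background=(0.0, 0.0, 0.0),
        read_noise_sd=0.0,
        shot_noise=False,
        seed=0,
    )


@pytest.fixture(scope="session")
def straight_filament() -> synth.FilamentGroundTruth:
    """One straight, fully decorated filament crossing a 256x256 field."""
    n_sites = 60
    length = n_sites * synth.SITE_LENGTH_UM
    path = np.column_stack([
        np.linspace(4.0, 4.0 + length, 200),
        np.full(200, 8.0),
    ])
    return synth.FilamentGroundTruth(
        id=0, path=path, length_um=length, n_sites=n_sites,
        occupancy=np.ones(n_sites, dtype=np.uint8),
    )


@pytest.fixture(scope="session")
def default_scene():
    """A realistic noisy scene at ~50% coverage with its ground truth."""
    spec = synth.SceneSpec(n_filaments=25, seed=42, hill_params=(500.0, 1.3, 500.0))
    render = synth.RenderConfig(image_shape=(384, 384), seed=7)
    img, gts = synth.make_scene(spec, render)
    return img, gts


@pytest.fixture(scope="session")
def analyzed_scene(default_scene):
    img, gts = default_scene
    table, summary = imaging.analyze_image(img)
    return img, gts, table, summary
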