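import numpy as np
import pytest

from synquant import CalibratedImage, QuantParams, SceneSpec, generate_scene
from synquant.synth import noise_free

PX = 0.1  # μm per pixel used throughout the suite


def image_from(arr, pixel_size_um=PX, bit_depth=8, role="presyn_marker"):
    return CalibratedImage(
        pixels=np.asarray(arr, dtype=float),
        pixel_size_um=pixel_size_um,
        bit_depth=bit_depth,
        channel_role=role,
    )


@pytest.fixture
def qparams():
    return QuantParams()


@pytest.fixture(scope="session")
def small_scene():
    """A noise-free two-soma scene shared by read-only tests."""
    spec = SceneSpec(frame_px=256, n_somata=2, seed=42)
    channels, truth = generate_scene(noise_free(spec))
    return spec, channels, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Same geometry rendered at the default noise level (SNR ≈ 8)."""
    spec = SceneSpec(frame_px=256, n_somata=2, seed=42)
    channels, truth = generate_scene(spec)
    return spec, channels, truth
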