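import numpy as np
import pytest

from ddrquant import (
    ResponseCurve,
    generate_monolayer_images,
    generate_spheroid_stack,
    geometric_series,
)


@pytest.fixture(scope="session")
def monolayer():
    """Small noiseless monolayer field with ground truth (30 nuclei, 256 px)."""
    channels, truth = generate_monolayer_images(
        30, image_size=256, seed=7, noise_sd=0.0, pi_fraction=0.3
    )
    return channels, truth


@pytest.fixture(scope="session")
def spheroid_stack():
    """Two-spheroid z-stack with ground truth (noiseless)."""
    return generate_spheroid_stack(2, n_planes=9, seed=11, noise_sd=0.0, pi_area_fraction=0.25)


@pytest.fixture
def series8():
    return geometric_series(0.10, 21.54, 8)


@pytest.fixture
def flat_curve(series8):
    """Flat response curve at the control level with spread-out controls."""
    rng = np.random.default_rng(5)
    responses = [1000.0 + rng.normal(0, 50, 3) for _ in series8]
    controls = 1000.0 + rng.normal(0, 50, 6)
    return ResponseCurve(series8, responses, controls)
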