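import numpy as np
import pytest

from microderm.synthetic import SyntheticSpec, generate_sample


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-size image spec for fast per-test rendering."""
    return SyntheticSpec(
        image_height=128, image_width=128, lesion_radius=28,
        hair_count=0, frame_width=0, bubble_count=0,
    )


@pytest.fixture(scope="session")
def malignant_sample(small_spec):
    from dataclasses import replace

    spec = replace(
        small_spec, asymmetry_amp=0.4, n_colors=4, texture_contrast=25, rng_seed=11
    )
    return generate_sample(spec)


@pytest.fixture(scope="session")
def benign_sample(small_spec):
    from dataclasses import replace

    spec = replace(
        small_spec, asymmetry_amp=0.05, n_colors=2, texture_contrast=3, rng_seed=12
    )
    return generate_sample(spec)


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
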