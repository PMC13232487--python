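import numpy as np
import pytest

from adipoquant import GeneratorConfig, generate_field, segment_field


def noise_free(**overrides) -> GeneratorConfig:
    """A noise-free generator config (exact rendering, no randomness in gray)."""
    base = dict(
        seed=11,
        lumen_intensity=(210.0, 0.0),
        membrane_intensity=(60.0, 0.0),
        background_intensity=(180.0, 0.0),
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def clean_field():
    """One noise-free field with crowns on every cell at fraction 0.5."""
    config = noise_free(
        cls_fraction=1.0, stained_membrane_fraction_dist=(0.5, 0.5)
    )
    image, truth = generate_field(config)
    return config, image, truth


@pytest.fixture(scope="session")
def clean_segmentation(clean_field):
    _, image, _ = clean_field
    return segment_field(image)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
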