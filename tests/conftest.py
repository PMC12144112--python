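import numpy as np
import pytest

from qdosim import (
    MediumProperties,
    Phantom,
    PhantomSpec,
    build_media,
    generate_phantom,
    make_source,
)


@pytest.fixture(scope="session")
def uniform_phantom_16():
    spec = PhantomSpec(
        shape=(16, 16, 16), pattern="uniform", tissue_densities=[(0, 1.0)],
        spacing=(2.0, 2.0, 2.0), seed=0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def two_tissue_phantom_16():
    spec = PhantomSpec(
        shape=(16, 16, 16), pattern="slab", tissue_densities=[(0, 1.0), (1, 1.2)],
        spacing=(2.0, 2.0, 2.0), seed=1,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def absorber_media_16(two_tissue_phantom_16):
    """Pure-absorber media on the two-tissue slab phantom."""
    table = {0: (0.025, 0.0, 0.0), 1: (0.025, 0.0, 0.0)}
    return build_media(two_tissue_phantom_16, table)


@pytest.fixture(scope="session")
def beam_source():
    return make_source(
        {"modality": "external_beam", "direction": (1, 0, 0), "field_size_mm": 24.0}
    )


@pytest.fixture(scope="session")
def slab_dose_dataset():
    """Synthetic exponential depth-dose volumes for surrogate training.

    20 pairs of (attenuation feature map, analytic slab dose) at 16^3 —
    smooth, noiseless targets so short trainings measure optimization, not
    Monte Carlo noise.
    """
    rng = np.random.default_rng(42)
    pairs = []
    z = np.arange(16)[:, None, None] * 2.0
    for _ in range(20):
        mu = rng.uniform(0.03, 0.08)
        dose = 2.0 * np.exp(-mu * z) * np.ones((16, 16, 16))
        feat = np.full((16, 16, 16), mu / 0.05)
        pairs.append((feat, dose))
    return pairs
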