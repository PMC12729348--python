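import numpy as np
import pytest

from nerveseg.phantom import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def wrist_spec_small():
    """Desk-scale wrist phantom family: 64x64 px at 0.2 mm/px."""
    return PhantomSpec.default("wrist", image_height=64, image_width=64,
                               pixel_spacing=0.2)


@pytest.fixture(scope="session")
def forearm_spec_small():
    return PhantomSpec.default("forearm", image_height=64, image_width=64,
                               pixel_spacing=0.2)


@pytest.fixture(scope="session")
def wrist_samples_small(wrist_spec_small):
    return generate_dataset(wrist_spec_small, 12, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def star_polygon(rng, n_vertices=16, center=(32.0, 32.0), r_lo=3.0, r_hi=14.0):
    """Random star-shaped (hence simple) polygon for rasterization oracles."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_lo, r_hi, n_vertices)
    cx, cy = center
    return np.column_stack([cx + radii * np.cos(angles),
                            cy + radii * np.sin(angles)])
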