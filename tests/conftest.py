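import numpy as np
import pytest

from cordleak.imaging import RegionSet
from cordleak.synthetic import SectionSpec, generate_section


@pytest.fixture(scope="session")
def clean_section():
    """Noise-free 512 µm section: 50 vessels, 20% leaked, seed 1."""
    spec = SectionSpec(n_vessels=50, leak_fraction=0.2, seed=1,
                       noise_gain=0.0, read_noise_sd=0.0)
    return generate_section(spec)


@pytest.fixture(scope="session")
def neuro_section():
    """Noise-free section with somata and inclusions rendered."""
    spec = SectionSpec(n_vessels=10, leak_fraction=0.0, seed=7,
                       n_neurons_per_horn=6, n_inclusions=12,
                       noise_gain=0.0, read_noise_sd=0.0)
    return generate_section(spec)


def all_gray_regions(shape, pixel_size_um=1.0):
    """A RegionSet whose whole frame is gray matter (no edge, no white)."""
    labels = np.full(shape, 2, dtype=np.uint8)
    return RegionSet(labels, pixel_size_um=pixel_size_um)


def disk_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
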