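import numpy as np
import pytest

from pbaekit.library import DescriptorTable, PolymerID
from pbaekit.simulate import LibrarySimConfig, generate_library


@pytest.fixture
def small_table():
    """A 6-polymer, 4-descriptor table with known values."""
    rng = np.random.default_rng(42)
    ids = [PolymerID("A", i + 1) for i in range(6)]
    names = ["d1", "d2", "d3", "d4"]
    return DescriptorTable(ids, names, rng.normal(10, 3, size=(6, 4)))


@pytest.fixture
def default_library():
    """One default simulated library (36 polymers, 30 descriptors, 5 latents)."""
    return generate_library(LibrarySimConfig(noise_seed=7, loadings_seed=7))
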