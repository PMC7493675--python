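import numpy as np
import pytest

from leukozone.grid import Volume
from leukozone.phantom import PhantomSpec, make_label_volume
from leukozone.zoning import ZoneParams, zone_partition


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_labels(default_spec) -> Volume:
    return make_label_volume(default_spec)


@pytest.fixture(scope="session")
def default_zones(default_labels):
    return zone_partition(default_labels, ZoneParams())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_uniform_labels(shape, spacing, fill):
    """A label volume filled with one code (toy fixtures build on this)."""
    return Volume(np.full(shape, fill, dtype=np.int8), spacing)
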