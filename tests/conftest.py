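import numpy as np
import pytest

from phonorsa import stimulus_design as sd
from phonorsa import synthetic_fmri as sf
from phonorsa.searchlight import Searchlight, SearchlightSpec


@pytest.fixture(scope="session")
def hearing_spec():
    return sd.ParadigmSpec(group="hearing")


@pytest.fixture(scope="session")
def deaf_spec():
    return sd.ParadigmSpec(group="deaf")


@pytest.fixture(scope="session")
def words():
    return sd.build_word_set()


@pytest.fixture(scope="session")
def word_map(words):
    return {w.orthography: w for w in words}


@pytest.fixture(scope="session")
def conditions(hearing_spec):
    return sd.enumerate_conditions(hearing_spec)


@pytest.fixture(scope="session")
def small_geometry():
    return sf.VolumeGeometry(shape=(10, 10, 10))


@pytest.fixture(scope="session")
def small_searchlight(small_geometry):
    return Searchlight(small_geometry, SearchlightSpec(radius=2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
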