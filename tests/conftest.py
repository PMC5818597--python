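import numpy as np
import pytest
from hypothesis import settings

from iscpipe import synthetic

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_design():
    """Compact assay design used throughout: full dose ladder, light imaging."""
    return synthetic.AssayDesign(cells_imaged_per_condition=600, seed=7)


@pytest.fixture
def gc(small_design):
    return synthetic.gc_archetype("gc_test")


@pytest.fixture
def ngc(small_design):
    return synthetic.ngc_archetype("ngc_test")


@pytest.fixture
def inert():
    return synthetic.inert_archetype("inert_test")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
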