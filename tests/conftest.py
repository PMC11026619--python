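import numpy as np
import pytest

from mrifuse.catalog import init_catalog
from mrifuse.synthetic_data import (
    default_cross_sectional_spec,
    default_longitudinal_spec,
    generate_study,
    make_template,
)


@pytest.fixture(scope="session")
def template64():
    """Standard 64-cube template phantom and brain mask."""
    return make_template((64, 64, 64), seed=0)


@pytest.fixture(scope="session")
def template32():
    """Small template for fast end-to-end paths."""
    return make_template((32, 32, 32), seed=0)


@pytest.fixture()
def cat():
    handle = init_catalog(":memory:")
    yield handle
    handle.close()


@pytest.fixture(scope="session")
def longitudinal_study(tmp_path_factory):
    """Generated longitudinal study directory + ground truth (32-cube)."""
    out = tmp_path_factory.mktemp("synthA")
    spec = default_longitudinal_spec(seed=0)
    path, truth = generate_study(spec, out)
    return path, truth


@pytest.fixture(scope="session")
def cross_sectional_study(tmp_path_factory):
    out = tmp_path_factory.mktemp("synthB")
    spec = default_cross_sectional_spec(seed=1)
    path, truth = generate_study(spec, out)
    return path, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
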