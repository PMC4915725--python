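import numpy as np
import pytest

from minfibril.geometry import build_fibril, build_fixture


@pytest.fixture(scope="session")
def default_fibril():
    """The reference unmineralized fibril (built once per session)."""
    return build_fibril()


@pytest.fixture(scope="session")
def mini_fibril_25():
    """Mineralized mini fibril used by several observable tests."""
    return build_fixture("mini_fibril", diameter_nm=6.0, mineral_wt=25.0)


@pytest.fixture()
def single_molecule():
    return build_fixture("single_molecule")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
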