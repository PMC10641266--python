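import numpy as np
import pytest

from cysscan import VH_TEMPLATE, build_manifest
from cysscan.synthetic import null_parent


@pytest.fixture(scope="session")
def template():
    return VH_TEMPLATE


@pytest.fixture(scope="session")
def parent_null():
    """The canonical-null scan parent (C23A/C104A of the built-in template)."""
    return null_parent()


@pytest.fixture(scope="session")
def manifest():
    """The 17-library study manifest."""
    return build_manifest()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230922)
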