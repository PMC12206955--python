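import numpy as np
import pytest

from sanmap.phantom import PhantomGeometry, build_phantom, default_protocols
from sanmap.tissues import tissue_table


@pytest.fixture(scope="session")
def labels_7t():
    """Default 64x64 phantom label map (15 mm FOV, 234 um pixels)."""
    return build_phantom(PhantomGeometry())


@pytest.fixture(scope="session")
def table_7t():
    return tissue_table("7T")


@pytest.fixture(scope="session")
def table_3t():
    return tissue_table("3T")


@pytest.fixture(scope="session")
def protocols_7t():
    return default_protocols("7T")


@pytest.fixture(scope="session")
def protocols_3t():
    return default_protocols("3T")
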