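import numpy as np
import pytest

from defolicarbon.radiative_transfer import (
    LeafParams,
    build_lut,
    prospect_leaf,
    sentinel2_like_srf,
)


@pytest.fixture(scope="session")
def default_leaf():
    return prospect_leaf(LeafParams())


@pytest.fixture(scope="session")
def srf():
    return sentinel2_like_srf()


@pytest.fixture(scope="session")
def lut_005(srf):
    """Retrieval lookup table at the default 0.05 LAI step."""
    return build_lut(np.arange(0.0, 8.0001, 0.05), srf=srf)
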