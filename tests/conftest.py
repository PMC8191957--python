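import math

import pytest

from microswim.fluid import WATER_25C
from microswim.spheroid import SpheroidBody


@pytest.fixture(scope="session")
def water():
    return WATER_25C


@pytest.fixture(
    params=[(2.6, 0.43), (3.1, 0.9), (10.0, 6.0), (70.0, 27.5), (242.0, 48.0), (5.0, 5.0)],
    ids=lambda p: f"B{p[0]}xW{p[1]}",
)
def body(request):
    """Prolate bodies spanning slender to spherical."""
    B, W = request.param
    return SpheroidBody(B=B, W=W)
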