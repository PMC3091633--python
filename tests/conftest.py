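import random

import pytest
from hypothesis import HealthCheck, settings

from ispcr import Primer

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def fwd_primer() -> Primer:
    # Folmer-style 25/26-nt COI primers: realistic lengths for the engine
    return Primer("LCO1490", "GGTCAACAAATCATAAAGATATTGG")


@pytest.fixture
def rev_primer() -> Primer:
    return Primer("HCO2198", "TAAACTTCAGGGTGACCAAAAAATCA")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260924)
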