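import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from meadownet.tables import CountTable

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_table():
    """Deterministic 6-sample x 5-OTU count table."""
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.integers(0, 40, size=(6, 5)) + 1,
        index=[f"s{i}" for i in range(6)],
        columns=[f"OTU{j}" for j in range(5)],
    )
    return CountTable(data, domain="bacteria")


@pytest.fixture
def small_frame():
    return pd.DataFrame({
        "disturbance": ["C", "C", "P", "P", "PL", "PL"],
        "surface": ["G", "G", "G", "N", "G", "N"],
        "block": ["C1", "C1", "P1", "P1", "PL1", "PL1"],
        "site": ["s1", "s2", "s1", "s1", "s1", "s1"],
    }, index=[f"s{i}" for i in range(6)])
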