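import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import beequant as bq

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_refdb() -> bq.ReferenceDB:
    """Six well-separated 120 nt references."""
    return bq.generate_reference_db(6, length=120, min_divergence=8, seed=3)


@pytest.fixture(scope="session")
def calibration_tables():
    """Noiseless 15-sample calibration pair over the 15 genera + calibrator."""
    return bq.simulate_calibration_tables(seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def mutate_at(sequence: str, positions, rng=None) -> str:
    """Substitute a different base at each given position."""
    rng = rng or np.random.default_rng(0)
    out = list(sequence)
    for pos in positions:
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)
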