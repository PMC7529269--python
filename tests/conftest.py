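import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scenario():
    """An ultra-small ischemic slab for fast end-to-end checks."""
    from cardiorom import get_scenario

    return get_scenario(
        "test1-mini",
        nx=12, ny=12, T_ms=30.0, n_snapshots=20,
        train_spec={"kind": "lattice", "starts": [4.0, 4.0],
                    "steps": [2.0, 2.0], "counts": [2, 2]},
        test_spec={"kind": "lattice", "starts": [5.0, 5.0],
                   "steps": [1.0, 1.0], "counts": [1, 1]},
    )
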