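import numpy as np
import pandas as pd
import pytest

from istclean import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_cells():
    """The hand-checkable line of cells at 0, 30 and 100 μm."""
    return pd.DataFrame(
        {"cell_id": ["a", "b", "c"], "x": [0.0, 30.0, 100.0], "y": [0.0, 0.0, 0.0]}
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-cell synthetic dataset reused across read-only tests."""
    cfg = SimConfig(n_cells=300, extent=(1000.0, 1000.0), seed=7)
    return simulate_dataset(cfg)
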