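import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """A small varying-coefficient dataset with known truth."""
    from netprofiler.simulate import simulate_varying_network

    panel, modulators, truth = simulate_varying_network(n=80, p=5, q=2, seed=7)
    return panel, modulators, truth
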