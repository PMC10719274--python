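import numpy as np
import pandas as pd
import pytest

from impnet.network import NodeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20231213)


@pytest.fixture
def unit_nodes():
    def make(n):
        return NodeTable(
            pd.DataFrame(
                {"node_id": range(n), "label": [f"r{i}" for i in range(n)], "volume_mm3": 1.0}
            )
        )

    return make


@pytest.fixture
def triangle():
    W = np.ones((3, 3)) - np.eye(3)
    return W


@pytest.fixture
def path3():
    return np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
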