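import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def four_point_distance():
    """Forced geometry: pairs {1,2} and {3,4} at 0.1, cross at >= 1.0."""
    d = np.array(
        [
            [0.0, 0.1, 1.0, 1.2],
            [0.1, 0.0, 1.1, 1.3],
            [1.0, 1.1, 0.0, 0.1],
            [1.2, 1.3, 0.1, 0.0],
        ]
    )
    return d


def random_graph(rng, n=12, p=0.3):
    seed = int(rng.integers(2**31))
    return nx.gnp_random_graph(n, p, seed=seed)


@pytest.fixture
def random_graph_pairs(rng):
    """Twenty pairs of small random graphs on a shared node set."""
    return [(random_graph(rng), random_graph(rng)) for _ in range(20)]


@pytest.fixture
def contact_file(tmp_path):
    """Tiny tij contact sequence with an out-of-order line."""
    path = tmp_path / "contacts.tsv"
    path.write_text("0 a b\n5 b c\n2 a c\n")
    return path
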