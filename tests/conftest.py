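import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from cdce import datasets


@pytest.fixture(scope="session")
def karate() -> nx.Graph:
    """Zachary karate club, nodes labeled 1..34."""
    return datasets.karate_club()


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.complete_graph(3)


@pytest.fixture
def external_data_dir() -> Path:
    """Directory for the non-redistributable benchmark graphs."""
    return Path(__file__).resolve().parent.parent / "data" / "external"
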