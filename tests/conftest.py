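import numpy as np
import pytest

from syncytia import core, synthetic


@pytest.fixture
def two_cell_graph():
    a = core.CellGeometry("a", area=400.0, perimeter=80.0)
    b = core.CellGeometry("b", area=300.0, perimeter=70.0)
    return core.CellGraph([a, b], [("a", "b", 20.0)])


@pytest.fixture
def hex7_graph():
    """Regular 7-cell hexagonal patch: center c0 with six identical neighbors."""
    graph, _ = synthetic.generate_cell_graph(7, jitter=0.0, seed=0)
    return graph


@pytest.fixture
def monolayer_graph():
    graph, _ = synthetic.generate_cell_graph(37, jitter=0.1, seed=1)
    return graph


def bleached_state(graph, cell_id, depth=0.5):
    c0 = np.ones(len(graph))
    c0[graph.index_of(cell_id)] = depth
    return core.ConcentrationState(time=0.0, concentrations=c0)
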