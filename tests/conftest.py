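import numpy as np
import pandas as pd
import pytest

from haltcircuit import LIFParams, load_connectome


@pytest.fixture
def chain_tables():
    """A -> B -> C chain: A and C cholinergic, B GABAergic."""
    neurons = pd.DataFrame(
        {
            "id": [0, 1, 2],
            "label": ["A", "B", "C"],
            "hemisphere": ["left", "right", "left"],
            "nt": ["ACh", "GABA", "ACh"],
            "class_tag": ["walk", "halt", "DN"],
        }
    )
    edges = pd.DataFrame({"pre": [0, 1], "post": [1, 2], "count": [10, 7]})
    return neurons, edges


@pytest.fixture
def chain_conn(chain_tables):
    return load_connectome(*chain_tables)


@pytest.fixture
def params():
    return LIFParams()


def make_conn(neuron_rows, edge_rows):
    """Rows: (id, nt[, class_tag]) and (pre, post, count)."""
    neurons = pd.DataFrame(
        {
            "id": [r[0] for r in neuron_rows],
            "label": [f"n{r[0]}" for r in neuron_rows],
            "hemisphere": "left",
            "nt": [r[1] for r in neuron_rows],
            "class_tag": [r[2] if len(r) > 2 else "other" for r in neuron_rows],
        }
    )
    edges = pd.DataFrame(
        {
            "pre": [r[0] for r in edge_rows],
            "post": [r[1] for r in edge_rows],
            "count": [r[2] for r in edge_rows],
        }
    )
    if not edge_rows:
        edges = pd.DataFrame(columns=["pre", "post", "count"])
    return load_connectome(neurons, edges)
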