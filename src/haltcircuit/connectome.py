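"""Signed connectome construction from neuron/edge tables.

A connectome dump is two columnar tables: a neuron table
(``id,label,hemisphere,nt,class_tag``) and an edge table (``pre,post,count``)
giving synapse counts between ordered neuron pairs. Connection signs follow
the presynaptic neurotransmitter prediction: GABAergic and glutamatergic
neurons are inhibitory, everything else (including unknown) excitatory, so
every neuron is Dale-consistent by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "NT_VOCAB",
    "INHIBITORY_NTS",
    "HEMISPHERE_VOCAB",
    "NeuronRecord",
    "SynapticEdge",
    "SignedConnectome",
    "WeightMatrix",
    "WiringDiagram",
    "ConnectomeLoadError",
    "load_connectome",
    "save_connectome",
    "build_weight_matrix",
    "silence_neurons",
    "extract_wiring_diagram",
]

#: Closed neurotransmitter vocabulary for the neuron table.
NT_VOCAB = frozenset({"ACh", "GABA", "Glu", "DA", "5-HT", "OA", "unknown"})

#: Neurotransmitters treated as inhibitory; all others are excitatory.
INHIBITORY_NTS = frozenset({"GABA", "Glu"})

HEMISPHERE_VOCAB = frozenset({"left", "right", "unknown"})


class ConnectomeLoadError(ValueError):
    """Raised when a connectome table violates its contract."""


@dataclass(frozen=True)
class NeuronRecord:
    """One neuron: stable id, free-text label, and annotations."""

    id: int
    label: str = ""
    hemisphere: str = "unknown"
    nt: str = "unknown"
    class_tag: str = ""

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError(f"neuron id must be non-negative, got {self.id}")
        if self.nt not in NT_VOCAB:
            raise ValueError(f"unknown neurotransmitter label {self.nt!r}")
        if self.hemisphere not in HEMISPHERE_VOCAB:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")

    @property
    def sign(self) -> int:
        """+1 for excitatory output, -1 for inhibitory (GABA/Glu)."""
        return -1 if self.nt in INHIBITORY_NTS else +1


@dataclass(frozen=True)
class SynapticEdge:
    """Directed connection with a positive synapse count."""

    pre: int
    post: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(
                f"synapse count must be >= 1, got {self.count} for "
                f"{self.pre}->{self.post}"
            )


@dataclass
class SignedConnectome:
    """Neurons plus signed, synapse-count-weighted directed edges.

    Edge signs are a function of the presynaptic neuron's neurotransmitter,
    so all outgoing edges of one neuron share a sign (Dale's principle).
    """

    neurons: dict[int, NeuronRecord]
    edges: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (pre, post), count in self.edges.items():
            if pre not in self.neurons or post not in self.neurons:
                raise ConnectomeLoadError(
                    f"edge {pre}->{post} references unknown neuron id"
                )
            if count < 1:
                raise ConnectomeLoadError(
                    f"edge {pre}->{post} has non-positive count {count}"
                )

    @property
    def ids(self) -> list[int]:
        return sorted(self.neurons)

    def sign(self, pre: int, post: int | None = None) -> int:
        """Sign of a neuron's output (edge sign if ``post`` given)."""
        if post is not None and (pre, post) not in self.edges:
            raise KeyError(f"no edge {pre}->{post}")
        return self.neurons[pre].sign

    def count(self, pre: int, post: int) -> int:
        return self.edges.get((pre, post), 0)

    def neuron_frame(self) -> pd.DataFrame:
        recs = [self.neurons[i] for i in self.ids]
        return pd.DataFrame(
            {
                "id": [r.id for r in recs],
                "label": [r.label for r in recs],
                "hemisphere": [r.hemisphere for r in recs],
                "nt": [r.nt for r in recs],
                "class_tag": [r.class_tag for r in recs],
            }
        )

    def edge_frame(self) -> pd.DataFrame:
        items = sorted(self.edges.items())
        return pd.DataFrame(
            {
                "pre": [k[0] for k, _ in items],
                "post": [k[1] for k, _ in items],
                "count": [c for _, c in items],
            }
        )

    def ids_by_tag(self, class_tag: str) -> list[int]:
        return [i for i in self.ids if self.neurons[i].class_tag == class_tag]

    def ids_by_label(self, label: str) -> list[int]:
        return [i for i in self.ids if self.neurons[i].label == label]


@dataclass
class WeightMatrix:
    """Sparse signed weights in membrane-potential units (mV per spike).

    ``weight(pre, post) = sign(pre) * count(pre, post) * w_unit``.
    """

    matrix: sp.csr_matrix
    ids: list[int]
    w_unit: float
    index: dict[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {nid: k for k, nid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def weight(self, pre: int, post: int) -> float:
        return float(self.matrix[self.index[pre], self.index[post]])


@dataclass
class WiringDiagram:
    """Rate-thresholded, synapse-count-thresholded signed graph."""

    nodes: pd.DataFrame  # id, label, rate, norm_rate
    edges: pd.DataFrame  # pre, post, count, sign
    min_synapses: int
    rate_threshold: float

    def to_csv(self, nodes_path: str | Path, edges_path: str | Path) -> None:
        self.nodes.to_csv(nodes_path, index=False)
        self.edges.to_csv(edges_path, index=False)


# ---------------------------------------------------------------------------
# loading / saving

_NEURON_COLS = ["id", "label", "hemisphere", "nt", "class_tag"]
_EDGE_COLS = ["pre", "post", "count"]


def load_connectome(
    neuron_table: str | Path | pd.DataFrame,
    edge_table: str | Path | pd.DataFrame,
) -> SignedConnectome:
    """Load a signed connectome from neuron and edge CSV tables.

    Duplicate (pre, post) rows are summed into a single edge (dumps may split
    an edge across neuropils). Unknown neurotransmitter labels default to
    excitatory with a warning. Edges referencing an absent neuron id or
    carrying a non-positive count raise :class:`ConnectomeLoadError`.
    """
    ndf = _as_frame(neuron_table, _NEURON_COLS, "neuron table")
    edf = _as_frame(edge_table, _EDGE_COLS, "edge table")

    neurons: dict[int, NeuronRecord] = {}
    n_unknown_nt = 0
    for row in ndf.itertuples(index=False):
        nid = int(row.id)
        if nid in neurons:
            raise ConnectomeLoadError(f"duplicate neuron id {nid}")
        nt = str(row.nt) if pd.notna(row.nt) else "unknown"
        if nt not in NT_VOCAB:
            n_unknown_nt += 1
            nt = "unknown"
        hemi = str(row.hemisphere) if pd.notna(row.hemisphere) else "unknown"
        if hemi not in HEMISPHERE_VOCAB:
            hemi = "unknown"
        neurons[nid] = NeuronRecord(
            id=nid,
            label="" if pd.isna(row.label) else str(row.label),
            hemisphere=hemi,
            nt=nt,
            class_tag="" if pd.isna(row.class_tag) else str(row.class_tag),
        )
    if n_unknown_nt:
        warnings.warn(
            f"{n_unknown_nt} neuron(s) with out-of-vocabulary neurotransmitter "
            "labels treated as excitatory 'unknown'",
            stacklevel=2,
        )

    edges: dict[tuple[int, int], int] = {}
    for rownum, row in enumerate(edf.itertuples(index=False)):
        pre, post, count = int(row.pre), int(row.post), int(row.count)
        if count < 1:
            raise ConnectomeLoadError(
                f"edge table row {rownum}: non-positive count {count}"
            )
        for nid in (pre, post):
            if nid not in neurons:
                raise ConnectomeLoadError(
                    f"edge table row {rownum}: unknown neuron id {nid}"
                )
        key = (pre, post)
        edges[key] = edges.get(key, 0) + count

    return SignedConnectome(neurons=neurons, edges=edges)


def save_connectome(
    conn: SignedConnectome,
    neuron_path: str | Path,
    edge_path: str | Path,
) -> None:
    """Write the two CSV tables; ``load_connectome`` round-trips them."""
    conn.neuron_frame().to_csv(neuron_path, index=False)
    conn.edge_frame().to_csv(edge_path, index=False)


def _as_frame(
    table: str | Path | pd.DataFrame, cols: list[str], what: str
) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ConnectomeLoadError(f"{what} missing columns {missing}")
    return table


# ---------------------------------------------------------------------------
# derived structures


def build_weight_matrix(conn: SignedConnectome, w_unit: float) -> WeightMatrix:
    """Signed synaptic weight matrix, ``w_unit`` mV per synapse per spike."""
    if w_unit <= 0:
        raise ValueError(f"w_unit must be positive, got {w_unit}")
    ids = conn.ids
    index = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    if conn.edges:
        rows, cols, vals = [], [], []
        for (pre, post), count in conn.edges.items():
            rows.append(index[pre])
            cols.append(index[post])
            vals.append(conn.neurons[pre].sign * count * w_unit)
        mat = sp.csr_matrix(
            (np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n)
        )
    else:
        mat = sp.csr_matrix((n, n), dtype=float)
    return WeightMatrix(matrix=mat, ids=ids, w_unit=w_unit)


def silence_neurons(
    conn: SignedConnectome, ids: Iterable[int]
) -> SignedConnectome:
    """Sever all outgoing synapses of ``ids``; incoming edges are retained.

    This mirrors optogenetic output silencing: the neuron may still integrate
    and spike, but its spikes reach nobody.
    """
    ids = set(ids)
    unknown = ids - set(conn.neurons)
    if unknown:
        raise KeyError(f"cannot silence unknown neuron ids {sorted(unknown)}")
    edges = {
        (pre, post): c
        for (pre, post), c in conn.edges.items()
        if pre not in ids
    }
    return SignedConnectome(neurons=dict(conn.neurons), edges=edges)


def extract_wiring_diagram(
    conn: SignedConnectome,
    node_ids: Iterable[int],
    rates: Mapping[int, float],
    min_synapses: int = 5,
    rate_threshold: float = 0.0,
) -> WiringDiagram:
    """Threshold a connectome into a displayable wiring diagram.

    Nodes with trial-averaged rate above ``rate_threshold`` are retained and
    their rates normalized to the maximum retained rate; edges among retained
    nodes with at least ``min_synapses`` synapses survive.
    """
    node_ids = sorted(set(node_ids))
    if not node_ids:
        raise ValueError("node_ids must be non-empty")
    missing = [i for i in node_ids if i not in rates]
    if missing:
        raise KeyError(f"rates missing for node ids {missing}")

    kept = [i for i in node_ids if rates[i] > rate_threshold]
    max_rate = max((rates[i] for i in kept), default=0.0)
    nodes = pd.DataFrame(
        {
            "id": kept,
            "label": [conn.neurons[i].label for i in kept],
            "rate": [rates[i] for i in kept],
            "norm_rate": [
                rates[i] / max_rate if max_rate > 0 else 0.0 for i in kept
            ],
        }
    )

    kept_set = set(kept)
    rows = [
        (pre, post, c, conn.neurons[pre].sign)
        for (pre, post), c in sorted(conn.edges.items())
        if pre in kept_set and post in kept_set and c >= min_synapses
    ]
    edges = pd.DataFrame(rows, columns=["pre", "post", "count", "sign"])
    return WiringDiagram(
        nodes=nodes,
        edges=edges,
        min_synapses=min_synapses,
        rate_threshold=rate_threshold,
    )
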