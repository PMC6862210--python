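"""Sequence recurrence network (SRN) construction.

The SRN of a protein sequence is an undirected graph whose nodes are the
residues in order.  Two kinds of edges exist:

* chain edges between consecutive residues (topological distance 1), and
* recurrence edges connecting each residue to the *nearest earlier*
  occurrence of the same residue type.

An optional dummy (bias) node, labelled "·", is attached as a pendant to the
first residue; it is the centre of the star-graph view of the same network.
Adjacency is binary and symmetric with a zero diagonal, so a recurrence edge
coinciding with a chain edge (e.g. in "AA") is stored once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .seqio import ProteinSequence

#: label used for the dummy / bias node
DUMMY_LABEL = "·"


@dataclass
class RecurrenceNetwork:
    """SRN of one sequence.

    Node ids are 1-based residue positions; the dummy node (if present) has
    id 0.  ``adjacency`` is indexed in node order (dummy first when present).
    """

    sequence_id: str
    L: int
    has_dummy: bool
    node_ids: list[int]
    node_labels: list[str]
    adjacency: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        """Number of nodes (= L + 1 with the dummy node)."""
        return len(self.node_ids)

    def index_of(self, node: int) -> int:
        offset = 0 if self.has_dummy else 1
        idx = node - offset
        if not (0 <= idx < self.n) or node < (0 if self.has_dummy else 1):
            raise KeyError(f"node {node} not in network (ids {self.node_ids[0]}..{self.node_ids[-1]})")
        return idx

    def edges(self) -> set[tuple[int, int]]:
        """Edge set as sorted (node_id, node_id) pairs."""
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return {(self.node_ids[i], self.node_ids[j]) for i, j in zip(ii, jj)}

    def degree(self, node: int) -> int:
        return int(self.adjacency[self.index_of(node)].sum())

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        mapping = dict(enumerate(self.node_ids))
        g = nx.relabel_nodes(g, mapping)
        nx.set_node_attributes(
            g, dict(zip(self.node_ids, self.node_labels)), "residue"
        )
        return g

    def write_edgelist(self, path: str | Path) -> None:
        """Export edges as a two-column TSV (node_a, node_b) for inspection."""
        with Path(path).open("w") as fh:
            fh.write("node_a\tnode_b\n")
            for a, b in sorted(self.edges()):
                fh.write(f"{a}\t{b}\n")


def build_srn(seq: ProteinSequence, include_dummy: bool = True) -> RecurrenceNetwork:
    """Build the sequence recurrence network of ``seq``.

    Edges: the dummy pendant (0, 1) when ``include_dummy``; chain edges
    (i, i+1) for consecutive residues; and for every position j with an
    earlier occurrence of the same residue type, a recurrence edge from j to
    the nearest such earlier position.  Duplicate edges collapse (binary
    adjacency).
    """
    L = len(seq.residues)
    if L < 1:
        raise ValueError("cannot build an SRN for an empty sequence")
    offset = 0 if include_dummy else 1
    n = L + 1 if include_dummy else L
    adj = np.zeros((n, n), dtype=np.int8)

    def connect(a: int, b: int) -> None:  # a, b are node ids
        adj[a - offset, b - offset] = 1
        adj[b - offset, a - offset] = 1

    if include_dummy:
        connect(0, 1)
    for i in range(1, L):
        connect(i, i + 1)
    last_seen: dict[str, int] = {}
    for j, res in enumerate(seq.residues, start=1):
        prev = last_seen.get(res)
        if prev is not None:
            connect(prev, j)
        last_seen[res] = j

    node_ids = list(range(0 if include_dummy else 1, L + 1))
    node_labels = ([DUMMY_LABEL] if include_dummy else []) + list(seq.residues)
    return RecurrenceNetwork(
        sequence_id=seq.id,
        L=L,
        has_dummy=include_dummy,
        node_ids=node_ids,
        node_labels=node_labels,
        adjacency=adj,
    )


def topological_distance(net: RecurrenceNetwork, a: int, b: int) -> int:
    """Minimal topological distance (shortest-path edge count) between nodes.

    Valid SRNs are connected through their chain edges; a disconnected pair
    therefore indicates a corrupted network and raises ``ValueError``.
    """
    ia, ib = net.index_of(a), net.index_of(b)
    if ia == ib:
        return 0
    g = nx.from_numpy_array(net.adjacency)
    try:
        return int(nx.shortest_path_length(g, ia, ib))
    except nx.NetworkXNoPath:
        raise ValueError(f"nodes {a} and {b} are disconnected: corrupted SRN") from None
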