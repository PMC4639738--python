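"""Weighted social networks from scan-sampling records.

Vertices are individuals; edge weights are the percent of scans (0-100) in
which the dyad showed the behaviour.  Proximity networks are undirected
(arm's reach is symmetric); grooming networks are directed, with the
groomer's out-edge carrying the percent of scans it spent grooming that
recipient.  Raw integer scan counts are kept alongside the percent weights
so downstream ratios stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data import Roster, ScanRecordSet

__all__ = [
    "WeightedNetwork",
    "build_proximity_network",
    "build_grooming_network",
    "export_network",
    "read_graphml_network",
]

PROXIMITY = "proximity"
GROOMING_GIVEN = "grooming_given"


@dataclass(frozen=True)
class WeightedNetwork:
    """Vertex set plus an integer scan-count matrix; weights are percent of scans."""

    ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)  # (N, N) int, zero diagonal
    directed: bool
    n_scans: int
    behaviour: str  # proximity | grooming_given
    group_id: str
    period_id: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        n = len(self.ids)
        if counts.shape != (n, n):
            raise ValueError("counts matrix shape does not match vertex count")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if np.any(np.diag(counts) != 0):
            raise ValueError("self-loops are not allowed")
        if counts.min() < 0 or counts.max() > self.n_scans:
            raise ValueError("counts must lie in [0, n_scans]")
        if not self.directed and not np.array_equal(counts, counts.T):
            raise ValueError("undirected network requires a symmetric count matrix")

    @property
    def n_vertices(self) -> int:
        return len(self.ids)

    @property
    def weights(self) -> np.ndarray:
        """Edge weights as percent of scans (0-100)."""
        return 100.0 * self.counts / self.n_scans

    def index(self, vertex: str) -> int:
        try:
            return self.ids.index(vertex)
        except ValueError:
            raise KeyError(f"vertex {vertex!r} not in network") from None


def _member_ids(records: ScanRecordSet, roster: Roster) -> tuple[str, ...]:
    return tuple(sorted(i.id for i in roster.members(records.group_id)))


def build_proximity_network(records: ScanRecordSet, roster: Roster) -> WeightedNetwork:
    """Undirected network: w_ij = 100 x (#scans containing pair {i,j}) / n_scans."""
    if records.n_scans == 0:
        raise ValueError("cannot build a network from zero scans")
    ids = _member_ids(records, roster)
    pos = {v: k for k, v in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for scan in records.scans:
        for a, b in scan.proximity_pairs:
            i, j = pos[a], pos[b]
            counts[i, j] += 1
            counts[j, i] += 1
    return WeightedNetwork(
        ids=ids,
        counts=counts,
        directed=False,
        n_scans=records.n_scans,
        behaviour=PROXIMITY,
        group_id=records.group_id,
        period_id=records.period_id,
    )


def build_grooming_network(records: ScanRecordSet, roster: Roster) -> WeightedNetwork:
    """Directed network: w_ij = 100 x (#scans in which i grooms j) / n_scans."""
    if records.n_scans == 0:
        raise ValueError("cannot build a network from zero scans")
    ids = _member_ids(records, roster)
    pos = {v: k for k, v in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for scan in records.scans:
        for a, b in scan.grooming_events:
            counts[pos[a], pos[b]] += 1
    return WeightedNetwork(
        ids=ids,
        counts=counts,
        directed=True,
        n_scans=records.n_scans,
        behaviour=GROOMING_GIVEN,
        group_id=records.group_id,
        period_id=records.period_id,
    )


def to_networkx(network: WeightedNetwork) -> "nx.Graph | nx.DiGraph":
    """Convert to a networkx graph with percent weights; zero edges omitted."""
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if network.directed else nx.Graph()
    g.graph.update(
        n_scans=network.n_scans,
        behaviour=network.behaviour,
        group_id=network.group_id,
        period_id=network.period_id,
    )
    g.add_nodes_from(network.ids)
    w = network.weights
    c = network.counts
    for i, u in enumerate(network.ids):
        cols = network.ids if network.directed else network.ids[i + 1 :]
        offset = 0 if network.directed else i + 1
        for j, v in enumerate(cols, start=offset):
            if c[i, j]:
                g.add_edge(u, v, weight=float(w[i, j]), count=int(c[i, j]))
    return g


def export_network(network: WeightedNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML (lossless) or an edge-list CSV.

    The edge list has columns ``source,target,weight,directed`` and omits
    zero-weight edges; GraphML keeps isolated vertices and the graph-level
    metadata needed for a lossless round trip.
    """
    if format == "graphml":
        nx.write_graphml(to_networkx(network), path)
    elif format == "edgelist":
        w = network.weights
        rows = []
        for i, u in enumerate(network.ids):
            for j, v in enumerate(network.ids):
                if (network.directed or j > i) and network.counts[i, j]:
                    rows.append(
                        {"source": u, "target": v, "weight": float(w[i, j]),
                         "directed": network.directed}
                    )
        pd.DataFrame(rows, columns=["source", "target", "weight", "directed"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graphml_network(path: str | Path) -> WeightedNetwork:
    """Read back a GraphML file written by :func:`export_network`."""
    g = nx.read_graphml(path)
    directed = g.is_directed()
    ids = tuple(sorted(g.nodes))
    pos = {v: k for k, v in enumerate(ids)}
    n_scans = int(g.graph["n_scans"])
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for u, v, data in g.edges(data=True):
        cnt = int(data.get("count", round(data["weight"] * n_scans / 100)))
        counts[pos[u], pos[v]] = cnt
        if not directed:
            counts[pos[v], pos[u]] = cnt
    return WeightedNetwork(
        ids=ids,
        counts=counts,
        directed=directed,
        n_scans=n_scans,
        behaviour=str(g.graph["behaviour"]),
        group_id=str(g.graph["group_id"]),
        period_id=str(g.graph["period_id"]),
    )
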