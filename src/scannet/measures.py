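"""Individual weighted-network measures: strength centrality and disparity.

Two measures per individual and behaviour:

* **vertex strength centrality** ``s_i / (N - 1)`` where the strength
  ``s_i`` sums the incident (undirected) or outgoing (directed) percent
  weights — the mean percent of scans spent with a potential partner,
  standardised for group size;
* **edge weight disparity** ``Y2(i) = sum_j (w_ij / s_i)^2`` — how unevenly
  the weight is spread over partners (1/(N-1) when perfectly even, 1 when a
  single partner takes everything) — and its **deviation**
  ``dY2 = Y2 - 1/(N-1)``, comparable across groups of different size.

Disparity is undefined for an individual with zero strength (an animal that
never groomed has no grooming distribution to be uneven about); such rows
carry ``defined = False`` and are excluded from disparity analyses while
keeping their zero strength centrality.

Ratios are computed from the exact integer scan counts, so the analytic
identities (equal distribution => dY2 == 0) hold exactly in floating point.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .data import Roster
from .networks import WeightedNetwork

__all__ = [
    "vertex_strength",
    "vertex_strength_centrality",
    "edge_weight_disparity",
    "deviation_from_disparity",
    "equal_disparity",
    "node_measures",
    "metrics_table",
]

MEASURE_COLUMNS = [
    "id", "group_id", "period", "behaviour", "sex", "age_class",
    "deprivation_class", "group_size", "strength", "strength_centrality",
    "disparity", "disparity_deviation", "defined",
]


def _out_counts(network: WeightedNetwork, vertex: str) -> np.ndarray:
    return network.counts[network.index(vertex)]


def vertex_strength(network: WeightedNetwork, vertex: str, direction: str = "out") -> float:
    """Sum of incident edge weights in percent units.

    For directed networks ``direction`` picks out-edges (behaviour given,
    the default) or in-edges (received).
    """
    i = network.index(vertex)
    if direction == "out":
        c = network.counts[i].sum()
    elif direction == "in":
        c = network.counts[:, i].sum()
    else:
        raise ValueError("direction must be 'out' or 'in'")
    return 100.0 * float(c) / network.n_scans


def vertex_strength_centrality(network: WeightedNetwork, vertex: str) -> float:
    """Strength divided by (N - 1); 0 for an isolated vertex, <= 100 always."""
    n = network.n_vertices
    if n < 2:
        raise ValueError("strength centrality needs N >= 2")
    return vertex_strength(network, vertex) / (n - 1)


def equal_disparity(n_vertices: int) -> float:
    """Disparity of a perfectly even distribution: 1 / (N - 1)."""
    if n_vertices < 2:
        raise ValueError("needs N >= 2")
    return 1.0 / (n_vertices - 1)


def edge_weight_disparity(network: WeightedNetwork, vertex: str) -> float | None:
    """Y2 = sum_j (w_ij / s_i)^2 over out-edges; None when s_i = 0 (undefined)."""
    if network.n_vertices < 2:
        raise ValueError("disparity needs N >= 2")
    c = _out_counts(network, vertex).astype(np.int64)
    s = int(c.sum())
    if s == 0:
        return None
    return float(np.sum(c * c)) / float(s * s)


def deviation_from_disparity(network: WeightedNetwork, vertex: str) -> float | None:
    """dY2 = Y2 - 1/(N-1); None when disparity is undefined."""
    y2 = edge_weight_disparity(network, vertex)
    if y2 is None:
        return None
    return y2 - equal_disparity(network.n_vertices)


def node_measures(network: WeightedNetwork) -> pd.DataFrame:
    """Per-vertex measures for one network (no roster covariates)."""
    rows = []
    for v in network.ids:
        y2 = edge_weight_disparity(network, v)
        rows.append(
            {
                "id": v,
                "strength": vertex_strength(network, v),
                "strength_centrality": vertex_strength_centrality(network, v),
                "disparity": y2,
                "disparity_deviation": None
                if y2 is None
                else y2 - equal_disparity(network.n_vertices),
                "defined": y2 is not None,
            }
        )
    return pd.DataFrame(rows)


def metrics_table(networks: Iterable[WeightedNetwork], roster: Roster) -> pd.DataFrame:
    """Long analysis table: one row per individual x behaviour x period.

    Joins the per-vertex measures with the roster covariates and the group
    size N; raises if a network vertex is missing from the roster.
    """
    frames = []
    for net in networks:
        missing = [v for v in net.ids if v not in roster]
        if missing:
            raise KeyError(f"network vertices {missing} not in roster")
        df = node_measures(net)
        df["group_id"] = net.group_id
        df["period"] = net.period_id
        df["behaviour"] = net.behaviour
        df["group_size"] = net.n_vertices
        df["sex"] = [roster[v].sex for v in df["id"]]
        df["age_class"] = [roster[v].age_class for v in df["id"]]
        df["deprivation_class"] = [roster[v].deprivation_class for v in df["id"]]
        frames.append(df[MEASURE_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=MEASURE_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    dup = out.duplicated(subset=["id", "behaviour", "period"])
    if dup.any():
        raise ValueError("duplicate (individual, behaviour, period) rows")
    return out
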