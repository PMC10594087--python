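"""Node centrality and global strength.

Definitions follow the weighted-network conventions of this literature:
strength is the sum of absolute incident weights (the signed sum is
exposed as ``expected_influence``), edge lengths for path-based indices
are ``1 / |weight|``, closeness is the inverse of the summed shortest
path distances (zero for nodes disconnected from any other), and
betweenness counts shortest paths with fractional credit under ties.
"""
from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .datatypes import Network

logger = logging.getLogger(__name__)


def strength(net: Network) -> pd.Series:
    """Per-node sum of absolute incident edge weights."""
    return pd.Series(
        np.abs(net.weights).sum(axis=1), index=net.item_labels, name="strength"
    )


def expected_influence(net: Network) -> pd.Series:
    """Per-node signed sum of incident edge weights."""
    return pd.Series(
        net.weights.sum(axis=1), index=net.item_labels, name="expected_influence"
    )


def global_strength(net: Network) -> float:
    """Weighted absolute sum over undirected edges (each counted once)."""
    return float(np.abs(net.weights).sum() / 2.0)


def distance_matrix(net: Network) -> np.ndarray:
    """All-pairs shortest-path distances under edge length ``1/|w|``.

    Unreachable pairs are ``+inf``; the diagonal is 0.
    """
    w = np.abs(net.weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return shortest_path(lengths, method="D", directed=False)


def closeness(net: Network) -> pd.Series:
    """Inverse of the summed distances to all other nodes; 0 if disconnected."""
    dist = distance_matrix(net)
    p = net.n_items
    values = np.zeros(p)
    for i in range(p):
        row = np.delete(dist[i], i)
        if row.size == 0:
            values[i] = 0.0
        elif np.isinf(row).any():
            values[i] = 0.0
            logger.info(
                "closeness: node %s disconnected from some node; using 0 convention",
                net.item_labels[i],
            )
        else:
            values[i] = 1.0 / row.sum()
    return pd.Series(values, index=net.item_labels, name="closeness")


def _graph(net: Network) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(net.item_labels)
    p = net.n_items
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if w != 0.0:
                graph.add_edge(
                    net.item_labels[i], net.item_labels[j], length=1.0 / abs(w)
                )
    return graph


def betweenness(net: Network) -> pd.Series:
    """Shortest-path betweenness with fractional credit for tied paths."""
    bc = nx.betweenness_centrality(_graph(net), normalized=False, weight="length")
    return pd.Series(
        [bc[label] for label in net.item_labels], index=net.item_labels, name="betweenness"
    )


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    if sd > 0:
        return (col - col.mean()) / sd
    return col * 0.0


def centrality_table(net: Network) -> pd.DataFrame:
    """Raw and z-standardized centrality indices per node."""
    table = pd.DataFrame(
        {
            "strength": strength(net),
            "closeness": closeness(net),
            "betweenness": betweenness(net),
            "expected_influence": expected_influence(net),
        }
    )
    for col in ["strength", "closeness", "betweenness", "expected_influence"]:
        table[f"z_{col}"] = _zscore(table[col])
    table.index.name = "item"
    return table
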