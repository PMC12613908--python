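"""Centrality indices on a weighted signed partial-correlation network.

Four indices per node:

* strength: sum of absolute incident edge weights;
* expected influence (EI): signed sum of incident edge weights (one-step);
* betweenness: Brandes count of shortest paths through the node on the
  distance graph with edge lengths 1/|w|, unordered pairs, endpoints
  excluded, fractional credit for tied paths;
* closeness: inverse of the mean shortest-path distance to the other
  reachable nodes (unreachable pairs excluded from the mean; an isolated
  node gets closeness 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .ggm import EDGE_THRESHOLD

INDICES = ("strength", "betweenness", "closeness", "expected_influence")


def _weights_and_labels(W) -> tuple[np.ndarray, list[str]]:
    if isinstance(W, pd.DataFrame):
        return W.to_numpy(float), list(W.columns)
    if hasattr(W, "partial_corr_"):  # a fitted GaussianGraphicalModel
        return np.asarray(W.partial_corr_, float), list(W.feature_names_in_)
    W = np.asarray(W, float)
    return W, [f"V{i}" for i in range(W.shape[0])]


def strength_and_expected_influence(W) -> pd.DataFrame:
    """Per-node strength (sum |w|) and one-step expected influence (sum w)."""
    M, labels = _weights_and_labels(W)
    return pd.DataFrame(
        {
            "strength": np.abs(M).sum(axis=1),
            "expected_influence": M.sum(axis=1),
        },
        index=labels,
    )


def _distance_graph(M: np.ndarray) -> nx.Graph:
    p = M.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if abs(M[i, j]) > EDGE_THRESHOLD:
                G.add_edge(i, j, distance=1.0 / abs(M[i, j]))
    return G


def shortest_path_centrality(W) -> pd.DataFrame:
    """Betweenness and closeness on the 1/|w| distance graph."""
    M, labels = _weights_and_labels(W)
    G = _distance_graph(M)
    p = M.shape[0]
    btw = nx.betweenness_centrality(G, weight="distance", normalized=False)
    clo = np.zeros(p)
    unreachable = np.zeros(p, dtype=int)
    for i in range(p):
        lengths = nx.single_source_dijkstra_path_length(G, i, weight="distance")
        d = [v for k, v in lengths.items() if k != i]
        unreachable[i] = p - 1 - len(d)
        clo[i] = 1.0 / float(np.mean(d)) if d else 0.0
    return pd.DataFrame(
        {
            "betweenness": [btw[i] for i in range(p)],
            "closeness": clo,
            "n_unreachable": unreachable,
        },
        index=labels,
    )


def centrality_profile(W, indices=INDICES) -> pd.DataFrame:
    """All requested centrality indices as a nodes x indices frame.

    Shortest-path indices are only computed when requested (they dominate
    the cost inside resampling loops).
    """
    parts = [strength_and_expected_influence(W)]
    if "betweenness" in indices or "closeness" in indices:
        parts.append(shortest_path_centrality(W))
    prof = pd.concat(parts, axis=1)
    return prof[[c for c in INDICES if c in indices]]


def standardize_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """z-score each index across nodes (population SD).

    A zero-variance index maps to all zeros (flagged via the
    ``constant_indices`` attribute on the returned frame's ``attrs``).
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 nodes to standardize")
    out = {}
    constant = []
    for col in profile.columns:
        v = profile[col].to_numpy(float)
        sd = v.std()  # population convention
        if sd == 0:
            out[col] = np.zeros_like(v)
            constant.append(col)
        else:
            out[col] = (v - v.mean()) / sd
    z = pd.DataFrame(out, index=profile.index)
    z.attrs["constant_indices"] = constant
    return z


def profile_long(profile: pd.DataFrame, group: str = "total") -> pd.DataFrame:
    """Long-format export: node, index, value, group."""
    long = profile.reset_index(names="node").melt(
        id_vars="node", var_name="index", value_name="value"
    )
    long["group"] = group
    return long
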