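"""Node centrality for weighted partial-correlation networks.

Three measures, as conventionally defined for psychopathology networks:

* strength — sum of absolute incident edge weights;
* closeness — inverse average shortest-path length, with edge length
  ``1/|w|`` so strong edges are short;
* betweenness — Brandes shortest-path bridging credit (equal-length ties
  share credit fractionally).

Standardized z-scores across the p nodes are what centrality plots show.
"""
from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

MEASURES = ("strength", "closeness", "betweenness")


def _weights(W) -> np.ndarray:
    return np.asarray(W.W if hasattr(W, "W") else W, dtype=float)


def strength(W, signed: bool = False) -> np.ndarray:
    """Per-node sum of |edge weight| (or of raw weights when ``signed``)."""
    A = _weights(W)
    return A.sum(axis=1) if signed else np.abs(A).sum(axis=1)


def shortest_path_distances(W) -> np.ndarray:
    """All-pairs shortest paths with edge length 1/|w|; +inf if unreachable."""
    A = np.abs(_weights(W))
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, 1.0 / np.where(A > 0, A, 1.0), 0.0)
    # csgraph treats zero entries of a dense matrix as absent edges
    return shortest_path(lengths, method="D", directed=False)


def closeness(W) -> np.ndarray:
    """1 / mean shortest-path distance to reachable nodes; 0 if isolated."""
    D = shortest_path_distances(W)
    p = D.shape[0]
    out = np.zeros(p)
    for i in range(p):
        d = D[i, np.arange(p) != i]
        d = d[np.isfinite(d)]
        if d.size:
            out[i] = 1.0 / d.mean()
    return out


def betweenness(W, fraction: bool = False) -> np.ndarray:
    """Brandes betweenness on the 1/|w| distance graph.

    Raw counts credit a node with the fraction of equal-length shortest
    paths it lies on, summed over unordered pairs of other nodes. With
    ``fraction=True`` counts are divided by (p-1)(p-2)/2, the number of
    pairs, giving the share of shortest paths a node sits on.
    """
    A = np.abs(_weights(W))
    p = A.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if A[i, j] > 0:
                G.add_edge(i, j, length=1.0 / A[i, j])
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    raw = np.array([bc[i] for i in range(p)])
    if fraction:
        denom = (p - 1) * (p - 2) / 2.0
        return raw / denom if denom > 0 else raw
    return raw


def standardize(values: np.ndarray) -> np.ndarray:
    """z = (x - mean)/SD over nodes (sample SD, ddof=1); zeros if constant."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("constant centrality column; z-scores set to 0", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(W, item_names=None, signed_strength: bool = False) -> pd.DataFrame:
    """Raw and standardized strength/closeness/betweenness per node."""
    A = _weights(W)
    p = A.shape[0]
    names = list(item_names) if item_names else [f"item{i + 1}" for i in range(p)]
    raw = {
        "strength": strength(A, signed=signed_strength),
        "closeness": closeness(A),
        "betweenness": betweenness(A),
    }
    df = pd.DataFrame({"item": names})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in MEASURES:
            df[m] = raw[m]
            df[f"{m}_z"] = standardize(raw[m])
    return df
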