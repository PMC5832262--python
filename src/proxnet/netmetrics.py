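"""Weighted undirected networks and per-individual connectedness metrics.

Three standard centrality measures serve as sociality proxies:

* eigenvector centrality — leading eigenvector of the weighted adjacency
  matrix (direct + indirect connectedness), rescaled so the maximum entry
  is 1 (the igraph convention; a unit-norm scaling is available);
* graph strength — sum of an individual's weighted edges (direct);
* degree — number of distinct associates with positive edge weight.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationMatrix

__all__ = [
    "build_network",
    "eigenvector_centrality",
    "strength",
    "degree",
    "metric_table",
    "summarize_table1",
    "write_edge_list",
    "write_graphml",
]

METRICS = ("eigenvector", "strength", "degree")


def build_network(m: AssociationMatrix, weight_threshold: float = 0.0) -> nx.Graph:
    """Weighted undirected graph: edge (i, j) iff weights[i][j] > threshold.

    All individuals appear as nodes even when isolated.  Asymmetric input
    is rejected: run the collar-bias correction first.
    """
    if not m.symmetric or not np.array_equal(m.weights, m.weights.T):
        raise ValueError(
            "association matrix is not symmetric; apply correct_collar_bias "
            "before building a network")
    g = nx.Graph()
    g.add_nodes_from(m.ids)
    iu, ju = np.triu_indices(m.n, k=1)
    for i, j in zip(iu, ju):
        w = m.weights[i, j]
        if w > weight_threshold:
            g.add_edge(m.ids[i], m.ids[j], weight=float(w))
    g.graph.update(sex=m.sex, density=m.density, replicate=m.replicate)
    return g


def _adjacency(graph: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = list(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    return nodes, A


def eigenvector_centrality(graph: nx.Graph, scaling: str = "max") -> dict:
    """Leading eigenvector of the weighted adjacency matrix.

    Computed by dense symmetric eigendecomposition; the Perron vector of a
    nonnegative symmetric matrix is entrywise nonnegative (up to sign),
    and tiny negative round-off is clipped.  ``scaling="max"`` rescales so
    the largest entry is 1; ``scaling="unit"`` leaves the unit L2 norm.

    An edgeless graph yields all zeros with a warning.  On a disconnected
    graph the vector is supported on the component with the largest leading
    eigenvalue (other entries ~ 0); a warning flags this.
    """
    nodes, A = _adjacency(graph)
    if graph.number_of_edges() == 0:
        warnings.warn("edgeless graph: eigenvector centrality is all zeros")
        return {v: 0.0 for v in nodes}
    if not nx.is_connected(graph):
        warnings.warn("disconnected graph: eigenvector centrality computed on the "
                      "full matrix; off-principal components are ~0")
    evals, evecs = np.linalg.eigh(A)
    v = evecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    if scaling == "max":
        v = v / v.max()
    elif scaling != "unit":
        raise ValueError("scaling must be 'max' or 'unit'")
    return {node: float(val) for node, val in zip(nodes, v)}


def strength(graph: nx.Graph) -> dict:
    """Sum of incident edge weights (row sum of the symmetric matrix)."""
    return {v: float(d) for v, d in graph.degree(weight="weight")}


def degree(graph: nx.Graph) -> dict:
    """Number of associates connected by a positive-weight edge."""
    return {v: int(d) for v, d in graph.degree()}


_METRIC_FUNCS = {"eigenvector": eigenvector_centrality, "strength": strength,
                 "degree": degree}


def metric_table(
    networks: Mapping[tuple, nx.Graph],
    metrics: Iterable[str] = METRICS,
) -> pd.DataFrame:
    """Long-format observation table: one row per individual x metric x
    treatment x replicate.

    *networks* maps (density, replicate) — or (sex, density, replicate) —
    to graphs.  With the full 3-density x 2-replicate design each
    individual contributes 6 values per metric, the repeated measures the
    mixed models consume.
    """
    rows = []
    for key, g in networks.items():
        if len(key) == 3:
            sex, density, rep = key
        else:
            density, rep = key
            sex = g.graph.get("sex")
        for metric in metrics:
            values = _METRIC_FUNCS[metric](g)
            for node, val in values.items():
                rows.append({"individual": node, "sex": sex, "density": float(density),
                             "replicate": int(rep), "metric": metric,
                             "value": float(val)})
    return pd.DataFrame(rows)


def summarize_table1(obs: pd.DataFrame, decimals: int | None = None) -> pd.DataFrame:
    """Per-network mean +/- sample SD of each metric, one row per
    density x replicate (x sex), in the layout of a treatment-summary
    table.  SD uses the n-1 denominator."""
    keys = [k for k in ("sex", "density", "replicate") if k in obs.columns]
    out = (obs.groupby(keys + ["metric"])["value"]
           .agg(mean="mean", sd=lambda v: v.std(ddof=1))
           .reset_index())
    wide = out.pivot_table(index=keys, columns="metric", values=["mean", "sd"])
    wide = wide.sort_index()
    if decimals is not None:
        wide = wide.round(decimals)
    return wide


def write_edge_list(graph: nx.Graph, path) -> None:
    df = pd.DataFrame([(u, v, d["weight"]) for u, v, d in graph.edges(data=True)],
                      columns=["source", "target", "weight"])
    df.to_csv(path, index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    g = graph.copy()
    g.graph.clear()  # GraphML writer rejects None-valued graph attributes
    nx.write_graphml(g, path)
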