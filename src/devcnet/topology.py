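"""Network centrality summaries for the differential network and its subnets."""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def avg_degree_centrality(graph: nx.Graph) -> float:
    """Mean normalised degree centrality, i.e. graph density 2E/(n(n-1))."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def avg_closeness(graph: nx.Graph) -> float:
    """Mean component-scaled (Wasserman-Faust) closeness centrality.

    For node v reaching r other nodes at total distance D, closeness is
    ((r)/D) * (r/(n-1)), which handles disconnected graphs gracefully.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("closeness needs at least 2 nodes")
    cc = nx.closeness_centrality(graph, wf_improved=True)
    return float(np.mean(list(cc.values())))


def avg_betweenness(graph: nx.Graph) -> float:
    """Mean shortest-path betweenness, normalised by (n-1)(n-2)/2."""
    if graph.number_of_nodes() < 3:
        logger.warning("betweenness undefined for n < 3; returning 0")
        return 0.0
    bc = nx.betweenness_centrality(graph, normalized=True)
    return float(np.mean(list(bc.values())))


def graph_entropy(graph: nx.Graph) -> float:
    """Shannon entropy (bits) of the degree-weighted node distribution.

    p_v = deg(v) / sum of degrees; H = -sum p_v log2 p_v. Zero-degree
    nodes contribute nothing. Requires at least one edge.
    """
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    total = degrees.sum()
    if total == 0:
        raise ValueError("graph entropy requires at least one edge")
    p = degrees[degrees > 0] / total
    return float(-(p * np.log2(p)).sum())


def centrality_report(graph: nx.Graph, name: str = "network") -> dict:
    """One row of the Table-style centrality comparison."""
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    return {
        "network": name,
        "n_nodes": n,
        "n_edges": e,
        "degree": round(avg_degree_centrality(graph), 5) if n >= 2 else float("nan"),
        "closeness": round(avg_closeness(graph), 5) if n >= 2 else float("nan"),
        "betweenness": round(avg_betweenness(graph), 5) if n >= 3 else 0.0,
        "entropy": round(graph_entropy(graph), 5) if e >= 1 else float("nan"),
    }


def centrality_table(graphs: dict[str, nx.Graph]) -> pd.DataFrame:
    """Centrality report rows for a named set of (sub)networks."""
    return pd.DataFrame([centrality_report(g, name) for name, g in graphs.items()])
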