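"""Bi-coloured differential network construction.

The DEVC-net is built on top of a background interaction network from two
edge classes:

* differential edges — background edges whose centred-product test is
  significant (p_dc <= alpha); these carry the covariance signal;
* non-differential edges — background edges whose BOTH endpoints are
  classified (DEG or DEVG); the edge itself carries no covariance signal
  but connects differential genes.

Nodes inherit their colour from the gene class; genes that appear only as
endpoints of differential edges without being DEG/DEVG themselves are kept
with the colour tag ``DECG_only`` (they are excluded from the DEG/DEVG/DD
subnet statistics). Isolated nodes never occur: the node set is the union
of edge endpoints. Threshold comparisons are inclusive (p <= alpha).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .datasets import BackgroundNetwork
from .stats import DEG, DEVG

DIFFERENTIAL = "differential"
NON_DIFFERENTIAL = "non_differential"
DECG_ONLY = "DECG_only"


def extract_differential_edges(
    bg: BackgroundNetwork, pair_stats: pd.DataFrame, alpha: float = 0.05
) -> list[tuple[str, str, dict]]:
    """Background edges with significant differential covariance."""
    out = []
    for row in pair_stats.itertuples(index=False):
        if (row.gene_m, row.gene_n) in bg and row.p_dc <= alpha:
            out.append(
                (
                    row.gene_m,
                    row.gene_n,
                    {"type": DIFFERENTIAL, "sign": int(row.sign), "p": float(row.p_dc)},
                )
            )
    return out


def extract_nondifferential_edges(
    bg: BackgroundNetwork, gene_stats: pd.DataFrame, alpha: float = 0.05
) -> list[tuple[str, str, dict]]:
    """Background edges whose both endpoints are DEG or DEVG."""
    cls = gene_stats["cls"]
    classified = set(cls.index[cls.isin([DEG, DEVG])])
    out = []
    for a, b in bg.edge_list():
        if a in classified and b in classified:
            out.append((a, b, {"type": NON_DIFFERENTIAL, "sign": 0, "p": float("nan")}))
    return out


def build_devc_net(
    bg: BackgroundNetwork,
    gene_stats: pd.DataFrame,
    pair_stats: pd.DataFrame,
    alpha: float = 0.05,
) -> nx.Graph:
    """Union of differential and non-differential edges as a networkx graph.

    An edge qualifying for both classes keeps type ``differential``. Node
    attributes: ``colour`` in {DEG, DEVG, DECG_only} and ``sign``.
    """
    net = nx.Graph()
    for a, b, data in extract_nondifferential_edges(bg, gene_stats, alpha):
        net.add_edge(a, b, **data)
    for a, b, data in extract_differential_edges(bg, pair_stats, alpha):
        net.add_edge(a, b, **data)  # overwrites a non-differential duplicate
    cls = gene_stats["cls"]
    sign = gene_stats["sign"]
    for node in net.nodes:
        c = cls.get(node, "none")
        net.nodes[node]["colour"] = c if c in (DEG, DEVG) else DECG_ONLY
        net.nodes[node]["sign"] = int(sign.get(node, 0))
    return net


def induce_subnets(net: nx.Graph) -> dict[str, nx.Graph]:
    """DEG-, DEVG- and DD- (bipartite DEG-DEVG) subnetworks of a DEVC-net.

    DEG/DEVG subnets are induced on the same-coloured nodes; the DD subnet
    keeps exactly the edges with one DEG and one DEVG endpoint. DECG_only
    nodes belong to no subnet. Edge and node attributes are inherited.
    """
    colour = nx.get_node_attributes(net, "colour")
    deg_nodes = [n for n, c in colour.items() if c == DEG]
    devg_nodes = [n for n, c in colour.items() if c == DEVG]
    dd = nx.Graph()
    for a, b, data in net.edges(data=True):
        if {colour.get(a), colour.get(b)} == {DEG, DEVG}:
            dd.add_edge(a, b, **data)
    for n in dd.nodes:
        dd.nodes[n].update(net.nodes[n])
    return {
        "DEG_subnet": net.subgraph(deg_nodes).copy(),
        "DEVG_subnet": net.subgraph(devg_nodes).copy(),
        "DD_subnet": dd,
    }


def nodes_table(net: nx.Graph, gene_stats: pd.DataFrame) -> pd.DataFrame:
    """Flat node table (gene, class/colour, sign, p-values, means)."""
    rows = []
    for node, data in sorted(net.nodes(data=True)):
        gs = gene_stats.loc[node] if node in gene_stats.index else None
        rows.append(
            {
                "gene": node,
                "class": data["colour"],
                "sign": data["sign"],
                "p_de": None if gs is None else gs["p_de"],
                "p_dv": None if gs is None else gs["p_dv"],
                "u": None if gs is None else gs["u"],
                "u_prime": None if gs is None else gs["u_prime"],
                "u_star": None if gs is None else gs["u_star"],
            }
        )
    return pd.DataFrame(rows, columns=["gene", "class", "sign", "p_de", "p_dv", "u", "u_prime", "u_star"])


def edges_table(net: nx.Graph) -> pd.DataFrame:
    """Flat edge table (gene_m, gene_n, type, sign, p_dc)."""
    rows = []
    for a, b, data in net.edges(data=True):
        m, n = (a, b) if a <= b else (b, a)
        rows.append(
            {"gene_m": m, "gene_n": n, "type": data["type"], "sign": data["sign"], "p_dc": data["p"]}
        )
    df = pd.DataFrame(rows, columns=["gene_m", "gene_n", "type", "sign", "p_dc"])
    return df.sort_values(["gene_m", "gene_n"], ignore_index=True) if len(df) else df
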