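"""Readers and writers for the on-disk TSV artifacts.

All files are plain TSV, UTF-8, '.' decimal. Expression: first row sample
ids, first column gene ids. Phenotype: two columns (sample id, label),
header optional. Network: two-column edge list, SIF-style third column
tolerated. Outputs: nodes.tsv / edges.tsv / modules.tsv / scores.tsv.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .datasets import VALID_LABELS, BackgroundNetwork, ExpressionDataset, _norm_edge

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def read_expression(expr_path, pheno_path) -> ExpressionDataset:
    """Load a gene x sample TSV and its sample→phenotype map.

    Genes with any empty or non-numeric cell are dropped; the dropped ids
    are recorded on ``dataset.dropped_genes`` and logged. Samples present
    in the expression file but absent from the phenotype file are an error.
    """
    raw = pd.read_csv(expr_path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")

    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1)
    dropped = list(values.index[bad])
    if dropped:
        logger.info("dropped %d gene(s) with missing/non-numeric cells", len(dropped))
    values = values[~bad].astype(float)

    pheno = pd.read_csv(pheno_path, sep="\t", header=None, dtype=str, comment="#")
    if pheno.shape[1] < 2:
        raise ValueError("phenotype file needs two tab-separated columns")
    # tolerate a header row ("sample\tlabel" etc.)
    if pheno.iloc[0, 1] not in VALID_LABELS and len(pheno) > 1:
        pheno = pheno.iloc[1:]
    labels = pd.Series(pheno.iloc[:, 1].values, index=pheno.iloc[:, 0].values)
    unknown = set(labels.unique()) - set(VALID_LABELS)
    if unknown:
        raise ValueError(
            f"unknown label token(s) {sorted(unknown)}; expected one of {VALID_LABELS}"
        )
    missing = [s for s in values.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without phenotype: {missing}")
    return ExpressionDataset(values, labels.loc[values.columns], dropped_genes=dropped)


def read_network(path) -> BackgroundNetwork:
    """Load a two-column edge list (SIF-style third column tolerated)."""
    edges: set[tuple[str, str]] = set()
    n_loops = 0
    n_dups = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected >=2 fields, got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ValueError(f"line {lineno}: empty endpoint")
            if a == b:
                n_loops += 1
                continue
            e = _norm_edge(a, b)
            if e in edges:
                n_dups += 1
            edges.add(e)
    if n_loops:
        logger.info("dropped %d self-loop(s)", n_loops)
    if n_dups:
        logger.info("collapsed %d duplicate pair(s)", n_dups)
    return BackgroundNetwork(edges)


NODE_COLS = ["gene", "class", "sign", "p_de", "p_dv", "u", "u_prime", "u_star"]
EDGE_COLS = ["gene_m", "gene_n", "type", "sign", "p_dc"]
MODULE_COLS = ["module", "gene"]
SCORE_COLS = ["module", "sample", "mDEG", "mDEVG", "mDECG", "DEVC"]


def write_tables(results: dict, out_dir) -> dict[str, Path]:
    """Write whichever result tables are present to ``out_dir``.

    Recognised keys: ``nodes``, ``edges``, ``modules``, ``scores``,
    ``centrality``, ``evaluation`` (each a DataFrame). Missing keys produce
    header-only files for the four core tables so downstream consumers can
    rely on their presence.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    defaults = {
        "nodes": NODE_COLS,
        "edges": EDGE_COLS,
        "modules": MODULE_COLS,
        "scores": SCORE_COLS,
    }
    written = {}
    for name, cols in defaults.items():
        df = results.get(name)
        if df is None:
            df = pd.DataFrame(columns=cols)
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        written[name] = path
    for name in ("centrality", "evaluation"):
        if name in results:
            path = out_dir / f"{name}.tsv"
            results[name].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
            written[name] = path
    return written


def write_graphml(net: nx.Graph, path) -> None:
    """Export the differential network with its colour/type attributes."""
    g = nx.Graph()
    for n, data in net.nodes(data=True):
        g.add_node(n, colour=str(data.get("colour", "")), sign=int(data.get("sign", 0)))
    for a, b, data in net.edges(data=True):
        g.add_edge(
            a,
            b,
            type=str(data.get("type", "")),
            sign=int(data.get("sign", 0)),
            p=float(data.get("p", float("nan"))),
        )
    nx.write_graphml(g, path)
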