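"""Single-sample module measurements and the additive DEVC score.

Each module is measured in each sample by three signed sums:

* mDEG  = sum over module DEGs of  sign(n) * e_n^s           (raw level)
* mDEVG = sum over module DEVGs of sign(n) * |e_n^s - u*_n|  (absolute
  relative level, the single-sample proxy for expression variance)
* mDECG = sum over module DECG edges of
  sign(m,n) * (e_m^s - u*_m) * (e_n^s - u*_n)                (co-expression
  level)

and DEVC = mDEG + mDEVG + mDECG. The pooled means u* are estimated once
from the reference cohorts and frozen, so a NEW sample can be scored
without re-estimating anything. No normalisation by module size is
applied by default: the same module is compared across samples, not
against other modules. An optional 1/k or 1/sqrt(k) weighting is exposed
for cross-module comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mcl import NetworkModule
from .stats import DEG, DEVG


def measure_abs_relative(e: float, u_star: float) -> float:
    """Absolute relative expression level |e - u*|."""
    return abs(e - u_star)


def measure_coexpression(e_m: float, u_star_m: float, e_n: float, u_star_n: float) -> float:
    """Co-expression level (e_m - u*_m)(e_n - u*_n)."""
    return (e_m - u_star_m) * (e_n - u_star_n)


def _module_gene_sets(module: NetworkModule, gene_stats: pd.DataFrame):
    in_mod = [g for g in module.genes if g in gene_stats.index]
    cls = gene_stats.loc[in_mod, "cls"] if in_mod else pd.Series(dtype=object)
    degs = [g for g in in_mod if cls[g] == DEG]
    devgs = [g for g in in_mod if cls[g] == DEVG]
    return degs, devgs


def score_mDEG(module, sample_values: pd.Series, gene_stats: pd.DataFrame) -> float:
    """Signed sum of raw expression over the module's DEGs; 0 if none."""
    degs, _ = _module_gene_sets(module, gene_stats)
    if not degs:
        return 0.0
    signs = gene_stats.loc[degs, "sign"].to_numpy(dtype=float)
    return float(np.dot(signs, sample_values.loc[degs].to_numpy(dtype=float)))


def score_mDEVG(module, sample_values: pd.Series, gene_stats: pd.DataFrame) -> float:
    """Signed sum of |e - u*| over the module's DEVGs; 0 if none."""
    _, devgs = _module_gene_sets(module, gene_stats)
    if not devgs:
        return 0.0
    signs = gene_stats.loc[devgs, "sign"].to_numpy(dtype=float)
    dev = np.abs(
        sample_values.loc[devgs].to_numpy(dtype=float)
        - gene_stats.loc[devgs, "u_star"].to_numpy(dtype=float)
    )
    return float(np.dot(signs, dev))


def score_mDECG(
    module,
    sample_values: pd.Series,
    gene_stats: pd.DataFrame,
    decg_edges: dict[tuple[str, str], int],
) -> float:
    """Signed sum of centred products over the module's DECG edges; 0 if none.

    ``decg_edges`` maps unordered significant pairs to their sign.
    """
    total = 0.0
    for a, b in module.edges:
        key = (a, b) if a <= b else (b, a)
        sgn = decg_edges.get(key)
        if sgn is None:
            continue
        total += sgn * measure_coexpression(
            sample_values[a], gene_stats.loc[a, "u_star"],
            sample_values[b], gene_stats.loc[b, "u_star"],
        )
    return float(total)


def score_DEVC(module, sample_values, gene_stats, decg_edges) -> tuple[float, float, float, float]:
    """(mDEG, mDEVG, mDECG, DEVC) for one module in one sample."""
    a = score_mDEG(module, sample_values, gene_stats)
    b = score_mDEVG(module, sample_values, gene_stats)
    c = score_mDECG(module, sample_values, gene_stats, decg_edges)
    return a, b, c, a + b + c


def decg_edge_signs(pair_stats: pd.DataFrame, alpha: float = 0.05) -> dict[tuple[str, str], int]:
    """Unordered significant pairs → sign, from a pair-stats table."""
    out = {}
    for row in pair_stats.itertuples(index=False):
        if row.p_dc <= alpha:
            key = tuple(sorted((row.gene_m, row.gene_n)))
            out[key] = int(row.sign)
    return out


def score_modules(
    modules: list[NetworkModule],
    expression: pd.DataFrame,
    gene_stats: pd.DataFrame,
    pair_stats: pd.DataFrame,
    alpha: float = 0.05,
    min_module_size: int = 2,
    normalization: str | None = None,
) -> pd.DataFrame:
    """Score every (module, sample) pair.

    Parameters
    ----------
    expression : DataFrame
        Genes x samples matrix; may be new samples, scored against the
        frozen u* means in ``gene_stats``.
    min_module_size : int
        Modules with fewer genes are skipped (singletons by default).
    normalization : {None, "1/k", "1/sqrt(k)"}
        Optional size weighting; k = number of module genes for the node
        terms and number of DECG edges for the edge term.

    Returns
    -------
    DataFrame with columns module, sample, mDEG, mDEVG, mDECG, DEVC; the
    DEVC column is the exact sum of the three components.
    """
    if normalization not in (None, "1/k", "1/sqrt(k)"):
        raise ValueError(f"unknown normalization {normalization!r}")
    edges = decg_edge_signs(pair_stats, alpha)
    rows = []
    for module in modules:
        if len(module.genes) < min_module_size:
            continue
        k = len(module.genes)
        w = 1.0 if normalization is None else (1.0 / k if normalization == "1/k" else 1.0 / np.sqrt(k))
        for sample in expression.columns:
            col = expression[sample]
            a, b, c, _ = score_DEVC(module, col, gene_stats, edges)
            a, b, c = w * a, w * b, w * c
            rows.append((module.id, sample, a, b, c, a + b + c))
    return pd.DataFrame(rows, columns=["module", "sample", "mDEG", "mDEVG", "mDECG", "DEVC"])
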