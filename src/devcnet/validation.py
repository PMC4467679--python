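"""Recovery of planted structure: how well the tests find what was planted.

Used to validate the whole detection stack against the synthetic
generator's ground truth. For each planted class the candidates are ranked
by the class's own p-value within the genes (or pairs) carrying that
class's classification, the top k are selected with k equal to the size of
the truth set, and precision/recall are computed against it. Planted
heterogeneous genes are genuinely variance-differential (equal cohort
means, inflated case variance), so they count as part of the DEVG truth
set; their individual classification is reported separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import BackgroundNetwork, ExpressionDataset
from .simulate import GroundTruth, SyntheticSpec, generate
from .stats import (
    DEG,
    DEVG,
    compute_gene_stats,
    compute_pair_stats,
    select_top_n,
)


def _top_k_scores(selected: set, truth: set) -> tuple[float, float]:
    tp = len(selected & truth)
    precision = tp / len(selected) if selected else 0.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def recovery_scores(
    ds: ExpressionDataset,
    bg: BackgroundNetwork,
    truth: GroundTruth,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Precision/recall per planted class plus the hetero→DEVG rate."""
    gene_stats = compute_gene_stats(ds, alpha)
    out: dict[str, float] = {}

    deg_truth = set(truth.deg)
    pool = gene_stats[gene_stats["cls"] == DEG]
    sel = set(select_top_n(pool["p_de"], max(len(deg_truth), 1)))
    out["deg_precision"], out["deg_recall"] = _top_k_scores(sel, deg_truth)

    devg_truth = set(truth.devg) | set(truth.hetero)
    pool = gene_stats[gene_stats["cls"] == DEVG]
    sel = set(select_top_n(pool["p_dv"], max(len(devg_truth), 1)))
    out["devg_precision"], out["devg_recall"] = _top_k_scores(sel, devg_truth)

    pair_stats = compute_pair_stats(ds, bg.edge_list(), gene_stats, alpha)
    keys = [f"{m}|{n}" for m, n in zip(pair_stats["gene_m"], pair_stats["gene_n"])]
    pv = pd.Series(pair_stats["p_dc"].to_numpy(), index=keys)
    pair_truth = {f"{min(a, b)}|{max(a, b)}" for a, b in truth.decg_pairs}
    sel = set(select_top_n(pv, max(len(pair_truth), 1)))
    out["decg_precision"], out["decg_recall"] = _top_k_scores(sel, pair_truth)

    if truth.hetero:
        out["hetero_devg_rate"] = float(
            (gene_stats.loc[truth.hetero, "cls"] == DEVG).mean()
        )
        out["hetero_deg_rate"] = float(
            (gene_stats.loc[truth.hetero, "cls"] == DEG).mean()
        )
    return out


def replicate_recovery(
    n_replicates: int = 20, base_seed: int = 0, alpha: float = 0.05, **spec_kwargs
) -> pd.DataFrame:
    """Recovery scores over independent generator replicates."""
    rows = []
    for r in range(n_replicates):
        seed = (base_seed + 1_000_003 * r) % (2**31 - 1)
        ds, bg, truth = generate(SyntheticSpec(seed=seed, **spec_kwargs))
        rows.append(recovery_scores(ds, bg, truth, alpha))
    return pd.DataFrame(rows)
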