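import numpy as np
import pandas as pd
import pytest

from devcnet.datasets import ExpressionDataset
from devcnet.mcl import mcl_decompose
from devcnet.network import build_devc_net
from devcnet.scoring import score_modules
from devcnet.simulate import SyntheticSpec, generate
from devcnet.stats import compute_gene_stats, compute_pair_stats


def make_dataset(control: np.ndarray, case: np.ndarray, genes=None) -> ExpressionDataset:
    """Assemble a dataset from genes x samples arrays for the two cohorts."""
    control = np.atleast_2d(np.asarray(control, dtype=float))
    case = np.atleast_2d(np.asarray(case, dtype=float))
    n_genes = control.shape[0]
    if genes is None:
        genes = [f"g{i:03d}" for i in range(n_genes)]
    cols = [f"c{i}" for i in range(control.shape[1])] + [f"t{i}" for i in range(case.shape[1])]
    values = pd.DataFrame(np.hstack([control, case]), index=genes, columns=cols)
    labels = pd.Series(
        ["control"] * control.shape[1] + ["case"] * case.shape[1], index=cols
    )
    return ExpressionDataset(values, labels)


@pytest.fixture(scope="session")
def synth():
    """The default synthetic fixture: planted DEG/DEVG/DECG/heterogeneous structure."""
    ds, bg, truth = generate(SyntheticSpec(seed=0))
    return {"ds": ds, "bg": bg, "truth": truth}


@pytest.fixture(scope="session")
def synth_pipeline(synth):
    """Full pipeline run (stats → network → modules → scores) on the fixture."""
    ds, bg = synth["ds"], synth["bg"]
    gene_stats = compute_gene_stats(ds)
    pair_stats = compute_pair_stats(ds, bg.edge_list(), gene_stats)
    net = build_devc_net(bg, gene_stats, pair_stats)
    modules = mcl_decompose(net)
    scores = score_modules(modules, ds.values, gene_stats, pair_stats)
    return {
        **synth,
        "gene_stats": gene_stats,
        "pair_stats": pair_stats,
        "net": net,
        "modules": modules,
        "scores": scores,
    }
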