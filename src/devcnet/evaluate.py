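"""Unsupervised evaluation of feature sets by repeated K-means.

Feature matrices are built either from selected genes (raw expression for
DEGs, absolute relative level |e - u*| for DEVGs, or combinations) or from
module scores (any combination of mDEG / mDEVG / mDECG, summing to the
full DEVC score). Samples are clustered by K-means many times and the
clustering is compared against the known phenotypes with an accuracy that
maximises agreement over every cluster→phenotype map, so label naming and
cluster order do not matter. Features are not standardised by default —
the score magnitudes are the designed signal — but a flag exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .datasets import ExpressionDataset
from .stats import DEG, DEVG

GENE_MODES = ("DEG_ori", "DEG_rel", "DEVG_ori", "DEVG_rel")
SCORE_COMPONENTS = ("mDEG", "mDEVG", "mDECG")


@dataclass
class ClusteringEvaluation:
    """Accuracy distribution of repeated K-means for one feature strategy."""

    feature_mode: str
    accuracies: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std_accuracy(self) -> float:
        """Population standard deviation (ddof=0) across reruns."""
        return float(np.std(self.accuracies))


def _gene_measurement(ds: ExpressionDataset, genes, gene_stats: pd.DataFrame, kind: str) -> np.ndarray:
    vals = ds.values.loc[list(genes)].to_numpy(dtype=float)
    if kind == "ori":
        return vals.T
    if kind == "rel":
        u_star = gene_stats.loc[list(genes), "u_star"].to_numpy(dtype=float)
        return np.abs(vals - u_star[:, None]).T
    raise ValueError(f"unknown measurement kind {kind!r}")


def build_feature_matrix(
    ds: ExpressionDataset,
    mode: str,
    gene_stats: pd.DataFrame | None = None,
    selection: dict[str, list[str]] | None = None,
    scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Samples x features matrix for one evaluation strategy.

    Gene modes: ``"DEG_ori"``, ``"DEG_rel"``, ``"DEVG_ori"``, ``"DEVG_rel"``
    or ``" & "``-joined combinations (e.g. ``"DEG_ori & DEVG_rel"``);
    ``selection`` maps class name (``"DEG"``/``"DEVG"``) to its gene list.

    Module modes: ``" & "``-joined subsets of ``mDEG``/``mDEVG``/``mDECG``
    or ``"DEVC"`` (all three); ``scores`` is the long table from
    :func:`devcnet.scoring.score_modules`; each module contributes one
    column holding the sum of the chosen components.
    """
    tokens = [t.strip() for t in mode.split("&")]
    if all(t in GENE_MODES for t in tokens):
        if gene_stats is None or selection is None:
            raise ValueError("gene modes need gene_stats and selection")
        blocks, names = [], []
        for t in tokens:
            cls, kind = t.split("_")
            genes = selection[cls]
            if not genes:
                raise ValueError(f"empty selection for {cls}")
            blocks.append(_gene_measurement(ds, genes, gene_stats, kind))
            names.extend(f"{t}:{g}" for g in genes)
        return pd.DataFrame(np.hstack(blocks), index=ds.sample_ids, columns=names)

    if mode == "DEVC":
        tokens = list(SCORE_COMPONENTS)
    if all(t in SCORE_COMPONENTS for t in tokens):
        if scores is None:
            raise ValueError("module modes need a scores table")
        wide = scores.pivot(index="sample", columns="module", values=tokens)
        total = sum(wide[t] for t in tokens)
        total.columns = [f"module_{m}" for m in total.columns]
        return total.loc[list(scores["sample"].unique())]

    raise ValueError(f"unknown feature mode {mode!r}")


def kmeans_partition(features: np.ndarray, k: int, seed: int) -> np.ndarray:
    """One K-means run (Lloyd's, random-sample init) → sample labels."""
    features = np.asarray(features, dtype=float)
    if k > features.shape[0]:
        raise ValueError(f"k={k} exceeds the number of samples {features.shape[0]}")
    km = KMeans(n_clusters=k, init="random", n_init=1, max_iter=300, random_state=seed)
    return km.fit_predict(features)


def clustering_accuracy(cluster_labels, true_labels) -> float:
    """Agreement maximised over all cluster→phenotype map functions.

    Each cluster is matched to its best-covering phenotype (maps need not
    be injective), the matched counts are summed and divided by the total
    sample count. Equals 1 exactly when the clustering refines the true
    classes; never below the largest class proportion.
    """
    cluster_labels = np.asarray(cluster_labels)
    true_labels = np.asarray(true_labels)
    if cluster_labels.shape != true_labels.shape:
        raise ValueError("label vectors must have equal length")
    total = len(true_labels)
    correct = 0
    for c in np.unique(cluster_labels):
        members = true_labels[cluster_labels == c]
        _, counts = np.unique(members, return_counts=True)
        correct += counts.max()
    return correct / total


def repeated_evaluation(
    features: pd.DataFrame | np.ndarray,
    true_labels,
    mode: str = "features",
    k: int = 2,
    n_runs: int = 1000,
    seed: int = 0,
    standardize: bool = False,
) -> ClusteringEvaluation:
    """Accuracy distribution over ``n_runs`` K-means restarts.

    Restart seeds are drawn deterministically from the master ``seed``.
    """
    X = np.asarray(features, dtype=float)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    true_labels = np.asarray(true_labels)
    accs = np.array(
        [clustering_accuracy(kmeans_partition(X, k, int(s)), true_labels) for s in run_seeds]
    )
    return ClusteringEvaluation(feature_mode=mode, accuracies=accs)


def compare_strategies(ev_a: ClusteringEvaluation, ev_b: ClusteringEvaluation) -> float:
    """Two-sided Welch t-test p-value between two accuracy distributions."""
    return float(sps.ttest_ind(ev_a.accuracies, ev_b.accuracies, equal_var=False).pvalue)


def evaluation_table(evaluations: list[ClusteringEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mode": [e.feature_mode for e in evaluations],
            "mean_accuracy": [e.mean_accuracy for e in evaluations],
            "std_accuracy": [e.std_accuracy for e in evaluations],
            "n_runs": [len(e.accuracies) for e in evaluations],
        }
    )
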