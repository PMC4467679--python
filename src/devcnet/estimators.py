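"""Scikit-learn style estimators wrapping the differential-network pipeline.

Both estimators follow the sklearn contract (``fit``/``transform``,
``get_params``/``set_params``, fitted attributes with trailing
underscores) and take ``X`` as a samples x genes matrix with ``y`` the
binary phenotype (``"control"``/``"case"``), so they compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import BackgroundNetwork, ExpressionDataset
from .mcl import mcl_decompose
from .network import build_devc_net
from .scoring import decg_edge_signs, score_modules
from .stats import DEG, DEVG, compute_gene_stats, compute_pair_stats, select_top_n

_PAIR_CAP = 2_000_000


def _as_dataset(X, y, feature_names=None) -> ExpressionDataset:
    if isinstance(X, pd.DataFrame):
        values = X.T.copy()
    else:
        X = np.asarray(X, dtype=float)
        genes = feature_names if feature_names is not None else [f"g{i}" for i in range(X.shape[1])]
        values = pd.DataFrame(X.T, index=list(genes),
                              columns=[f"s{i}" for i in range(X.shape[0])])
    labels = pd.Series(np.asarray(y, dtype=object), index=values.columns)
    return ExpressionDataset(values, labels)


def _sample_frame(X, genes) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [g for g in genes if g not in X.columns]
        if missing:
            raise ValueError(f"missing gene columns: {missing[:5]}...")
        return X[list(genes)].T
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(genes):
        raise ValueError(f"expected {len(genes)} gene columns, got {X.shape[1]}")
    return pd.DataFrame(X.T, index=list(genes), columns=[f"s{i}" for i in range(X.shape[0])])


class DifferentialGeneSelector(BaseEstimator, TransformerMixin):
    """Select differential genes and emit their single-sample measurements.

    Fits the per-gene tests on a labelled cohort, ranks genes within the
    requested class(es) and transforms samples into the class-appropriate
    measurement: raw expression for DEGs, absolute relative level
    |e - u*| (u* frozen at fit time) for DEVGs.

    Parameters
    ----------
    alpha : float
        Significance level for classification (inclusive threshold).
    top_n : int
        Genes kept per class, ranked by ascending p-value.
    mode : str
        ``"DEG_ori"``, ``"DEVG_rel"``, ``"DEG_ori & DEVG_rel"`` etc.; the
        prefix picks the class ranking, the suffix the measurement.

    Attributes
    ----------
    gene_stats_ : DataFrame
        Per-gene moments, p-values, class and sign.
    selected_ : dict
        Class name → ordered selected gene list.
    """

    def __init__(self, alpha: float = 0.05, top_n: int = 1000, mode: str = "DEG_ori & DEVG_rel"):
        self.alpha = alpha
        self.top_n = top_n
        self.mode = mode

    def _tokens(self):
        return [t.strip() for t in self.mode.split("&")]

    def fit(self, X, y, feature_names=None):
        ds = _as_dataset(X, y, feature_names)
        self.gene_stats_ = compute_gene_stats(ds, self.alpha)
        self.selected_ = {}
        for token in self._tokens():
            cls, _ = token.split("_")
            col = "p_de" if cls == DEG else "p_dv"
            pool = self.gene_stats_[self.gene_stats_["cls"] == cls]
            self.selected_[cls] = select_top_n(pool[col], min(self.top_n, max(len(pool), 1)))
        self.n_features_in_ = ds.values.shape[0]
        self.feature_names_out_ = [
            f"{token}:{g}" for token in self._tokens()
            for g in self.selected_[token.split("_")[0]]
        ]
        return self

    def transform(self, X):
        check_is_fitted(self, "gene_stats_")
        all_genes = list(self.gene_stats_.index)
        frame = _sample_frame(X, all_genes)
        blocks = []
        for token in self._tokens():
            cls, kind = token.split("_")
            genes = self.selected_[cls]
            vals = frame.loc[genes].to_numpy(dtype=float).T
            if kind == "rel":
                u_star = self.gene_stats_.loc[genes, "u_star"].to_numpy(dtype=float)
                vals = np.abs(vals - u_star)
            blocks.append(vals)
        return np.hstack(blocks) if blocks else np.empty((frame.shape[1], 0))

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)


class DEVCNetScorer(BaseEstimator, TransformerMixin):
    """Fit a differential network + modules; transform samples to module scores.

    ``fit`` runs the whole construction: per-gene and per-pair tests on the
    background-network candidate edges, bi-coloured network assembly, MCL
    module decomposition, and freezes the pooled means u*. ``transform``
    scores each sample against every module, returning a samples x modules
    matrix of the chosen component combination (default the full additive
    DEVC score). New, unlabelled samples can be transformed.

    Parameters
    ----------
    network : BackgroundNetwork or iterable of edges, optional
        Background interactions; if None, all gene pairs are candidates
        (guarded by a hard cap).
    alpha : float
        Significance level for all three tests.
    inflation : float
        MCL inflation exponent.
    components : tuple of str
        Subset of ("mDEG", "mDEVG", "mDECG") summed into the output.
    min_module_size : int
        Modules with fewer genes are not scored.
    """

    def __init__(
        self,
        network=None,
        alpha: float = 0.05,
        inflation: float = 1.8,
        components: tuple = ("mDEG", "mDEVG", "mDECG"),
        min_module_size: int = 2,
        normalization: str | None = None,
    ):
        self.network = network
        self.alpha = alpha
        self.inflation = inflation
        self.components = components
        self.min_module_size = min_module_size
        self.normalization = normalization

    def _background(self, genes) -> BackgroundNetwork:
        if isinstance(self.network, BackgroundNetwork):
            return self.network
        if self.network is not None:
            return BackgroundNetwork(set(tuple(e) for e in self.network))
        n = len(genes)
        if n * (n - 1) // 2 > _PAIR_CAP:
            raise ValueError(
                f"all-pairs mode needs {n*(n-1)//2} pairs (cap {_PAIR_CAP}); supply a network"
            )
        return BackgroundNetwork({(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]})

    def fit(self, X, y, feature_names=None):
        ds = _as_dataset(X, y, feature_names)
        bg = self._background(ds.gene_ids)
        known = set(ds.gene_ids)
        candidates = [e for e in bg.edge_list() if e[0] in known and e[1] in known]
        self.gene_stats_ = compute_gene_stats(ds, self.alpha)
        self.pair_stats_ = compute_pair_stats(ds, candidates, self.gene_stats_, self.alpha)
        self.network_ = build_devc_net(bg, self.gene_stats_, self.pair_stats_, self.alpha)
        self.modules_ = mcl_decompose(self.network_, inflation=self.inflation)
        self.decg_edges_ = decg_edge_signs(self.pair_stats_, self.alpha)
        self.scored_modules_ = [m for m in self.modules_ if len(m) >= self.min_module_size]
        self.n_features_in_ = ds.values.shape[0]
        self.gene_ids_ = ds.gene_ids
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "modules_")
        frame = _sample_frame(X, self.gene_ids_)
        table = self.score_table(frame)
        comps = list(self.components)
        wide = table.pivot(index="sample", columns="module", values=comps)
        out = sum(wide[c] for c in comps)
        return out.loc[list(frame.columns)].to_numpy(dtype=float)

    def score_table(self, expression: pd.DataFrame) -> pd.DataFrame:
        """Long (module, sample, mDEG, mDEVG, mDECG, DEVC) table."""
        check_is_fitted(self, "modules_")
        return score_modules(
            self.modules_,
            expression,
            self.gene_stats_,
            self.pair_stats_,
            alpha=self.alpha,
            min_module_size=self.min_module_size,
            normalization=self.normalization,
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "modules_")
        return np.asarray([f"module_{m.id}" for m in self.scored_modules_], dtype=object)
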