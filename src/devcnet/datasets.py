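"""Core in-memory containers: expression matrix with phenotypes, background network."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"
VALID_LABELS = (CONTROL, CASE)


class CohortError(ValueError):
    """Raised when a phenotype cohort is too small to test."""


@dataclass
class ExpressionDataset:
    """A gene x sample expression matrix with a binary phenotype per sample.

    Parameters
    ----------
    values : pandas.DataFrame
        Real-valued matrix, genes in rows (index = gene ids), samples in
        columns. Expression is used on the scale supplied (assumed
        log-like); no transform is applied.
    labels : pandas.Series
        Phenotype per sample id, each ``"control"`` or ``"case"``. Must
        cover every column of ``values``.

    Notes
    -----
    Each cohort must contain at least two samples: every downstream test
    compares control against case distributions and is undefined otherwise.
    """

    values: pd.DataFrame
    labels: pd.Series
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValueError(f"samples without phenotype label: {missing}")
        bad = set(self.labels.unique()) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown phenotype label(s): {sorted(bad)}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if np.asarray(self.values, dtype=float).size and np.isnan(
            self.values.to_numpy(dtype=float)
        ).any():
            raise ValueError("missing values remain after loading")
        for lab in VALID_LABELS:
            if (self.labels == lab).sum() < 2:
                raise CohortError(
                    f"insufficient cohort: need >=2 {lab} samples, "
                    f"got {(self.labels == lab).sum()}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def control_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == CONTROL])

    @property
    def case_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == CASE])

    @property
    def control(self) -> pd.DataFrame:
        """Genes x control-samples sub-matrix."""
        return self.values[self.control_samples]

    @property
    def case(self) -> pd.DataFrame:
        """Genes x case-samples sub-matrix."""
        return self.values[self.case_samples]

    def subset_genes(self, genes) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(genes)], self.labels)


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class BackgroundNetwork:
    """An undirected prior interaction network (e.g. protein-protein edges).

    Edges are unordered gene-id pairs; self-loops and duplicate pairs are
    rejected at construction (loaders drop them before constructing).
    """

    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        normed = set()
        for a, b in self.edges:
            if not a or not b:
                raise ValueError("edge endpoint must be a non-empty string")
            if a == b:
                raise ValueError(f"self-loop on {a!r} not allowed")
            normed.add(_norm_edge(a, b))
        self.edges = normed

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return _norm_edge(a, b) in self.edges

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges in deterministic (sorted) order."""
        return sorted(self.edges)
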