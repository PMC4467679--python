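"""Synthetic case/control expression data with planted differential structure.

The generator emulates the four signal classes a differential
variance/covariance analysis is designed to detect, on a log-intensity-like
scale (baseline gene means uniform in [5, 10], Gaussian noise):

* DEG genes: the case mean is shifted by ``delta`` noise standard
  deviations;
* DEVG genes: equal means, case standard deviation scaled by
  sqrt(var_ratio);
* DECG pairs: bivariate normal with equal means in both cohorts but
  correlation ``rho_control`` in controls and ``rho_case`` in cases (a
  flipped-correlation pair changes covariance without touching any
  marginal);
* heterogeneous genes: a fraction of case samples is shifted up by
  ``delta`` and the rest down by ``delta``, so the cohort means stay
  (nearly) equal while the case variance inflates — the motivating case
  where mean-based tests fail but variance tests succeed;
* null genes: identical distributions in both cohorts.

The background network contains every planted DECG pair plus uniformly
random padding edges among non-DECG genes. A fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import BackgroundNetwork, ExpressionDataset


@dataclass
class SyntheticSpec:
    """Planted-effect description for the generator (defaults = study conditions)."""

    n_control: int = 50
    n_case: int = 50
    n_deg: int = 100
    n_devg: int = 100
    n_decg_pairs: int = 100
    n_hetero: int = 100
    n_null: int = 600
    delta: float = 2.0          # DEG mean shift, in units of noise_sd
    var_ratio: float = 4.0      # DEVG case/control variance ratio
    rho_control: float = 0.8    # DECG pair correlation in controls
    rho_case: float = -0.8      # DECG pair correlation in cases
    hetero_fraction: float = 0.5  # fraction of case samples shifted up
    noise_sd: float = 1.0
    extra_random_edges: int = 200
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_control, self.n_case, self.n_deg, self.n_devg,
                  self.n_decg_pairs, self.n_hetero, self.n_null,
                  self.extra_random_edges)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not (abs(self.rho_control) < 1 and abs(self.rho_case) < 1):
            raise ValueError("|rho| must be < 1")
        if not (0 < self.hetero_fraction < 1):
            raise ValueError("hetero_fraction must be in (0, 1)")
        if self.noise_sd <= 0 or self.var_ratio <= 0:
            raise ValueError("noise_sd and var_ratio must be positive")


@dataclass
class GroundTruth:
    """Planted genes/pairs by class, as written to the truth tables."""

    deg: list[str] = field(default_factory=list)
    devg: list[str] = field(default_factory=list)
    hetero: list[str] = field(default_factory=list)
    null: list[str] = field(default_factory=list)
    decg_pairs: list[tuple[str, str]] = field(default_factory=list)

    def gene_table(self) -> pd.DataFrame:
        rows = (
            [(g, "DEG") for g in self.deg]
            + [(g, "DEVG") for g in self.devg]
            + [(g, "hetero") for g in self.hetero]
            + [(g, "DECG") for p in self.decg_pairs for g in p]
            + [(g, "null") for g in self.null]
        )
        return pd.DataFrame(rows, columns=["gene", "class"])

    def pair_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.decg_pairs, columns=["gene_m", "gene_n"])


def _gene_names(prefix: str, count: int, width: int = 4) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(count)]


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, BackgroundNetwork, GroundTruth]:
    """Draw one dataset, its background network and the ground truth."""
    rng = np.random.default_rng(spec.seed)
    n_c, n_t = spec.n_control, spec.n_case
    n_samples = n_c + n_t
    sd = spec.noise_sd

    deg = _gene_names("DEG_", spec.n_deg)
    devg = _gene_names("DEVG_", spec.n_devg)
    het = _gene_names("HET_", spec.n_hetero)
    decg = _gene_names("DECG_", 2 * spec.n_decg_pairs)
    null = _gene_names("NULL_", spec.n_null)
    genes = deg + devg + het + decg + null
    mu = rng.uniform(5.0, 10.0, size=len(genes))
    mu_of = dict(zip(genes, mu))

    blocks: dict[str, np.ndarray] = {}
    for g in deg:
        x = mu_of[g] + rng.normal(0, sd, n_samples)
        x[n_c:] += spec.delta * sd
        blocks[g] = x
    for g in devg:
        x = np.empty(n_samples)
        x[:n_c] = mu_of[g] + rng.normal(0, sd, n_c)
        x[n_c:] = mu_of[g] + rng.normal(0, sd * np.sqrt(spec.var_ratio), n_t)
        blocks[g] = x
    n_up = int(round(spec.hetero_fraction * n_t))
    for g in het:
        x = mu_of[g] + rng.normal(0, sd, n_samples)
        shift = np.concatenate([np.full(n_up, spec.delta * sd),
                                np.full(n_t - n_up, -spec.delta * sd)])
        x[n_c:] += shift
        blocks[g] = x
    pairs = []
    for i in range(spec.n_decg_pairs):
        a, b = decg[2 * i], decg[2 * i + 1]
        x = np.empty(n_samples)
        y = np.empty(n_samples)
        for sl, rho, n in ((slice(0, n_c), spec.rho_control, n_c),
                           (slice(n_c, None), spec.rho_case, n_t)):
            z1 = rng.normal(0, 1, n)
            z2 = rng.normal(0, 1, n)
            x[sl] = mu_of[a] + sd * z1
            y[sl] = mu_of[b] + sd * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        blocks[a] = x
        blocks[b] = y
        pairs.append((a, b))
    for g in null:
        blocks[g] = mu_of[g] + rng.normal(0, sd, n_samples)

    values = pd.DataFrame(
        np.vstack([blocks[g] for g in genes]),
        index=genes,
        columns=[f"C{i:03d}" for i in range(n_c)] + [f"T{i:03d}" for i in range(n_t)],
    )
    if spec.lognormal:
        values = np.exp(values / 4.0)  # mildly skewed positive scale
    labels = pd.Series(["control"] * n_c + ["case"] * n_t, index=values.columns)
    ds = ExpressionDataset(values, labels)

    edges = set(tuple(sorted(p)) for p in pairs)
    non_decg = deg + devg + het + null
    max_extra = len(non_decg) * (len(non_decg) - 1) // 2
    if spec.extra_random_edges > max_extra:
        raise ValueError("extra_random_edges exceeds the available non-DECG pairs")
    while len(edges) < len(pairs) + spec.extra_random_edges:
        a, b = rng.choice(len(non_decg), size=2, replace=False)
        edges.add(tuple(sorted((non_decg[a], non_decg[b]))))
    bg = BackgroundNetwork(edges)

    truth = GroundTruth(deg=deg, devg=devg, hetero=het, null=null, decg_pairs=pairs)
    return ds, bg, truth


def export_fixture(spec: SyntheticSpec, out_dir) -> dict[str, Path]:
    """Write expression / phenotype / network / truth TSVs for the CLI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds, bg, truth = generate(spec)
    paths = {
        "expression": out_dir / "expression.tsv",
        "phenotype": out_dir / "phenotype.tsv",
        "network": out_dir / "network.tsv",
        "truth_genes": out_dir / "truth_genes.tsv",
        "truth_pairs": out_dir / "truth_pairs.tsv",
    }
    ds.values.to_csv(paths["expression"], sep="\t", index_label="gene")
    ds.labels.rename("label").to_csv(paths["phenotype"], sep="\t", header=False)
    with open(paths["network"], "w", encoding="utf-8") as fh:
        for a, b in bg.edge_list():
            fh.write(f"{a}\t{b}\n")
    truth.gene_table().to_csv(paths["truth_genes"], sep="\t", index=False)
    truth.pair_table().to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths
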