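"""Per-gene and per-pair differential statistics.

Three complementary signals distinguish case from control cohorts:

* differential expression (DEG): Welch two-sided t-test on the original
  expression level, H0: E(X) = E(X');
* differential expression variance (DEVG): Wilcoxon rank-sum on the
  absolute relative expression level |x - u| (each sample's deviation from
  its own cohort mean; folded-normal under Gaussian expression, hence a
  rank test rather than a t-test), with the extra condition that the means
  are NOT significantly different — DEG and DEVG are disjoint classes;
* differential expression covariance (DECG): Wilcoxon rank-sum on the
  per-sample co-expression level c_s = (x_s - u*)(y_s - v*), the product of
  the two genes' expressions centred at their POOLED means u*, v* (over all
  samples), so a new single sample can be scored against frozen means.

Raw p-values are thresholded at alpha (default 0.05) or ranked top-N; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

DEG = "DEG"
DEVG = "DEVG"
NONE = "none"


# ---------------------------------------------------------------------------
# moments

def compute_moments(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-gene cohort means, pooled mean and unbiased cohort variances.

    Returns a DataFrame indexed by gene with columns ``u`` (control mean),
    ``u_prime`` (case mean), ``u_star`` (pooled mean over all samples),
    ``var_control``, ``var_case`` (ddof=1), and the mean absolute
    deviations ``mad_control``, ``mad_case`` about each cohort's own mean.
    """
    ctrl = ds.control.to_numpy(dtype=float)
    case = ds.case.to_numpy(dtype=float)
    u = ctrl.mean(axis=1)
    u_prime = case.mean(axis=1)
    u_star = ds.values.to_numpy(dtype=float).mean(axis=1)
    return pd.DataFrame(
        {
            "u": u,
            "u_prime": u_prime,
            "u_star": u_star,
            "var_control": ctrl.var(axis=1, ddof=1),
            "var_case": case.var(axis=1, ddof=1),
            "mad_control": np.abs(ctrl - u[:, None]).mean(axis=1),
            "mad_case": np.abs(case - u_prime[:, None]).mean(axis=1),
        },
        index=ds.values.index,
    )


# ---------------------------------------------------------------------------
# rank-sum helper

def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two 1-D samples.

    Exact enumeration when both samples have <=10 observations and no
    ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    exact_ok = (
        len(x) <= 10 and len(y) <= 10 and len(np.unique(pooled)) == len(pooled)
    )
    method = "exact" if exact_ok else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def _ranksum_p_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for matched 2-D arrays."""
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 <= 10 and n2 <= 10:
        return np.array([_ranksum_p(x, y) for x, y in zip(X, Y)])
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(
            X, Y, axis=1, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    p = np.asarray(res.pvalue, dtype=float)
    const = np.ptp(np.concatenate([X, Y], axis=1), axis=1) == 0
    p = np.where(const | np.isnan(p), 1.0, np.minimum(p, 1.0))
    return p


# ---------------------------------------------------------------------------
# the three tests

def test_deg(ds: ExpressionDataset) -> pd.Series:
    """Two-sided Welch t-test p-value per gene (control vs case means)."""
    ctrl = ds.control.to_numpy(dtype=float)
    case = ds.case.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(ctrl, case, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        logger.info("%d gene(s) with zero variance in both cohorts; p_de=1", degenerate.sum())
        p = np.where(degenerate, 1.0, p)
    return pd.Series(p, index=ds.values.index, name="p_de")


def test_devg(ds: ExpressionDataset, moments: pd.DataFrame | None = None) -> pd.Series:
    """Rank-sum p-value per gene on absolute deviations from cohort means.

    Compares {|x_s - u| : s control} against {|x_s - u'| : s case}, each
    sample's absolute deviation from its OWN cohort mean.
    """
    if moments is None:
        moments = compute_moments(ds)
    moments = moments.reindex(ds.values.index)
    ctrl = ds.control.to_numpy(dtype=float)
    case = ds.case.to_numpy(dtype=float)
    dev_c = np.abs(ctrl - moments["u"].to_numpy()[:, None])
    dev_t = np.abs(case - moments["u_prime"].to_numpy()[:, None])
    return pd.Series(_ranksum_p_rows(dev_c, dev_t), index=ds.values.index, name="p_dv")


def test_decg(
    ds: ExpressionDataset,
    candidate_pairs,
    moments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank-sum p-value per gene pair on pooled-mean-centred products.

    For each candidate pair (m, n), the per-sample co-expression level is
    c_s = (e_m^s - u*_m)(e_n^s - u*_n) with u* the pooled mean over ALL
    samples; control and case c_s distributions are compared.
    """
    if moments is None:
        moments = compute_moments(ds)
    pairs = [tuple(p) for p in candidate_pairs]
    known = set(ds.gene_ids)
    for m, n in pairs:
        if m not in known or n not in known:
            raise KeyError(f"pair ({m!r}, {n!r}) references a gene absent from the dataset")
    if not pairs:
        return pd.DataFrame(columns=["gene_m", "gene_n", "p_dc"])
    idx = {g: i for i, g in enumerate(ds.gene_ids)}
    vals = ds.values.to_numpy(dtype=float)
    u_star = moments["u_star"].to_numpy()
    centred = vals - u_star[:, None]
    mi = np.array([idx[m] for m, _ in pairs])
    ni = np.array([idx[n] for _, n in pairs])
    c = centred[mi] * centred[ni]  # pairs x samples
    is_ctrl = (ds.labels == "control").to_numpy()
    p = _ranksum_p_rows(c[:, is_ctrl], c[:, ~is_ctrl])
    return pd.DataFrame(
        {
            "gene_m": [m for m, _ in pairs],
            "gene_n": [n for _, n in pairs],
            "p_dc": p,
            "mean_c_control": c[:, is_ctrl].mean(axis=1),
            "mean_c_case": c[:, ~is_ctrl].mean(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# classification and signs

def classify_genes(p_de: pd.Series, p_dv: pd.Series, alpha: float = 0.05) -> pd.Series:
    """DEG if p_de <= alpha; DEVG if p_dv <= alpha AND p_de > alpha; else none.

    A gene with both tests significant is a DEG: the DEVG definition
    requires the means NOT to differ, so the classes are disjoint.
    """
    cls = pd.Series(NONE, index=p_de.index, name="cls", dtype=object)
    cls[p_dv <= alpha] = DEVG
    cls[p_de <= alpha] = DEG
    return cls


def assign_signs(moments: pd.DataFrame, cls: pd.Series) -> pd.Series:
    """Regulation-trend sign per classified gene.

    DEG: +1 iff the case mean exceeds the control mean (up-regulated).
    DEVG: +1 iff the case mean absolute deviation exceeds the control one
    (the spread increases in disease). Exact ties resolve to +1 (logged).
    Unclassified genes get sign 0.
    """
    sign = pd.Series(0, index=cls.index, name="sign", dtype=int)
    is_deg = cls == DEG
    is_devg = cls == DEVG
    diff_mean = moments["u_prime"] - moments["u"]
    diff_mad = moments["mad_case"] - moments["mad_control"]
    ties = ((is_deg & (diff_mean == 0)) | (is_devg & (diff_mad == 0))).sum()
    if ties:
        logger.warning("%d exact tie(s) in sign assignment; using +1", ties)
    sign[is_deg] = np.where(diff_mean[is_deg] >= 0, 1, -1)
    sign[is_devg] = np.where(diff_mad[is_devg] >= 0, 1, -1)
    return sign


def pair_signs(pair_stats: pd.DataFrame) -> pd.Series:
    """+1 iff the mean co-expression level rises from control to case."""
    diff = pair_stats["mean_c_case"] - pair_stats["mean_c_control"]
    if (diff == 0).any():
        logger.warning("%d exact tie(s) in pair sign assignment; using +1", (diff == 0).sum())
    return pd.Series(np.where(diff >= 0, 1, -1), index=pair_stats.index, name="sign")


# ---------------------------------------------------------------------------
# convenience aggregates

def compute_gene_stats(ds: ExpressionDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Full per-gene table: moments, p_de, p_dv, class and sign."""
    moments = compute_moments(ds)
    stats = moments.copy()
    stats["p_de"] = test_deg(ds)
    stats["p_dv"] = test_devg(ds, moments)
    stats["cls"] = classify_genes(stats["p_de"], stats["p_dv"], alpha)
    stats["sign"] = assign_signs(moments, stats["cls"])
    return stats


def compute_pair_stats(
    ds: ExpressionDataset,
    candidate_pairs,
    gene_stats: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-pair table: p_dc, sign and subset membership.

    ``subset`` is ``both_nonDE`` when neither endpoint is differentially
    expressed at alpha (the pair can surface genes invisible to mean-based
    tests) and ``with_DE`` otherwise.
    """
    if gene_stats is None:
        gene_stats = compute_gene_stats(ds, alpha)
    ps = test_decg(ds, candidate_pairs, gene_stats)
    if ps.empty:
        ps["sign"] = pd.Series(dtype=int)
        ps["subset"] = pd.Series(dtype=object)
        return ps
    ps["sign"] = pair_signs(ps)
    p_de = gene_stats["p_de"]
    non_de_m = p_de.loc[ps["gene_m"]].to_numpy() > alpha
    non_de_n = p_de.loc[ps["gene_n"]].to_numpy() > alpha
    ps["subset"] = np.where(non_de_m & non_de_n, "both_nonDE", "with_DE")
    return ps


def select_top_n(pvalues: pd.Series, n: int) -> list[str]:
    """Genes by ascending p-value, ties broken lexicographically; first n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    order = sorted(pvalues.items(), key=lambda kv: (kv[1], str(kv[0])))
    return [g for g, _ in order[:n]]


def hypergeometric_tail(
    pop_n: int, pop_k: int, draw_n: int, obs_k: int, strict: bool = True
) -> float:
    """Upper-tail hypergeometric enrichment p-value.

    Probability of observing more (``strict=True``: P(X > obs_k)) or at
    least as many (``strict=False``: P(X >= obs_k)) annotated genes among
    ``draw_n`` drawn from a population of ``pop_n`` containing ``pop_k``
    annotated, than the ``obs_k`` observed.
    """
    if not (0 <= obs_k <= draw_n <= pop_n and obs_k <= pop_k <= pop_n):
        raise ValueError(
            f"invalid hypergeometric arguments: pop_n={pop_n}, pop_k={pop_k}, "
            f"draw_n={draw_n}, obs_k={obs_k}"
        )
    k = obs_k if strict else obs_k - 1
    return float(sps.hypergeom.sf(k, pop_n, pop_k, draw_n))
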