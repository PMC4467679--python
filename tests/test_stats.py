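from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devcnet.datasets import ExpressionDataset
from devcnet.stats import test_decg as decg_test
from devcnet.stats import test_deg as deg_test
from devcnet.stats import test_devg as devg_test
from devcnet.stats import (
    DEG,
    DEVG,
    NONE,
    assign_signs,
    classify_genes,
    compute_gene_stats,
    compute_moments,
    compute_pair_stats,
    hypergeometric_tail,
    pair_signs,
    select_top_n,
)
from conftest import make_dataset


class TestMoments:
    def test_hand_arithmetic(self):
        ds = make_dataset([[1, 3]], [[2, 4]])
        m = compute_moments(ds).iloc[0]
        assert m["u"] == 2 and m["u_prime"] == 3 and m["u_star"] == 2.5

    def test_constant_gene(self):
        ds = make_dataset([[5, 5]], [[5, 5]])
        m = compute_moments(ds).iloc[0]
        assert m["u"] == m["u_prime"] == m["u_star"] == 5
        assert m["var_control"] == m["var_case"] == 0

    def test_unbiased_variance(self):
        ds = make_dataset([[0, 2]], [[1, 5]])
        m = compute_moments(ds).iloc[0]
        assert m["var_control"] == 2.0  # ((0-1)^2+(2-1)^2)/(2-1)
        assert m["var_case"] == 8.0

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        ctrl, case = rng.normal(size=(4, 6)), rng.normal(size=(4, 5))
        m1 = compute_moments(make_dataset(ctrl, case))
        m2 = compute_moments(make_dataset(ctrl[:, ::-1], case[:, [3, 1, 0, 4, 2]]))
        pd.testing.assert_frame_equal(m1, m2)


class TestDifferentialTests:
    def test_deg_extreme_separation(self):
        rng = np.random.default_rng(0)
        ds = make_dataset([np.zeros(5) + rng.normal(0, 1e-3, 5)],
                          [np.full(5, 10.0) + rng.normal(0, 1e-3, 5)])
        assert deg_test(ds).iloc[0] < 1e-4

    def test_identical_cohorts_are_null(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ds = make_dataset([vals], [vals])
        assert deg_test(ds).iloc[0] > 0.99
        assert devg_test(ds).iloc[0] > 0.99

    def test_degenerate_constant_gene(self):
        ds = make_dataset([[5, 5, 5]], [[5, 5, 5]])
        assert deg_test(ds).iloc[0] == 1.0
        assert devg_test(ds).iloc[0] == 1.0

    def test_devg_detects_variance_change(self):
        rng = np.random.default_rng(1)
        ds = make_dataset([rng.normal(0, 1, 50)], [rng.normal(0, 2, 50)])
        assert devg_test(ds).iloc[0] <= 0.05

    def test_devg_power_at_variance_ratio_four(self):
        # closed-form rank-sum power: AUC = 1 - (2/pi) atan(1/2) = 0.7048,
        # z = 3.53 at n=50+50, two-sided power at 0.05 ~ 0.94
        rng = np.random.default_rng(11)
        ctrl = rng.normal(0, 1, (200, 50))
        case = rng.normal(0, 2, (200, 50))
        p = devg_test(make_dataset(ctrl, case))
        assert (p <= 0.05).mean() >= 0.90

    def test_decg_power_on_flipped_correlation(self):
        rng = np.random.default_rng(12)
        n = 50
        rows, pairs = [], []
        for i in range(200):
            x = np.empty(2 * n)
            y = np.empty(2 * n)
            for sl, rho in ((slice(0, n), 0.9), (slice(n, None), -0.9)):
                z1, z2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
                x[sl] = z1
                y[sl] = rho * z1 + np.sqrt(1 - rho**2) * z2
            rows += [x, y]
            pairs.append((f"g{2*i:03d}", f"g{2*i+1:03d}"))
        arr = np.vstack(rows)
        ds = make_dataset(arr[:, :n], arr[:, n:],
                          genes=[f"g{i:03d}" for i in range(400)])
        p = decg_test(ds, pairs)["p_dc"]
        assert (p <= 0.05).mean() >= 0.95

    def test_decg_identical_cohorts_null(self):
        rng = np.random.default_rng(2)
        block = rng.normal(0, 1, (2, 10))
        ds = make_dataset(block, block)
        p = decg_test(ds, [("g000", "g001")])["p_dc"].iloc[0]
        assert p > 0.99

    def test_decg_unknown_gene_errors(self):
        ds = make_dataset(np.zeros((2, 3)), np.ones((2, 3)))
        with pytest.raises(KeyError, match="nope"):
            decg_test(ds, [("g000", "nope")])

    def test_cohort_order_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        ctrl, case = rng.normal(size=(5, 8)), rng.normal(size=(5, 7))
        perm_c, perm_t = rng.permutation(8), rng.permutation(7)
        ds1, ds2 = make_dataset(ctrl, case), make_dataset(ctrl[:, perm_c], case[:, perm_t])
        pairs = [("g000", "g001"), ("g002", "g004")]
        np.testing.assert_allclose(deg_test(ds1), deg_test(ds2))
        np.testing.assert_allclose(devg_test(ds1), devg_test(ds2))
        np.testing.assert_allclose(
            decg_test(ds1, pairs)["p_dc"], decg_test(ds2, pairs)["p_dc"]
        )

    def test_location_shift_invariance(self):
        # adding a constant to every value of a gene (both cohorts) leaves
        # all three p-values unchanged
        rng = np.random.default_rng(4)
        ctrl, case = rng.normal(size=(3, 12)), rng.normal(size=(3, 12))
        ds1 = make_dataset(ctrl, case)
        ds2 = make_dataset(ctrl + 7.0, case + 7.0)
        pairs = [("g000", "g001")]
        np.testing.assert_allclose(deg_test(ds1), deg_test(ds2), atol=1e-12)
        np.testing.assert_allclose(devg_test(ds1), devg_test(ds2), atol=1e-12)
        np.testing.assert_allclose(
            decg_test(ds1, pairs)["p_dc"], decg_test(ds2, pairs)["p_dc"], atol=1e-12
        )


class TestTypeIError:
    def test_all_three_tests_hold_nominal_level(self):
        rng = np.random.default_rng(42)
        n = 20
        ctrl = rng.normal(0, 1, (2000, n))
        case = rng.normal(0, 1, (2000, n))
        ds = make_dataset(ctrl, case, genes=[f"g{i:04d}" for i in range(2000)])
        assert abs((deg_test(ds) <= 0.05).mean() - 0.05) <= 0.02
        assert abs((devg_test(ds) <= 0.05).mean() - 0.05) <= 0.02
        arr = rng.normal(0, 1, (4000, 2 * n))
        ds2 = make_dataset(arr[:, :n], arr[:, n:], genes=[f"h{i:04d}" for i in range(4000)])
        pairs = [(f"h{i:04d}", f"h{i+2000:04d}") for i in range(2000)]
        p = decg_test(ds2, pairs)["p_dc"]
        assert abs((p <= 0.05).mean() - 0.05) <= 0.02


class TestClassification:
    @pytest.mark.parametrize(
        "p_de,p_dv,expected",
        [
            (0.01, 0.001, DEG),   # mean difference takes precedence
            (0.5, 0.01, DEVG),
            (0.5, 0.5, NONE),
            (0.05, 0.5, DEG),     # inclusive threshold
            (0.5, 0.05, DEVG),
        ],
    )
    def test_rules(self, p_de, p_dv, expected):
        cls = classify_genes(pd.Series([p_de], index=["g"]),
                             pd.Series([p_dv], index=["g"]))
        assert cls["g"] == expected

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=50),
           st.floats(0.001, 0.999))
    @settings(deadline=None, max_examples=50)
    def test_deg_devg_disjoint_for_every_alpha(self, pvals, alpha):
        idx = [f"g{i}" for i in range(len(pvals))]
        p_de = pd.Series([a for a, _ in pvals], index=idx)
        p_dv = pd.Series([b for _, b in pvals], index=idx)
        cls = classify_genes(p_de, p_dv, alpha)
        assert not ((cls == DEG) & (cls == DEVG)).any()
        assert ((cls == DEG) == (p_de <= alpha)).all()
        assert ((cls == DEVG) == ((p_dv <= alpha) & (p_de > alpha))).all()


class TestSigns:
    def test_deg_up_regulated(self):
        ds = make_dataset([[1, 3]], [[2, 4]])  # u=2, u'=3
        moments = compute_moments(ds)
        signs = assign_signs(moments, pd.Series([DEG], index=ds.gene_ids))
        assert signs.iloc[0] == 1

    def test_devg_spread_increase(self):
        ds = make_dataset([[4, 6]], [[3, 7]])  # mad 1 vs 2
        moments = compute_moments(ds)
        signs = assign_signs(moments, pd.Series([DEVG], index=ds.gene_ids))
        assert signs.iloc[0] == 1

    def test_pair_sign_negative_when_coexpression_drops(self):
        ps = pd.DataFrame({"gene_m": ["a"], "gene_n": ["b"],
                           "mean_c_control": [0.5], "mean_c_case": [-0.5]})
        assert pair_signs(ps).iloc[0] == -1


class TestSelection:
    def test_ranking(self):
        p = pd.Series({"a": 0.2, "b": 0.1, "c": 0.3})
        assert select_top_n(p, 2) == ["b", "a"]

    def test_tie_broken_lexicographically(self):
        p = pd.Series({"b": 0.1, "a": 0.1})
        assert select_top_n(p, 1) == ["a"]

    def test_n_larger_than_population(self):
        p = pd.Series({"a": 0.2, "b": 0.1})
        assert select_top_n(p, 10) == ["b", "a"]


def _hypergeom_upper_brute(pop_n, pop_k, draw_n, obs_k, strict):
    """Exhaustive enumeration of the hypergeometric upper tail."""
    lo = obs_k + 1 if strict else obs_k
    total = comb(pop_n, draw_n)
    return sum(
        comb(pop_k, k) * comb(pop_n - pop_k, draw_n - k)
        for k in range(lo, min(pop_k, draw_n) + 1)
    ) / total


class TestHypergeometric:
    def test_small_example_against_enumeration(self):
        # brute force: sum of C(4,k)C(6,5-k)/C(10,5) for k=2..4 = 0.738095...
        expected = _hypergeom_upper_brute(10, 4, 5, 2, strict=False)
        assert expected == pytest.approx(0.7380952380952381)
        assert hypergeometric_tail(10, 4, 5, 2, strict=False) == pytest.approx(expected)

    def test_at_least_zero_is_certain(self):
        assert hypergeometric_tail(10, 4, 5, 0, strict=False) == 1.0

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_strict_nonstrict_identity_is_pmf(self, data):
        pop_n = data.draw(st.integers(2, 40))
        pop_k = data.draw(st.integers(0, pop_n))
        draw_n = data.draw(st.integers(1, pop_n))
        obs_k = data.draw(st.integers(max(0, draw_n + pop_k - pop_n), min(draw_n, pop_k)))
        diff = hypergeometric_tail(pop_n, pop_k, draw_n, obs_k, strict=False) - \
            hypergeometric_tail(pop_n, pop_k, draw_n, obs_k, strict=True)
        pmf = comb(pop_k, obs_k) * comb(pop_n - pop_k, draw_n - obs_k) / comb(pop_n, draw_n)
        assert diff == pytest.approx(pmf, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(10, 4, 5, 6)
        with pytest.raises(ValueError):
            hypergeometric_tail(10, 12, 5, 2)


class TestAggregates:
    def test_gene_stats_columns_and_bounds(self, synth_pipeline):
        gs = synth_pipeline["gene_stats"]
        assert gs["p_de"].between(0, 1).all()
        assert gs["p_dv"].between(0, 1).all()
        assert set(gs["cls"].unique()) <= {DEG, DEVG, NONE}
        assert (gs.loc[gs["cls"] != NONE, "sign"].isin([1, -1])).all()

    def test_pair_subset_definition(self, synth_pipeline):
        ps = synth_pipeline["pair_stats"]
        gs = synth_pipeline["gene_stats"]
        non_de = (gs.loc[ps["gene_m"], "p_de"].to_numpy() > 0.05) & \
                 (gs.loc[ps["gene_n"], "p_de"].to_numpy() > 0.05)
        assert ((ps["subset"] == "both_nonDE").to_numpy() == non_de).all()
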