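"""Chi-square statistic, matched permutation tests, expression models, BH."""

import numpy as np
import pandas as pd
import pytest

from chromsig.signatures import GeneSignatureTable
from chromsig.stats import (
    bh_adjust, chi_square_stat, draw_matched_subsample, fraction_percent,
    matched_permutation_test, signature_expression_model,
)


def sig_table(labels):
    return GeneSignatureTable(table=pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(labels))], "states": "",
        "groups": "", "signature": list(labels), "signature_class": ""}))


class TestChiSquare:
    def test_matching_proportions_give_zero(self):
        assert chi_square_stat([10, 30, 60], [0.1, 0.3, 0.6]) == 0.0

    def test_hand_computed_value(self):
        assert chi_square_stat([10, 0], [0.5, 0.5]) == pytest.approx(10.0)

    def test_invariant_to_category_relabeling(self):
        obs = np.array([5, 9, 2.0])
        p = np.array([0.3, 0.5, 0.2])
        perm = [2, 0, 1]
        assert chi_square_stat(obs, p) == pytest.approx(
            chi_square_stat(obs[perm], p[perm]))

    def test_expected_zero_with_observations_is_infinite(self):
        assert chi_square_stat([5, 5], [1.0, 0.0]) == float("inf")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_stat([-1, 2], [0.5, 0.5])


class TestPermutationTest:
    def test_homogeneous_pool_gives_p_one(self):
        t = sig_table(["S3"] * 13)
        r = matched_permutation_test([f"g{i}" for i in range(3)],
                                     [f"g{i}" for i in range(3, 13)],
                                     t, n_perm=100, seed=0)
        assert r.observed_statistic == 0.0
        assert r.p_value == 1.0

    def test_empirical_p_never_zero(self):
        rng = np.random.default_rng(0)
        labels = ["S3"] * 100 + ["S8"] * 20
        t = sig_table(labels)
        target = [f"g{i}" for i in range(100, 120)]  # all S8: extreme excess
        pool = [f"g{i}" for i in range(100)]
        r = matched_permutation_test(target, pool, t, n_perm=1000, seed=1)
        assert r.p_value == pytest.approx(1 / 1001)

    def test_planted_silent_excess_detected(self):
        rng = np.random.default_rng(2)
        pool_labels = list(rng.choice(["S3", "S7", "S8", "S16"], 600,
                                      p=[0.6, 0.2, 0.1, 0.1]))
        target_labels = list(rng.choice(["S3", "S8"], 60, p=[0.2, 0.8]))
        t = sig_table(pool_labels + target_labels)
        pool = [f"g{i}" for i in range(600)]
        target = [f"g{i}" for i in range(600, 660)]
        r = matched_permutation_test(target, pool, t, n_perm=10_000, seed=3)
        assert r.p_value <= 0.001

    def test_overlapping_target_and_pool_rejected(self):
        t = sig_table(["S3"] * 10)
        with pytest.raises(ValueError, match="disjoint"):
            matched_permutation_test(["g0"], ["g0", "g1"], t, n_perm=10)

    def test_te_matching_preserves_te_count_per_draw(self):
        rng = np.random.default_rng(4)
        n = 200
        labels = rng.choice(["S3", "S8"], n)
        t = sig_table(labels)
        te = pd.Series(rng.random(n) < 0.4,
                       index=[f"g{i}" for i in range(n)])
        cov = pd.DataFrame({"te_overlap": te})
        target = [f"g{i}" for i in range(40)]
        pool = [f"g{i}" for i in range(40, n)]
        t_te = int(te[target].sum())
        for k in range(20):
            draw = draw_matched_subsample(target, pool, cov, "TE_PREVALENCE",
                                          np.random.default_rng(k))
            assert len(draw) == len(target)
            assert int(te[draw].sum()) == t_te

    def test_te_matching_infeasible_reports_deficit(self):
        t = sig_table(["S3"] * 10)
        te = pd.Series([True] * 5 + [False] * 5,
                       index=[f"g{i}" for i in range(10)])
        cov = pd.DataFrame({"te_overlap": te})
        with pytest.raises(ValueError, match="infeasible"):
            matched_permutation_test([f"g{i}" for i in range(5)],
                                     [f"g{i}" for i in range(5, 10)],
                                     t, n_perm=10, matching="TE_PREVALENCE",
                                     covariates=cov)

    def test_expression_window_restricts_pool(self):
        n = 300
        rng = np.random.default_rng(5)
        t = sig_table(rng.choice(["S3", "S8"], n))
        expr = pd.Series(np.concatenate([np.full(30, 10.0),
                                         rng.uniform(8, 12, 150),
                                         rng.uniform(0.1, 100, n - 180)]),
                         index=[f"g{i}" for i in range(n)])
        cov = pd.DataFrame({"expression": expr})
        target = [f"g{i}" for i in range(30)]          # median 10
        pool = [f"g{i}" for i in range(30, n)]
        in_window = [g for g in pool if 7.5 <= expr[g] <= 12.5]
        draw = draw_matched_subsample(target, pool, cov, "EXPRESSION_WINDOW",
                                      np.random.default_rng(0))
        assert set(draw) <= set(in_window)
        r = matched_permutation_test(target, pool, t, n_perm=100,
                                     matching="EXPRESSION_WINDOW",
                                     covariates=cov, seed=0)
        assert 0 < r.p_value <= 1

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(6)
        t = sig_table(rng.choice(["S1", "S3", "S8"], 100))
        target = [f"g{i}" for i in range(20)]
        pool = [f"g{i}" for i in range(20, 100)]
        a = matched_permutation_test(target, pool, t, n_perm=500, seed=9)
        b = matched_permutation_test(target, pool, t, n_perm=500, seed=9)
        assert a.p_value == b.p_value and a.n_exceeding == b.n_exceeding


class TestExpressionModel:
    def test_two_group_difference_equals_ols_coefficient(self):
        y = pd.Series([1.0, 2, 3, 10, 11, 12])
        sig = pd.Series(["S1"] * 3 + ["S3"] * 3)
        loc = pd.Series(["AUTOSOME"] * 6)
        fit = signature_expression_model(y, sig, loc)
        coef = fit.coefficients.set_index("term")
        assert coef.loc["signature[S3]", "estimate"] == pytest.approx(9.0)
        assert coef.loc["Intercept", "estimate"] == pytest.approx(2.0)

    def test_saturated_balanced_design_reproduces_group_means(self):
        rng = np.random.default_rng(7)
        rows = []
        means = {("S1", "AUTOSOME"): 2.0, ("S1", "PAR"): 3.0,
                 ("S3", "AUTOSOME"): 5.0, ("S3", "PAR"): 4.0}
        for (s, l), mu in means.items():
            for _ in range(10):
                rows.append((mu, s, l))
        df = pd.DataFrame(rows, columns=["y", "sig", "loc"])
        fit = signature_expression_model(df["y"], df["sig"], df["loc"])
        coef = fit.coefficients.set_index("term")["estimate"]
        assert coef["Intercept"] == pytest.approx(2.0)
        assert coef["signature[S3]"] == pytest.approx(3.0)
        assert coef["location[PAR]"] == pytest.approx(1.0)
        assert coef["signature[S3]:location[PAR]"] == pytest.approx(-2.0)

    def test_zero_location_effect_interactions_near_zero(self):
        rng = np.random.default_rng(8)
        n = 400
        sig = pd.Series(rng.choice(["S1", "S3", "S8"], n))
        loc = pd.Series(rng.choice(["AUTOSOME", "PAR"], n))
        mu = sig.map({"S1": 1.0, "S3": 4.0, "S8": 0.5})
        y = mu + rng.normal(0, 0.5, n)
        fit = signature_expression_model(y, sig, loc)
        coef = fit.coefficients.set_index("term")
        for term in coef.index:
            if ":" in term:
                est, se = coef.loc[term, ["estimate", "std_error"]]
                assert abs(est) < 3 * se

    def test_adding_constant_shifts_only_intercept(self):
        y = pd.Series([1.0, 2, 3, 10, 11, 12])
        sig = pd.Series(["S1"] * 3 + ["S3"] * 3)
        loc = pd.Series(["AUTOSOME"] * 6)
        a = signature_expression_model(y, sig, loc).coefficients.set_index("term")
        b = signature_expression_model(y + 5, sig, loc).coefficients.set_index("term")
        assert b.loc["Intercept", "estimate"] - a.loc["Intercept", "estimate"] \
            == pytest.approx(5.0)
        assert b.loc["signature[S3]", "estimate"] == pytest.approx(
            a.loc["signature[S3]", "estimate"])

    def test_signature_only_on_par_marked_inestimable(self):
        y = pd.Series([1.0, 2, 3, 4, 8, 9])
        sig = pd.Series(["S1", "S1", "S3", "S3", "S5", "S5"])
        loc = pd.Series(["AUTOSOME", "PAR", "AUTOSOME", "PAR", "PAR", "PAR"])
        fit = signature_expression_model(y, sig, loc)
        coef = fit.coefficients.set_index("term")
        assert not coef.loc["signature[S5]:location[PAR]", "estimable"]

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            signature_expression_model(pd.Series([1.0, 2]),
                                       pd.Series(["S1", "S1"]),
                                       pd.Series(["AUTOSOME", "AUTOSOME"]))


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.07])[0] == pytest.approx(0.07)

    def test_step_up_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFractionPercent:
    def test_percentage_rounds_to_printed_precision(self):
        assert fraction_percent(121, 2_862_827) == 0.004

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fraction_percent(1, 0)
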