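"""Residualization, stratified correlations, Fisher r-to-z differential
co-abundance and binomial group enrichment."""

import numpy as np
import pandas as pd
import pytest

from serometa.coabundance import (
    DifferentialCoabundance,
    binomial_group_enrichment,
    classify_pairs,
    compute_p_parameter,
    fisher_z_test,
    groupwise_correlations,
    residualize,
    select_pairs,
)
from serometa.differential_abundance import build_design


class TestResidualize:
    def test_exact_linear_data_gives_zero_residuals(self, small_scaled):
        scaled, metadata, _ = small_scaled
        design = build_design(metadata)
        y = design.to_numpy() @ np.arange(1.0, design.shape[1] + 1)
        X = pd.DataFrame({"m": y}, index=scaled.values.index)
        resid = residualize(X, metadata)
        np.testing.assert_allclose(resid["m"], 0.0, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, small_scaled):
        scaled, metadata, _ = small_scaled
        resid = residualize(scaled.values, metadata)
        design = build_design(metadata)
        inner = design.to_numpy().T @ resid.to_numpy()
        assert np.abs(inner).max() < 1e-8

    def test_matches_hat_matrix_oracle(self, small_scaled):
        scaled, metadata, _ = small_scaled
        resid = residualize(scaled.values, metadata)
        X = build_design(metadata).to_numpy()
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        oracle = (np.eye(len(X)) - H) @ scaled.values.to_numpy()
        np.testing.assert_allclose(resid.to_numpy(), oracle, atol=1e-10)


class TestGroupwiseCorrelations:
    def test_duplicated_metabolite_perfectly_correlated(self, small_scaled):
        scaled, metadata, _ = small_scaled
        X = scaled.values.iloc[:, :3].copy()
        X["dup"] = X.iloc[:, 0]
        r_case, r_ctrl = groupwise_correlations(X, metadata)
        assert r_case.loc[X.columns[0], "dup"] == pytest.approx(1.0)
        assert r_ctrl.loc[X.columns[0], "dup"] == pytest.approx(1.0)

    def test_matches_textbook_covariance_oracle(self, small_scaled):
        scaled, metadata, _ = small_scaled
        X = scaled.values.iloc[:, :6]
        r_case, _ = groupwise_correlations(X, metadata)
        sub = X[(metadata["status"] == "case").to_numpy()].to_numpy()
        a, b = sub[:, 0], sub[:, 1]
        a_c, b_c = a - a.mean(), b - b.mean()
        oracle = (a_c @ b_c) / np.sqrt((a_c @ a_c) * (b_c @ b_c))
        assert r_case.iloc[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self, small_scaled):
        scaled, metadata, _ = small_scaled
        r_case, r_ctrl = groupwise_correlations(scaled.values.iloc[:, :10], metadata)
        for r in (r_case, r_ctrl):
            np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T, atol=1e-12)
            np.testing.assert_allclose(np.diag(r.to_numpy()), 1.0)

    def test_too_small_stratum_errors(self, small_scaled):
        scaled, metadata, _ = small_scaled
        tiny = metadata.iloc[:6].copy()
        tiny.loc[:, "status"] = ["case"] * 3 + ["control"] * 3
        with pytest.raises(ValueError, match="4 samples"):
            groupwise_correlations(scaled.values.iloc[:6, :4], tiny)


def _corr_frames(vals: dict):
    names = sorted({k for pair in vals for k in pair})
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for (a, b), v in vals.items():
        r.loc[a, b] = r.loc[b, a] = v
    return r


class TestSelectPairs:
    def test_either_stratum_rule(self):
        r_case = _corr_frames({("a", "b"): 0.1, ("a", "c"): 0.2, ("b", "c"): 0.3})
        r_ctrl = _corr_frames({("a", "b"): 0.6, ("a", "c"): 0.2, ("b", "c"): 0.3})
        pairs = select_pairs(r_case, r_ctrl)
        assert len(pairs) == 1
        assert (pairs.loc[0, "metabolite_a"], pairs.loc[0, "metabolite_b"]) == ("a", "b")

    def test_threshold_zero_keeps_all_pairs(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(30, 8))
        r = pd.DataFrame(np.corrcoef(A, rowvar=False),
                         index=list("abcdefgh"), columns=list("abcdefgh"))
        pairs = select_pairs(r, r, threshold=0.0)
        assert len(pairs) == 8 * 7 // 2

    def test_xenobiotics_excluded_before_pairing(self):
        r = _corr_frames({("a", "x"): 0.9, ("a", "b"): 0.9, ("b", "x"): 0.9})
        pairs = select_pairs(r, r, exclude=["x"])
        assert set(pairs["metabolite_a"]) | set(pairs["metabolite_b"]) == {"a", "b"}


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_test(0.4, 60, 0.4, 58)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_on_strong_discordant_pair(self):
        # r=0.73 (n=60) vs r=0.02 (n=58): z evaluates to ~4.81
        z, p = fisher_z_test(0.73, 60, 0.02, 58)
        import math

        oracle = (math.atanh(0.73) - math.atanh(0.02)) / math.sqrt(1 / 57 + 1 / 55)
        assert z == pytest.approx(oracle, abs=1e-12)
        assert z == pytest.approx(4.81, abs=0.01)
        assert p < 1e-5

    def test_antisymmetry(self):
        z1, p1 = fisher_z_test(0.6, 50, 0.2, 40)
        z2, p2 = fisher_z_test(0.2, 40, 0.6, 50)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            fisher_z_test(1.0, 50, 0.5, 50)


class TestClassifyPairs:
    @pytest.mark.parametrize(
        "r_ctrl, r_case, expected",
        [
            (0.7, 0.05, "lost_positive"),
            (-0.6, 0.1, "lost_negative"),
            (0.02, 0.73, "gained_positive"),
            (0.1, -0.8, "gained_negative"),
            (0.8, -0.6, "changed_other"),
        ],
    )
    def test_categories(self, r_ctrl, r_case, expected):
        pairs = pd.DataFrame(
            {
                "metabolite_a": ["a"], "metabolite_b": ["b"],
                "r_case": [r_case], "r_control": [r_ctrl],
                "significant": [True],
            }
        )
        assert classify_pairs(pairs).loc[0, "category"] == expected

    def test_non_significant_pairs_uncategorized(self):
        pairs = pd.DataFrame(
            {
                "metabolite_a": ["a"], "metabolite_b": ["b"],
                "r_case": [0.1], "r_control": [0.9],
                "significant": [False],
            }
        )
        assert classify_pairs(pairs).loc[0, "category"] == ""


class TestBinomialEnrichment:
    def test_p_parameter_identity(self):
        assert round(compute_p_parameter(161, 19_127), 3) == 0.008

    def test_zero_successes_give_p_one(self):
        pairs = pd.DataFrame(
            {
                "metabolite_a": ["a", "a"], "metabolite_b": ["b", "c"],
                "significant": [False, False],
            }
        )
        groups = pd.Series({"a": "g1", "b": "g1", "c": "g2"})
        res = binomial_group_enrichment(pairs, groups, p_parameter=0.1)
        assert (res["p"] == 1.0).all()

    def test_matches_tail_summation_oracle(self):
        from math import comb

        n, k, prob = 100, 5, 0.008
        oracle = sum(
            comb(n, j) * prob**j * (1 - prob) ** (n - j) for j in range(k, n + 1)
        )
        pairs = pd.DataFrame(
            {
                "metabolite_a": ["a"] * n,
                "metabolite_b": [f"b{j}" for j in range(n)],
                "significant": [True] * k + [False] * (n - k),
            }
        )
        groups = pd.Series(
            {"a": "target", **{f"b{j}": f"other{j % 3}" for j in range(n)}}
        )
        res = binomial_group_enrichment(pairs, groups, p_parameter=prob)
        row = res.set_index("group").loc["target"]
        assert row["p"] == pytest.approx(oracle, rel=1e-10)
        assert row["k"] == k and row["n"] == n
        assert oracle == pytest.approx(0.0014, abs=2e-4)

    def test_spanning_pairs_count_once_per_group(self):
        pairs = pd.DataFrame(
            {
                "metabolite_a": ["a", "a", "b"],
                "metabolite_b": ["b", "c", "c"],
                "significant": [True, True, False],
            }
        )
        groups = pd.Series({"a": "g1", "b": "g2", "c": "g3"})
        res = binomial_group_enrichment(pairs, groups).set_index("group")
        # sum of per-group k double counts spanning pairs
        assert res["k"].sum() >= int(pairs["significant"].sum())
        assert res.loc["g1", "k"] == 2 and res.loc["g2", "k"] == 1


class TestDifferentialCoabundanceEstimator:
    def test_pair_table_invariant_to_metabolite_order(self, small_scaled):
        scaled, metadata, annotation = small_scaled
        X = scaled.values.iloc[:, :40]
        ann = annotation.loc[X.columns]
        est1 = DifferentialCoabundance().fit(X, metadata, ann)
        perm = np.random.default_rng(2).permutation(X.shape[1])
        est2 = DifferentialCoabundance().fit(X.iloc[:, perm], metadata,
                                             ann.iloc[perm])

        def key(df):
            return {
                frozenset((r.metabolite_a, r.metabolite_b)): round(r.z, 9)
                for r in df.itertuples()
            }

        assert key(est1.pairs_) == key(est2.pairs_)

    def test_significance_threshold_is_q_below_fdr(self, small_scaled):
        scaled, metadata, annotation = small_scaled
        est = DifferentialCoabundance().fit(
            scaled.values, metadata, annotation.loc[scaled.values.columns]
        )
        pairs = est.pairs_
        assert ((pairs["q"] < 0.1) == pairs["significant"]).all()
        assert (pairs[["r_case", "r_control"]].abs().max(axis=1) >= 0.5).all()
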