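"""ANOVA/Tukey, correlation, MANOVA and canonical discriminant analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import thallometry as tm
from thallometry import stats as st
from thallometry.stats import StatsError


def scatter_oracle(df, variables, group_col="group"):
    """Direct two-loop computation of W and B."""
    X = df[list(variables)].to_numpy(float)
    groups = df[group_col].astype(str)
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for grp in sorted(groups.unique()):
        sub = X[(groups == grp).to_numpy()]
        m = sub.mean(axis=0)
        for row in sub:
            d = row - m
            W += np.outer(d, d)
        d = m - grand
        B += len(sub) * np.outer(d, d)
    return W, B


def eigen_oracle(W, B, f):
    """Brute-force eigenvalues of W^-1 B, descending."""
    evals = np.linalg.eigvals(np.linalg.solve(W, B))
    evals = np.sort(np.real(evals))[::-1]
    return evals[:f]


class TestDescriptives:
    def test_mean_and_sample_sd(self):
        df = pd.DataFrame({"da": [1.0, 2.0, 3.0], "group": "a"})
        df = pd.concat([df, pd.DataFrame({"da": [5.0, 5.0], "group": "b"})],
                       ignore_index=True)
        out = st.descriptives(df, variables=["da"])
        a = out[out["group"] == "a"].iloc[0]
        assert a["mean"] == pytest.approx(2.0)
        assert a["sd"] == pytest.approx(1.0)
        b = out[out["group"] == "b"].iloc[0]
        assert b["sd"] == 0.0

    def test_singleton_group_rejected(self):
        df = pd.DataFrame({"da": [1.0, 2.0, 3.0],
                           "group": ["a", "a", "b"]})
        with pytest.raises(StatsError, match="n < 2"):
            st.descriptives(df, variables=["da"])

    def test_matches_two_pass_oracle(self, riccardia_table):
        out = st.descriptives(riccardia_table)
        for _, row in out.iterrows():
            vals = riccardia_table.loc[
                riccardia_table["group"] == row["group"], row["variable"]]
            vals = vals.to_numpy(float)
            mean = vals.sum() / len(vals)
            sd = np.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1))
            assert row["mean"] == pytest.approx(mean)
            assert row["sd"] == pytest.approx(sd)


class TestAnovaPairwise:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        df = pd.DataFrame({"da": np.concatenate([vals, vals]),
                           "group": ["a"] * 30 + ["b"] * 30})
        out = st.anova_pairwise(df, "da")
        assert out["p_adj"].iloc[0] > 0.9
        assert out.attrs["F"] == pytest.approx(0.0, abs=1e-12)

    def test_extreme_separation_significant(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "da": np.concatenate([rng.normal(0, 1, 20),
                                  rng.normal(100, 1, 20)]),
            "group": ["a"] * 20 + ["b"] * 20})
        out = st.anova_pairwise(df, "da")
        assert out["p_adj"].iloc[0] < 1e-4
        assert out["code"].iloc[0] == "***"

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"da": [1.0] * 10 + [2.0] * 10,
                           "group": ["a"] * 10 + ["b"] * 10})
        with pytest.raises(StatsError, match="variance"):
            st.anova_pairwise(df, "da")

    def test_pair_count_and_codes(self, riccardia_table):
        out = st.anova_pairwise(riccardia_table, "da")
        assert len(out) == 6  # all pairs of four groups
        assert set(out["code"]) <= {"***", "**", "*", ".", "ns"}

    def test_agrees_with_scipy_tukey(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "da": np.concatenate([rng.normal(m, 1, 15) for m in (0, 1, 3)]),
            "group": np.repeat(["a", "b", "c"], 15)})
        out = st.anova_pairwise(df, "da")
        groups = [df.loc[df["group"] == g, "da"].to_numpy()
                  for g in ("a", "b", "c")]
        ref = sps.tukey_hsd(*groups)
        expected = {(0, 1): ref.pvalue[0, 1], (0, 2): ref.pvalue[0, 2],
                    (1, 2): ref.pvalue[1, 2]}
        got = dict(zip(zip(out["group1"].map({"a": 0, "b": 1, "c": 2}),
                           out["group2"].map({"a": 0, "b": 1, "c": 2})),
                       out["p_adj"]))
        for pair, p in expected.items():
            assert got[pair] == pytest.approx(p, abs=1e-3)


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        r, p = st.correlation_matrix(df, variables=["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert np.allclose(np.diag(r), 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=2000),
                           "y": rng.normal(size=2000)})
        r, _ = st.correlation_matrix(df, variables=["x", "y"])
        assert abs(r.loc["x", "y"]) < 0.1

    def test_matches_covariance_ratio_formula(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        r, p = st.correlation_matrix(df, variables=["a", "b", "c"])
        for i in "abc":
            for j in "abc":
                x = df[i].to_numpy()
                y = df[j].to_numpy()
                cov = ((x - x.mean()) * (y - y.mean())).sum()
                expect = cov / np.sqrt(((x - x.mean()) ** 2).sum()
                                       * ((y - y.mean()) ** 2).sum())
                assert r.loc[i, j] == pytest.approx(expect)
        assert (p.to_numpy()[~np.eye(3, dtype=bool)] > 0).all()

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(StatsError, match="zero-variance"):
            st.correlation_matrix(df, variables=["a", "b"])


class TestManova:
    def test_permuted_labels_lambda_near_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(400, 3)),
                          columns=["a", "b", "c"])
        df["group"] = rng.permutation(np.repeat(["g1", "g2", "g3", "g4"], 100))
        res = st.manova_wilks(df, variables=["a", "b", "c"])
        assert res["wilks_lambda"] > 0.9

    def test_lambda_equals_product_over_eigenvalues(self, riccardia_table):
        res = st.manova_wilks(riccardia_table)
        model = st.cda_fit(riccardia_table)
        assert res["wilks_lambda"] == pytest.approx(
            np.prod(1.0 / (1.0 + model.eigenvalues)), abs=1e-10)

    def test_two_group_single_variable_matches_t_test(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 25)
        b = rng.normal(1, 1, 30)
        df = pd.DataFrame({"x": np.concatenate([a, b]),
                           "group": ["a"] * 25 + ["b"] * 30})
        res = st.manova_wilks(df, variables=["x"])
        t, p = sps.ttest_ind(a, b)
        n = 55
        assert res["wilks_lambda"] == pytest.approx(
            1.0 / (1.0 + t * t / (n - 2)))
        assert res["p_value"] == pytest.approx(p, rel=1e-6)

    def test_agrees_with_statsmodels(self, riccardia_table):
        from statsmodels.multivariate.manova import MANOVA

        res = st.manova_wilks(riccardia_table)
        sm = MANOVA.from_formula(
            "da + db + dc + bl + bs + ba ~ group", data=riccardia_table)
        table = sm.mv_test().results["group"]["stat"]
        assert res["wilks_lambda"] == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), abs=1e-8)
        assert res["F"] == pytest.approx(
            float(table.loc["Wilks' lambda", "F Value"]), rel=1e-4)


class TestCDAFit:
    def test_eigenvalues_match_brute_force(self, riccardia_table):
        model = st.cda_fit(riccardia_table)
        W, B = scatter_oracle(riccardia_table, model.variables)
        expect = eigen_oracle(W, B, model.n_functions)
        assert np.allclose(model.eigenvalues, expect, atol=1e-8)

    def test_canonical_correlation_identity(self, riccardia_table):
        model = st.cda_fit(riccardia_table)
        assert np.allclose(
            model.canonical_correlations ** 2,
            model.eigenvalues / (1 + model.eigenvalues), atol=1e-10)

    def test_function_count_and_proportions(self, riccardia_table):
        model = st.cda_fit(riccardia_table)
        assert model.n_functions == 3  # min(g-1, p) = min(3, 6)
        assert model.proportions.sum() == pytest.approx(1.0)
        assert (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_two_group_coefficients_collinear_with_closed_form(self):
        rng = np.random.default_rng(7)
        n = 60
        X = rng.normal(size=(2 * n, 4)) @ rng.normal(size=(4, 4))
        X[n:] += rng.normal(size=4)
        df = pd.DataFrame(X, columns=list("abcd"))
        df["group"] = ["g1"] * n + ["g2"] * n
        model = st.cda_fit(df, variables=list("abcd"))
        assert model.n_functions == 1
        W, _ = scatter_oracle(df, list("abcd"))
        mu1 = X[:n].mean(axis=0)
        mu2 = X[n:].mean(axis=0)
        direction = np.linalg.solve(W, mu1 - mu2)
        v = model.raw_coefficients[:, 0]
        cos = np.dot(v, direction) / (np.linalg.norm(v)
                                      * np.linalg.norm(direction))
        assert abs(abs(cos) - 1.0) < 1e-8

    def test_no_between_group_signal_flagged(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        base = df.iloc[:40].copy()
        mirrored = base.copy()
        df = pd.concat([base, mirrored], ignore_index=True)
        df["group"] = ["g1"] * 40 + ["g2"] * 40  # identical group data
        model = st.cda_fit(df, variables=["a", "b"])
        assert model.eigenvalues[0] == pytest.approx(0.0, abs=1e-10)
        assert np.isnan(model.proportions).all() or \
            model.eigenvalues.sum() > 0

    def test_unit_within_group_variance_of_scores(self, riccardia_table):
        model = st.cda_fit(riccardia_table)
        scores = model.transform(riccardia_table)
        groups = riccardia_table["group"]
        n, g = len(groups), groups.nunique()
        pooled = np.zeros(model.n_functions)
        for grp in groups.unique():
            sub = scores[(groups == grp).to_numpy()]
            pooled += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
        assert np.allclose(pooled / (n - g), 1.0, atol=1e-10)


class TestCDAClassify:
    def test_separated_clusters_perfectly_classified(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, (40, 3))
        b = rng.normal(10, 1, (40, 3))
        df = pd.DataFrame(np.vstack([a, b]), columns=["x", "y", "z"])
        df["group"] = ["g1"] * 40 + ["g2"] * 40
        model = st.cda_fit(df, variables=["x", "y", "z"])
        mat, rate = st.cda_classify(model, df)
        assert rate == 1.0

    def test_row_sums_equal_group_sizes(self, riccardia_table):
        model = st.cda_fit(riccardia_table)
        mat, rate = st.cda_classify(model, riccardia_table)
        sizes = riccardia_table.groupby("group").size()
        for grp in sizes.index:
            assert mat.loc[grp].sum() == sizes[grp]
        assert 0 <= rate <= 1

    def test_affine_rescaling_invariance(self, riccardia_table):
        model = st.cda_fit(riccardia_table)
        _, rate = st.cda_classify(model, riccardia_table)
        scaled = riccardia_table.copy()
        for v in st.DEFAULT_VARIABLES:
            scaled[v] = scaled[v] * 3.7 - 11.0
        model2 = st.cda_fit(scaled)
        _, rate2 = st.cda_classify(model2, scaled)
        assert rate2 == pytest.approx(rate)

    def test_variable_mismatch_rejected(self, riccardia_table):
        model = st.cda_fit(riccardia_table)
        with pytest.raises(StatsError, match="mismatch"):
            st.cda_classify(model, riccardia_table.drop(columns=["da"]))

    def test_classification_beats_chance_on_riccardia_sim(self):
        for seed in range(5):
            df = tm.generate_group_tables(seed=seed)
            model = st.cda_fit(df)
            _, rate = st.cda_classify(model, df)
            assert rate > 0.25


class TestSignificanceCodes:
    @pytest.mark.parametrize("p,code", [
        (0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.07, "."),
        (0.5, "ns"),
    ])
    def test_thresholds(self, p, code):
        assert st.significance_code(p) == code


class TestNormality:
    def test_shapiro_reported_per_group_variable(self, riccardia_table):
        out = st.normality(riccardia_table)
        assert len(out) == 4 * 6
        assert ((out["W"] > 0) & (out["W"] <= 1)).all()
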