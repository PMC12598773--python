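import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ecoplace.stats import linear_regression, pearson_matrix, rda


class TestPearson:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [3.0, 5, 7, 9]})
        out = pearson_matrix(df).set_index(["var1", "var2"])
        assert out.loc[("x", "y"), "r"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.array([1.0, 2, 5, 7, 9])
        df = pd.DataFrame({"x": x, "y": -x})
        out = pearson_matrix(df).set_index(["var1", "var2"])
        assert out.loc[("x", "y"), "r"] == pytest.approx(-1.0)

    def test_matches_scipy_oracle_to_1e10(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)),
                          columns=list("abcd"))
        out = pearson_matrix(df).set_index(["var1", "var2"])
        for i, a in enumerate("abcd"):
            for b in "abcd"[i + 1:]:
                r_ref, p_ref = sps.pearsonr(df[a], df[b])
                assert out.loc[(a, b), "r"] == pytest.approx(r_ref, abs=1e-10)
                assert out.loc[(a, b), "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        out = pearson_matrix(df).set_index(["var1", "var2"])
        for v in "abc":
            assert out.loc[(v, v), "r"] == pytest.approx(1.0)

    def test_pairwise_complete_deletion(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, np.nan, 5, 6],
                           "y": [2.0, 4, 6, 8, 10, 12]})
        out = pearson_matrix(df).set_index(["var1", "var2"])
        assert out.loc[("x", "y"), "n"] == 5
        assert out.loc[("x", "y"), "r"] == pytest.approx(1.0)

    def test_zero_variance_is_missing(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        out = pearson_matrix(df).set_index(["var1", "var2"])
        assert np.isnan(out.loc[("x", "y"), "r"])

    def test_min_n_enforced(self):
        df = pd.DataFrame({"x": [1.0, 2, np.nan, np.nan],
                           "y": [2.0, 5, 1, 1]})
        out = pearson_matrix(df, min_n=3).set_index(["var1", "var2"])
        assert np.isnan(out.loc[("x", "y"), "r"])


class TestLinearRegression:
    def test_identity(self):
        x = np.arange(6.0)
        res = linear_regression(x, x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_constant_response(self):
        res = linear_regression(np.arange(5.0), np.full(5, 3.0))
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_matches_scipy_oracle_to_1e10(self, rng):
        x = rng.normal(size=12)
        y = 2.0 * x + rng.normal(size=12)
        res = linear_regression(x, y)
        ref = sps.linregress(x, y)
        assert res.slope == pytest.approx(ref.slope, abs=1e-10)
        assert res.intercept == pytest.approx(ref.intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(ref.rvalue ** 2, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestRda:
    def _random_xy(self, rng, n=20, p=4, q=5, noise=1.0):
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"x{i}" for i in range(p)])
        B = rng.normal(size=(p, q))
        Y = pd.DataFrame(X.to_numpy() @ B + noise * rng.normal(size=(n, q)),
                         columns=[f"y{i}" for i in range(q)])
        return X, Y

    def test_exact_linear_map_fully_constrained(self, rng):
        X, Y = self._random_xy(rng, noise=0.0)
        res = rda(Y, X)
        assert res.constrained_proportion == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictors_explain_nothing(self, rng):
        # Y varies along one coordinate; X is constructed orthogonal to it
        n = 12
        y = rng.normal(size=n)
        y = y - y.mean()
        x = rng.normal(size=n)
        x = x - x.mean()
        x = x - (x @ y) / (y @ y) * y     # project out y
        res = rda(pd.DataFrame({"y": y}), pd.DataFrame({"x": x}))
        assert res.constrained_proportion == pytest.approx(0.0, abs=1e-10)

    def test_matches_bruteforce_projection_ss_ratio(self, rng):
        X, Y = self._random_xy(rng, n=20, p=4)
        res = rda(Y, X)
        # independent oracle: hat-matrix projection of centered Y
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        Xz = X.to_numpy() - X.to_numpy().mean(axis=0)
        Xz = Xz / Xz.std(axis=0, ddof=1)
        H = Xz @ np.linalg.inv(Xz.T @ Xz) @ Xz.T
        expected = np.sum((H @ Yc) ** 2) / np.sum(Yc ** 2)
        assert res.constrained_proportion == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_predictor_rotation(self, rng):
        X, Y = self._random_xy(rng, n=18, p=3)
        res1 = rda(Y, X)
        R = sps.ortho_group.rvs(3, random_state=42)
        X2 = pd.DataFrame(X.to_numpy() @ R, columns=X.columns)
        res2 = rda(Y, X2)
        assert res1.constrained_proportion == pytest.approx(
            res2.constrained_proportion, abs=1e-10)

    def test_eigenvalues_sorted_axes_orthogonal(self, rng):
        X, Y = self._random_xy(rng, n=25, p=3, q=4)
        res = rda(Y, X)
        eig = res.eigenvalues
        assert np.all(np.diff(eig) <= 1e-12) and np.all(eig >= 0)
        S = res.site_scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_collinear_predictor_dropped_with_warning(self, rng):
        X, Y = self._random_xy(rng, n=15, p=3)
        X["dup"] = X["x0"] * 2.0
        with pytest.warns(UserWarning, match="collinear"):
            res = rda(Y, X)
        assert "dup" in res.dropped_predictors or "x0" in res.dropped_predictors

    def test_too_few_samples_rejected(self, rng):
        X, Y = self._random_xy(rng, n=5, p=4)
        with pytest.raises(ValueError):
            rda(Y, X)


def test_depth_driven_clade_correlates_strongest_with_depth(rng):
    """A clade generated from depth via a logistic beats unrelated clades
    in |r| against depth."""
    from ecoplace.synth import logistic_deep_fraction
    depth = np.tile(np.arange(25.0, 525.0, 50.0), 6)
    deep = logistic_deep_fraction(depth, 250.0, 0.02) + rng.normal(
        0, 0.05, size=len(depth))
    unrelated = pd.DataFrame(rng.normal(size=(len(depth), 3)),
                             columns=["u1", "u2", "u3"])
    df = unrelated.assign(deep=deep, depth=depth)
    out = pearson_matrix(df).set_index(["var1", "var2"])

    def r_with_depth(v):
        key = (v, "depth") if (v, "depth") in out.index else ("depth", v)
        return abs(out.loc[key, "r"])

    assert r_with_depth("deep") > max(r_with_depth(u) for u in ["u1", "u2", "u3"])
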