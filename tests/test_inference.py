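import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from phylofauna.errors import DegenerateScalingError, RankDeficiencyError, ValidationError
from phylofauna.inference import (
    ModelResult,
    ModelSpec,
    build_report,
    fit_interaction_model,
    median_split,
    pearson_screen,
    vegetation_factors,
    vif,
    zscale,
)


def ols_oracle(X, y):
    """Independent closed-form normal-equations solve with intercept."""
    Xc = np.column_stack([np.ones(len(X)), X])
    XtX = Xc.T @ Xc
    beta = np.linalg.solve(XtX, Xc.T @ y)
    resid = y - Xc @ beta
    df = len(y) - Xc.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    t = beta / se
    p = 2 * scipy.stats.t.sf(np.abs(t), df)
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1 - resid @ resid / tss
    adj = 1 - (1 - r2) * (len(y) - 1) / df
    return beta, se, t, p, r2, adj


def make_data(rng, n=19, interaction_beta=0.0, noise=1.0):
    df = pd.DataFrame(
        {
            "veg_source": rng.integers(0, 2, n),
            "ses_mpd": rng.normal(size=n),
            "cwm_sla": rng.normal(20, 3, n),
            "rao_sla": rng.uniform(0, 0.5, n),
        },
        index=[f"site{i}" for i in range(n)],
    )
    df["y"] = (
        0.5 * df["ses_mpd"]
        + interaction_beta * df["ses_mpd"] * df["rao_sla"]
        + rng.normal(0, noise, n)
    )
    return df


class TestZscale:
    def test_symmetric_triple(self):
        np.testing.assert_allclose(zscale(np.array([1.0, 2, 3])), [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 3, 100)
        z = zscale(x)
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_hand_oracle(self):
        x = np.array([2.0, 4, 4, 4, 5, 5, 7, 9])
        sd = math.sqrt(32 / 7)  # mean 5, SS 32, n-1 = 7
        np.testing.assert_allclose(zscale(x), (x - 5) / sd)

    def test_constant_raises(self):
        with pytest.raises(DegenerateScalingError):
            zscale(np.array([3.0, 3, 3]))


class TestFitInteractionModel:
    def spec(self, **kw):
        return ModelSpec(response="y", trait="sla", **kw)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            df = make_data(rng)
            res = fit_interaction_model(df, self.spec(max_outliers=0))
            # rebuild the exact design the model used
            X = pd.DataFrame(index=df.index)
            for c in ("veg_source", "ses_mpd", "cwm_sla", "rao_sla"):
                X[c] = zscale(df[c].astype(float).to_numpy())
            X["phylodiv:funtraitdiv"] = X["ses_mpd"] * X["rao_sla"]
            beta, se, t, p, r2, adj = ols_oracle(X.to_numpy(), df["y"].to_numpy())
            for k, term in enumerate(res.terms, start=1):
                assert res.coef[term] == pytest.approx(beta[k], abs=1e-8)
                assert res.se[term] == pytest.approx(se[k], abs=1e-8)
                assert res.t[term] == pytest.approx(t[k], abs=1e-8)
                assert res.p[term] == pytest.approx(p[k], abs=1e-8)
            assert res.r2 == pytest.approx(r2, abs=1e-10)
            assert res.adj_r2 == pytest.approx(adj, abs=1e-10)

    def test_perfect_fit_flagged(self):
        rng = np.random.default_rng(1)
        df = make_data(rng, noise=1.0)
        df["y"] = 2.0 * df["ses_mpd"]  # exactly linear in one predictor
        res = fit_interaction_model(df, self.spec(max_outliers=0))
        assert res.perfect_fit
        assert res.r2 == pytest.approx(1.0)
        assert abs(res.t["ses_mpd"]) >= 1e5

    def test_pure_noise_t_bounded(self):
        rng = np.random.default_rng(7)
        df = make_data(rng, n=1000, noise=1.0)
        df["y"] = rng.normal(size=1000)
        res = fit_interaction_model(df, self.spec(max_outliers=0))
        assert all(abs(t) < 4 for t in res.t.values())
        assert res.r2 < 0.02

    def test_singular_design_raises(self):
        rng = np.random.default_rng(2)
        df = make_data(rng)
        df["cwm_sla"] = 2 * df["ses_mpd"] + 1  # exact collinearity
        with pytest.raises(RankDeficiencyError):
            fit_interaction_model(df, self.spec(max_outliers=0))

    def test_t_p_invariant_to_affine_predictor_rescaling(self):
        rng = np.random.default_rng(3)
        df = make_data(rng)
        res1 = fit_interaction_model(df, self.spec(max_outliers=0))
        df2 = df.copy()
        df2["cwm_sla"] = df2["cwm_sla"] * 100 - 7
        res2 = fit_interaction_model(df2, self.spec(max_outliers=0))
        for term in res1.terms:
            assert res1.t[term] == pytest.approx(res2.t[term], rel=1e-9)
            assert res1.p[term] == pytest.approx(res2.p[term], rel=1e-9)

    def test_listwise_deletion(self):
        rng = np.random.default_rng(4)
        df = make_data(rng)
        df.loc["site0", "rao_sla"] = np.nan
        res = fit_interaction_model(df, self.spec(max_outliers=0))
        assert res.n_used == 18


class TestOutlierExclusion:
    def spec(self, **kw):
        return ModelSpec(response="y", trait="sla", **kw)

    def test_clean_data_no_exclusions(self):
        rng = np.random.default_rng(0)
        df = make_data(rng, n=40, noise=0.5)
        res = fit_interaction_model(df, self.spec())
        assert res.excluded == []

    def test_planted_outlier_recovered(self):
        rng = np.random.default_rng(11)
        df = make_data(rng, n=40, noise=0.5)
        df.loc["site5", "y"] += 10 * 0.5  # 10 residual SDs
        res = fit_interaction_model(df, self.spec())
        assert res.excluded == ["site5"]

    def test_cap_at_three_with_warning(self):
        rng = np.random.default_rng(12)
        df = make_data(rng, n=60, noise=0.5)
        planted = ["site1", "site2", "site3", "site4"]
        for s in planted:
            df.loc[s, "y"] += 12 * 0.5 * rng.choice([-1, 1])
        with pytest.warns(UserWarning, match="cap"):
            res = fit_interaction_model(df, self.spec())
        assert len(res.excluded) == 3
        assert set(res.excluded) <= set(planted)

    def test_idempotent_once_clean(self):
        rng = np.random.default_rng(13)
        df = make_data(rng, n=40, noise=0.5)
        df.loc["site7", "y"] += 8
        res1 = fit_interaction_model(df, self.spec())
        df2 = df.drop(index=res1.excluded)
        res2 = fit_interaction_model(df2, self.spec())
        assert res2.excluded == []
        assert res2.coef == pytest.approx(res1.coef)


class TestVif:
    def test_orthogonal_unity(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        out = vif(X)
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_duplicate_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        out = vif(X)
        assert math.isinf(out["a"])

    def test_closed_form_correlation(self):
        # construct two vectors with sample correlation exactly 0.6
        u = zscale(np.array([1.0, -1, 1, -1, 1, -1]))
        v = zscale(np.array([1.0, 1, -1, -1, 1, -1]))
        v = zscale(v - v @ u / (len(u) - 1) * u)  # orthogonalize
        y = 0.6 * u + 0.8 * v
        X = pd.DataFrame({"a": u, "b": y})
        out = vif(X)
        assert out["a"] == pytest.approx(1 / (1 - 0.36), rel=1e-9)


class TestPearsonScreen:
    def test_perfect_correlations(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4]})
        df["double"] = 2 * df["x"]
        df["neg"] = -df["x"]
        r, p = pearson_screen(df)
        assert r.loc["x", "double"] == pytest.approx(1.0)
        assert r.loc["x", "neg"] == pytest.approx(-1.0)
        assert np.all(np.diag(r) == 1.0)

    def test_hand_covariance(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 4, 3]})
        r, p = pearson_screen(df)
        assert r.loc["x", "y"] == pytest.approx(0.6)

    def test_constant_column_nan(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        r, _ = pearson_screen(df)
        assert math.isnan(r.loc["x", "c"])

    def test_pairwise_deletion(self):
        df = pd.DataFrame(
            {"x": [1.0, 2, 3, 4, np.nan], "y": [2.0, 4, 6, 8, 100], "z": [1.0, 1, 2, np.nan, 3]}
        )
        r, _ = pearson_screen(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)  # NaN row dropped pairwise


class TestVegetationFactors:
    def test_rank_one_gradient(self):
        grad = np.linspace(0, 1, 8)
        comm = pd.DataFrame({"spA": grad, "spB": 1 - grad})
        with pytest.warns(UserWarning, match="non-degenerate"):
            scores = vegetation_factors(comm)
        assert scores.shape[1] == 1  # single non-degenerate axis

    def test_species_permutation_invariance(self):
        rng = np.random.default_rng(0)
        comm = pd.DataFrame(rng.dirichlet(np.ones(6), size=10), columns=list("abcdef"))
        s1 = vegetation_factors(comm)
        s2 = vegetation_factors(comm[list("fedcba")])
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        comm = pd.DataFrame(rng.uniform(size=(10, 6)))
        scores = vegetation_factors(comm).to_numpy()
        X = comm.to_numpy() - comm.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        oracle = X @ evecs[:, order[:2]]
        for c in range(2):
            col = oracle[:, c]
            match = min(
                np.abs(scores[:, c] - col).max(), np.abs(scores[:, c] + col).max()
            )
            assert match < 1e-8

    def test_too_small_raises(self):
        with pytest.raises(ValidationError):
            vegetation_factors(pd.DataFrame({"a": [1.0, 2]}))


class TestMedianSplit:
    def test_even_split(self):
        labels, thr = median_split(pd.Series([-2.0, -1, 0, 1]))
        assert thr == pytest.approx(-0.5)
        assert list(labels) == ["below", "below", "above", "above"]

    def test_all_equal_warns(self):
        with pytest.warns(UserWarning):
            labels, _ = median_split(pd.Series([1.0, 1, 1]))
        assert set(labels) == {"below"}

    def test_tie_goes_below(self):
        labels, thr = median_split(pd.Series([-1.9, -0.8, 0.3]))
        assert thr == pytest.approx(-0.8)
        assert list(labels) == ["below", "below", "above"]


class TestBuildReport:
    def res(self, p_int):
        return ModelResult(
            response="log_abund_springtail",
            trait="sla",
            terms=["ses_mpd", "phylodiv:funtraitdiv"],
            coef={"ses_mpd": 0.5, "phylodiv:funtraitdiv": 0.3, "const": 1.0},
            se={"ses_mpd": 0.2, "phylodiv:funtraitdiv": 0.1},
            t={"ses_mpd": 2.5, "phylodiv:funtraitdiv": 3.0},
            p={"ses_mpd": 0.049, "phylodiv:funtraitdiv": p_int},
            r2=0.5,
            adj_r2=0.4,
            vif={"ses_mpd": 1.1, "phylodiv:funtraitdiv": 1.2},
            n_used=19,
        )

    def test_one_row_per_model(self):
        report = build_report([self.res(0.2), self.res(0.3)])
        assert len(report) == 2
        assert report.loc[0, "n_sites"] == 19

    def test_significance_marks(self):
        report = build_report([self.res(0.07)])
        cell_sig = report.loc[0, "ses_mpd"]
        cell_marg = report.loc[0, "phylodiv:funtraitdiv"]
        assert cell_sig.endswith("**")
        assert cell_marg.endswith(".")

    def test_boundary_p05_is_marginal(self):
        report = build_report([self.res(0.05)])
        assert report.loc[0, "phylodiv:funtraitdiv"].endswith(".")

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            build_report([])
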