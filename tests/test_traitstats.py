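import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pilosity.traitstats import (
    GLOBAL_PREDICTORS,
    ModelSpec,
    aicc,
    complete_cases,
    enumerate_models,
    fit_ols,
    rank_models,
    read_trait_csv,
    vif,
)


def table_from(cols: dict) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    df.insert(0, "species", [f"s{i}" for i in range(len(df))])
    return df


class TestFitOls:
    def test_hand_computed_least_squares(self):
        t = table_from({"face": [1.0, 2.0, 3.0], "svd": [1.0, 2.0, 4.0]})
        f = fit_ols(t, ModelSpec("svd", ("face",)))
        assert f.coefficients["face"] == pytest.approx(1.5)
        assert f.coefficients["(intercept)"] == pytest.approx(-2 / 3)
        assert f.rss == pytest.approx(1 / 6)
        assert f.r2 == pytest.approx(27 / 28)  # 0.9643
        assert f.adj_r2 == pytest.approx(13 / 14)  # 0.9286

    def test_perfect_fit_degenerate_sentinel(self):
        t = table_from({"face": [1.0, 2.0, 3.0, 4.0], "svd": [2.0, 4.0, 6.0, 8.0]})
        f = fit_ols(t, ModelSpec("svd", ("face",)))
        assert f.degenerate and math.isinf(f.loglik)
        assert f.r2 == pytest.approx(1.0)

    def test_duplicated_predictor_rank_deficient(self):
        t = table_from(
            {"face": [1.0, 2.0, 3.0, 5.0], "head_dorsal": [2.0, 4.0, 6.0, 10.0],
             "svd": [1.0, 2.0, 4.0, 9.0]}
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(t, ModelSpec("svd", ("face", "head_dorsal")))

    def test_insufficient_rows(self):
        t = table_from({"face": [1.0, 2.0], "svd": [1.0, 2.0]})
        with pytest.raises(ValueError, match="insufficient"):
            fit_ols(t, ModelSpec("svd", ("face",)))

    def test_matches_statsmodels(self, rng):
        # independent route: same fit through statsmodels OLS
        import statsmodels.api as sm

        X = rng.normal(size=(12, 3))
        y = X @ [1.0, -0.5, 2.0] + rng.normal(size=12)
        t = table_from(
            {"face": X[:, 0], "head_dorsal": X[:, 1], "body_length": X[:, 2], "svd": y}
        )
        f = fit_ols(t, ModelSpec("svd", ("face", "head_dorsal", "body_length")))
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert f.r2 == pytest.approx(ref.rsquared)
        assert f.adj_r2 == pytest.approx(ref.rsquared_adj)
        assert f.loglik == pytest.approx(ref.llf)

    def test_interaction_term_built_and_marginality_enforced(self, rng):
        X = rng.normal(size=(10, 2))
        y = X[:, 0] * X[:, 1] + rng.normal(size=10)
        t = table_from({"face": X[:, 0], "body_length": X[:, 1], "svd": y})
        spec = ModelSpec("svd", ("face", "body_length"), (("body_length", "face"),))
        f = fit_ols(t, spec)
        assert "body_length:face" in f.coefficients
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec("svd", ("face",), (("body_length", "face"),))


class TestAicc:
    def test_small_sample_correction_value(self):
        # n = 10, k = 4: correction 2*4*5/5 = 8
        assert aicc(0.0, 4, 10) == pytest.approx(2 * 4 + 8)

    def test_approaches_aic_for_large_n(self):
        n = 10**7
        assert aicc(-50.0, 4, n) == pytest.approx(108.0, abs=2 * 4 * 5 / (n - 5))

    def test_undefined_when_saturated(self):
        with pytest.raises(ValueError):
            aicc(0.0, 9, 10)


class TestEnumerate:
    def test_power_set_of_three(self):
        specs = enumerate_models(ModelSpec("svd", ("a", "b", "c")))
        assert len(specs) == 8

    def test_full_global_512(self):
        specs = enumerate_models(ModelSpec("svd", GLOBAL_PREDICTORS))
        assert len(specs) == 512

    def test_marginality_property(self):
        gs = ModelSpec(
            "svd", ("face", "body_length", "head_dorsal"), (("body_length", "face"),)
        )
        specs = enumerate_models(gs)
        for s in specs:
            if ("body_length", "face") in s.interactions:
                assert "body_length" in s.mains and "face" in s.mains

    def test_size_cap_from_n(self):
        specs = enumerate_models(ModelSpec("svd", GLOBAL_PREDICTORS), n=10)
        assert max(s.n_terms for s in specs) == 6  # n - 4


class TestRankModels:
    def test_single_candidate(self, rng):
        t = table_from(
            {"face": rng.normal(size=8), "svd": rng.normal(size=8)}
        )
        rk = rank_models(t, [ModelSpec("svd", ("face",))])
        assert rk.delta[0] == 0.0
        assert rk.weight[0] == pytest.approx(1.0)
        assert rk.acc_weight[-1] == pytest.approx(1.0)

    def test_known_delta_weights(self, rng):
        # two models with AICc gap 4.80 -> weights 0.9168 / 0.0832
        n = 20
        x1 = rng.normal(size=n)
        y = x1 + 0.3 * rng.normal(size=n)
        t = table_from({"face": x1, "head_dorsal": rng.normal(size=n), "svd": y})
        rk = rank_models(
            t, [ModelSpec("svd", ("face",)), ModelSpec("svd", ("head_dorsal",))]
        )
        # verify the closed form on the exact printed gap
        d = np.array([0.0, 4.80])
        w = np.exp(-d / 2) / np.exp(-d / 2).sum()
        assert w == pytest.approx([0.9168, 0.0832], abs=5e-5)
        # and that rank_models computes weights the same way from its deltas
        expect = np.exp(-rk.delta / 2) / np.exp(-rk.delta / 2).sum()
        np.testing.assert_allclose(rk.weight, expect)

    def test_weights_sum_to_one_and_acc_monotone(self, rng):
        t = table_from(
            {
                "face": rng.normal(size=9),
                "head_dorsal": rng.normal(size=9),
                "body_length": rng.normal(size=9),
                "svd": rng.normal(size=9),
            }
        )
        specs = enumerate_models(
            ModelSpec("svd", ("face", "head_dorsal", "body_length")), n=9
        )
        rk = rank_models(t, specs)
        assert rk.weight.sum() == pytest.approx(1.0)
        assert np.all(np.diff(rk.acc_weight) >= -1e-12)
        assert np.all(rk.delta >= 0) and rk.delta[0] == 0.0

    def test_invariant_to_loglik_constant(self):
        # adding a constant to every log-likelihood shifts every AICc
        # equally: delta and weights are unchanged
        ll = np.array([-40.0, -42.4, -45.0])
        k, n = 3, 10
        a0 = np.array([aicc(l, k, n) for l in ll])
        a1 = np.array([aicc(l + 7.7, k, n) for l in ll])
        np.testing.assert_allclose(a1 - a1.min(), a0 - a0.min(), atol=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        # independent route: statsmodels fits + explicit sort over all
        # subsets of 5 predictors
        import statsmodels.api as sm

        n, preds = 14, ["face", "head_dorsal", "front_leg", "body_length", "thorax_dorsal"]
        X = rng.normal(size=(n, 5))
        y = X[:, 0] - X[:, 4] + rng.normal(size=n)
        t = table_from({p: X[:, i] for i, p in enumerate(preds)} | {"svd": y})
        specs = [
            ModelSpec("svd", subset)
            for size in range(6)
            for subset in itertools.combinations(preds, size)
        ]
        rk = rank_models(t, specs)

        oracle = []
        for size in range(6):
            for subset in itertools.combinations(range(5), size):
                Xs = sm.add_constant(X[:, list(subset)]) if subset else np.ones((n, 1))
                res = sm.OLS(y, Xs).fit()
                kk = len(subset) + 2
                a = 2 * kk - 2 * res.llf + 2 * kk * (kk + 1) / (n - kk - 1)
                oracle.append((a, tuple(preds[i] for i in subset)))
        oracle.sort(key=lambda t_: (t_[0], len(t_[1]), t_[1]))
        assert [f.spec.mains for f in rk.fits] == [m for _, m in oracle]
        np.testing.assert_allclose(
            [f.aicc for f in rk.fits], [a for a, _ in oracle], rtol=1e-10
        )

    def test_degenerate_fit_ranks_first_without_weight(self):
        t = table_from(
            {
                "face": [1.0, 2.0, 3.0, 4.0, 5.0, 6.5],
                "head_dorsal": [2.0, 1.0, 4.0, 3.5, 5.0, 6.0],
                "svd": [2.0, 4.0, 6.0, 8.0, 10.0, 13.0],
            }
        )
        specs = enumerate_models(ModelSpec("svd", ("face", "head_dorsal")))
        rk = rank_models(t, specs)
        assert rk.top.spec.mains == ("face",)  # fewest-term perfect fit
        assert math.isnan(rk.weight[0])
        finite = ~np.isnan(rk.weight)
        assert rk.weight[finite].sum() == pytest.approx(1.0)

    def test_removing_predictor_never_increases_r2(self, rng):
        t = table_from(
            {
                "face": rng.normal(size=10),
                "head_dorsal": rng.normal(size=10),
                "svd": rng.normal(size=10),
            }
        )
        full = fit_ols(t, ModelSpec("svd", ("face", "head_dorsal")))
        sub = fit_ols(t, ModelSpec("svd", ("face",)))
        assert sub.r2 <= full.r2 + 1e-12


class TestVif:
    def test_orthogonal_predictors(self):
        t = table_from(
            {"face": [1.0, -1.0, 1.0, -1.0], "head_dorsal": [1.0, 1.0, -1.0, -1.0]}
        )
        v = vif(t, ["face", "head_dorsal"])
        assert v["face"] == pytest.approx(1.0)
        assert v["head_dorsal"] == pytest.approx(1.0)

    def test_correlation_point_six(self):
        # construct exact sample correlation 0.6: VIF = 1/(1-0.36) = 1.5625
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        e = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])  # mean 0, orthogonal to x
        e *= math.sqrt((x @ x) / (e @ e))  # equal norm
        z = 0.6 * x + math.sqrt(1 - 0.36) * e
        t = table_from({"face": x, "head_dorsal": z})
        v = vif(t, ["face", "head_dorsal"])
        assert v["face"] == pytest.approx(1.5625)
        assert v["head_dorsal"] == pytest.approx(1.5625)

    def test_duplicated_predictor_infinite(self):
        t = table_from(
            {"face": [1.0, 2.0, 3.0, 4.0, 5.0], "head_dorsal": [2.0, 4.0, 6.0, 8.0, 10.0]}
        )
        v = vif(t, ["face", "head_dorsal"])
        assert math.isinf(v["face"])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = rng.normal(size=(15, 3))
        X[:, 2] += 0.8 * X[:, 0]
        t = table_from({"face": X[:, 0], "head_dorsal": X[:, 1], "body_length": X[:, 2]})
        mine = vif(t, ["face", "head_dorsal", "body_length"])
        Xc = np.column_stack([np.ones(15), X])
        for j, name in enumerate(["face", "head_dorsal", "body_length"]):
            ref = variance_inflation_factor(Xc, j + 1)
            assert mine[name] == pytest.approx(ref)


class TestTableIo:
    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        pd.DataFrame({"species": ["a", "a"], "svd": [1, 2]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="duplicated"):
            read_trait_csv(p)

    def test_complete_cases_drops_missing(self):
        t = table_from(
            {"face": [1.0, np.nan, 3.0, 4.0], "svd": [1.0, 2.0, np.nan, 4.0]}
        )
        sub = complete_cases(t, "svd", ["face"])
        assert list(sub["species"]) == ["s0", "s3"]
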