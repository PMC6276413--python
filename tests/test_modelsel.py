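import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from lipidgrs import modelsel as ms


def _toy_data(seed=0, n=80, betas=(3.0, -2.0, 0.0, 0.0), sd=1.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, len(betas))),
                     columns=[f"x{i}" for i in range(len(betas))])
    y = pd.Series(X.to_numpy() @ np.asarray(betas)
                  + rng.normal(0, sd, n), name="y")
    return y, X


class TestOlsFit:
    def test_exact_linear_response_gives_r2_one(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.standard_normal(30)})
        y = 2.0 + 5.0 * X["x"]
        fit = ms.ols_fit(y, X)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.bse["x"] == pytest.approx(0.0, abs=1e-10)

    def test_coefficients_match_normal_equations(self):
        # independent oracle: solve (Z'Z) beta = Z'y directly
        X = pd.DataFrame({
            "x1": [1.2, 0.5, -0.3, 2.2, 1.9, -1.1, 0.0, 0.7, -0.6, 1.4],
            "x2": [0.3, -1.2, 0.8, 0.1, -0.5, 1.7, 0.9, -0.4, 0.2, -1.0]})
        y = pd.Series([3.1, -0.2, 0.5, 5.0, 3.8, -1.5, 1.0, 1.9, -0.7, 2.6])
        Z = np.column_stack([np.ones(10), X.to_numpy()])
        beta_expected = np.linalg.solve(Z.T @ Z, Z.T @ y.to_numpy())
        fit = ms.ols_fit(y, X)
        assert fit.params.to_numpy() == pytest.approx(beta_expected, rel=1e-10)

    def test_rank_deficiency_names_the_collinear_column(self):
        y, X = _toy_data()
        X = X.copy()
        X["dup"] = 2.0 * X["x0"]
        with pytest.raises(ValueError, match="dup"):
            ms.ols_fit(y, X)

    def test_too_few_observations_rejected(self):
        y, X = _toy_data(n=4)
        with pytest.raises(ValueError, match="n > p"):
            ms.ols_fit(y, X)


class TestAdjustedR2:
    def test_identity_against_direct_formula(self):
        assert ms.adjusted_r2(0.2578, 304, 3) == pytest.approx(
            1 - (1 - 0.2578) * 303 / 300)

    def test_matches_statsmodels_on_a_fit(self):
        y, X = _toy_data(seed=2)
        fit = ms.ols_fit(y, X)
        assert ms.adjusted_r2(fit.r2, fit.nobs, len(fit.predictors)
                              ) == pytest.approx(fit.adj_r2, abs=1e-12)


class TestBestSubset:
    def test_matches_independent_exhaustive_enumeration(self):
        """The returned subset equals the argmin over all 16 subsets of 4
        candidates, with the criterion recomputed independently from
        first principles (lstsq RSS + Gaussian log-likelihood)."""
        y, X = _toy_data(seed=3, n=60, betas=(2.0, -1.0, 0.4, 0.0))
        n = len(y)

        def crit_indep(subset, which):
            Z = np.column_stack([np.ones(n), X[list(subset)].to_numpy()])
            resid = y.to_numpy() - Z @ np.linalg.lstsq(Z, y.to_numpy(),
                                                       rcond=None)[0]
            rss = float(resid @ resid)
            llf = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1)
            k = len(subset) + 2
            if which == "aic":
                return -2 * llf + 2 * k
            if which == "bic":
                return -2 * llf + k * np.log(n)
            return -2 * llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)

        for criterion in ("aic", "aicc", "bic"):
            scores = {
                subset: crit_indep(subset, criterion)
                for r in range(5)
                for subset in itertools.combinations(X.columns, r)
            }
            expected = min(scores, key=lambda s: (round(scores[s], 9), len(s), s))
            fit = ms.best_subset(y, X, criterion=criterion)
            assert tuple(fit.predictors) == expected
            # the report's criterion value agrees with the enumeration
            assert getattr(fit, criterion) == pytest.approx(
                scores[expected], rel=1e-12)

    def test_full_size_model_matches_ols_criterion(self):
        y, X = _toy_data(seed=4)
        full = ms.ols_fit(y, X)
        gram = ms._GramRss(y, X)
        rss_full = gram.rss(list(range(X.shape[1])))
        aic, _, _ = ms._criteria_from_rss(rss_full, len(y), X.shape[1] + 1)
        assert aic == pytest.approx(full.aic, rel=1e-12)

    def test_empty_candidates_return_intercept_only(self):
        y, _ = _toy_data()
        fit = ms.best_subset(y, pd.DataFrame(index=y.index))
        assert fit.predictors == []
        assert fit.r2 == 0.0

    def test_bic_model_nested_in_aic_model_on_weak_predictor_fixture(self):
        y, X = _toy_data(seed=5, n=120, betas=(2.0, 0.25, 0.0, 0.0))
        aic_fit = ms.best_subset(y, X, "aic")
        bic_fit = ms.best_subset(y, X, "bic")
        assert set(bic_fit.predictors) <= set(aic_fit.predictors)
        assert len(bic_fit.predictors) < len(aic_fit.predictors)

    def test_strong_predictor_found_among_noise(self):
        """BIC consistency: a unit-effect predictor is always selected; the
        support is exactly {x3} in most replicates (each noise candidate
        enters with probability ~P(t^2 > log n) ~ 1.7% at n=300, so ~88%
        of replicates are exact with 7 noise candidates)."""
        exact = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(rng.standard_normal((300, 8)),
                             columns=[f"x{i}" for i in range(8)])
            y = pd.Series(1.0 * X["x3"] + rng.normal(0, 1.0, 300))
            fit = ms.best_subset(y, X, "bic")
            assert "x3" in fit.predictors
            exact += fit.predictors == ["x3"]
        assert exact >= 16


class TestLars:
    def test_first_entry_is_max_marginal_correlation_in_orthonormal_design(self):
        rng = np.random.default_rng(6)
        Q, _ = np.linalg.qr(rng.standard_normal((50, 4)))
        X = pd.DataFrame(Q, columns=list("abcd"))
        y = pd.Series(3.0 * Q[:, 2] + 0.5 * Q[:, 0] + rng.normal(0, 0.1, 50))
        supports = ms.lars_supports(y, X)
        Xs = (X - X.mean()) / X.std(ddof=0)
        yc = y - y.mean()
        first_expected = X.columns[int(np.argmax(np.abs(Xs.T @ yc)))]
        assert supports[1] == [first_expected]

    def test_path_endpoint_equals_full_ols(self):
        y, X = _toy_data(seed=7, n=60, betas=(2.0, -1.5, 0.8, 0.3))
        supports = ms.lars_supports(y, X)
        assert set(supports[-1]) == set(X.columns)
        # a refit on the endpoint support IS the full OLS model
        endpoint = ms.ols_fit(y, X[supports[-1]])
        full = ms.ols_fit(y, X)
        for name in X.columns:
            assert endpoint.params[name] == pytest.approx(full.params[name],
                                                          rel=1e-10)

    def test_entry_order_on_correlated_two_predictor_fixture(self):
        # x1 carries the signal, x2 = 0.6 x1 + noise: x1 must enter first,
        # then x2 completes the path
        rng = np.random.default_rng(8)
        x1 = rng.standard_normal(100)
        x2 = 0.6 * x1 + 0.8 * rng.standard_normal(100)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        y = pd.Series(2.0 * x1 + rng.normal(0, 0.5, 100))
        supports = ms.lars_supports(y, X)
        assert supports[1] == ["x1"]
        assert set(supports[2]) == {"x1", "x2"}

    def test_constant_predictor_excluded_with_warning(self):
        y, X = _toy_data(seed=9)
        X = X.copy()
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            fit = ms.lars_select(y, X)
        assert "flat" not in fit.predictors


class TestBootstrapStepwise:
    def test_same_seed_reproduces_the_report(self):
        y, X = _toy_data(seed=10, n=150)
        f1 = ms.bootstrap_stepwise(y, X, B=60, seed=42)
        f2 = ms.bootstrap_stepwise(y, X, B=60, seed=42)
        assert f1.predictors == f2.predictors
        pd.testing.assert_series_equal(f1.params, f2.params)

    def test_strong_predictor_has_high_inclusion_frequency(self):
        y, X = _toy_data(seed=11, n=300, betas=(1.0, 0.0, 0.0, 0.0), sd=1.0)
        fit = ms.bootstrap_stepwise(y, X, B=100, seed=1)
        assert fit.inclusion_frequency["x0"] > 0.95
        assert "x0" in fit.predictors

    def test_pure_noise_candidates_yield_intercept_only(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.standard_normal((200, 6)),
                         columns=[f"n{i}" for i in range(6)])
        y = pd.Series(rng.standard_normal(200))
        with pytest.warns(UserWarning, match="threshold"):
            fit = ms.bootstrap_stepwise(y, X, B=80, seed=3)
        assert fit.predictors == []

    def test_small_b_rejected(self):
        y, X = _toy_data()
        with pytest.raises(ValueError, match="B"):
            ms.bootstrap_stepwise(y, X, B=10)


class TestOptimism:
    def test_bookkeeping_identity_is_exact(self):
        y, X = _toy_data(seed=13, n=100)
        sel = ms.make_selector("bsrp", criterion="aic")
        rep = ms.optimism_correct(sel, y, X, B=25, seed=5)
        assert rep.corrected_r2 == rep.apparent_r2 - rep.optimism_r2
        assert rep.corrected_adj_r2 == rep.apparent_adj_r2 - rep.optimism_adj_r2

    def test_noise_free_fixed_model_has_zero_optimism(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame({"x": rng.standard_normal(40)})
        y = 1.0 + 2.0 * X["x"]
        rep = ms.optimism_correct(ms.make_selector("none"), y, X, B=20, seed=6)
        assert rep.optimism_r2 == pytest.approx(0.0, abs=1e-12)
        assert rep.corrected_r2 == pytest.approx(1.0, abs=1e-12)

    def test_selection_over_noise_candidates_is_optimistic(self):
        """Model selection over pure-noise candidates overfits: the mean
        optimism is strictly positive and the correction strips away the
        bulk of the spurious apparent fit.  (With aggressive selection on
        pure noise the corrected R^2 can overshoot below 0 -- models
        selected on a resample predict the original data worse than the
        mean -- so 'closer to zero than apparent' is not guaranteed.)"""
        optimisms, apparents, correcteds = [], [], []
        sel = ms.make_selector("bsrp", criterion="aic")
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            X = pd.DataFrame(rng.standard_normal((100, 10)),
                             columns=[f"n{i}" for i in range(10)])
            y = pd.Series(rng.standard_normal(100))
            rep = ms.optimism_correct(sel, y, X, B=40, seed=seed)
            optimisms.append(rep.optimism_r2)
            apparents.append(rep.apparent_r2)
            correcteds.append(rep.corrected_r2)
        assert np.mean(optimisms) > 0
        assert all(c < a for c, a in zip(correcteds, apparents))
        assert np.mean(correcteds) < 0.5 * np.mean(apparents)

    def test_seed_reproducibility(self):
        y, X = _toy_data(seed=15)
        sel = ms.make_selector("bsrp", criterion="bic")
        r1 = ms.optimism_correct(sel, y, X, B=20, seed=9)
        r2 = ms.optimism_correct(sel, y, X, B=20, seed=9)
        assert r1.optimism_adj_r2 == r2.optimism_adj_r2


class TestSquaredPartialCorrelation:
    def test_single_predictor_pc2_equals_r2(self):
        y, X = _toy_data(seed=16, betas=(2.0,))
        fit = ms.ols_fit(y, X)
        assert fit.pc2["x0"] == pytest.approx(fit.r2, abs=1e-12)

    def test_t_formula_matches_double_residualisation(self):
        y, X = _toy_data(seed=17, n=60, betas=(2.0, -1.0, 0.5, 0.2))
        fit = ms.ols_fit(y, X)
        for j in X.columns:
            others = [c for c in X.columns if c != j]
            Zo = np.column_stack([np.ones(len(y)), X[others].to_numpy()])
            ry = y.to_numpy() - Zo @ np.linalg.lstsq(Zo, y.to_numpy(),
                                                     rcond=None)[0]
            rx = X[j].to_numpy() - Zo @ np.linalg.lstsq(Zo, X[j].to_numpy(),
                                                        rcond=None)[0]
            pc2_oracle = float(np.corrcoef(ry, rx)[0, 1] ** 2)
            assert fit.pc2[j] == pytest.approx(pc2_oracle, abs=1e-10)

    def test_null_predictor_pc2_vanishes_at_large_n(self):
        y, X = _toy_data(seed=18, n=5000, betas=(2.0, 0.0, 0.0, 0.0))
        fit = ms.ols_fit(y, X)
        assert fit.pc2["x1"] < 0.01

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            ms.squared_partial_correlation(pd.Series([1.0]), 0)


class TestInteractionScan:
    def test_built_in_interaction_detected(self):
        rng = np.random.default_rng(19)
        n = 300
        g = rng.integers(0, 6, n).astype(float)
        alcohol = (rng.random(n) < 0.3).astype(float)
        y = pd.Series(2.0 * g + 3.0 * alcohol + 1.5 * g * alcohol
                      + rng.normal(0, 2.0, n))
        out = ms.interaction_scan(y, pd.Series(g),
                                  pd.DataFrame({"alcohol": alcohol}))
        assert out.loc["alcohol", "p_interaction"] < 0.05
        assert out.loc["alcohol", "beta_interaction"] == pytest.approx(1.5,
                                                                       abs=0.5)

    def test_constant_variable_skipped(self):
        rng = np.random.default_rng(20)
        y = pd.Series(rng.standard_normal(50))
        g = pd.Series(rng.integers(0, 4, 50).astype(float))
        out = ms.interaction_scan(y, g, pd.DataFrame({"flat": np.ones(50)}))
        assert bool(out.loc["flat", "skipped"])
        assert np.isnan(out.loc["flat", "p_interaction"])


class TestSelectBestModel:
    def _rep(self, corrected, n_pred):
        fit = ms.FitReport(
            predictors=[f"p{i}" for i in range(n_pred)],
            params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            tvalues=pd.Series(dtype=float), pvalues=pd.Series(dtype=float),
            r2=0.0, adj_r2=0.0, aic=0.0, aicc=0.0, bic=0.0,
            pc2=pd.Series(dtype=float), nobs=304, df_resid=300)
        opt = ms.OptimismReport(0.0, 0.0, 0.0, 0.0, 0.0, corrected, 100, 0)
        return fit, opt

    def test_argmax_of_corrected_adjusted_r2(self):
        reports = {"lars": self._rep(0.2388, 3), "bsrp_aic": self._rep(0.2076, 4),
                   "bsrp_aicc": self._rep(0.2808, 5), "bsm": self._rep(0.2501, 4)}
        assert ms.select_best_model(reports) == "bsrp_aicc"

    def test_tie_breaks_toward_fewer_predictors(self):
        reports = {"big": self._rep(0.25, 5), "small": self._rep(0.25, 3)}
        assert ms.select_best_model(reports) == "small"


def test_candidate_builder_units_and_grs(default_sim):
    from lipidgrs.grs import run_grs_pipeline

    cohort, gm, _ = default_sim
    grs = run_grs_pipeline(cohort, gm).grs
    y, X = ms.build_candidates(cohort, grs, "hdl")
    assert "grs_hdl" in X.columns
    assert X["energy_100kcal"].mean() == pytest.approx(
        cohort.loc[X.index, "energy"].mean() / 100)
    assert set(np.unique(X["sex"])) <= {0.0, 1.0}
    assert len(y) == len(X)
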