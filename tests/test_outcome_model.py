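import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from wmhnet.ordinal import (
    SeparationError,
    extract_effect,
    fit_proportional_odds,
    pseudo_r2,
)
from wmhnet.outcome import (
    ModelConfig,
    dichotomize,
    fdr_adjust,
    residualize,
    run_region_models,
)

from conftest import simulate_po_data


class TestDichotomize:
    def test_33_distinct_median_goes_low(self, rng):
        v = rng.permutation(np.arange(33, dtype=float))
        g = dichotomize(v)
        assert g.sum() == 16 and (g == 0).sum() == 17
        assert g[np.argsort(v)[16]] == 0  # the true median itself is low

    def test_even_distinct(self):
        g = dichotomize(np.array([1.0, 2.0, 3.0, 4.0]))
        assert g.tolist() == [0, 0, 1, 1]

    def test_ties_at_median_go_low(self):
        g = dichotomize(np.array([0.0, 0.0, 0.0, 5.0, 9.0]))
        assert g.tolist() == [0, 0, 0, 1, 1]

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(np.full(10, 0.3))


class TestResidualize:
    def test_orthogonal_covariate_just_centered(self):
        against = np.array([1.0, -1.0, 1.0, -1.0])
        cov = np.array([3.0, 3.0, 5.0, 5.0])  # orthogonal to against
        r = residualize(cov, against)
        assert r == pytest.approx(cov - cov.mean(), abs=1e-12)

    def test_collinear_residuals_zero(self):
        against = np.array([1.0, 2.0, 3.0, 4.0])
        r = residualize(2 * against, against)
        assert np.allclose(r, 0, atol=1e-12)

    def test_six_point_hand_solved_fixture(self):
        # normal equations solved by hand: y = a + b x with
        # x = [0,1,2,3,4,5], y = [1,3,2,5,4,6] -> b = 0.9429..., a = 1.1428...
        x = np.arange(6, dtype=float)
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        a = y.mean() - b * x.mean()
        r = residualize(y, x)
        assert r == pytest.approx(y - (a + b * x), abs=1e-12)

    def test_zero_correlation_exact(self, rng):
        for _ in range(20):
            against = rng.normal(size=25)
            cov = rng.normal(size=25) + 0.5 * against
            r = residualize(cov, against)
            assert abs(np.dot(r, against - against.mean())) < 1e-10
            assert abs(r.mean()) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            residualize(np.arange(4.0), np.ones(4))


class TestFitProportionalOdds:
    def test_binary_reduction_matches_logistic(self, rng):
        X = rng.normal(size=(120, 2))
        y = (X @ [1.0, -0.5] + rng.logistic(size=120) > 0).astype(int)
        fit = fit_proportional_odds(y, X, beta_names=["a", "b"])
        lg = sm.Logit(y, sm.add_constant(X)).fit(disp=False, tol=1e-12)
        assert np.abs(fit.beta - np.asarray(lg.params)[1:]).max() < 1e-6
        # cutpoint is minus the logistic intercept under this convention
        assert fit.cutpoints[0] == pytest.approx(-lg.params[0], abs=1e-6)

    def test_matches_statsmodels_ordered_model(self, rng):
        y, X = simulate_po_data(rng, 300, [0.8, -0.4], [-1.0, 0.5, 1.5])
        fit = fit_proportional_odds(y, X)
        om = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False)
        assert np.abs(fit.beta - np.asarray(om.params)[:2]).max() < 1e-4
        assert fit.loglik == pytest.approx(om.llf, abs=1e-6)

    def test_parameter_recovery_within_3se(self, rng):
        y, X = simulate_po_data(rng, 500, [1.0], [-1.0, 0.0, 1.0])
        fit = fit_proportional_odds(y, X, beta_names=["x"])
        b, se = fit.coef("x")
        assert abs(b - 1.0) < 3 * se

    def test_sign_convention(self, rng):
        # strongly positive slope -> higher x means higher grades
        y, X = simulate_po_data(rng, 400, [2.0], [0.0])
        fit = fit_proportional_odds(y, X)
        assert fit.beta[0] > 0
        assert np.corrcoef(X[:, 0], y)[0, 1] > 0

    def test_perfect_separation_detected(self):
        x = np.linspace(-1, 1, 30)
        y = (x > 0).astype(int)
        with pytest.raises(SeparationError):
            fit_proportional_odds(y, x[:, None])

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            fit_proportional_odds(np.zeros(10, dtype=int), np.ones((10, 1)))

    def test_unobserved_levels_collapse_with_warning(self, rng):
        y = np.array([0, 0, 2, 2, 4, 4, 0, 2, 4, 2] * 4)
        X = rng.normal(size=(40, 1))
        with pytest.warns(UserWarning, match="unobserved"):
            fit = fit_proportional_odds(y, X)
        assert fit.cutpoints.size == 2

    def test_wald_p_uniform_under_permutation(self, rng):
        y, X = simulate_po_data(rng, 80, [0.5], [-1.0, 0.5])
        pvals = []
        for _ in range(300):
            Xp = X.copy()
            Xp[:, 0] = rng.permutation(X[:, 0])
            fit = fit_proportional_odds(y, Xp, beta_names=["x"])
            pvals.append(extract_effect(fit, "x").p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestExtractEffect:
    @staticmethod
    def _fixed_fit(beta, se):
        from wmhnet.ordinal import PropOddsFit
        cov = np.diag([0.1, se ** 2])
        return PropOddsFit(cutpoints=np.array([0.0]), beta=np.array([beta]),
                           beta_names=["x"], cov=cov, loglik=-10.0, n=20,
                           levels=np.array([0, 1]), converged=True)

    def test_null_coefficient_closed_form(self):
        eff = extract_effect(self._fixed_fit(0.0, 1.0), "x")
        assert eff.or_estimate == 1.0
        assert eff.ci_low == pytest.approx(np.exp(-1.959964), abs=1e-3)
        assert eff.ci_high == pytest.approx(np.exp(1.959964), abs=1e-2)
        assert eff.p_value == pytest.approx(1.0)

    def test_se_limit_ci_collapses(self):
        eff = extract_effect(self._fixed_fit(np.log(2), 1e-12), "x")
        assert eff.or_estimate == pytest.approx(2.0)
        assert eff.ci_low == pytest.approx(2.0, rel=1e-6)
        assert eff.ci_high == pytest.approx(2.0, rel=1e-6)

    def test_matches_logistic_oracle(self, rng):
        X = rng.normal(size=(150, 1))
        y = (X[:, 0] + rng.logistic(size=150) > 0).astype(int)
        fit = fit_proportional_odds(y, X, beta_names=["x"])
        eff = extract_effect(fit, "x")
        lg = sm.Logit(y, sm.add_constant(X)).fit(disp=False)
        assert eff.or_estimate == pytest.approx(np.exp(lg.params[1]), rel=1e-5)
        ci = lg.conf_int()
        assert eff.ci_low == pytest.approx(np.exp(ci[1][0]), rel=5e-3)
        assert eff.ci_high == pytest.approx(np.exp(ci[1][1]), rel=5e-3)

    def test_missing_term_errors(self):
        with pytest.raises(KeyError):
            extract_effect(self._fixed_fit(0.0, 1.0), "nope")

    def test_profile_ci_covers_estimate(self, rng):
        y, X = simulate_po_data(rng, 200, [0.8], [-0.5, 0.5])
        fit = fit_proportional_odds(y, X, beta_names=["x"])
        fit._data = (y, X)
        eff = extract_effect(fit, "x", ci_method="profile")
        assert eff.ci_low < eff.or_estimate < eff.ci_high


class TestPseudoR2:
    def test_identical_fits_gain_zero(self, rng):
        y, X = simulate_po_data(rng, 150, [0.5], [0.0, 1.0])
        fit = fit_proportional_odds(y, X)
        assert pseudo_r2(fit, fit) == pytest.approx(0.0, abs=1e-10)

    def test_strong_predictor_positive_gain(self, rng):
        y, X = simulate_po_data(rng, 200, [2.0], [-1.0, 1.0])
        fit = fit_proportional_odds(y, X)
        null = fit_proportional_odds(y, np.empty((200, 0)))
        assert pseudo_r2(fit, null) > 0.1

    def test_nagelkerke_formula_oracle(self, rng):
        y, X = simulate_po_data(rng, 120, [1.0], [0.0])
        fit = fit_proportional_odds(y, X)
        null = fit_proportional_odds(y, np.empty((120, 0)))
        n, ll, ll0 = 120, fit.loglik, null.loglik
        cs = 1 - np.exp(2 * (ll0 - ll) / n)
        nag = cs / (1 - np.exp(2 * ll0 / n))
        assert pseudo_r2(fit, null) == pytest.approx(nag, abs=1e-12)
        assert pseudo_r2(fit, null, "mcfadden") == pytest.approx(1 - ll / ll0, abs=1e-12)

    def test_nesting_violation_rejected(self, rng):
        y, X = simulate_po_data(rng, 100, [1.0], [0.0])
        fit = fit_proportional_odds(y, X)
        null = fit_proportional_odds(y, np.empty((100, 0)))
        with pytest.raises(ValueError, match="nesting"):
            pseudo_r2(null, fit)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        p = np.full(5, 0.2)
        assert fdr_adjust(p) == pytest.approx(p)

    def test_step_up_example(self):
        assert fdr_adjust(np.array([0.01, 0.02, 0.03])) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, 50)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_matches_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
            assert fdr_adjust(p) == pytest.approx(adj_sm, abs=1e-12)

    def test_brute_force_definition(self, rng):
        def brute(p):
            m = len(p)
            order = np.argsort(p)
            out = np.empty(m)
            for rank_pos, idx in enumerate(order, start=1):
                cands = [p[j] * m / (list(order).index(j) + 1)
                         for j in order[rank_pos - 1:]]
                out[idx] = min(1.0, min(cands))
            return out
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 15))
            assert fdr_adjust(p) == pytest.approx(brute(p), abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.5]))


class TestRunRegionModels:
    def _chaco_and_cohort(self, rng, n=60, n_regions=4, effect=0.0):
        chaco = pd.DataFrame(
            rng.beta(2, 4, size=(n, n_regions)),
            columns=range(1, n_regions + 1),
            index=[f"p{i:03d}" for i in range(n)],
        )
        cohort = pd.DataFrame({
            "patient_id": chaco.index,
            "age": rng.normal(70, 10, n),
            "nihss": rng.integers(1, 18, n),
            "lesion_volume_ml": rng.lognormal(np.log(20), 0.5, n),
            "wmh_volume_ml": rng.lognormal(np.log(10), 0.4, n),
        })
        high = (chaco[1] > chaco[1].median()).astype(int).to_numpy()
        latent = effect * high + rng.logistic(size=n)
        cohort["mrs"] = (latent[:, None] > np.linspace(-2, 2, 6)[None, :]).sum(axis=1)
        return chaco, cohort

    def test_output_schema_and_fdr(self, rng):
        chaco, cohort = self._chaco_and_cohort(rng)
        res = run_region_models(chaco, cohort)
        assert set(res.columns) >= {"region_id", "or_estimate", "ci_low", "ci_high",
                                    "p_raw", "p_fdr", "r2_base", "r2_full",
                                    "r2_gain", "n_low", "n_high", "status"}
        ok = res["status"] == "ok"
        assert ok.all()
        assert (res.loc[ok, "p_fdr"] >= res.loc[ok, "p_raw"] - 1e-15).all()
        assert (res.loc[ok, "ci_low"] <= res.loc[ok, "or_estimate"] + 1e-12).all()
        assert (res.loc[ok, "or_estimate"] <= res.loc[ok, "ci_high"] + 1e-12).all()
        assert res.loc[ok, "r2_gain"].to_numpy() == pytest.approx(
            (res.loc[ok, "r2_full"] - res.loc[ok, "r2_base"]).to_numpy())
        assert (res.loc[ok, "r2_gain"] >= -1e-8).all()

    def test_strong_effect_detected(self, rng):
        chaco, cohort = self._chaco_and_cohort(rng, n=150, effect=2.5)
        res = run_region_models(chaco, cohort).set_index("region_id")
        assert res.loc[1, "p_fdr"] < 0.05
        assert res.loc[1, "or_estimate"] > 1

    def test_degenerate_region_recorded_not_fatal(self, rng):
        chaco, cohort = self._chaco_and_cohort(rng)
        chaco[2] = 0.5  # constant -> dichotomize fails
        res = run_region_models(chaco, cohort, kept_regions=[1, 2, 3]
                                ).set_index("region_id")
        assert res.loc[2, "status"].startswith("failed")
        assert res.loc[1, "status"] == "ok" and res.loc[3, "status"] == "ok"

    def test_global_chaco_base_variant(self, rng):
        chaco, cohort = self._chaco_and_cohort(rng)
        cohort["global_chaco"] = chaco.mean(axis=1).to_numpy()
        res = run_region_models(chaco, cohort,
                                config=ModelConfig(base_adjust="global_chaco"))
        assert (res["status"] == "ok").all()

    def test_group_sizes_sum_to_n(self, rng):
        chaco, cohort = self._chaco_and_cohort(rng, n=33)
        res = run_region_models(chaco, cohort)
        ok = res["status"] == "ok"
        assert ((res.loc[ok, "n_low"] + res.loc[ok, "n_high"]) == 33).all()
        # with 33 distinct values the median observation itself is low
        assert (res.loc[ok, "n_low"] >= 17).all()
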