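"""Bud-set CLMM: closed-form category probabilities, collapse to
fixed-effects and logistic oracles, quadrature agreement, D50% algebra and
its Monte-Carlo meaning, and climate correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from epiclonal.config import ClmmParams, SimConfig
from epiclonal.phenology import (SCORE_LEVELS, BudSetClmm, BudSetClmmResults,
                                 cumulative_logit_probs, pearson_climate)
from epiclonal.simulate import simulate_budset, simulate_sites


def budset_df(n_donors=20, ramets=4, days=(225, 235, 245, 255), seed=0,
              params=None, sites=2):
    p = params or ClmmParams()
    cfg = SimConfig(seed=seed, n_sites=sites, trees_per_site=n_donors // sites,
                    ramets_per_donor=ramets, obs_days=days, clmm_params=p)
    return simulate_budset(cfg, simulate_sites(cfg)).observations


class TestCategoryProbabilities:
    def test_closed_form(self):
        alphas = np.array([-1.0, 0.0, 1.0])
        probs = cumulative_logit_probs(alphas, np.array(0.0))
        cum = expit(alphas)
        expected = np.diff(np.concatenate([[0.0], cum, [1.0]]))
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    def test_sum_to_one(self, rng):
        alphas = np.sort(rng.normal(size=6))
        z = rng.normal(size=20)
        probs = cumulative_logit_probs(alphas, z)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)

    def test_large_thresholds_put_mass_on_first_category(self):
        probs = cumulative_logit_probs(np.array([30.0, 31, 32, 33, 34, 35]),
                                       np.array(0.0))
        assert probs[0] > 0.999999


class TestFixedEffectsCollapse:
    def test_sigma_zero_matches_ordered_model(self):
        """Data simulated without random effects: the mixed fit agrees with a
        plain proportional-odds fit in all coefficients."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        p = ClmmParams(sigma_tree=0.0, sigma_ramet=0.0)
        obs = budset_df(seed=3, n_donors=20, params=p)
        model = BudSetClmm.from_dataframe(obs)
        # flat threshold directions need a tight stop to resolve 1e-4
        res = model.fit(gtol=1e-8, ftol=1e-15, maxiter=2000)
        assert res.sigma_tree < 0.05 and res.sigma_ramet < 0.05

        endog = pd.Series(pd.Categorical(model.design.y,
                                         categories=range(model.k_levels),
                                         ordered=True))
        om = OrderedModel(endog, model.design.X, distr="logit")
        from scipy import optimize
        ref0 = om.fit(method="bfgs", disp=False)
        pol = optimize.minimize(lambda x: -om.loglike(x),
                                np.asarray(ref0.params, float),
                                method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 1000})
        ref_params = pol.x
        cuts = om.transform_threshold_params(ref_params)[1:-1]
        cuts_natural = cuts + ref_params[:model.design.X.shape[1]] \
            @ model.design.centers
        np.testing.assert_allclose(res.beta.to_numpy(),
                                   ref_params[:model.design.X.shape[1]],
                                   atol=1e-4)
        np.testing.assert_allclose(res.thresholds, cuts_natural, atol=1e-4)

    def test_single_day_binary_matches_logistic(self):
        """One observation day and two categories: the model collapses to
        logistic regression of 'still growing' on CN."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 400
        cn = rng.normal(12, 2, n)
        alpha_true, slope = 2.4, 0.2
        y_grow = rng.random(n) < expit(alpha_true - slope * cn)
        obs = pd.DataFrame({
            "ramet_id": [f"r{i}" for i in range(n)],
            "donor_id": [f"d{i}" for i in range(n)],
            "site_id": "S1", "day": 240, "cn": cn,
            "score": np.where(y_grow, 3.0, 0.0)})
        res = BudSetClmm.from_dataframe(obs).fit()
        X = sm.add_constant(cn)
        logit = sm.GLM(y_grow.astype(float), X,
                       family=sm.families.Binomial()).fit()
        # our beta_cn has the opposite sign convention
        assert res.beta_cn == pytest.approx(-logit.params[1], abs=1e-3)

    def test_quadrature_agreement_on_toy(self):
        """Laplace log-likelihood within 0.1 of adaptive quadrature on a
        3-donor x 2-ramet x 2-day instance."""
        cfg = SimConfig(seed=5, n_sites=3, trees_per_site=1,
                        ramets_per_donor=2, obs_days=(225, 250))
        obs = simulate_budset(cfg, simulate_sites(cfg)).observations
        m = BudSetClmm.from_dataframe(obs)
        for params in (m._start_params(),
                       m.pack(np.linspace(-1.5, 1.5, 6),
                              np.zeros(m.design.X.shape[1]), 0.7, 0.4)):
            la = m.loglike(params)
            gq = m.loglike_quadrature(params, n_nodes=25)
            assert abs(la - gq) < 0.1


@pytest.fixture(scope="module")
def fitted():
    p = ClmmParams(site_effect_per_degree=0.0)
    obs = budset_df(seed=17, n_donors=24, ramets=6,
                    days=(222, 229, 236, 243, 250, 257), params=p)
    return p, BudSetClmm.from_dataframe(obs).fit()


class TestFitOnSimulatedData:
    def test_slope_sign_and_magnitude(self, fitted):
        p, res = fitted
        assert res.converged
        assert 0.5 * p.beta_day < res.beta_day < 2.0 * p.beta_day

    def test_monotone_phenophase_progression(self, fitted):
        _, res = fitted
        site = res.model.design.site_levels[0]
        earlier = res.category_probabilities(225, site, 12.0)
        later = res.category_probabilities(255, site, 12.0)
        # cumulative probability of the least-advanced categories shrinks
        assert np.all(np.cumsum(later.to_numpy())[:-1]
                      <= np.cumsum(earlier.to_numpy())[:-1] + 1e-12)

    def test_loglik_invariant_to_row_order_and_labels(self, fitted):
        _, res = fitted
        m = res.model
        df = m.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m2 = BudSetClmm.from_dataframe(df)
        assert m2.loglike(res.params) == pytest.approx(res.loglik, abs=1e-6)
        relabel = m.data.assign(
            donor_id="x" + m.data["donor_id"],
            ramet_id="y" + m.data["ramet_id"])
        m3 = BudSetClmm.from_dataframe(relabel)
        assert m3.loglike(res.params) == pytest.approx(res.loglik, abs=1e-6)

    def test_summary_lists_all_parameters(self, fitted):
        _, res = fitted
        text = res.summary()
        for token in ("sigma_tree", "sigma_ramet", "day", "cn",
                      "log-likelihood"):
            assert token in text


def results_with(alphas_natural, beta_day, beta_cn, u_tree):
    """A results object over a minimal one-site design with prescribed
    parameters and donor random-effect modes."""
    levels = list(SCORE_LEVELS)
    rows = []
    for d in range(2):
        for i, s in enumerate(levels):
            rows.append((f"r{d}_{i}", f"d{d}", "S1", 200 + i, 12.0, s))
    obs = pd.DataFrame(rows, columns=["ramet_id", "donor_id", "site_id",
                                      "day", "cn", "score"])
    m = BudSetClmm.from_dataframe(obs)
    beta = np.zeros(m.design.X.shape[1])
    beta[m.design.exog_names.index("day")] = beta_day
    beta[m.design.exog_names.index("cn")] = beta_cn
    alphas_internal = np.asarray(alphas_natural) - beta @ m.design.centers
    params = m.pack(alphas_internal, beta, 0.3, 0.3)
    return BudSetClmmResults(m, params, 0.0, True,
                             np.asarray(u_tree, float), np.zeros(14))


class TestD50:
    def test_algebra(self):
        """alpha_(1.5)=5, beta_CN=0, beta_S=0, ranef=0, beta_D=0.1 -> 50."""
        res = results_with(np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0]),
                           beta_day=0.1, beta_cn=0.0, u_tree=[0.0, 0.0])
        out = res.d50(cn_ref=12.0)
        assert np.allclose(out["d50"], 50.0)

    def test_ranef_shift_linearity(self):
        delta = 0.7
        res0 = results_with(np.array([2.0, 3, 4, 5, 6, 7]), 0.1, 0.05,
                            [0.0, 0.0])
        res1 = results_with(np.array([2.0, 3, 4, 5, 6, 7]), 0.1, 0.05,
                            [delta, 0.0])
        d0 = res0.d50()["d50"].to_numpy()
        d1 = res1.d50()["d50"].to_numpy()
        assert d1[0] - d0[0] == pytest.approx(-delta / 0.1)
        assert d1[1] == pytest.approx(d0[1])

    def test_beta_day_zero_rejected(self):
        res = results_with(np.array([2.0, 3, 4, 5, 6, 7]), 0.1, 0.0,
                           [0.0, 0.0])
        res.beta["day"] = 0.0
        with pytest.raises(ValueError):
            res.d50()

    def test_monte_carlo_crossing_day(self, rng):
        """The formula's D50 equals the day at which the simulated fraction
        of ramets at score >= 1.5 crosses 50% (one parameter draw; the
        acceptance suite repeats this over many draws)."""
        from helpers import empirical_d50_crossing

        alphas = np.sort(rng.normal(37, 2, 6))
        alphas += 0.05 * np.arange(6)
        beta_day, beta_cn, sigma_r = 0.15, 0.1, 0.4
        formula = (alphas[3] - beta_cn * 12.0) / beta_day
        crossing = empirical_d50_crossing(alphas, beta_day, beta_cn, sigma_r,
                                          n=10000, rng=rng)
        assert abs(crossing - formula) <= 1.0


class TestPearsonClimate:
    def test_perfect_linear_relation(self):
        sites = simulate_sites(SimConfig(seed=2, n_sites=12))
        d50 = pd.DataFrame({
            "donor_id": [f"d{i}" for i in range(12)],
            "site_id": sites["site_id"],
            "d50": 240 + 2.0 * sites["t_jan"]})
        out = pearson_climate(d50, sites).set_index("variable")
        assert out.loc["t_jan", "r"] == pytest.approx(1.0)
        assert out.loc["t_jan", "p_value"] < 1e-10

    def test_zero_variance_rejected(self):
        sites = simulate_sites(SimConfig(seed=2, n_sites=5))
        d50 = pd.DataFrame({"donor_id": list("abcde"),
                            "site_id": sites["site_id"], "d50": 240.0})
        with pytest.raises(ValueError):
            pearson_climate(d50, sites)


class TestInputValidation:
    def test_score_outside_scale_rejected(self):
        obs = budset_df(seed=1, n_donors=4, ramets=2, days=(230, 240))
        obs.loc[0, "score"] = 1.7
        with pytest.raises(ValueError):
            BudSetClmm.from_dataframe(obs)

    def test_ramet_with_two_donors_rejected(self):
        obs = budset_df(seed=1, n_donors=4, ramets=2, days=(230, 240))
        obs.loc[obs.index[-1], "ramet_id"] = obs.loc[0, "ramet_id"]
        with pytest.raises(ValueError):
            BudSetClmm.from_dataframe(obs)

    def test_unobserved_levels_collapsed_with_warning(self):
        p = ClmmParams(thresholds=(30.0, 31, 32, 33, 34, 50.0),
                       beta_day=0.15)
        obs = budset_df(seed=4, n_donors=6, ramets=3, params=p)
        if set(obs["score"]) == set(SCORE_LEVELS):
            pytest.skip("all levels realised under this seed")
        m = BudSetClmm.from_dataframe(obs)
        assert any("collapsed" in w for w in m.design.warnings_)
        assert m.k_levels == obs["score"].nunique()
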