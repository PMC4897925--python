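import numpy as np
import pandas as pd
import pytest
from scipy import stats

from minetown import pointsource as ps
from minetown import star, synthetic
from minetown.mcmc import bernoulli_loglik
from conftest import children_at_distances


class TestDistanceRisk:
    def test_plateau_value_is_exact(self):
        d = np.array([0.0, 0.3, 0.8])
        assert np.all(ps.distance_risk(d, alpha=2.0, phi=1.0, delta=0.8) == 3.0)

    def test_zero_alpha_gives_unit_odds_everywhere(self):
        d = np.linspace(0, 10, 50)
        assert np.all(ps.distance_risk(d, 0.0, 1.0, 0.5) == 1.0)

    def test_one_decay_scale_past_plateau(self):
        # d = delta + phi: f = 1 + alpha/e
        val = ps.distance_risk(1.8, alpha=2.0, phi=1.0, delta=0.8)
        assert val == pytest.approx(1 + 2 * np.exp(-1), abs=1e-12)
        assert val == pytest.approx(1.7358, abs=1e-4)

    def test_continuous_at_plateau_edge_and_monotone_beyond(self):
        eps = 1e-9
        lo = ps.distance_risk(0.8 - eps, 2.0, 1.1, 0.8)
        hi = ps.distance_risk(0.8 + eps, 2.0, 1.1, 0.8)
        assert lo == pytest.approx(hi, abs=1e-6)
        d = np.linspace(0.8, 8, 200)
        f = ps.distance_risk(d, 2.0, 1.1, 0.8)
        assert np.all(np.diff(f) <= 0)
        assert f[-1] == pytest.approx(1.0, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ps.distance_risk(1.0, 1.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            ps.distance_risk(1.0, -0.5, 1.0, 0.5)


class TestModelLinpred:
    def test_alpha_zero_reduces_to_confounder_model(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        beta = np.array([0.5, -0.2])
        d = rng.uniform(0.1, 3, 20)
        with_f = ps.model_linpred(d, X, -1.0, beta, params=(0.0, 1.0, 0.5))
        without = ps.model_linpred(d, X, -1.0, beta, params=None)
        assert np.allclose(with_f, without, atol=1e-15)

    def test_odds_ratio_at_source_is_one_plus_alpha(self):
        # log-f formulation: child at the source vs far-field child, same
        # covariates -> odds ratio exactly 1 + alpha
        X = np.zeros((2, 1))
        eta = ps.model_linpred(np.array([0.2, 1e6]), X, -1.5, np.zeros(1),
                               params=(2.0, 1.1, 0.8))
        assert np.exp(eta[0] - eta[1]) == pytest.approx(3.0, abs=1e-12)

    def test_likelihood_matches_bruteforce_on_ten_children(self):
        rng = np.random.default_rng(1)
        n = 10
        d = rng.uniform(0.05, 4, n)
        X = rng.normal(size=(n, 2))
        y = rng.binomial(1, 0.4, n).astype(float)
        beta0, beta = -0.7, np.array([0.4, -0.9])
        s = rng.normal(0, 0.3, n)
        alpha, phi, delta = 1.7, 1.2, 0.6
        eta = ps.model_linpred(d, X, beta0, beta, params=(alpha, phi, delta), s=s)
        ll = bernoulli_loglik(y, eta)
        # independent per-child computation
        ll_brute = 0.0
        for i in range(n):
            if d[i] <= delta:
                f = 1 + alpha
            else:
                f = 1 + alpha * np.exp(-(((d[i] - delta) / phi) ** 2))
            e = beta0 + np.log(f) + X[i, 0] * beta[0] + X[i, 1] * beta[1] + s[i]
            p = 1 / (1 + np.exp(-e))
            ll_brute += np.log(p if y[i] == 1 else 1 - p)
        assert ll == pytest.approx(ll_brute, abs=1e-12)


class TestSpatialBasis:
    @pytest.fixture(scope="class")
    def town(self):
        return synthetic.generate_town(synthetic.TownConfig(n_children=150, seed=3))

    def test_knot_count_capped_by_residences(self, town):
        eff = ps.build_spatial_basis(town, n_knots=40, seed=0)
        assert eff.n_knots == 40
        with pytest.warns(UserWarning):
            eff2 = ps.build_spatial_basis(town.head(20), n_knots=40, seed=0)
        assert eff2.n_knots == 20

    def test_single_knot_is_effectively_zero(self, town):
        eff = ps.build_spatial_basis(town, n_knots=1, seed=0)
        assert eff.n_effective == 0
        assert eff.design.shape == (len(town), 0)

    def test_weights_sum_to_zero_exactly(self, town):
        eff = ps.build_spatial_basis(town, n_knots=25, seed=0)
        rng = np.random.default_rng(4)
        for _ in range(5):
            w = eff.weights_from_u(rng.standard_normal(eff.n_effective))
            assert abs(w.sum()) < 1e-10

    def test_known_surface_recovered_by_least_squares(self, town):
        eff = ps.build_spatial_basis(town, n_knots=20, seed=1)
        rng = np.random.default_rng(5)
        u_true = rng.standard_normal(eff.n_effective)
        surface = eff.design @ u_true
        u_hat, *_ = np.linalg.lstsq(eff.design, surface, rcond=None)
        assert np.allclose(u_hat, u_true, atol=1e-8)

    def test_degenerate_geometry_rejected(self):
        tab = pd.DataFrame({"child_id": ["a", "b"], "lat": [1.0, 1.0], "lon": [2.0, 2.0]})
        with pytest.raises(ValueError):
            ps.build_spatial_basis(tab, n_knots=2)


@pytest.fixture(scope="module")
def m2_fixture():
    """n=1000 children around a single mine; outcomes from Model 2 truth."""
    center = (-30.30, -71.10)
    src = pd.DataFrame({"source_id": ["gold"], "lat": [center[0]], "lon": [center[1]]})
    cfg = synthetic.TownConfig(n_children=1000, town_center=center, mine_locations=src,
                               residence_spread_km=1.5, seed=6)
    truth = synthetic.TruthParams(alpha=2.0, phi=1.1, delta=0.8, beta0=-2.0, spatial_sd=0.0)
    tab = synthetic.generate_town(cfg)
    tab = synthetic.simulate_outcomes(tab, truth, src, outcome="asthma",
                                      exposure_mode="gold", seed=7)
    from minetown import geodesy

    d = geodesy.build_exposures(tab, src).table["d_gold"].to_numpy()
    return tab, d, tab["asthma"].to_numpy(float)


QUICK = ps.McmcSettings(chains=2, iterations=2500, burnin=1000, thin=3)


class TestFitModel:
    def test_model0_posterior_matches_mle(self, m2_fixture):
        tab, d, y = m2_fixture
        x = (tab["lat"] > tab["lat"].median()).to_numpy(float)[:, None]
        fit = ps.fit_model(y, x, None, model_id=0, mcmc=QUICK, seed=8)
        import statsmodels.api as sm

        mle = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        post = fit.draws["beta"].mean(axis=0)
        sd = fit.draws["beta"].std(axis=0)
        assert np.all(np.abs(post - mle.params) < 1.5 * np.maximum(sd, mle.bse))

    def test_alpha_spike_collapses_model2_onto_model0(self, m2_fixture):
        tab, d, y = m2_fixture
        spike = star.PriorSpec(alpha_mu=np.log(1e-6), alpha_sigma=1e-3,
                               delta_hi=float(d.max()))
        # long chains: the KS tolerance is tight relative to MCMC noise
        long = ps.McmcSettings(chains=2, iterations=9000, burnin=1000, thin=2)
        f0 = ps.fit_model(y, np.empty((len(y), 0)), None, model_id=0,
                          mcmc=long, seed=9)
        f2 = ps.fit_model(y, np.empty((len(y), 0)), d, model_id=2, priors=spike,
                          mcmc=long, seed=10)
        ks = stats.ks_2samp(f0.draws["beta"][:, 0], f2.draws["beta"][:, 0])
        assert ks.statistic < 0.05

    def test_dic_identity_recomputed_from_draws(self, m2_fixture):
        tab, d, y = m2_fixture
        pr = star.PriorSpec(alpha_mu=np.log(np.e - 1), alpha_sigma=0.67,
                            delta_hi=float(d.max()))
        fit = ps.fit_model(y, np.empty((len(y), 0)), d, model_id=2, priors=pr,
                           mcmc=QUICK, seed=11)
        dic, p_eff, dbar = ps.compute_dic(fit)
        assert dbar == pytest.approx(fit.draws["deviance"].mean(), abs=1e-9)
        assert dic == pytest.approx(dbar + p_eff, abs=1e-9)
        assert dic == pytest.approx(fit.dic, abs=1e-9)

    def test_degenerate_posterior_has_zero_pd(self, m2_fixture):
        tab, d, y = m2_fixture
        pr = star.PriorSpec(alpha_mu=0.0, alpha_sigma=0.5, delta_hi=float(d.max()))
        fit = ps.fit_model(y, np.empty((len(y), 0)), d, model_id=2, priors=pr,
                           mcmc=QUICK, seed=12)
        # collapse all draws onto a single state: DIC must equal that deviance
        for k in fit.draws:
            fit.draws[k] = fit.draws[k][:1].repeat(10, axis=0)
        dic, p_eff, dbar = ps.compute_dic(fit)
        assert p_eff == pytest.approx(0.0, abs=1e-8)
        assert dic == pytest.approx(dbar, abs=1e-8)

    def test_invalid_model_id_rejected(self, m2_fixture):
        tab, d, y = m2_fixture
        with pytest.raises(ValueError):
            ps.fit_model(y, np.empty((len(y), 0)), d, model_id=4)


class TestFCurveAndThreshold:
    @pytest.fixture(scope="class")
    def fitted(self, m2_fixture):
        tab, d, y = m2_fixture
        pr = star.PriorSpec(alpha_mu=np.log(np.e - 1), alpha_sigma=0.67,
                            delta_hi=float(d.max()))
        return ps.fit_model(y, np.empty((len(y), 0)), d, model_id=2, priors=pr,
                            mcmc=QUICK, seed=13)

    def test_curve_mean_near_source_reflects_truth(self, fitted):
        curve = ps.posterior_f_curve(fitted, np.array([0.0]))
        assert 2.0 < curve["mean"].iloc[0] < 4.5  # truth 1 + alpha = 3

    def test_curve_decays_to_one_for_every_draw(self, fitted):
        a = fitted.draws["alpha"]
        far = ps.posterior_f_curve(fitted, np.array([60.0]))
        assert far["ucl"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_band_ordering_everywhere(self, fitted):
        curve = ps.posterior_f_curve(fitted, np.linspace(0, 5, 50))
        assert (curve["lcl"] <= curve["mean"] + 1e-12).all()
        assert (curve["mean"] <= curve["ucl"] + 1e-12).all()

    def test_empty_grid_rejected(self, fitted):
        with pytest.raises(ValueError):
            ps.posterior_f_curve(fitted, np.array([]))

    def test_model0_has_no_curve(self, m2_fixture):
        tab, d, y = m2_fixture
        f0 = ps.fit_model(y, np.empty((len(y), 0)), None, model_id=0,
                          mcmc=QUICK, seed=14)
        with pytest.raises(ValueError):
            ps.posterior_f_curve(f0, np.linspace(0, 3, 10))

    def test_threshold_flat_high_band_censored_at_range_end(self):
        curve = pd.DataFrame({"distance_km": np.linspace(0, 3, 31),
                              "mean": 1.5, "lcl": 1.2, "ucl": 1.8})
        thr = ps.threshold_distance(curve)
        assert thr.censored and thr.km == 3.0

    def test_threshold_none_when_band_touches_one_at_source(self):
        curve = pd.DataFrame({"distance_km": np.linspace(0, 3, 31),
                              "mean": 1.1, "lcl": 1.01, "ucl": 1.3})
        assert ps.threshold_distance(curve) is None

    def test_threshold_linear_interpolation(self):
        curve = pd.DataFrame({"distance_km": [0.0, 1.0],
                              "mean": [2.0, 1.2], "lcl": [1.5, 1.0], "ucl": [3, 2]})
        thr = ps.threshold_distance(curve, tol=0.05)
        # lcl crosses 1.05 at 0 + (1.5-1.05)/(1.5-1.0) = 0.9
        assert thr.km == pytest.approx(0.9, abs=1e-12)
        assert not thr.censored
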