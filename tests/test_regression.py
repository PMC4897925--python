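import numpy as np
import pandas as pd
import pytest

from minetown import regression, synthetic


def table_from_2x2(a, b, c, d):
    """Outcome x exposure table -> long data (a=exposed cases, b=exposed non-cases,
    c=unexposed cases, d=unexposed non-cases)."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return pd.Series(y, name="y"), pd.DataFrame({"exposed": x})


class TestFitLogistic:
    def test_balanced_table_gives_or_one(self):
        y, X = table_from_2x2(50, 50, 50, 50)
        fit = regression.fit_logistic(y, X)
        assert fit.or_table().loc["exposed", "OR"] == pytest.approx(1.0, abs=1e-8)

    def test_two_by_two_matches_closed_form(self):
        a, b, c, d = 22, 47, 44, 162
        y, X = table_from_2x2(a, b, c, d)
        fit = regression.fit_logistic(y, X)
        assert fit.or_table().loc["exposed", "OR"] == pytest.approx((a * d) / (b * c), abs=1e-6)
        # Wald SE of log OR equals the classical 2x2 formula
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert fit.se["exposed"] == pytest.approx(se, rel=1e-4)

    def test_intercept_only_reproduces_sample_logit(self):
        y = pd.Series(np.r_[np.ones(30), np.zeros(70)])
        fit = regression.fit_logistic(y, pd.DataFrame(index=y.index))
        assert fit.params["const"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_irls_agrees_with_newton_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x1": rng.normal(size=40), "x2": rng.binomial(1, 0.4, 40)})
        eta = -0.3 + 0.8 * X["x1"] - 0.5 * X["x2"]
        y = pd.Series((rng.uniform(size=40) < 1 / (1 + np.exp(-eta))).astype(float))
        fit = regression.fit_logistic(y, X)
        # independent Newton-Raphson on the log-likelihood
        Xd = np.column_stack([np.ones(40), X.to_numpy()])
        beta = np.zeros(3)
        for _ in range(60):
            p = 1 / (1 + np.exp(-Xd @ beta))
            grad = Xd.T @ (y - p)
            hess = -(Xd * (p * (1 - p))[:, None]).T @ Xd
            beta = beta - np.linalg.solve(hess, grad)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-6)

    def test_wald_interval_coverage_near_nominal(self):
        rng = np.random.default_rng(1)
        truth = 0.9
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.binomial(1, 0.5, 300).astype(float)
            eta = -1.0 + truth * x
            y = pd.Series((rng.uniform(size=300) < 1 / (1 + np.exp(-eta))).astype(float))
            fit = regression.fit_logistic(y, pd.DataFrame({"x": x}))
            t = fit.or_table().loc["x"]
            hits += t["lcl"] <= np.exp(truth) <= t["ucl"]
        assert 0.90 <= hits / reps <= 0.99

    def test_complete_separation_flagged(self):
        y, X = table_from_2x2(20, 0, 0, 20)
        fit = regression.fit_logistic(y, X)
        assert fit.separation


class TestBuildDesign:
    def test_gapped_index_keeps_rows_aligned(self, study_fixture):
        # tables that have been through exclusions carry non-contiguous
        # indexes; dummy expansion must not misalign against numeric columns
        table, _ = study_fixture
        gapped = table.drop(index=table.index[5:8])
        gapped["q1"] = (np.arange(len(gapped)) % 4 == 0).astype(int)
        y, X, _ = regression.build_design(gapped, "asthma", ["q1", "sex"])
        assert np.isfinite(X.to_numpy(float)).all()
        assert (X.index == y.index).all()
        sel = gapped.dropna(subset=["asthma"])
        assert (X["sex_female"] == (sel["sex"] == "female").astype(float).loc[X.index]).all()


class TestScreenConfounders:
    def make_table(self, rng, n=2000, effect_or=1.0):
        cfg = synthetic.TownConfig(n_children=n, seed=int(rng.integers(2**31 - 1)))
        tab = synthetic.generate_town(cfg)
        tab = synthetic.draw_covariates(tab, seed=int(rng.integers(2**31 - 1)))
        eta = -1.0 + np.log(effect_or) * (tab["parental_atopy"] == "yes")
        tab["asthma"] = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        return tab

    def test_null_covariate_rarely_selected(self):
        rng = np.random.default_rng(2)
        picked = sum(
            "parental_atopy" in regression.screen_confounders(
                self.make_table(rng, effect_or=1.0), "asthma", ["parental_atopy"])
            for _ in range(30)
        )
        assert picked / 30 <= 0.2  # type-I error of the 5% screen

    def test_strong_covariate_always_selected(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            tab = self.make_table(rng, effect_or=3.0)
            assert "parental_atopy" in regression.screen_confounders(
                tab, "asthma", ["parental_atopy", "paved_street"])

    def test_screen_recovers_default_truth_effects(self):
        # asthma generated with atopy, both-parents and working-mother effects
        cfg = synthetic.TownConfig(n_children=4000, seed=21)
        truth = synthetic.default_truth("asthma")
        tab = synthetic.generate_town(cfg)
        tab = synthetic.draw_covariates(tab, seed=22)
        tab = synthetic.simulate_outcomes(tab, truth, cfg.mine_locations,
                                          outcome="asthma", seed=23)
        got = set(regression.screen_confounders(tab, "asthma", synthetic.COVARIATE_COLUMNS))
        assert {"parental_atopy", "lives_with_both_parents", "mother_working"} <= got


class TestMultipleImpute:
    def test_complete_table_returned_unchanged(self, study_fixture):
        table, _ = study_fixture
        complete = table.dropna().reset_index(drop=True)
        out = regression.multiple_impute(complete, m=3, seed=0)
        assert len(out) == 3
        for t in out:
            pd.testing.assert_frame_equal(t, complete)

    def test_seven_imputations_produced_and_complete(self, study_fixture):
        table, _ = study_fixture
        out = regression.multiple_impute(table, m=7, seed=1)
        assert len(out) == 7
        for t in out:
            assert t[synthetic.COVARIATE_COLUMNS].isna().sum().sum() == 0

    def test_overly_missing_column_rejected(self, study_fixture):
        table, _ = study_fixture
        tab = table.copy()
        tab.loc[tab.index[:270], "heater_type"] = pd.NA
        with pytest.raises(ValueError, match="heater_type"):
            regression.multiple_impute(tab, m=3, seed=0)

    def test_mar_pooled_or_nearly_unbiased(self):
        # MAR gaps in the exposure covariate; pooled log-OR should track truth
        rng = np.random.default_rng(4)
        truth = 1.0
        est = []
        for _ in range(30):
            n = 400
            sex = rng.binomial(1, 0.5, n)
            x = rng.binomial(1, 0.3 + 0.2 * sex, n).astype(float)
            eta = -1.0 + truth * x
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
            tab = pd.DataFrame({
                "asthma": y,
                "sex": np.where(sex == 1, "female", "male"),
                "smoking_at_home": np.where(x == 1, "yes", "no"),
            })
            # missingness driven by the observed sex column only
            miss = rng.uniform(size=n) < np.where(sex == 1, 0.45, 0.15)
            tab.loc[miss, "smoking_at_home"] = pd.NA
            fits = []
            for t in regression.multiple_impute(tab, m=5, seed=int(rng.integers(2**31 - 1))):
                yy, XX, _ = regression.build_design(t, "asthma", ["smoking_at_home", "sex"])
                fits.append(regression.fit_logistic(yy, XX))
            est.append(regression.pool_rubin(fits).estimate["smoking_at_home_yes"])
        assert abs(np.mean(est) - truth) < 0.15 * truth


class TestPoolRubin:
    def _fit_like(self, params, var):
        idx = pd.Index(["const", "x"])
        return regression.LogisticFit(
            params=pd.Series(params, idx),
            cov=pd.DataFrame(np.diag(var), index=idx, columns=idx),
            n_used=100, n_total=100, converged=True,
        )

    def test_identical_fits_pool_to_single_fit(self):
        f = self._fit_like([0.2, 0.7], [0.01, 0.04])
        pooled = regression.pool_rubin([f, f, f])
        assert pooled.between["x"] == 0.0
        assert pooled.total["x"] == pytest.approx(0.04)
        single = f.or_table().loc["x"]
        got = pooled.or_table().loc["x"]
        assert got["lcl"] == pytest.approx(single["lcl"], rel=1e-6)
        assert got["ucl"] == pytest.approx(single["ucl"], rel=1e-6)

    def test_hand_computed_rubin_formulas(self):
        v = 0.04
        f1 = self._fit_like([0.0, 0.0], [v, v])
        f2 = self._fit_like([0.0, 1.0], [v, v])
        pooled = regression.pool_rubin([f1, f2])
        assert pooled.estimate["x"] == pytest.approx(0.5)
        assert pooled.between["x"] == pytest.approx(0.5)  # var([0,1], ddof=1)
        assert pooled.total["x"] == pytest.approx(v + 1.5 * 0.5)

    def test_mismatched_coefficients_rejected(self):
        f1 = self._fit_like([0.0, 0.0], [0.1, 0.1])
        f2 = regression.LogisticFit(
            params=pd.Series([0.0], pd.Index(["const"])),
            cov=pd.DataFrame([[0.1]], index=["const"], columns=["const"]),
            n_used=100, n_total=100, converged=True,
        )
        with pytest.raises(ValueError):
            regression.pool_rubin([f1, f2])
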