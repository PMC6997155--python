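"""Condition index, trait mixed model, beta GAM and difference smooths."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit
from scipy.stats import chi2

from forageq.inference import (BetaGAM, CubicRegressionSpline, body_condition,
                               fit_trait_model, simulate_trip_quality)
from forageq.synthetic import generate_bird_metadata


class TestBodyCondition:
    def test_per_sex_standardization(self):
        md = generate_bird_metadata(40, seed=1)
        ci = body_condition(md)
        for _, sub in ci.groupby("sex"):
            assert abs(sub["condition"].mean()) < 1e-8
            assert abs(sub["condition"].std(ddof=1) - 1.0) < 1e-8

    def test_perfect_allometry_degenerate(self):
        md = generate_bird_metadata(20, seed=2, noise_sd=0.0)
        ci = body_condition(md)
        assert (ci["condition"] == 0).all()
        assert ci["degenerate"].all()

    def test_matches_normal_equations_oracle(self):
        md = pd.DataFrame({
            "bird_id": list("abcde"),
            "sex": ["F"] * 5,
            "mass_g": [3000.0, 3200.0, 2900.0, 3500.0, 3100.0],
            "tarsus_mm": [95.0, 98.0, 93.0, 101.0, 96.0],
        })
        ci = body_condition(md).set_index("bird_id")
        ylog = np.log(md["mass_g"].to_numpy())
        X = np.column_stack([np.ones(5), 3 * np.log(md["tarsus_mm"].to_numpy())])
        beta = np.linalg.solve(X.T @ X, X.T @ ylog)
        r = ylog - X @ beta
        z = (r - r.mean()) / r.std(ddof=1)
        np.testing.assert_allclose(ci.loc[list("abcde"), "condition"], z, atol=1e-10)

    def test_nonpositive_measurements_rejected(self):
        md = generate_bird_metadata(5, seed=0)
        md.loc[0, "mass_g"] = -1.0
        with pytest.raises(ValueError):
            body_condition(md)


class TestTraitModel:
    def _tq(self, seed, sex_effect=0.0, bird_sd=0.0, n_birds=10, trips=6):
        rng = np.random.default_rng(seed)
        md = generate_bird_metadata(n_birds, seed=seed)
        md["sex"] = np.where(np.arange(n_birds) % 2 == 0, "F", "M")
        rows = []
        be = rng.normal(0, bird_sd, n_birds)
        for i, bird in enumerate(md["bird_id"]):
            sx = 1.0 if md["sex"].iloc[i] == "M" else 0.0
            for t in range(trips):
                eta = -1.0 + sex_effect * sx + be[i] + rng.normal(0, 0.4)
                rows.append({"group": "observed", "year": 2015,
                             "julian_day": 150, "bird_id": bird,
                             "trip_id": f"{bird}_{t}", "S": float(expit(eta))})
        return pd.DataFrame(rows), md

    def test_zero_between_bird_variance_matches_ols(self):
        import statsmodels.formula.api as smf
        import warnings
        tq, md = self._tq(seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_trait_model(tq, md)
        cond = body_condition(md)
        df = tq.merge(cond[["bird_id", "sex", "condition"]], on="bird_id")
        df["logit_S"] = logit(df["S"])
        ols = smf.ols("logit_S ~ sex + condition + C(year)", df).fit()
        for name in ("Intercept", "sex[T.M]", "condition"):
            assert abs(fit.fe_params[name] - ols.params[name]) < 0.02

    def test_type_one_error_calibrated(self):
        """No-effect simulation: fixed-effect rejections at the 5% level
        stay within Monte Carlo error of nominal."""
        import warnings
        rej = 0
        n_rep = 120
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(n_rep):
                tq, md = self._tq(seed=1000 + s)
                fit = fit_trait_model(tq, md)
                rej += fit.pvalues["sex[T.M]"] < 0.05
        rate = rej / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se + 0.01

    def test_sex_effect_recovered(self):
        import warnings
        hits = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(20):
                tq, md = self._tq(seed=2000 + s, sex_effect=0.6, bird_sd=0.2,
                                  n_birds=20)
                fit = fit_trait_model(tq, md)
                est = fit.fe_params["sex[T.M]"]
                se = fit.bse["sex[T.M]"]
                hits += abs(est - 0.6) < 2 * se
        assert hits >= 18


class TestSplineBasis:
    def test_interpolates_coefficients_at_knots(self):
        knots = np.array([0.0, 1.0, 2.5, 4.0, 6.0])
        cs = CubicRegressionSpline(knots)
        B = cs.design(knots)
        np.testing.assert_allclose(B, np.eye(5), atol=1e-12)

    def test_penalty_equals_integrated_squared_curvature(self):
        knots = np.linspace(0, 10, 7)
        cs = CubicRegressionSpline(knots)
        rng = np.random.default_rng(4)
        beta = rng.normal(0, 1, 7)
        x = np.linspace(0, 10, 4001)
        f = cs.design(x) @ beta
        d2 = np.gradient(np.gradient(f, x), x)
        numeric = np.trapezoid(d2[5:-5] ** 2, x[5:-5])
        exact = beta @ cs.penalty @ beta
        assert abs(numeric - exact) / exact < 0.02


def beta_ml_oracle(y, X):
    """Direct maximum likelihood for a parametric beta regression."""
    def nll(par):
        b, lphi = par[:-1], par[-1]
        mu = np.clip(expit(X @ b), 1e-8, 1 - 1e-8)
        phi = np.exp(lphi)
        a, c = mu * phi, (1 - mu) * phi
        return -np.sum(gammaln(phi) - gammaln(a) - gammaln(c)
                       + (a - 1) * np.log(y) + (c - 1) * np.log1p(-y))
    x0 = np.zeros(X.shape[1] + 1)
    x0[-1] = np.log(10.0)
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    return res.x[:-1], float(np.exp(res.x[-1]))


class TestBetaGAM:
    def test_flat_response_shrinks_smooths_and_matches_ml_oracle(self):
        """Constant-mean data: smooths are penalized down to (near) their
        null space and the parametric fit matches a direct two-group beta
        maximum-likelihood oracle."""
        tq = simulate_trip_quality(300, seed=5, bird_sd=0.0)
        res = BetaGAM(tq).fit()
        # each smooth offers 9 basis dof; near-flat truth should leave only
        # a small remainder beyond the unpenalized (linear) null space
        assert res.edf["smooth_obs"] + res.edf["smooth_sim"] < 5.0
        y = tq["S"].to_numpy()
        X = np.column_stack([np.ones(len(tq)),
                             (tq["group"] == "observed").to_numpy(float)])
        b_or, phi_or = beta_ml_oracle(y, X)
        tab = res.parametric_table()
        assert abs(tab.loc["intercept", "estimate"] - b_or[0]) < 5e-3
        assert abs(tab.loc["group[observed]", "estimate"] - b_or[1]) < 5e-3
        assert abs(res.phi - phi_or) / phi_or < 0.05

    def test_smooth_offset_recovery(self):
        """Groups differ by a smooth logistic-scale step of 0.5 from day 150
        on; the fitted group smooths recover the generating curves."""
        step = lambda d: 0.5 * expit((np.asarray(d) - 150.0) / 4.0)
        base = lambda d: 0.6 * np.sin((np.asarray(d) - 120) / 60 * np.pi)
        tq = simulate_trip_quality(400, seed=6, bird_sd=0.0,
                                   f_obs=lambda d: base(d) + step(d),
                                   f_sim=base)
        res = BetaGAM(tq).fit()
        grid = np.linspace(121, 179, 80)
        d = res.difference_smooth(grid)
        rmse = np.sqrt(np.mean((d["D"].to_numpy() - step(grid)) ** 2))
        assert rmse < 0.15

    def test_difference_smooth_antisymmetric_under_label_swap(self):
        # fixed moderate hyperparameters: the design is exactly symmetric
        # under the swap, so the fitted difference negates to solver precision
        tq = simulate_trip_quality(120, seed=7)
        lam = np.array([5.0, 5.0, 5.0])
        r1 = BetaGAM(tq).fit(lam=lam, phi=60.0)
        sw = tq.copy()
        sw["group"] = sw["group"].map({"observed": "simulated",
                                       "simulated": "observed"})
        r2 = BetaGAM(sw).fit(lam=lam, phi=60.0)
        np.testing.assert_allclose(r1.difference_smooth()["D"],
                                   -r2.difference_smooth()["D"],
                                   rtol=0, atol=1e-8)

    def test_constant_offset_recovered_within_two_se(self):
        tq = simulate_trip_quality(400, seed=8, group_effect=0.4)
        res = BetaGAM(tq).fit()
        d = res.difference_smooth()
        mean_d = d["D"].mean()
        se = d["se"].mean()
        assert abs(mean_d - 0.4) < 2 * se

    def test_penalty_monotonicity(self):
        tq = simulate_trip_quality(150, seed=9)
        m = BetaGAM(tq)
        lls, edfs = [], []
        for lam in (1e-4, 1.0, 1e4):
            r = m.fit(lam=np.array([lam, lam, 1.0]), phi=50.0)
            lls.append(r.loglik)
            edfs.append(r.edf["smooth_obs"] + r.edf["smooth_sim"])
        assert lls[0] >= lls[1] >= lls[2]
        assert edfs[0] > edfs[1] > edfs[2]

    def test_deviance_invariant_to_row_order_and_bird_relabel(self):
        tq = simulate_trip_quality(150, seed=10)
        r1 = BetaGAM(tq).fit(lam=np.array([1.0, 1.0, 1.0]), phi=50.0)
        shuf = tq.sample(frac=1.0, random_state=3).reset_index(drop=True)
        shuf["bird_id"] = shuf["bird_id"].map(
            lambda b: None if b is None else f"renamed_{b}")
        r2 = BetaGAM(shuf).fit(lam=np.array([1.0, 1.0, 1.0]), phi=50.0)
        assert abs(r1.deviance_explained - r2.deviance_explained) < 1e-6

    def test_extrapolation_refused(self):
        tq = simulate_trip_quality(100, seed=11)
        res = BetaGAM(tq).fit(lam=np.array([1.0, 1.0, 1.0]), phi=50.0)
        with pytest.raises(ValueError, match="extrapolation"):
            res.difference_smooth(np.array([80.0, 200.0]))

    def test_boundary_response_rejected(self):
        tq = simulate_trip_quality(60, seed=12)
        tq.loc[0, "S"] = 1.0
        with pytest.raises(ValueError, match="strictly inside"):
            BetaGAM(tq)


class TestWaldContrasts:
    def test_matches_hand_formula(self):
        tq = simulate_trip_quality(300, seed=13,
                                   year_effects={2015: 0.0, 2016: 0.4})
        res = BetaGAM(tq).fit()
        out = res.wald_year_contrasts().iloc[0]
        i = 2  # year dummy follows intercept + group
        est = res.params[i]
        var = res.cov_params[i, i]
        x2 = est ** 2 / var
        assert np.isclose(out["chi2"], x2)
        assert np.isclose(out["p"], chi2.sf(x2, 1))

    def test_null_year_pvalues_roughly_uniform(self):
        """Equal generating year means: Wald p-values across seeded
        replicates look uniform (KS test)."""
        from scipy.stats import kstest
        ps = []
        for s in range(60):
            tq = simulate_trip_quality(150, seed=3000 + s, bird_sd=0.0,
                                       year_effects={2015: 0.0, 2016: 0.0})
            res = BetaGAM(tq).fit()
            ps.append(res.wald_year_contrasts()["p"].iloc[0])
        assert kstest(ps, "uniform").pvalue > 0.01
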