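"""Trip-quality inference: condition index, trait model, beta-likelihood GAM.

The central model is a penalized additive regression for trip-mean habitat
quality S in (0, 1) under a beta likelihood with logit link:

    logit E[S] = b0 + b_group * 1[observed] + year effects
                 + f_obs(day) * 1[observed] + f_sim(day) * 1[simulated]
                 + bird random intercept

with f_* penalized cubic regression splines (second-derivative penalty,
sum-to-zero constrained) and the bird intercepts a ridge-penalized block
(the usual random-effect-as-penalized-smooth equivalence).  Coefficients
are estimated by penalized Fisher scoring (PIRLS); the smoothing
parameters and the beta precision phi are chosen by minimizing the
Laplace-approximate restricted marginal likelihood.  The coefficient
covariance (inverse penalized Hessian) supports the pointwise
difference-of-smooths procedure used to locate the part of the season
where observed foraging quality departs from the resampling null, and
Wald contrasts between years.

Model/Results usage::

    gam = BetaGAM(trip_quality)          # TripQuality-style DataFrame
    res = gam.fit()
    print(res.summary())
    diff = res.difference_smooth()       # day grid, D, lo, hi, significant
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit, polygamma
from scipy.stats import chi2, norm

__all__ = [
    "body_condition",
    "fit_trait_model",
    "CubicRegressionSpline",
    "BetaGAM",
    "BetaGAMResults",
    "simulate_trip_quality",
]


# --------------------------------------------------------------------------
# body condition & trait model


def body_condition(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sex body condition index.

    Within each sex, ordinary least squares of log(mass) on 3*log(tarsus);
    the index is the standardized residual (mean 0, SD 1 within sex).  A
    perfect allometric fit leaves zero residual variance, in which case
    the indices are set to 0 with a warning flag.
    """
    need = {"bird_id", "sex", "mass_g", "tarsus_mm"}
    if not need <= set(metadata.columns):
        raise ValueError(f"metadata must have columns {sorted(need)}")
    if (metadata["mass_g"] <= 0).any() or (metadata["tarsus_mm"] <= 0).any():
        raise ValueError("mass and tarsus must be positive")
    out = []
    for sex, sub in metadata.groupby("sex"):
        ylog = np.log(sub["mass_g"].to_numpy(float))
        xlog = 3.0 * np.log(sub["tarsus_mm"].to_numpy(float))
        X = np.column_stack([np.ones(len(sub)), xlog])
        coef, *_ = np.linalg.lstsq(X, ylog, rcond=None)
        resid = ylog - X @ coef
        sd = resid.std(ddof=1) if len(resid) > 1 else 0.0
        degenerate = sd < 1e-12
        z = np.zeros(len(resid)) if degenerate else (resid - resid.mean()) / sd
        out.append(pd.DataFrame({"bird_id": sub["bird_id"], "sex": sex,
                                 "condition": z, "degenerate": degenerate}))
    return pd.concat(out, ignore_index=True)


def fit_trait_model(trip_quality: pd.DataFrame, metadata: pd.DataFrame):
    """Mixed model of individual traits on trip-mean quality.

    Gaussian random-intercept model on logit(S) with sex, condition and
    year as fixed effects and bird identity as the random effect, fitted
    by REML (statsmodels MixedLM).  Returns the fitted results object;
    singular fits (zero between-bird variance) still yield valid fixed
    effects and are flagged by ``converged``/warnings.
    """
    cond = body_condition(metadata)
    df = trip_quality.merge(cond[["bird_id", "sex", "condition"]], on="bird_id")
    if df["bird_id"].nunique() < 2:
        raise ValueError("need at least two birds")
    df = df.copy()
    df["logit_S"] = logit(np.clip(df["S"], 1e-9, 1 - 1e-9))
    model = smf.mixedlm("logit_S ~ sex + condition + C(year)", df,
                        groups=df["bird_id"])
    return model.fit(reml=True)


# --------------------------------------------------------------------------
# cubic regression spline basis


class CubicRegressionSpline:
    """Cardinal natural cubic spline basis with exact curvature penalty.

    Coefficients are the function values at the knots; the penalty matrix
    gives the integrated squared second derivative.  Evaluation outside
    the knot range is clamped to the boundary knots.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.unique(np.asarray(knots, float))
        if len(knots) < 4:
            raise ValueError("need at least 4 distinct knots")
        self.knots = knots
        k = len(knots)
        h = np.diff(knots)
        D = np.zeros((k - 2, k))
        B = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        self._F = np.vstack([np.zeros(k), np.linalg.solve(B, D), np.zeros(k)])
        self.penalty = D.T @ np.linalg.solve(B, D)

    def design(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, float), self.knots[0], self.knots[-1])
        k = len(self.knots)
        j = np.clip(np.searchsorted(self.knots, x, side="right") - 1, 0, k - 2)
        h = self.knots[j + 1] - self.knots[j]
        dl = x - self.knots[j]
        dr = self.knots[j + 1] - x
        am, ap = dr / h, dl / h
        cm = (dr ** 3 / h - h * dr) / 6.0
        cp = (dl ** 3 / h - h * dl) / 6.0
        X = np.zeros((len(x), k))
        rows = np.arange(len(x))
        X[rows, j] += am
        X[rows, j + 1] += ap
        X += cm[:, None] * self._F[j] + cp[:, None] * self._F[j + 1]
        return X


def _constrain_to_zero_mean(X: np.ndarray, S: np.ndarray):
    """Absorb the sum-to-zero identifiability constraint over the data rows."""
    C = X.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(C.T, mode="complete")
    Z = q[:, 1:]
    return X @ Z, Z.T @ S @ Z, Z


# --------------------------------------------------------------------------
# beta likelihood internals


def _beta_loglik(y, mu, phi):
    a = mu * phi
    b = (1 - mu) * phi
    return np.sum(gammaln(phi) - gammaln(a) - gammaln(b)
                  + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y))


def _beta_score_weights(y, mu, phi):
    """Score and Fisher weight of the beta loglik w.r.t. the logit predictor."""
    ystar = np.log(y) - np.log1p(-y)
    mustar = digamma(mu * phi) - digamma((1 - mu) * phi)
    dmu = mu * (1 - mu)
    u = phi * (ystar - mustar) * dmu
    w = phi ** 2 * (polygamma(1, mu * phi) + polygamma(1, (1 - mu) * phi)) * dmu ** 2
    return u, np.maximum(w, 1e-10)


# --------------------------------------------------------------------------
# the model


class BetaGAM:
    """Beta-likelihood additive model for trip-mean habitat quality.

    Parameters
    ----------
    data : DataFrame
        TripQuality table with columns group (two levels, the first level
        after sorting taken as reference/simulated), year, julian_day,
        bird_id, S in (0, 1).
    n_knots : int
        Basis functions per group smooth (default 10).
    observed_group : str
        Level of ``group`` treated as the observed birds (indicator = 1,
        bird random intercepts attached); default "observed".
    """

    def __init__(self, data: pd.DataFrame, n_knots: int = 10,
                 observed_group: str = "observed"):
        need = {"group", "year", "julian_day", "bird_id", "S"}
        if not need <= set(data.columns):
            raise ValueError(f"data must have columns {sorted(need)}")
        y = data["S"].to_numpy(float)
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("response must lie strictly inside (0, 1)")
        groups = sorted(data["group"].unique())
        if len(groups) != 2 or observed_group not in groups:
            raise ValueError("group must have exactly two levels incl. the observed one")
        counts = data["group"].value_counts()
        if counts.min() < 30:
            raise ValueError("need at least 30 trips per group")
        self.data = data.reset_index(drop=True)
        self.y = y
        self.observed_group = observed_group
        obs = (self.data["group"] == observed_group).to_numpy()
        day = self.data["julian_day"].to_numpy(float)
        self.day_range = (float(day.min()), float(day.max()))

        # parametric block
        self.years = sorted(self.data["year"].unique())
        cols = [np.ones(len(y)), obs.astype(float)]
        names = ["intercept", f"group[{observed_group}]"]
        for yr in self.years[1:]:
            cols.append((self.data["year"] == yr).to_numpy(float))
            names.append(f"year[{yr}]")
        Xp = np.column_stack(cols)

        # group-specific smooths on a common knot grid
        knots = np.quantile(day, np.linspace(0, 1, n_knots))
        self.spline = CubicRegressionSpline(knots)
        Braw = self.spline.design(day)
        Bc, Sc, self._Z = _constrain_to_zero_mean(Braw, self.spline.penalty)
        X_obs = Bc * obs[:, None].astype(float)
        X_sim = Bc * (~obs)[:, None].astype(float)

        # bird random intercepts: one ridge-penalized level per bird id;
        # rows with a missing bird id (pseudo-trips of the resampling null,
        # which have no individual) carry no random effect
        bird = self.data["bird_id"]
        self.bird_levels = sorted(bird.dropna().unique())
        Xb = np.zeros((len(y), len(self.bird_levels)))
        for i, b in enumerate(self.bird_levels):
            Xb[:, i] = (bird == b).to_numpy(float)

        self.X = np.hstack([Xp, X_obs, X_sim, Xb])
        self.param_names = names
        p_par = Xp.shape[1]
        p_sm = Bc.shape[1]
        self.slices = {
            "parametric": slice(0, p_par),
            "smooth_obs": slice(p_par, p_par + p_sm),
            "smooth_sim": slice(p_par + p_sm, p_par + 2 * p_sm),
            "bird": slice(p_par + 2 * p_sm, p_par + 2 * p_sm + len(self.bird_levels)),
        }
        self._S_blocks = [("smooth_obs", Sc), ("smooth_sim", Sc),
                          ("bird", np.eye(len(self.bird_levels)))]
        # positive-eigenvalue log determinants and ranks of each penalty
        self._block_eig = []
        for _, Sk in self._S_blocks:
            ev = np.linalg.eigvalsh(Sk)
            pos = ev[ev > 1e-9 * ev.max()]
            self._block_eig.append((len(pos), float(np.sum(np.log(pos)))))

    # -- fitting -----------------------------------------------------------

    def _penalty(self, lam: np.ndarray) -> np.ndarray:
        p = self.X.shape[1]
        S = np.zeros((p, p))
        for lk, (name, Sk) in zip(lam, self._S_blocks):
            sl = self.slices[name]
            S[sl, sl] += lk * Sk
        return S

    def _pirls(self, lam, phi, beta0=None, max_iter=100, tol=1e-9,
               gtol=None):
        X, y = self.X, self.y
        S = self._penalty(lam)
        if beta0 is None:
            beta = np.zeros(X.shape[1])
            beta[0] = logit(y.mean())
        else:
            beta = beta0.copy()
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-8, 1 - 1e-8)
        pll = _beta_loglik(y, mu, phi) - 0.5 * beta @ S @ beta
        H = None
        for _ in range(max_iter):
            u, w = _beta_score_weights(y, mu, phi)
            XtW = X.T * w
            H = XtW @ X + S
            grad = X.T @ u - S @ beta
            if gtol is not None and np.abs(grad).max() < gtol:
                break
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            new_pll = -np.inf
            t = 1.0
            for _ in range(40):
                cand = beta + t * step
                mu_c = np.clip(expit(X @ cand), 1e-8, 1 - 1e-8)
                new_pll = _beta_loglik(y, mu_c, phi) - 0.5 * cand @ S @ cand
                if new_pll >= pll - 1e-12:
                    break
                t *= 0.5
            if gtol is not None and t < 1e-8 and new_pll - pll < 1e-12:
                break  # numerical floor reached before the gradient target
            beta = beta + t * step
            mu = np.clip(expit(X @ beta), 1e-8, 1 - 1e-8)
            if gtol is None and abs(new_pll - pll) < tol * (1 + abs(pll)):
                pll = new_pll
                break
            pll = new_pll
        u, w = _beta_score_weights(y, mu, phi)
        H = (self.X.T * w) @ self.X + S
        return beta, mu, H, S, pll

    def _laml(self, rho, state) -> float:
        """Negative Laplace-approximate restricted marginal likelihood."""
        lam = np.exp(rho[:-1])
        phi = np.exp(rho[-1])
        if phi > 1e7 or np.any(lam > 1e12):
            return 1e10
        beta, mu, H, S, pll = self._pirls(lam, phi, beta0=state.get("beta"))
        state["beta"] = beta
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        logdetS = sum(r * np.log(lk) + ld
                      for lk, (r, ld) in zip(lam, self._block_eig))
        mp = self.X.shape[1] - sum(r for r, _ in self._block_eig)
        laml = pll + 0.5 * logdetS - 0.5 * logdetH + 0.5 * mp * np.log(2 * np.pi)
        return -laml

    def fit(self, maxiter: int = 200, lam: np.ndarray | None = None,
            phi: float | None = None) -> "BetaGAMResults":
        """Estimate coefficients, smoothing parameters and precision.

        Outer Nelder-Mead on (log smoothing parameters, log phi) against
        the Laplace-approximate REML criterion; inner penalized Fisher
        scoring, warm-started between outer evaluations.  Supplying both
        ``lam`` and ``phi`` skips the outer search and fits the
        coefficients at those fixed values.
        """
        if lam is not None and phi is not None:
            return self._finalize(np.asarray(lam, float), float(phi), None, True)
        y = self.y
        m, v = y.mean(), y.var()
        phi0 = float(np.clip(m * (1 - m) / max(v, 1e-6) - 1, 2.0, 1e4))
        x0 = np.concatenate([np.zeros(len(self._S_blocks)), [np.log(phi0)]])
        # explicit simplex: unit log-scale steps (the default simplex barely
        # perturbs zero coordinates, stalling the smoothing-parameter search)
        simplex = [x0]
        for i in range(len(x0)):
            v = x0.copy()
            v[i] += 2.0 if i < len(self._S_blocks) else 0.5
            simplex.append(v)
        state: dict = {}
        opt = minimize(self._laml, x0, args=(state,), method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-5,
                                "initial_simplex": np.array(simplex)})
        return self._finalize(np.exp(opt.x[:-1]), float(np.exp(opt.x[-1])),
                              state.get("beta"), bool(opt.success))

    def _finalize(self, lam: np.ndarray, phi: float, beta0,
                  outer_converged: bool) -> "BetaGAMResults":
        y = self.y
        beta, mu, H, S, pll = self._pirls(lam, phi, beta0=beta0,
                                          max_iter=300, gtol=1e-9)
        Vb = np.linalg.inv(H)
        XtWX = H - S
        edf_vec = np.sum(Vb * XtWX.T, axis=1)  # diag of Vb @ XtWX
        ll = _beta_loglik(y, mu, phi)
        ll_sat = _beta_loglik(y, np.clip(y, 1e-8, 1 - 1e-8), phi)
        # null (intercept-only) fit at the same phi for deviance explained
        b0 = logit(y.mean())
        for _ in range(50):
            mu0 = np.full_like(y, np.clip(expit(b0), 1e-8, 1 - 1e-8))
            u0, w0 = _beta_score_weights(y, mu0, phi)
            step = u0.sum() / w0.sum()
            b0 += step
            if abs(step) < 1e-12:
                break
        ll_null = _beta_loglik(y, np.full_like(y, np.clip(expit(b0), 1e-8, 1 - 1e-8)), phi)
        return BetaGAMResults(
            model=self, params=beta, cov_params=Vb, lam=lam, phi=phi,
            edf_vec=edf_vec, loglik=float(ll), loglik_sat=float(ll_sat),
            loglik_null=float(ll_null), fitted=mu, outer_converged=outer_converged,
        )


@dataclass
class BetaGAMResults:
    """Fitted beta GAM: estimates, covariance, smooth diagnostics."""

    model: BetaGAM
    params: np.ndarray
    cov_params: np.ndarray
    lam: np.ndarray
    phi: float
    edf_vec: np.ndarray
    loglik: float
    loglik_sat: float
    loglik_null: float
    fitted: np.ndarray
    outer_converged: bool

    # -- diagnostics -------------------------------------------------------

    @property
    def edf(self) -> dict[str, float]:
        return {name: float(self.edf_vec[sl].sum())
                for name, sl in self.model.slices.items()}

    @property
    def deviance_explained(self) -> float:
        dev = 2 * (self.loglik_sat - self.loglik)
        dev0 = 2 * (self.loglik_sat - self.loglik_null)
        return float(1 - dev / dev0) if dev0 > 0 else np.nan

    def fixed_effects_share(self) -> float:
        """Share of explained deviance attributable to non-bird terms.

        Computed by refitting with the bird random-intercept block removed
        (its smoothing parameter sent to +inf) at the estimated phi, and
        taking the ratio of that fit's deviance explained to the full
        model's.  An interpretation choice — reported, not a likelihood
        quantity.
        """
        lam = self.lam.copy()
        lam[-1] = 1e12  # bird block is last
        beta, mu, *_ = self.model._pirls(lam, self.phi, beta0=self.params)
        ll = _beta_loglik(self.model.y, mu, self.phi)
        de_fixed = 1 - (2 * (self.loglik_sat - ll)) / (2 * (self.loglik_sat - self.loglik_null))
        de_full = self.deviance_explained
        return float(de_fixed / de_full) if de_full > 0 else np.nan

    def parametric_table(self) -> pd.DataFrame:
        sl = self.model.slices["parametric"]
        est = self.params[sl]
        se = np.sqrt(np.diag(self.cov_params)[sl])
        t = est / se
        p = 2 * norm.sf(np.abs(t))
        return pd.DataFrame({"estimate": est, "se": se, "t": t, "p": p},
                            index=self.model.param_names)

    def smooth_table(self) -> pd.DataFrame:
        """Approximate Wald test per smooth (chi-square on the block)."""
        rows = {}
        for name in ("smooth_obs", "smooth_sim"):
            sl = self.model.slices[name]
            b = self.params[sl]
            V = self.cov_params[sl, sl]
            Vinv = np.linalg.pinv(V, rcond=1e-10)
            x2 = float(b @ Vinv @ b)
            df = max(self.edf[name], 1e-3)
            rows[name] = {"edf": self.edf[name], "chi2": x2,
                          "p": float(chi2.sf(x2, max(np.round(df), 1)))}
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = [
            "Beta-likelihood additive model (logit link)",
            f"  n = {len(self.model.y)} trips, phi = {self.phi:.2f}, "
            f"deviance explained = {100 * self.deviance_explained:.1f}%",
            f"  smoothing parameters: {np.array2string(self.lam, precision=3)}",
            "", "Parametric terms:", self.parametric_table().to_string(),
            "", "Smooth terms:", self.smooth_table().to_string(),
        ]
        return "\n".join(lines)

    # -- prediction machinery ----------------------------------------------

    def _row(self, day: np.ndarray, observed: bool) -> np.ndarray:
        """Linear-predictor design rows at reference year, no bird effect."""
        m = self.model
        n = len(day)
        p = self.model.X.shape[1]
        X = np.zeros((n, p))
        X[:, 0] = 1.0
        X[:, 1] = 1.0 if observed else 0.0
        B = m.spline.design(day) @ m._Z
        # the constraint was absorbed over data rows; reuse the same map
        sl = m.slices["smooth_obs" if observed else "smooth_sim"]
        X[:, sl] = B
        return X

    def difference_smooth(self, grid: np.ndarray | None = None,
                          level: float = 0.95,
                          allow_extrapolation: bool = False) -> pd.DataFrame:
        """Pointwise observed-minus-simulated difference with 95% band.

        The design rows for the two groups at each grid day are
        differenced (year and intercept terms cancel; the group indicator
        and the two smooths remain), giving D(d) = x_diff @ beta with
        SE from the coefficient covariance.  ``significant`` marks days
        whose interval excludes zero.
        """
        lo_d, hi_d = self.model.day_range
        if grid is None:
            grid = np.arange(np.ceil(lo_d), np.floor(hi_d) + 1)
        grid = np.asarray(grid, float)
        if not allow_extrapolation and (grid.min() < lo_d - 1e-9 or grid.max() > hi_d + 1e-9):
            raise ValueError("grid outside the fitted day range "
                             "(pass allow_extrapolation=True to override)")
        Xd = self._row(grid, True) - self._row(grid, False)
        D = Xd @ self.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xd, self.cov_params, Xd))
        zq = norm.ppf(0.5 + level / 2)
        lo = D - zq * se
        hi = D + zq * se
        return pd.DataFrame({"day": grid, "D": D, "se": se, "lo": lo, "hi": hi,
                             "significant": (lo > 0) | (hi < 0)})

    def wald_year_contrasts(self) -> pd.DataFrame:
        """Pairwise Wald chi-square tests between year intercepts (df = 1)."""
        m = self.model
        if len(m.years) < 2:
            raise ValueError("need at least two year levels")
        p = len(self.params)
        vecs = {m.years[0]: np.zeros(p)}
        for i, yr in enumerate(m.years[1:]):
            v = np.zeros(p)
            v[2 + i] = 1.0  # year dummies follow intercept + group
            vecs[yr] = v
        rows = []
        for i, y1 in enumerate(m.years):
            for y2 in m.years[i + 1:]:
                c = vecs[y1] - vecs[y2]
                var = float(c @ self.cov_params @ c)
                if var <= 0:
                    continue
                x2 = float((c @ self.params) ** 2 / var)
                rows.append((y1, y2, x2, float(chi2.sf(x2, 1))))
        return pd.DataFrame(rows, columns=["year_a", "year_b", "chi2", "p"])


# --------------------------------------------------------------------------
# trip-quality simulator (for calibration and power checks)


def simulate_trip_quality(n_per_group: int, seed: int,
                          f_obs=None, f_sim=None,
                          group_effect: float = 0.0,
                          year_effects: dict[int, float] | None = None,
                          day_range: tuple[int, int] = (120, 180),
                          phi: float = 60.0, n_birds: int = 15,
                          bird_sd: float = 0.15) -> pd.DataFrame:
    """Generate a TripQuality table from a known beta-GAM data process.

    Observed and simulated groups share uniformly scattered Julian days;
    the linear predictor is smooth(day) + group/year effects (+ bird
    random intercepts for observed trips), and S ~ Beta(mu*phi, (1-mu)*phi).
    """
    rng = np.random.default_rng(seed)
    f_obs = f_obs or (lambda d: 0.0 * d)
    f_sim = f_sim or (lambda d: 0.0 * d)
    year_effects = year_effects or {2015: 0.0}
    years = np.array(sorted(year_effects))
    rows = []
    bird_eff = rng.normal(0, bird_sd, n_birds)
    for grp, f, gshift in (("observed", f_obs, group_effect), ("simulated", f_sim, 0.0)):
        day = rng.uniform(*day_range, n_per_group)
        yr = years[rng.integers(0, len(years), n_per_group)]
        eta = (np.asarray(f(day), float) + gshift
               + np.array([year_effects[v] for v in yr]))
        if grp == "observed":
            bi = rng.integers(0, n_birds, n_per_group)
            eta = eta + bird_eff[bi]
            bird = [f"bird{int(i):02d}" for i in bi]
        else:
            bird = [None] * n_per_group  # pseudo-trips have no individual
        mu = expit(eta)
        S = rng.beta(mu * phi, (1 - mu) * phi)
        S = np.clip(S, 1e-6, 1 - 1e-6)
        for i in range(n_per_group):
            rows.append((grp, int(yr[i]), float(day[i]), bird[i],
                         f"{grp[:3]}_{len(rows)}", float(S[i])))
    return pd.DataFrame(rows, columns=["group", "year", "julian_day",
                                       "bird_id", "trip_id", "S"])
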