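"""Presence-background maximum-entropy species distribution model.

A minimal, deterministic maxent: the fitted distribution over a background
sample maximizes entropy subject to (L1-relaxed) presence feature-mean
constraints, which is equivalent to minimizing

    J(beta) = log Z(beta) - beta . mean(f_presence) + sum_j pen_j |beta_j|

with Z summed over background, pen_j = lambda * sd_j / sqrt(n_presence)
(the per-feature penalty scaled by the global regularization multiplier
lambda), over linear + quadratic + pairwise-product + hinge features
scaled to [0, 1] on the background.  The objective is convex and is
minimized by cyclic coordinate descent with exact per-update objective
accounting, which also yields the percent-contribution decomposition.

Suitability uses the complementary log-log transform
``1 - exp(-exp(H) * p_raw)`` with H the entropy of the fitted raw
distribution, reading approximately as probability of presence.

Usage follows the Model/Results convention::

    model = Maxent(presence_df, background_df, variables=["sst", "chla"])
    res = model.fit(lam=2.0)
    res.cloglog(grid_df)
    res.percent_contribution()
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "FeatureConfig",
    "FeatureExpansion",
    "Maxent",
    "MaxentResults",
    "CVResult",
    "auc",
    "cross_validate",
    "permutation_importance",
]


@dataclass(frozen=True)
class FeatureConfig:
    linear: bool = True
    quadratic: bool = True
    product: bool = True
    hinge: bool = True
    n_hinge_knots: int = 4


class FeatureExpansion:
    """Deterministic feature map fitted on the background sample.

    Each raw variable is min-max scaled to [0, 1] over the background;
    features are the scaled variables, their squares, pairwise products,
    and forward/reverse hinges with knots at background quantiles.  Every
    feature records its parent variable(s) for importance attribution.
    """

    def __init__(self, background: pd.DataFrame, variables: list[str],
                 config: FeatureConfig = FeatureConfig()):
        self.variables = list(variables)
        self.config = config
        B = background[self.variables].to_numpy(float)
        if not np.isfinite(B).all():
            raise ValueError("non-finite values in background variables")
        self.lo = B.min(axis=0)
        self.hi = B.max(axis=0)
        span = self.hi - self.lo
        self.span = np.where(span > 0, span, 1.0)
        Bs = (B - self.lo) / self.span
        self.knots = {}
        if config.hinge and config.n_hinge_knots > 0:
            qs = np.linspace(0, 1, config.n_hinge_knots + 2)[1:-1]
            for i, v in enumerate(self.variables):
                self.knots[v] = np.quantile(Bs[:, i], qs)
        self.names: list[str] = []
        self.parents: list[tuple[str, ...]] = []
        self._plan()

    def _plan(self) -> None:
        c, V = self.config, self.variables
        if c.linear:
            for v in V:
                self.names.append(v)
                self.parents.append((v,))
        if c.quadratic:
            for v in V:
                self.names.append(f"{v}^2")
                self.parents.append((v,))
        if c.product:
            for i, v in enumerate(V):
                for w in V[i + 1:]:
                    self.names.append(f"{v}*{w}")
                    self.parents.append((v, w))
        if c.hinge:
            for v in V:
                for t in self.knots.get(v, ()):
                    self.names.append(f"hinge({v}>{t:.3g})")
                    self.parents.append((v,))
                for t in self.knots.get(v, ()):
                    self.names.append(f"hinge({v}<{t:.3g})")
                    self.parents.append((v,))

    @property
    def n_features(self) -> int:
        return len(self.names)

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        X = data[self.variables].to_numpy(float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in point variables")
        Xs = (X - self.lo) / self.span
        cols = []
        c, V = self.config, self.variables
        if c.linear:
            cols.append(Xs)
        if c.quadratic:
            cols.append(Xs ** 2)
        if c.product:
            for i in range(len(V)):
                for j in range(i + 1, len(V)):
                    cols.append((Xs[:, i] * Xs[:, j])[:, None])
        if c.hinge:
            for i, v in enumerate(V):
                kn = self.knots.get(v, np.empty(0))
                if len(kn):
                    fwd = np.maximum(0.0, Xs[:, i][:, None] - kn[None, :]) / np.maximum(1 - kn, 1e-12)
                    rev = np.maximum(0.0, kn[None, :] - Xs[:, i][:, None]) / np.maximum(kn, 1e-12)
                    cols.append(fwd)
                    cols.append(rev)
        return np.hstack(cols)


class Maxent:
    """Presence-background maxent model (fit with :meth:`fit`)."""

    def __init__(self, presence: pd.DataFrame, background: pd.DataFrame,
                 variables: list[str] | None = None,
                 features: FeatureConfig = FeatureConfig()):
        if variables is None:
            variables = [c for c in presence.columns
                         if c in background.columns
                         and np.issubdtype(presence[c].dtype, np.number)]
        if len(presence) < 10:
            raise ValueError("need at least 10 presence points")
        self.variables = list(variables)
        self.presence = presence
        self.background = background
        self.expansion = FeatureExpansion(background, self.variables, features)
        self.Fb = self.expansion.transform(background)
        self.fbar_p = self.expansion.transform(presence).mean(axis=0)
        self.n_presence = len(presence)

    def fit(self, lam: float = 2.0, max_iter: int = 1_000_000,
            tol: float = 1e-8) -> "MaxentResults":
        """Cyclic coordinate descent on the convex regularized objective.

        ``max_iter`` caps total coordinate updates (hard stop, reported via
        ``converged``); convergence is declared when a full sweep lowers
        the objective by less than ``tol``.
        """
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        Fb = self.Fb
        n_b, p = Fb.shape
        sd = Fb.std(axis=0)
        pen = lam * sd / np.sqrt(self.n_presence)
        beta = np.zeros(p)
        eta = np.zeros(n_b)
        gain = np.zeros(p)

        def probs(eta):
            w = np.exp(eta - eta.max())
            return w / w.sum()

        pvec = probs(eta)
        updates = 0
        converged = False
        while updates < max_iter:
            sweep_drop = 0.0
            for j in range(p):
                fj = Fb[:, j]
                m1 = pvec @ fj
                g = m1 - self.fbar_p[j]
                h = max(pvec @ (fj * fj) - m1 * m1, 1e-12)
                z = h * beta[j] - g
                bnew = np.sign(z) * max(abs(z) - pen[j], 0.0) / h
                delta = bnew - beta[j]
                if delta == 0.0:
                    continue
                # exact objective change for this coordinate move
                for _ in range(30):
                    dlogZ = np.log(pvec @ np.exp(delta * fj))
                    dJ = (dlogZ - delta * self.fbar_p[j]
                          + pen[j] * (abs(beta[j] + delta) - abs(beta[j])))
                    if dJ <= 1e-15:
                        break
                    delta *= 0.5
                else:
                    continue
                beta[j] += delta
                eta = eta + delta * fj
                pvec = probs(eta)
                gain[j] += max(-dJ, 0.0)
                sweep_drop += max(-dJ, 0.0)
                updates += 1
                if updates >= max_iter:
                    break
            if sweep_drop < tol:
                converged = True
                break
        logZ = float(np.log(np.sum(np.exp(eta - eta.max()))) + eta.max())
        pvec = probs(eta)
        H = float(-np.sum(pvec * np.log(np.maximum(pvec, 1e-300))))
        return MaxentResults(model=self, params=beta, logZ=logZ, entropy=H,
                             p_background=pvec, lam=lam, penalties=pen,
                             gain=gain, converged=converged, n_updates=updates)


@dataclass
class MaxentResults:
    """Fitted maxent model: weights, normalizer, entropy, fit trace."""

    model: Maxent
    params: np.ndarray
    logZ: float
    entropy: float
    p_background: np.ndarray
    lam: float
    penalties: np.ndarray
    gain: np.ndarray
    converged: bool
    n_updates: int

    def raw(self, data: pd.DataFrame) -> np.ndarray:
        """Raw maxent probability (normalized over the background)."""
        F = self.model.expansion.transform(data)
        return np.exp(F @ self.params - self.logZ)

    def cloglog(self, data: pd.DataFrame) -> np.ndarray:
        """Cloglog suitability 1 - exp(-exp(H) * p_raw), in (0, 1)."""
        return 1.0 - np.exp(-np.exp(self.entropy) * self.raw(data))

    def percent_contribution(self) -> pd.Series:
        """Objective-gain share per variable, normalized to 100%.

        Each coordinate update's objective improvement is credited to the
        updated feature's parent variable; product features split evenly
        between their two parents.
        """
        contrib = {v: 0.0 for v in self.model.variables}
        for g, parents in zip(self.gain, self.model.expansion.parents):
            for v in parents:
                contrib[v] += g / len(parents)
        total = sum(contrib.values())
        if total <= 0:
            return pd.Series({v: 0.0 for v in contrib})
        return pd.Series({v: 100.0 * c / total for v, c in contrib.items()})

    def to_json(self) -> str:
        """Serializable model: feature names, weights, normalizer, entropy."""
        return json.dumps({
            "variables": self.model.variables,
            "feature_names": self.model.expansion.names,
            "weights": self.params.tolist(),
            "penalties": self.penalties.tolist(),
            "logZ": self.logZ,
            "entropy": self.entropy,
            "lambda": self.lam,
            "converged": self.converged,
        }, indent=1)

    def summary(self) -> str:
        lines = [
            "Maximum-entropy presence-background model",
            f"  presences: {self.model.n_presence}   background: {len(self.p_background)}",
            f"  features: {self.model.expansion.n_features}   lambda: {self.lam}",
            f"  converged: {self.converged} after {self.n_updates} coordinate updates",
            f"  entropy H: {self.entropy:.4f}",
            "  percent contribution:",
        ]
        for v, c in self.percent_contribution().items():
            lines.append(f"    {v:>8s}: {c:6.1f}%")
        return "\n".join(lines)


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(random presence score > random background score).

    Ties count 0.5.
    """
    ps = np.asarray(presence_scores, float)
    bs = np.asarray(background_scores, float)
    if len(ps) == 0 or len(bs) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([ps, bs]))
    u = ranks[:len(ps)].sum() - len(ps) * (len(ps) + 1) / 2.0
    return float(u / (len(ps) * len(bs)))


@dataclass
class CVResult:
    """k-fold cross-validation: per-fold models and AUCs, averaged projection."""

    folds: list[MaxentResults]
    fold_auc: np.ndarray
    mean_auc: float = field(init=False)
    sd_auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_auc = float(np.mean(self.fold_auc))
        self.sd_auc = float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Averaged projection: arithmetic mean of fold cloglog outputs."""
        return np.mean([f.cloglog(data) for f in self.folds], axis=0)


def cross_validate(presence: pd.DataFrame, background: pd.DataFrame,
                   k: int = 10, lam: float = 2.0, seed: int = 0,
                   variables: list[str] | None = None,
                   features: FeatureConfig = FeatureConfig(),
                   max_iter: int = 1_000_000, tol: float = 1e-8) -> CVResult:
    """Seeded k-fold CV over presences; AUC on held-out presences vs background."""
    n = len(presence)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} presences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, int)
    for f in range(k):
        fold_of[order[f::k]] = f
    results, aucs = [], []
    for f in range(k):
        train = presence.iloc[fold_of != f]
        test = presence.iloc[fold_of == f]
        res = Maxent(train, background, variables, features).fit(lam, max_iter, tol)
        results.append(res)
        aucs.append(auc(res.cloglog(test), res.cloglog(background)))
    return CVResult(results, np.array(aucs))


def permutation_importance(results: MaxentResults, presence: pd.DataFrame,
                           background: pd.DataFrame, seed: int = 0) -> pd.Series:
    """AUC drop per variable when its values are permuted, normalized to 100%.

    The permutation shuffles one variable's values jointly across the
    presence + background evaluation points, breaking its association with
    the labels while preserving its marginal.
    """
    rng = np.random.default_rng(seed)
    base = auc(results.cloglog(presence), results.cloglog(background))
    drops = {}
    npres = len(presence)
    combined = pd.concat([presence, background], ignore_index=True)
    for v in results.model.variables:
        perm = combined.copy()
        perm[v] = rng.permutation(perm[v].to_numpy())
        scores = results.cloglog(perm)
        drops[v] = max(0.0, base - auc(scores[:npres], scores[npres:]))
    total = sum(drops.values())
    if total <= 0:
        return pd.Series({v: 0.0 for v in drops})
    return pd.Series({v: 100.0 * d / total for v, d in drops.items()})
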