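"""Cluster-robust inference for repeated measures of individual birds.

Point estimation is the ordinary pooled GLM (IRLS), which is exactly the
GEE estimator under an independence working correlation.  Uncertainty
comes from the cluster-level sandwich covariance

    V = B⁻¹ (Σ_c s_c s_cᵀ) B⁻¹,

with s_c = X_cᵀ (y_c − μ_c) the score contribution of cluster c (birds
are clusters) and B = Xᵀ W X the Fisher information ("bread") at the
canonical link.  No small-sample correction is applied, matching the
plain robust covariance and Wald z reported by geepack-style software.

Families: gaussian-identity and binomial-logit.  Classical two-sample
machinery (Welch t, Yates-corrected 2×2 chi-square) lives here too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as spstats

from .errors import (
    ConvergenceError,
    InputError,
    RankDeficientError,
    SeparationError,
)

MAX_IRLS_ITER = 100
IRLS_TOL = 1e-10


@dataclass
class FitResult:
    """One fitted GEE/GLM: estimates, robust covariance, Wald inference."""

    family: str
    names: list[str]
    coef: np.ndarray
    vcov_robust: np.ndarray
    n_obs: int
    n_clusters: int
    residuals: np.ndarray = field(repr=False)
    clusters: np.ndarray = field(repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_robust))

    @property
    def wald_z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * spstats.norm.sf(np.abs(self.wald_z))

    def ci95(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        half = 1.959963984540054 * self.se[i]
        return float(self.coef[i] - half), float(self.coef[i] + half)

    def __getitem__(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_obs": int(self.n_obs),
            "n_clusters": int(self.n_clusters),
            "coefficients": {
                nm: {
                    "estimate": float(b),
                    "robust_se": float(s),
                    "wald_z": float(z),
                    "p": float(p),
                }
                for nm, b, s, z, p in zip(self.names, self.coef, self.se, self.wald_z, self.p)
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _design(frame: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack(
        [np.ones(len(frame))] + [frame[p].to_numpy(dtype=float) for p in predictors]
    )
    names = ["(Intercept)"] + list(predictors)
    # incremental rank check names the first aliased column
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            raise RankDeficientError(names[j])
    return X, names


def _irls_binomial(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Logistic MLE by Fisher scoring; converges on relative deviance change."""
    beta = np.zeros(X.shape[1])
    dev = np.inf
    for _ in range(MAX_IRLS_ITER):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        w = np.clip(w, 1e-12, None)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, wx.T @ z)
        eta = X @ beta
        new_dev = 2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta)
        if np.isfinite(dev) and abs(dev - new_dev) <= IRLS_TOL * (abs(new_dev) + 0.1):
            return beta
        dev = new_dev
    raise ConvergenceError(f"IRLS did not converge in {MAX_IRLS_ITER} iterations")


def fit_gee_independence(
    frame: pd.DataFrame,
    response: str,
    predictors: list[str],
    cluster: str = "bird_id",
    family: str = "gaussian",
) -> FitResult:
    """Fit a GEE with independence working correlation, clustered by bird.

    Point estimates equal the pooled GLM; the covariance is the
    cluster-level sandwich, so inference is robust to within-bird
    correlation of any form.
    """
    if family not in ("gaussian", "binomial"):
        raise InputError(f"unsupported family {family!r}")
    y = frame[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise InputError(f"non-finite values in response {response!r}")
    X, names = _design(frame, predictors)
    clusters = frame[cluster].to_numpy()
    n_clusters = len(pd.unique(clusters))
    if n_clusters < 2:
        # sandwich needs >= 2 clusters; with one cluster only point estimates
        # are meaningful, and we still report the HC0-style covariance
        pass

    if family == "binomial":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise InputError("binomial response must be 0/1")
        if uniq.size < 2:
            raise SeparationError(f"response {response!r} is constant in this stratum")
        beta = _irls_binomial(X, y)
        mu = special.expit(X @ beta)
        w = mu * (1.0 - mu)
        resid = y - mu
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        mu = X @ beta
        w = np.ones_like(y)
        resid = y - mu

    bread_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    # meat: sum over clusters of score outer products, score_c = X_c' (y_c - mu_c)
    codes, _ = pd.factorize(clusters)
    score_x = X * resid[:, None]
    meat_parts = np.zeros((codes.max() + 1, X.shape[1]))
    np.add.at(meat_parts, codes, score_x)
    meat = meat_parts.T @ meat_parts
    vcov = bread_inv @ meat @ bread_inv
    vcov = 0.5 * (vcov + vcov.T)

    return FitResult(
        family=f"{family}-{'logit' if family == 'binomial' else 'identity'}",
        names=names,
        coef=beta,
        vcov_robust=vcov,
        n_obs=len(y),
        n_clusters=n_clusters,
        residuals=resid,
        clusters=clusters,
    )


def partial_effect(
    fit: FitResult, frame: pd.DataFrame, focal: str, grid
) -> pd.DataFrame:
    """Partial-effect curve of one predictor with the others held at their means.

    The 95 % band is the delta-method Wald interval on the linear
    predictor from the robust covariance; binomial fits map the curve and
    band through the inverse logit.  Grid values outside the observed
    range are flagged, not rejected.
    """
    if focal not in fit.names:
        raise InputError(f"{focal!r} is not a model term")
    grid = np.asarray(grid, dtype=float)
    x_row = np.ones(len(fit.names))
    for j, nm in enumerate(fit.names):
        if nm == "(Intercept)":
            continue
        x_row[j] = float(frame[nm].mean())
    Xg = np.tile(x_row, (grid.size, 1))
    j_focal = fit.names.index(focal)
    Xg[:, j_focal] = grid
    eta = Xg @ fit.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, fit.vcov_robust, Xg))
    lo, hi = eta - 1.96 * se, eta + 1.96 * se
    if fit.family.startswith("binomial"):
        eta, lo, hi = special.expit(eta), special.expit(lo), special.expit(hi)
    observed = frame[focal].to_numpy(dtype=float)
    extrapolated = (grid < observed.min()) | (grid > observed.max())
    return pd.DataFrame(
        {"grid": grid, "estimate": eta, "lo95": lo, "hi95": hi, "extrapolated": extrapolated}
    )


def residual_acf(fit: FitResult, time_order: np.ndarray | None = None, max_lag: int = 10) -> np.ndarray:
    """Within-cluster pooled autocorrelation of working residuals.

    Lags never span cluster (bird) boundaries.  The estimator is the
    standard biased-denominator ACF: cross products at each lag pooled
    over clusters, divided by the pooled lag-0 sum of squares.  Lags with
    no available pair are nan.
    """
    resid = fit.residuals
    clusters = fit.clusters
    if time_order is not None:
        idx = np.argsort(np.asarray(time_order), kind="stable")
        resid, clusters = resid[idx], clusters[idx]
    r = resid - resid.mean()
    denom = float(np.sum(r * r))
    out = np.full(max_lag + 1, np.nan)
    out[0] = 1.0 if denom > 0 else np.nan
    for lag in range(1, max_lag + 1):
        num = 0.0
        any_pair = False
        for _, g in pd.Series(r).groupby(pd.Series(clusters), sort=False):
            v = g.to_numpy()
            if v.size > lag:
                num += float(np.sum(v[:-lag] * v[lag:]))
                any_pair = True
        if any_pair and denom > 0:
            out[lag] = num / denom
    return out


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise InputError("both samples have zero variance")
    res = spstats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chisq_2x2_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-continuity-corrected Pearson chi-square on a 2×2 table, 1 df."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise InputError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InputError("chi-square table has a zero margin")
    chi2, p, _, _ = spstats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)
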