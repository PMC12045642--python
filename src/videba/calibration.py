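"""Energetic calibration: flow-speed power fit, SMR and the VeDBA mixed model.

Two statistical layers sit on top of the per-cycle measurements:

1. Ṁ_O2 against flow speed U is fitted with the three-parameter power
   function Ṁ_O2 = a + b·U^c (nonlinear least squares, deterministic
   multi-start).  The intercept a is the extrapolated standard metabolic
   rate (SMR, Ṁ_O2 at U = 0), and net cost of swimming = Ṁ_O2 − SMR.

2. Ṁ_O2 (or net cost) against VeDBA is fitted with a Gaussian
   random-intercept linear mixed model, y_ij = β₀ + β₁·VeDBA_ij + u_i + ε_ij
   with u_i ~ N(0, σ²_id), estimated by REML.  Fixed-effect significance
   uses an F test with Satterthwaite denominator degrees of freedom,
   computed from numeric derivatives of the closed-form REML likelihood of
   this model.  Marginal/conditional R² follow the Nakagawa–Schielzeth
   variance decomposition.  The contribution of the random intercept is
   tested with a likelihood-ratio test of ML refits (χ²₁ reference,
   conservative at the σ² = 0 boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.api import OLS, add_constant
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import FitError, ValidationError

__all__ = [
    "PowerFit",
    "LMMFit",
    "fit_power",
    "smr",
    "net_cost",
    "fit_lmm",
    "lrt_random_effect",
    "predict_mo2",
]

#: deterministic multi-start grid for the power-fit exponent
C_START_GRID = (0.5, 1.0, 1.5, 2.0, 3.0)


# ---------------------------------------------------------------------------
# power fit and SMR
# ---------------------------------------------------------------------------

@dataclass
class PowerFit:
    """Three-parameter power fit Ṁ_O2 = a + b·U^c; SMR = a."""

    a: float
    b: float
    c: float
    sse: float
    cov: np.ndarray | None = None
    scope: str = "pooled"  # pooled | individual id

    def predict(self, U: np.ndarray) -> np.ndarray:
        U = np.asarray(U, dtype=float)
        return self.a + self.b * np.power(U, self.c)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "sse": self.sse,
            "scope": self.scope,
            "cov": None if self.cov is None else np.asarray(self.cov).tolist(),
        }


def _power(U, a, b, c):
    return a + b * np.power(U, c)


def fit_power(U: np.ndarray, mo2: np.ndarray, scope: str = "pooled") -> PowerFit:
    """Nonlinear least squares for Ṁ_O2 = a + b·U^c with b ≥ 0, c > 0.

    A fixed multi-start over c ∈ {0.5, 1, 1.5, 2, 3} (with a, b warm-started
    by OLS at each fixed c) makes the fit deterministic; the best SSE wins,
    so the result can never be worse than the best fixed-c linear fit.
    """
    U = np.asarray(U, dtype=float)
    y = np.asarray(mo2, dtype=float)
    if len(np.unique(U)) < 4:
        raise FitError("power fit needs >= 4 distinct flow speeds")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(U)):
        raise FitError("power fit requires finite inputs")

    best = None
    for c0 in C_START_GRID:
        # OLS warm start at fixed exponent
        Xc = np.column_stack([np.ones_like(U), np.power(U, c0)])
        ab, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        a0, b0 = float(ab[0]), max(float(ab[1]), 1e-8)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    _power,
                    U,
                    y,
                    p0=(a0, b0, c0),
                    bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, 20.0]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _power(U, *popt)) ** 2))
        # the fixed-c OLS solution itself is a feasible candidate
        sse_fixed = float(np.sum((y - Xc @ [a0, max(float(ab[1]), 0.0)]) ** 2))
        if sse_fixed < sse:
            popt, pcov, sse = np.array([a0, max(float(ab[1]), 0.0), c0]), None, sse_fixed
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitError("power fit failed to converge from every start")
    popt, pcov, sse = best
    return PowerFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), sse=sse, cov=pcov, scope=scope)


def smr(fit: PowerFit) -> float:
    """Standard metabolic rate: the extrapolated Ṁ_O2 at U = 0."""
    return fit.a


def net_cost(table: pd.DataFrame, smr_by_individual: dict[str, float]) -> pd.DataFrame:
    """Append net cost of swimming (Ṁ_O2 − SMR of the individual).

    Negative values are retained: an extrapolated SMR can exceed the lowest
    measured rates.
    """
    missing = set(table["individual"]) - set(smr_by_individual)
    if missing:
        raise FitError(f"missing per-individual SMR for {sorted(missing)}")
    out = table.copy()
    out["net_cost"] = out["mo2"] - out["individual"].map(smr_by_individual)
    return out


# ---------------------------------------------------------------------------
# random-intercept mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """REML fit of y = β₀ + β₁·VeDBA + u_individual + ε."""

    beta0: float
    beta1: float
    cov_beta: np.ndarray  # 2x2 fixed-effect covariance
    sigma2_id: float
    sigma2_eps: float
    ranef: dict[str, float]  # per-individual intercept deviations u_i
    r2_marginal: float
    r2_conditional: float
    fstat: float
    ddf: float
    pvalue: float
    boundary: bool
    loglik_reml: float
    response: str = "mo2"
    ddf_method: str = "satterthwaite"
    n_obs: int = 0
    n_groups: int = 0

    @property
    def se_beta1(self) -> float:
        return float(np.sqrt(self.cov_beta[1, 1]))

    @property
    def se_beta0(self) -> float:
        return float(np.sqrt(self.cov_beta[0, 0]))

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "se_beta0": self.se_beta0,
            "se_beta1": self.se_beta1,
            "cov_beta": np.asarray(self.cov_beta).tolist(),
            "sigma2_id": self.sigma2_id,
            "sigma2_eps": self.sigma2_eps,
            "ranef": self.ranef,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "fstat": self.fstat,
            "ddf": self.ddf,
            "pvalue": self.pvalue,
            "boundary": self.boundary,
            "loglik_reml": self.loglik_reml,
            "response": self.response,
            "ddf_method": self.ddf_method,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LMMFit":
        d = dict(d)
        d.pop("se_beta0", None)
        d.pop("se_beta1", None)
        d["cov_beta"] = np.asarray(d["cov_beta"])
        return cls(**d)


def _group_blocks(x: np.ndarray, y: np.ndarray, groups: np.ndarray):
    X = np.column_stack([np.ones_like(x), x])
    blocks = []
    for g in pd.unique(groups):
        sel = groups == g
        blocks.append((g, X[sel], y[sel]))
    return blocks


def _reml_quantities(theta: np.ndarray, blocks) -> tuple[float, np.ndarray, np.ndarray]:
    """Closed-form REML log-likelihood (up to constant), GLS β and its cov.

    theta = (σ²_id, σ²_ε); V_i = σ²_ε I + σ²_id J per group, inverted with
    the Sherman–Morrison identity.
    """
    s_id, s_eps = max(theta[0], 0.0), max(theta[1], 1e-12)
    M = np.zeros((2, 2))
    m = np.zeros(2)
    logdet = 0.0
    parts = []
    for _, Xi, yi in blocks:
        ni = len(yi)
        gamma = s_id / (s_eps + ni * s_id)
        # V_i^-1 A = (A - gamma * 1 1' A) / s_eps
        Xs = Xi.sum(axis=0)
        ys = yi.sum()
        XtVX = (Xi.T @ Xi - gamma * np.outer(Xs, Xs)) / s_eps
        XtVy = (Xi.T @ yi - gamma * Xs * ys) / s_eps
        M += XtVX
        m += XtVy
        logdet += (ni - 1) * np.log(s_eps) + np.log(s_eps + ni * s_id)
        parts.append((Xi, yi, gamma, Xs, ys))
    cov = np.linalg.inv(M)
    beta = cov @ m
    quad = 0.0
    for Xi, yi, gamma, Xs, ys in parts:
        ri = yi - Xi @ beta
        rs = ri.sum()
        quad += (ri @ ri - gamma * rs * rs) / s_eps
    sign, logdetM = np.linalg.slogdet(M)
    ll = -0.5 * (logdet + logdetM + quad)
    return ll, beta, cov


def reml_loglik(theta, x, y, groups) -> float:
    """REML log-likelihood (up to an additive constant) at variance pair theta."""
    blocks = _group_blocks(np.asarray(x, float), np.asarray(y, float), np.asarray(groups))
    return _reml_quantities(np.asarray(theta, float), blocks)[0]


def _satterthwaite_ddf(theta_hat: np.ndarray, blocks, coef_index: int = 1) -> float:
    """Satterthwaite denominator df for one fixed effect.

    ddf = 2 f² / (gᵀ A g) with f(θ) = Var(β̂_k)(θ), g its numeric gradient
    and A the inverse observed information of the REML likelihood in θ.
    """
    def f(theta):
        return _reml_quantities(theta, blocks)[2][coef_index, coef_index]

    def ll(theta):
        return _reml_quantities(theta, blocks)[0]

    n = sum(len(b[2]) for b in blocks)
    # steps must be large enough to survive cancellation in the 4-point
    # Hessian (the log-likelihood is O(1e2), its curvature O(1e-4))
    steps = np.maximum(np.abs(theta_hat) * 5e-3, 1e-4)
    grad = np.zeros(2)
    H = np.zeros((2, 2))
    for i in range(2):
        e = np.zeros(2)
        e[i] = steps[i]
        tp, tm = theta_hat + e, np.maximum(theta_hat - e, [0.0, 1e-12])
        grad[i] = (f(tp) - f(tm)) / (tp[i] - tm[i])
    ll0 = ll(theta_hat)
    for i in range(2):
        ei = np.zeros(2); ei[i] = steps[i]
        tp, tm = theta_hat + ei, np.maximum(theta_hat - ei, [0.0, 1e-12])
        H[i, i] = (ll(tp) - 2 * ll0 + ll(tm)) / ((tp[i] - theta_hat[i]) * (theta_hat[i] - tm[i]))
    ei = np.array([steps[0], 0.0])
    ej = np.array([0.0, steps[1]])
    tpp = theta_hat + ei + ej
    tpm = np.maximum(theta_hat + ei - ej, [0.0, 1e-12])
    tmp = np.maximum(theta_hat - ei + ej, [0.0, 1e-12])
    tmm = np.maximum(theta_hat - ei - ej, [0.0, 1e-12])
    H[0, 1] = H[1, 0] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (
        (tpp[0] - tmm[0]) * (tpp[1] - tmm[1])
    )
    try:
        A = np.linalg.inv(-H)
        denom = float(grad @ A @ grad)
        fval = float(f(theta_hat))
        if denom <= 0 or not np.isfinite(denom):
            raise np.linalg.LinAlgError
        ddf = 2.0 * fval**2 / denom
    except np.linalg.LinAlgError:
        ddf = float(n - 2)
    return float(np.clip(ddf, 1.0, n - 2))


def fit_lmm(
    table: pd.DataFrame,
    response: str = "mo2",
    predictor: str = "mean_vedba",
    group: str = "individual",
    ddf_method: str = "satterthwaite",
    infer: bool = True,
) -> LMMFit:
    """REML random-intercept fit of ``response ~ predictor + (1 | group)``.

    A fit whose random-intercept variance collapses to ~0 is returned with
    ``boundary=True`` rather than raising.  ``infer=False`` skips the
    Satterthwaite test (cheap fits for simulation studies).
    """
    if ddf_method == "kenward-roger":
        raise NotImplementedError(
            "Kenward–Roger denominator df is not provided; use 'satterthwaite' "
            "(the two agree closely at this design size)"
        )
    if ddf_method != "satterthwaite":
        raise ValidationError(f"unknown ddf method {ddf_method!r}")
    groups = table[group].to_numpy()
    if len(pd.unique(groups)) < 2:
        raise FitError("mixed model needs >= 2 individuals")
    x = table[predictor].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = MixedLM(y, X, groups)
        res = md.fit(reml=True)
    sigma2_id = float(np.asarray(res.cov_re)[0, 0])
    sigma2_eps = float(res.scale)
    boundary = sigma2_id < 1e-8 * max(sigma2_eps, 1e-12)

    blocks = _group_blocks(x, y, groups)
    theta = np.array([sigma2_id, sigma2_eps])
    ll, beta, cov_beta = _reml_quantities(theta, blocks)

    # per-individual BLUPs: shrinkage n_i σ²_id / (σ²_ε + n_i σ²_id) on group mean residuals
    ranef = {}
    for g, Xi, yi in blocks:
        ni = len(yi)
        shrink = ni * sigma2_id / (sigma2_eps + ni * sigma2_id) if sigma2_id > 0 else 0.0
        ranef[str(g)] = float(shrink * np.mean(yi - Xi @ beta))

    var_fixed = float(np.var(beta[1] * x, ddof=1))
    total = var_fixed + sigma2_id + sigma2_eps
    r2m = var_fixed / total
    r2c = (var_fixed + sigma2_id) / total

    if infer:
        ddf = _satterthwaite_ddf(theta, blocks, coef_index=1)
        fstat = float(beta[1] ** 2 / cov_beta[1, 1])
        pvalue = float(stats.f.sf(fstat, 1, ddf))
    else:
        ddf = float("nan")
        fstat = float(beta[1] ** 2 / cov_beta[1, 1])
        pvalue = float("nan")

    return LMMFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        cov_beta=cov_beta,
        sigma2_id=sigma2_id,
        sigma2_eps=sigma2_eps,
        ranef=ranef,
        r2_marginal=r2m,
        r2_conditional=r2c,
        fstat=fstat,
        ddf=ddf,
        pvalue=pvalue,
        boundary=boundary,
        loglik_reml=float(ll),
        response=response,
        ddf_method=ddf_method,
        n_obs=len(y),
        n_groups=len(blocks),
    )


def _ml_profile_loglik(lam: float, blocks) -> float:
    """Gaussian ML log-likelihood profiled over β and σ²_ε at fixed λ = σ²_id/σ²_ε."""
    M = np.zeros((2, 2))
    m = np.zeros(2)
    logdet = 0.0
    n = 0
    for _, Xi, yi in blocks:
        ni = len(yi)
        n += ni
        w = lam / (1.0 + ni * lam)
        Xs = Xi.sum(axis=0)
        ys = yi.sum()
        M += Xi.T @ Xi - w * np.outer(Xs, Xs)
        m += Xi.T @ yi - w * Xs * ys
        logdet += np.log1p(ni * lam)
    beta = np.linalg.solve(M, m)
    rss = 0.0
    for _, Xi, yi in blocks:
        ni = len(yi)
        w = lam / (1.0 + ni * lam)
        ri = yi - Xi @ beta
        rss += ri @ ri - w * ri.sum() ** 2
    s_eps = rss / n
    return -0.5 * (logdet + n * np.log(s_eps) + n + n * np.log(2 * np.pi))


def lrt_random_effect(
    table: pd.DataFrame,
    response: str = "mo2",
    predictor: str = "mean_vedba",
    group: str = "individual",
) -> tuple[float, float]:
    """Likelihood-ratio test of the random intercept (ML refits).

    Both models are refitted by maximum likelihood — REML likelihoods are
    not comparable here.  The full model's ML likelihood is maximized over
    the profiled variance ratio λ = σ²_id/σ²_ε (1-D, deterministic); the
    reduced model is ordinary least squares.  The χ²₁ reference is
    conservative because the null σ²_id = 0 sits on the parameter boundary.
    """
    x = table[predictor].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    groups = table[group].to_numpy()
    blocks = _group_blocks(x, y, groups)
    res = optimize.minimize_scalar(
        lambda u: -_ml_profile_loglik(np.exp(u), blocks), bounds=(-12.0, 8.0), method="bounded",
        options={"xatol": 1e-8},
    )
    ll_red = _ml_profile_loglik(0.0, blocks)  # λ = 0 is exactly the OLS model
    ll_full = max(-float(res.fun), ll_red)
    chi2 = max(2.0 * (ll_full - ll_red), 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def predict_mo2(
    fit: LMMFit,
    vedba: np.ndarray | float,
    individual: str | None = None,
    interval: str = "prediction",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Predict Ṁ_O2 (or net cost) for new VeDBA values, with a 95% interval.

    Individual-level prediction adds the fitted intercept deviation u_i; an
    unknown individual falls back to the population level with a warning.
    ``interval="confidence"`` covers the conditional mean (fixed-effect
    covariance, plus σ²_id at population level); ``interval="prediction"``
    additionally includes the residual variance σ²_ε and therefore covers
    new observations.
    """
    v = np.atleast_1d(np.asarray(vedba, dtype=float))
    level = "population"
    offset = 0.0
    if individual is not None:
        if individual in fit.ranef:
            offset = fit.ranef[individual]
            level = "individual"
        else:
            warnings.warn(
                f"individual {individual!r} unknown to the fit; using population-level prediction"
            )
    point = fit.beta0 + fit.beta1 * v + offset
    Xn = np.column_stack([np.ones_like(v), v])
    var = np.einsum("ij,jk,ik->i", Xn, fit.cov_beta, Xn)
    if level == "population":
        var = var + fit.sigma2_id
    if interval == "prediction":
        var = var + fit.sigma2_eps
    elif interval != "confidence":
        raise ValidationError(f"unknown interval kind {interval!r}")
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return pd.DataFrame(
        {
            "vedba": v,
            "predicted": point,
            "lo": point - half,
            "hi": point + half,
            "level": level,
            "interval": interval,
        }
    )
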