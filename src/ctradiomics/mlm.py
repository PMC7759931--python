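"""Random-intercept linear mixed models.

One model underlies the whole pipeline: for patient ``i`` at visit ``j``,

    y_ij = x_ij' beta + b_i + e_ij,    b_i ~ N(0, sigma2_patient),
                                       e_ij ~ N(0, sigma2_resid),

i.e. a Gaussian linear model with a patient-level random intercept capturing
within-patient dependence of repeated visits.  The screening, selection, null
simulation and association stages each perform many thousands of such fits on
small cohorts, so the fitter here profiles the likelihood analytically down to
a one-dimensional optimisation over the variance ratio
``lambda = sigma2_patient / sigma2_resid`` using closed-form group-wise GLS
(Woodbury identity per patient).  REML and ML estimators are supported; Wald
t-tests use a Satterthwaite degrees-of-freedom approximation; a Huber-type
iteratively-reweighted fit provides an outlier sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

_LOG2PI = math.log(2.0 * math.pi)
_LAM_LO, _LAM_HI = -30.0, 20.0  # bounds for log(lambda)


class ConvergenceError(RuntimeError):
    """Raised when the profiled likelihood cannot be optimised."""


@dataclass
class MLMFit:
    """A fitted random-intercept linear mixed model."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    df: np.ndarray
    pvalues: np.ndarray
    sigma2_patient: float
    sigma2_resid: float
    loglike: float            # log-likelihood of the estimator used
    loglike_ml: float         # full (ML) log-likelihood at the estimates
    loglike_reml: float       # restricted log-likelihood at the estimates
    method: str               # "REML" | "ML" | "robust"
    exog_names: list[str]
    n_obs: int
    n_groups: int
    fittedvalues: np.ndarray  # fixed-effect part X beta
    resid: np.ndarray         # marginal residuals y - X beta
    converged: bool = True
    weights: np.ndarray | None = None  # robust case weights, if any

    @property
    def icc(self) -> float:
        tot = self.sigma2_patient + self.sigma2_resid
        return float(self.sigma2_patient / tot) if tot > 0 else 0.0

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "df": self.df,
                "p": self.pvalues,
            },
            index=self.exog_names,
        )


@dataclass
class LRTResult:
    """Likelihood-ratio test between nested ML fits."""

    statistic: float
    df: int
    pvalue: float


@dataclass
class _SuffStats:
    """Per-group sufficient statistics; everything a profile evaluation needs."""

    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    S: np.ndarray    # (G, p) group sums of rows of X
    t: np.ndarray    # (G,) group sums of y
    n_i: np.ndarray  # (G,) group sizes (sums of weights in the weighted case)
    n: int
    p: int


def _factorize_groups(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    if (codes < 0).any():
        raise ValueError("groups contain missing values")
    return codes.astype(np.intp), len(uniques)


def _suffstats(y: np.ndarray, X: np.ndarray, idx: np.ndarray, G: int) -> _SuffStats:
    n, p = X.shape
    S = np.empty((G, p))
    for j in range(p):
        S[:, j] = np.bincount(idx, weights=X[:, j], minlength=G)
    t = np.bincount(idx, weights=y, minlength=G)
    n_i = np.bincount(idx, minlength=G).astype(float)
    return _SuffStats(X.T @ X, X.T @ y, float(y @ y), S, t, n_i, n, p)


def _profile(lam: float, st: _SuffStats):
    """GLS quantities at a given variance ratio lambda.

    With W = (I + lam Z Z')^-1 block-diagonal per group,
    X'WX = X'X - sum_i c_i s_i s_i' with c_i = lam/(1 + lam n_i).
    """
    c = lam / (1.0 + lam * st.n_i)
    A = st.XtX - (st.S * c[:, None]).T @ st.S
    b = st.Xty - st.S.T @ (c * st.t)
    q = st.yty - float(np.dot(c * st.t, st.t))
    try:
        L = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ConvergenceError("singular X'WX in profile step") from exc
    beta = cho_solve(L, b)
    rss = max(q - float(beta @ b), 1e-300)
    logdet_V0 = float(np.log1p(lam * st.n_i).sum())
    logdet_A = 2.0 * float(np.log(np.diag(L[0])).sum())
    return beta, rss, logdet_V0, logdet_A


def _neg2_profile_crit(u: float, st: _SuffStats, reml: bool) -> float:
    lam = math.exp(u)
    _, rss, ldV, ldA = _profile(lam, st)
    if reml:
        dof = st.n - st.p
        return dof * (_LOG2PI + math.log(rss / dof) + 1.0) + ldV + ldA
    return st.n * (_LOG2PI + math.log(rss / st.n) + 1.0) + ldV


def _loglike_at(lam: float, st: _SuffStats, reml: bool) -> float:
    return -0.5 * _neg2_profile_crit(math.log(max(lam, 1e-300)), st, reml)


def _reml_loglike_theta(theta: np.ndarray, st: _SuffStats) -> float:
    """Unprofiled restricted log-likelihood at theta = (sigma2_b, sigma2_e)."""
    s2b, s2e = max(theta[0], 0.0), theta[1]
    lam = s2b / s2e
    _, rss, ldV, ldA = _profile(lam, st)
    dof = st.n - st.p
    return -0.5 * (dof * _LOG2PI + dof * math.log(s2e) + ldV + ldA + rss / s2e)


def _satterthwaite_df(st: _SuffStats, s2b: float, s2e: float) -> np.ndarray:
    """Satterthwaite df per fixed coefficient from the REML curvature."""
    n, p = st.n, st.p
    fallback = np.full(p, float(n - p))
    if s2b < 1e-8 * s2e:
        return fallback

    def covbeta(theta):
        lam = max(theta[0], 0.0) / theta[1]
        c = lam / (1.0 + lam * st.n_i)
        A = st.XtX - (st.S * c[:, None]).T @ st.S
        return theta[1] * np.linalg.inv(A)

    theta = np.array([s2b, s2e])
    h = 1e-4 * np.maximum(theta, 1e-8)
    # observed information of (s2b, s2e) under REML, by central differences
    H = np.empty((2, 2))
    f0 = _reml_loglike_theta(theta, st)
    for a in range(2):
        ea = np.zeros(2)
        ea[a] = h[a]
        H[a, a] = (
            _reml_loglike_theta(theta + ea, st)
            - 2.0 * f0
            + _reml_loglike_theta(theta - ea, st)
        ) / h[a] ** 2
    eb = np.array([h[0], 0.0])
    ec = np.array([0.0, h[1]])
    H[0, 1] = H[1, 0] = (
        _reml_loglike_theta(theta + eb + ec, st)
        - _reml_loglike_theta(theta + eb - ec, st)
        - _reml_loglike_theta(theta - eb + ec, st)
        + _reml_loglike_theta(theta - eb - ec, st)
    ) / (4.0 * h[0] * h[1])
    try:
        Vtheta = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return fallback
    if not np.all(np.isfinite(Vtheta)) or Vtheta[0, 0] < 0 or Vtheta[1, 1] < 0:
        return fallback

    dfs = np.empty(p)
    for k in range(p):
        fk = covbeta(theta)[k, k]
        g = np.empty(2)
        for a in range(2):
            ea = np.zeros(2)
            ea[a] = h[a]
            g[a] = (covbeta(theta + ea)[k, k] - covbeta(theta - ea)[k, k]) / (2 * h[a])
        denom = float(g @ Vtheta @ g)
        dfs[k] = 2.0 * fk**2 / denom if denom > 0 else float(n - p)
    return np.clip(dfs, 1.0, float(n - p))


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return np.asarray(X, dtype=float), [str(c) for c in X.columns]
    Xa = np.atleast_2d(np.asarray(X, dtype=float))
    if Xa.shape[0] == 1 and Xa.shape[1] > 1 and Xa.ndim == 2:
        Xa = Xa.T if Xa.shape[0] < Xa.shape[1] else Xa
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    return Xa, [f"x{j}" for j in range(Xa.shape[1])]


def fit_mlm(
    y,
    X,
    groups,
    method: str = "REML",
    compute_df: bool = True,
) -> MLMFit:
    """Fit the random-intercept model by profiled REML or ML.

    Parameters
    ----------
    y : array-like, response (e.g. log mutant allele fraction).
    X : array-like or DataFrame, fixed-effect design including the intercept
        column; must have full column rank.
    groups : array-like of patient identifiers, one per row.
    method : "REML" (default, used for Wald inference) or "ML" (required for
        likelihood-ratio tests across fixed-effect designs).
    compute_df : skip the Satterthwaite step when Wald p-values are not needed
        (the null-simulation stage only consumes log-likelihoods).
    """
    method = method.upper()
    if method not in ("REML", "ML"):
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y, dtype=float).ravel()
    Xa, names = _as_design(X)
    if Xa.shape[0] != y.shape[0]:
        raise ValueError("y and X have different numbers of rows")
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise ValueError("design matrix X is singular (not full column rank)")
    idx, G = _factorize_groups(groups)
    if G < 2:
        raise ValueError("need at least 2 groups (patients)")
    if len(idx) != len(y):
        raise ValueError("groups length mismatch")

    st = _suffstats(y, Xa, idx, G)
    reml = method == "REML"

    # coarse grid then bounded refinement: the profile criterion is smooth and
    # in practice unimodal in log(lambda)
    grid = np.linspace(_LAM_LO, _LAM_HI, 26)
    vals = [_neg2_profile_crit(u, st, reml) for u in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        _neg2_profile_crit,
        bounds=(lo, hi),
        args=(st, reml),
        method="bounded",
        options={"xatol": 1e-8},
    )
    u_hat = float(res.x)
    if _neg2_profile_crit(_LAM_LO, st, reml) < res.fun:
        u_hat = _LAM_LO  # boundary: no between-patient variance
    lam = math.exp(u_hat)

    beta, rss, _ldV, _ldA = _profile(lam, st)
    dof = st.n - st.p if reml else st.n
    s2e = rss / dof
    s2b = lam * s2e if u_hat > _LAM_LO else 0.0

    c = lam / (1.0 + lam * st.n_i)
    A = st.XtX - (st.S * c[:, None]).T @ st.S
    cov_beta = s2e * np.linalg.inv(A)
    bse = np.sqrt(np.diag(cov_beta))
    tvals = beta / bse
    if compute_df:
        dfs = _satterthwaite_df(st, s2b, s2e)
    else:
        dfs = np.full(st.p, float(st.n - st.p))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)

    fitted = Xa @ beta
    ll_ml = _loglike_at(lam, st, reml=False)
    ll_reml = _loglike_at(lam, st, reml=True)
    return MLMFit(
        params=beta,
        bse=bse,
        tvalues=tvals,
        df=dfs,
        pvalues=pvals,
        sigma2_patient=float(s2b),
        sigma2_resid=float(s2e),
        loglike=ll_reml if reml else ll_ml,
        loglike_ml=ll_ml,
        loglike_reml=ll_reml,
        method=method,
        exog_names=names,
        n_obs=st.n,
        n_groups=G,
        fittedvalues=fitted,
        resid=y - fitted,
    )


def marginal_r2(fit: MLMFit) -> float:
    """Variance explained by the fixed effects alone (Nakagawa marginal R²):

        Var(X beta) / (Var(X beta) + sigma2_patient + sigma2_resid).
    """
    if fit.n_obs < 2:
        return 0.0
    var_fixed = float(np.var(fit.fittedvalues, ddof=1))
    denom = var_fixed + fit.sigma2_patient + fit.sigma2_resid
    return var_fixed / denom if denom > 0 else 0.0


def lrt(full: MLMFit, restricted: MLMFit) -> LRTResult:
    """Likelihood-ratio test of nested fixed-effect designs (ML fits only)."""
    if full.method != "ML" or restricted.method != "ML":
        raise ValueError(
            "LRT requires ML fits: REML likelihoods are not comparable across "
            "fixed-effect designs"
        )
    if full.n_obs != restricted.n_obs:
        raise ValueError("fits use different numbers of rows")
    ddf = len(full.params) - len(restricted.params)
    if ddf <= 0:
        raise ValueError("full model must have more fixed parameters")
    stat = 2.0 * (full.loglike - restricted.loglike)
    return LRTResult(statistic=stat, df=ddf, pvalue=float(stats.chi2.sf(max(stat, 0.0), ddf)))


def fit_robust_mlm(
    y,
    X,
    groups,
    c: float = 1.345,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> MLMFit:
    """Huber-weighted random-intercept fit (outlier sensitivity analysis).

    Iteratively reweighted scheme: marginal residuals are scaled by their MAD,
    rows get Huber weights w = min(1, c/|r/s|), and the weighted model
    (equivalently, rows of y and X scaled by sqrt(w)) is refit until the
    coefficients stabilise.  This is a deliberate simplification of fully
    robust mixed-model estimators; it down-weights gross outliers while
    leaving clean data essentially untouched.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xa, names = _as_design(X)
    w = np.ones_like(y)
    fit = fit_mlm(y, pd.DataFrame(Xa, columns=names), groups, method="REML")
    beta = fit.params
    for _ in range(max_iter):
        r = y - Xa @ beta
        s = 1.4826 * float(np.median(np.abs(r - np.median(r))))
        if s <= 0:
            break
        u = np.abs(r / s)
        w = np.where(u <= c, 1.0, c / np.maximum(u, 1e-12))
        sw = np.sqrt(w)
        fit_w = fit_mlm(
            y * sw,
            pd.DataFrame(Xa * sw[:, None], columns=names),
            groups,
            method="REML",
        )
        if np.max(np.abs(fit_w.params - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = fit_w.params
            fit = fit_w
            break
        beta = fit_w.params
        fit = fit_w
    fitted = Xa @ beta
    return MLMFit(
        params=beta,
        bse=fit.bse,
        tvalues=fit.tvalues,
        df=fit.df,
        pvalues=fit.pvalues,
        sigma2_patient=fit.sigma2_patient,
        sigma2_resid=fit.sigma2_resid,
        loglike=fit.loglike,
        loglike_ml=fit.loglike_ml,
        loglike_reml=fit.loglike_reml,
        method="robust",
        exog_names=names,
        n_obs=len(y),
        n_groups=fit.n_groups,
        fittedvalues=fitted,
        resid=y - fitted,
        weights=w,
    )
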