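"""Global predictor selection for clustered data.

Two procedures pick the radiomic features that jointly best predict
log(ctDNAmaf) while respecting within-patient dependence:

* an L1-penalised (LASSO) random-intercept model, fitted by coordinate
  descent on the GLS-whitened data with the variance components re-estimated
  along the path; the penalty is chosen by the *random-entry rule* — the
  smallest lambda whose active set still contains none of a bank of spiked-in
  random predictors (one random per real predictor);
* greedy forward/backward stepwise search maximising the marginal R² of the
  mixed model, halting as soon as the best candidate addition is a random
  predictor (or the improvement is negligible).

Both report which rule stopped them, and by construction never return a
"[random...]" column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mlm import fit_mlm, marginal_r2
from .synthetic import is_random_feature

logger = logging.getLogger(__name__)


@dataclass
class LassoPath:
    lambdas: np.ndarray
    active_sets: list[list[str]]
    coefs: pd.DataFrame  # lambdas x predictors


@dataclass
class SelectionResult:
    selected: list[str]
    method: str                 # "lasso" | "stepwise"
    stopping_cause: str         # "random-entered" | "no-improvement" | "max-steps" | "lambda-rule"
    path: list = field(default_factory=list)
    lambda_star: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "method": self.method,
            "stopping_cause": self.stopping_cause,
            "lambda_star": self.lambda_star,
            "seed": self.seed,
        }


def _check_standardized(X: pd.DataFrame) -> None:
    mu = X.mean(axis=0).to_numpy()
    sd = X.std(axis=0, ddof=0).to_numpy()
    if np.any(np.abs(mu) > 1e-6) or np.any(np.abs(sd - 1.0) > 1e-3):
        bad = X.columns[(np.abs(mu) > 1e-6) | (np.abs(sd - 1.0) > 1e-3)][0]
        raise ValueError(
            f"predictors must be z-scored before the LASSO (column {bad!r} "
            "is not standardized)"
        )


def _whiten(y, X, idx, G, lam_ratio):
    """Per-group transform by (I + lam J)^(-1/2) (Woodbury square root)."""
    yw = y.copy()
    Xw = X.copy()
    for g in range(G):
        rows = np.where(idx == g)[0]
        ng = len(rows)
        a = (1.0 / np.sqrt(1.0 + lam_ratio * ng) - 1.0) / ng
        yw[rows] += a * y[rows].sum()
        Xw[rows] += a * X[rows].sum(axis=0)
    return yw, Xw


def _variance_ratio(resid, groups) -> float:
    """Re-estimate sigma2_patient/sigma2_resid from residuals (intercept-only
    random-intercept REML fit)."""
    try:
        f = fit_mlm(resid, np.ones((len(resid), 1)), groups, method="REML",
                    compute_df=False)
    except ValueError:
        return 0.0
    return f.sigma2_patient / f.sigma2_resid if f.sigma2_resid > 0 else 0.0


def lasso_mlm_path(
    y,
    X_std: pd.DataFrame,
    groups,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    max_sweeps: int = 200,
    tol: float = 1e-6,
) -> LassoPath:
    """Coordinate-descent LASSO on the whitened random-intercept model.

    ``X_std`` must be z-scored (checked).  An unpenalised intercept is carried
    implicitly via centring of the whitened response.  Variance components are
    re-estimated from the residuals at each lambda and the data re-whitened,
    so the penalised fixed effects and the random-intercept structure stay
    consistent along the path.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not isinstance(X_std, pd.DataFrame):
        X_std = pd.DataFrame(np.asarray(X_std, dtype=float))
    _check_standardized(X_std)
    names = [str(c) for c in X_std.columns]
    X = X_std.to_numpy(dtype=float)
    n, p = X.shape
    codes, uniques = pd.factorize(np.asarray(groups))
    G = len(uniques)

    lam_ratio = _variance_ratio(y - y.mean(), groups)
    yw, Xw = _whiten(y, X, codes, G, lam_ratio)
    # implicit unpenalised intercept: centre whitened data
    ywc = yw - yw.mean()
    Xwc = Xw - Xw.mean(axis=0)
    if lambdas is None:
        lam_max = np.max(np.abs(Xwc.T @ ywc)) / n
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be decreasing")

    beta = np.zeros(p)
    active_sets: list[list[str]] = []
    coef_rows = []
    for lam_pen in lambdas:
        col_ss = (Xwc**2).sum(axis=0) / n
        r = ywc - Xwc @ beta
        for _ in range(max_sweeps):
            delta = 0.0
            for j in range(p):
                bj = beta[j]
                rho = (Xwc[:, j] @ r) / n + col_ss[j] * bj
                bnew = np.sign(rho) * max(abs(rho) - lam_pen, 0.0) / max(col_ss[j], 1e-12)
                if bnew != bj:
                    r += Xwc[:, j] * (bj - bnew)
                    beta[j] = bnew
                    delta = max(delta, abs(bnew - bj))
            if delta < tol:
                break
        # refresh the variance components and whitening for the next lambda
        resid_orig = y - y.mean() - (X - X.mean(axis=0)) @ beta
        lam_ratio = _variance_ratio(resid_orig, groups)
        yw, Xw = _whiten(y, X, codes, G, lam_ratio)
        ywc = yw - yw.mean()
        Xwc = Xw - Xw.mean(axis=0)
        active = [names[j] for j in range(p) if abs(beta[j]) > 1e-9]
        active_sets.append(active)
        coef_rows.append(beta.copy())
    coefs = pd.DataFrame(coef_rows, index=lambdas, columns=names)
    return LassoPath(lambdas=lambdas, active_sets=active_sets, coefs=coefs)


def select_lambda_by_random_entry(
    path: LassoPath, random_cols=None
) -> tuple[float | None, list[str]]:
    """Smallest lambda whose active set contains no random predictor; the
    selection is the real active set there.  If a random predictor is active
    along the whole path the selection is empty (with a warning)."""
    lam_star = None
    selected: list[str] = []
    if random_cols is not None:
        random_cols = set(random_cols)

    def _is_random(name):
        return name in random_cols if random_cols is not None else is_random_feature(name)

    for lam, active in zip(path.lambdas, path.active_sets):
        if any(_is_random(a) for a in active):
            break
        lam_star = float(lam)
        selected = [a for a in active if not _is_random(a)]
    if lam_star is None:
        logger.warning("a random predictor is active at every lambda; "
                       "returning the empty selection")
    return lam_star, selected


def lasso_select(
    y, X_std: pd.DataFrame, groups, random_cols=None, **path_kwargs
) -> SelectionResult:
    path = lasso_mlm_path(y, X_std, groups, **path_kwargs)
    lam_star, selected = select_lambda_by_random_entry(path, random_cols)
    return SelectionResult(
        selected=selected,
        method="lasso",
        stopping_cause="lambda-rule" if lam_star is not None else "random-entered",
        path=path.active_sets,
        lambda_star=lam_star,
    )


def stepwise_r2(
    y,
    X: pd.DataFrame,
    groups,
    random_cols=None,
    max_steps: int = 20,
    tol: float = 1e-4,
    method: str = "ML",
) -> SelectionResult:
    """Greedy forward/backward search maximising marginal R² of the MLM.

    Forward: add the candidate giving the largest R² gain; halt when that
    candidate is a random predictor or the gain is below ``tol``.  Backward:
    after each addition, drop any selected feature whose removal costs less
    than ``tol``.  Ties break by feature name order, so the search is
    deterministic.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    names = sorted(str(c) for c in X.columns)
    if random_cols is not None:
        random_set = set(random_cols)
    else:
        random_set = {c for c in names if is_random_feature(c)}

    def _r2(sel: list[str]) -> float:
        cols = {"intercept": np.ones(n)}
        for s in sel:
            cols[s] = X[s].to_numpy(dtype=float)
        fit = fit_mlm(y, pd.DataFrame(cols), groups, method=method, compute_df=False)
        return marginal_r2(fit)

    selected: list[str] = []
    current = _r2(selected)
    cause = "max-steps"
    steps = []
    for _ in range(max_steps):
        best_name, best_r2 = None, current
        for c in names:
            if c in selected:
                continue
            try:
                r2 = _r2(selected + [c])
            except (ValueError, np.linalg.LinAlgError):
                continue
            if r2 > best_r2 + 1e-12:
                best_name, best_r2 = c, r2
        if best_name is None or best_r2 - current < tol:
            cause = "no-improvement"
            break
        if best_name in random_set:
            cause = "random-entered"
            break
        selected.append(best_name)
        current = best_r2
        steps.append(("add", best_name, current))
        # backward pass
        improved = True
        while improved and len(selected) > 1:
            improved = False
            for c in sorted(selected):
                trial = [s for s in selected if s != c]
                r2 = _r2(trial)
                if current - r2 < tol:
                    selected = trial
                    current = r2
                    steps.append(("drop", c, current))
                    improved = True
                    break
    return SelectionResult(
        selected=sorted(selected),
        method="stepwise",
        stopping_cause=cause,
        path=steps,
    )
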