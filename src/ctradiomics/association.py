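"""Associations among log(ctDNAmaf), serum LDH and the radiomics signature.

Three pairwise relationships are modelled with patient random-intercept
models, each in a linear and a quadratic variant: ctDNAmaf vs the signature,
ctDNAmaf vs (log) LDH, and the signature vs LDH.  Model form is chosen from
residual diagnostics: a linear fit to genuinely quadratic data leaves a
curvature trend in the standardised-residual-versus-fitted relationship, so
the quadratic variant is preferred when that trend exceeds a threshold (the
quadratic variant's marginal R² can never fall below the linear one's, since
the models are nested).  Pairs whose best marginal R² stays below a
near-independence threshold are flagged — the situation where two markers
carry complementary rather than redundant information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mlm import MLMFit, fit_mlm, marginal_r2

LDH_ULN = 246.0  # serum LDH upper limit of normal, U/L


@dataclass
class PairModel:
    name: str
    linear: MLMFit | None
    quadratic: MLMFit | None
    r2_linear: float
    r2_quadratic: float
    chosen: str                  # "linear" | "quadratic" | "failed"
    curvature: float             # curvature trend of the linear fit
    near_independent: bool
    error: str | None = None

    @property
    def r2(self) -> float:
        return self.r2_quadratic if self.chosen == "quadratic" else self.r2_linear


@dataclass
class AssociationReport:
    pairs: dict[str, PairModel]
    residual_tables: dict[str, pd.DataFrame]
    n_ldh_above_uln: int | None = None
    warnings: list[str] = field(default_factory=list)

    def r2_summary(self) -> pd.Series:
        return pd.Series({k: v.r2 for k, v in self.pairs.items()})


def fit_association(y, x, groups, degree: int = 1) -> MLMFit:
    """Random-intercept polynomial regression of y on x (degree 1 or 2).

    x is centred before powers are formed, for numerical conditioning; the
    fitted values and R² are unaffected.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if len(y) < 10:
        raise ValueError("need at least 10 observations")
    xc = x - x.mean()
    cols = {"intercept": np.ones_like(xc), "x": xc}
    if degree == 2:
        cols["x2"] = xc**2
    return fit_mlm(y, pd.DataFrame(cols), groups, method="REML")


def residual_diagnostics(fit: MLMFit, groups=None) -> tuple[pd.DataFrame, dict]:
    """Standardised residuals vs fitted values, with trend summaries.

    ``trend`` is the correlation of residuals with fitted values (≈0 for any
    least-squares-type fit); ``curvature`` correlates residuals with the
    squared centred fitted values and flags a missed quadratic term.
    """
    sd = float(np.sqrt(fit.sigma2_patient + fit.sigma2_resid))
    # saturated fits estimate a numerically-zero variance; their residuals are
    # pure rounding noise and standardise to zero
    floor = 1e-10 * (1.0 + float(np.std(fit.fittedvalues)))
    std_resid = fit.resid / sd if sd > floor else np.zeros_like(fit.resid)
    table = pd.DataFrame({"fitted": fit.fittedvalues, "std_resid": std_resid})
    if groups is not None:
        table["patient"] = np.asarray(groups)
    f = fit.fittedvalues
    fc = f - f.mean()
    if np.std(fc) > 0 and np.std(std_resid) > 0:
        trend = float(np.corrcoef(std_resid, f)[0, 1])
        f2 = fc**2
        curvature = (
            float(np.corrcoef(std_resid, f2)[0, 1]) if np.std(f2) > 0 else 0.0
        )
    else:
        trend, curvature = 0.0, 0.0
    return table, {"trend": trend, "curvature": curvature}


def _fit_pair(name, y, x, groups, curvature_threshold, independence_threshold):
    try:
        lin = fit_association(y, x, groups, degree=1)
        quad = fit_association(y, x, groups, degree=2)
    except (ValueError, np.linalg.LinAlgError) as exc:
        return (
            PairModel(name, None, None, float("nan"), float("nan"), "failed",
                      float("nan"), False, error=str(exc)),
            pd.DataFrame(),
        )
    r2l, r2q = marginal_r2(lin), marginal_r2(quad)
    _, diag = residual_diagnostics(lin)
    chosen = "quadratic" if abs(diag["curvature"]) > curvature_threshold else "linear"
    best = quad if chosen == "quadratic" else lin
    table, _ = residual_diagnostics(best, groups)
    pm = PairModel(
        name=name,
        linear=lin,
        quadratic=quad,
        r2_linear=r2l,
        r2_quadratic=r2q,
        chosen=chosen,
        curvature=diag["curvature"],
        near_independent=max(r2l, r2q) < independence_threshold,
    )
    return pm, table


def association_triangle(
    cohort: pd.DataFrame,
    signature_values,
    curvature_threshold: float = 0.1,
    independence_threshold: float = 0.1,
) -> AssociationReport:
    """Fit the three pairwise models (both degrees each) and assemble the
    report.  LDH enters on the log scale; a missing or constant LDH column
    degrades to a partial report with a warning rather than an error."""
    y = np.log(cohort["maf"].to_numpy(dtype=float))
    groups = cohort["patient"].to_numpy()
    sig = np.asarray(signature_values, dtype=float)
    pairs: dict[str, PairModel] = {}
    tables: dict[str, pd.DataFrame] = {}
    warnings: list[str] = []

    pm, tab = _fit_pair("ctdna~signature", y, sig, groups,
                        curvature_threshold, independence_threshold)
    pairs[pm.name] = pm
    tables[pm.name] = tab

    n_uln = None
    if "ldh" in cohort.columns and cohort["ldh"].notna().all():
        ldh = cohort["ldh"].to_numpy(dtype=float)
        n_uln = int((ldh > LDH_ULN).sum())
        if np.std(ldh) == 0:
            warnings.append("LDH column is constant; LDH models skipped")
            for name in ("ctdna~ldh", "signature~ldh"):
                pairs[name] = PairModel(name, None, None, float("nan"),
                                        float("nan"), "failed", float("nan"),
                                        False, error="constant LDH")
                tables[name] = pd.DataFrame()
        else:
            log_ldh = np.log(ldh)
            pm, tab = _fit_pair("ctdna~ldh", y, log_ldh, groups,
                                curvature_threshold, independence_threshold)
            pairs[pm.name] = pm
            tables[pm.name] = tab
            pm, tab = _fit_pair("signature~ldh", sig, log_ldh, groups,
                                curvature_threshold, independence_threshold)
            pairs[pm.name] = pm
            tables[pm.name] = tab
    else:
        warnings.append("LDH column missing or incomplete; partial report")
    return AssociationReport(
        pairs=pairs,
        residual_tables=tables,
        n_ldh_above_uln=n_uln,
        warnings=warnings,
    )
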