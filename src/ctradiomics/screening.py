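"""Feature-by-feature mixed-model screening with spike-in calibration.

Each (transformed) radiomic feature is screened as the single fixed predictor
of log(ctDNAmaf) in a patient random-intercept model, optionally with log
lesion volume as an additional fixed predictor.  A set of spiked-in Gaussian
"[random...]" predictors — independent of the response by construction — is
screened alongside the real features, and the Benjamini-Hochberg FDR
correction is applied to the combined real + random p-value set, so the
random features calibrate the multiplicity behaviour of the screen.  In the
volume-adjusted screen every feature additionally receives a likelihood-ratio
test of its added value over volume alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mlm import fit_mlm, lrt, marginal_r2
from .synthetic import is_random_feature, spike_random_features

logger = logging.getLogger(__name__)


@dataclass
class TransformSpec:
    """Per-feature scale transform, optionally followed by a z-score with
    stored (training) constants.

    kinds: ``identity``, ``log``, ``log_shift`` (log(a + f)) and
    ``loglog_shift`` (log(log(f) + a), e.g. a=9 for the low gray-level run
    emphasis whose raw scale is doubly compressed).
    """

    kind: str = "identity"
    shift: float = 0.0
    zscore: bool = False
    mean: float | None = None
    sd: float | None = None

    def core(self, values: np.ndarray, name: str = "feature") -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "identity":
            out = v
        elif self.kind == "log":
            self._check_positive(v, name, v)
            out = np.log(v)
        elif self.kind == "log_shift":
            arg = self.shift + v
            self._check_positive(arg, name, v)
            out = np.log(arg)
        elif self.kind == "loglog_shift":
            self._check_positive(v, name, v)
            arg = np.log(v) + self.shift
            self._check_positive(arg, name, v)
            out = np.log(arg)
        else:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        return out

    @staticmethod
    def _check_positive(arg, name, raw):
        bad = ~(np.asarray(arg) > 0)
        if np.any(bad):
            off = np.asarray(raw)[bad][0]
            raise ValueError(
                f"transform of feature {name!r} takes log of a non-positive "
                f"argument (offending value {off!r})"
            )


def apply_transform(values, spec: TransformSpec, name: str = "feature") -> np.ndarray:
    """Apply the scale transform and, if requested, a z-score using the stored
    constants (fitting them from the data on first use)."""
    out = spec.core(values, name)
    if spec.zscore:
        if spec.mean is None or spec.sd is None:
            spec.mean = float(np.mean(out))
            spec.sd = float(np.std(out, ddof=0)) or 1.0
        out = (out - spec.mean) / spec.sd
    return out


def default_transform_registry(feature_names) -> dict[str, TransformSpec]:
    """Default per-feature transforms: log for strictly positive, typically
    right-skewed texture magnitudes, identity otherwise.  Chosen by
    configuration, not search; override per feature as needed."""
    log_feats = {
        "GLNUz", "GLNUr", "ZLNU", "RLNU", "Volume", "Busyness", "Coarseness",
        "HGRE", "HGZE", "LRHGE", "SZHGE", "SRHGE", "LZE", "LRE", "LZHGE",
    }
    reg: dict[str, TransformSpec] = {}
    for name in feature_names:
        if name == "LGRE":
            reg[name] = TransformSpec("loglog_shift", shift=9.0)
        elif name in log_feats:
            reg[name] = TransformSpec("log")
        else:
            reg[name] = TransformSpec("identity")
    return reg


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def screen_features(
    cohort: pd.DataFrame,
    feature_cols: list[str] | None = None,
    transforms: dict[str, TransformSpec] | None = None,
    n_random: int = 100,
    random_icc: float = 0.5,
    adjust_volume: bool = False,
    fdr_level: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the feature-by-feature screen and return the results table.

    ``cohort`` must carry ``patient``, ``maf`` and ``volume_mm3`` plus the
    feature columns.  Without volume adjustment, log volume itself is screened
    as a feature.  Half of the ``n_random`` spike-ins carry patient dependence
    at ``random_icc``; half are fully independent.  Rows are sorted by
    BH-adjusted Wald p-value.
    """
    if cohort["patient"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    y = np.log(cohort["maf"].to_numpy(dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("maf must be positive (floor zeros before screening)")
    groups = cohort["patient"].to_numpy()
    logvol = np.log(cohort["volume_mm3"].to_numpy(dtype=float))
    n = len(y)

    if feature_cols is None:
        skip = {"patient", "visit", "day", "maf", "maf_extrapolated", "ldh",
                "volume_mm3", "log_volume"}
        feature_cols = [c for c in cohort.columns if c not in skip]
    X_feat = {c: cohort[c].to_numpy(dtype=float) for c in feature_cols}
    transforms = transforms or {}
    if not adjust_volume:
        X_feat["Volume"] = logvol  # volume competes as a feature in this screen

    if n_random > 0:
        n_dep = n_random // 2
        spikes = []
        if n_dep:
            spikes.append(
                spike_random_features(n_dep, icc=random_icc, patient_ids=groups,
                                      seed=seed, start=1)
            )
        if n_random - n_dep:
            spikes.append(
                spike_random_features(n_random - n_dep, icc=0.0, patient_ids=groups,
                                      seed=seed + 1, start=n_dep + 1)
            )
        for sp in spikes:
            for c in sp.columns:
                X_feat[c] = sp[c].to_numpy()

    restricted_ml = None
    if adjust_volume:
        Xr = pd.DataFrame({"intercept": np.ones(n), "log_volume": logvol})
        restricted_ml = fit_mlm(y, Xr, groups, method="ML", compute_df=False)

    rows = []
    for name, raw in X_feat.items():
        spec = transforms.get(name)
        try:
            f = apply_transform(raw, replace(spec, mean=None, sd=None), name) \
                if spec is not None else raw
        except ValueError as exc:
            logger.warning("feature %s skipped: %s", name, exc)
            continue
        cols = {"intercept": np.ones(n)}
        if adjust_volume and name != "Volume":
            cols["log_volume"] = logvol
        cols["feature"] = f
        X = pd.DataFrame(cols)
        try:
            fit = fit_mlm(y, X, groups, method="REML")
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("feature %s skipped: %s", name, exc)
            continue
        k = len(fit.params) - 1  # feature coefficient is last
        row = {
            "feature": name,
            "t": fit.tvalues[k],
            "p": fit.pvalues[k],
            "r2": marginal_r2(fit),
            "is_random": is_random_feature(name),
        }
        if adjust_volume:
            full_ml = fit_mlm(y, X, groups, method="ML", compute_df=False)
            res = lrt(full_ml, restricted_ml)
            row["lrt_stat"] = res.statistic
            row["lrt_p"] = res.pvalue
        rows.append(row)

    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["sig"] = [_stars(p) for p in out["p_adj"]]
    out["significant"] = out["p_adj"] < fdr_level
    out = out.sort_values(["p_adj", "p", "feature"], kind="stable").reset_index(drop=True)
    return out


def spearman_volume_profile(features: pd.DataFrame, volume) -> pd.Series:
    """Spearman rank correlation of each feature column with lesion volume
    (average ranks on ties); constant features yield NaN."""
    v = np.asarray(volume, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    out = {}
    for c in features.columns:
        f = features[c].to_numpy(dtype=float)
        if np.all(f == f[0]):
            out[c] = float("nan")
        else:
            out[c] = float(stats.spearmanr(f, v).statistic)
    return pd.Series(out, name="spearman_rho")


def detect_outliers_robust_cov(
    data: pd.DataFrame | np.ndarray,
    quantile: float = 0.975,
    max_iter: int = 100,
) -> np.ndarray:
    """Flag multivariate outliers via a deterministic robust covariance.

    A reweighted minimum-covariance-determinant-style estimate: start from
    coordinate-wise medians and MADs, iterate concentration steps on the
    half-sample with smallest Mahalanobis distances, apply a chi-square
    consistency correction, and flag rows whose squared robust distance
    exceeds the chi2(p) ``quantile``.  When n <= 2p the scatter is shrunk
    toward its diagonal (logged) to stay well-conditioned.  Fully
    deterministic: duplicated inputs produce identical flags.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2D")
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few rows for a robust scatter estimate")
    shrink = 0.0
    if n <= 2 * p:
        shrink = 0.5
        logger.info("robust covariance: n=%d <= 2p=%d, shrinking scatter "
                    "toward its diagonal (intensity %.2f)", n, 2 * p, shrink)

    def _condition(C):
        C = (1.0 - shrink) * C + shrink * np.diag(np.diag(C))
        C.flat[:: p + 1] += 1e-10 * max(np.trace(C) / p, 1.0)
        return C

    mu = np.median(X, axis=0)
    mad = 1.4826 * np.median(np.abs(X - mu), axis=0)
    sd = X.std(axis=0)
    bad = mad <= 0
    mad[bad] = np.where(sd[bad] > 0, sd[bad], 1.0)
    C = _condition(np.diag(mad**2))
    h = (n + p + 1) // 2
    subset_prev: np.ndarray | None = None
    for _ in range(max_iter):
        try:
            Ci = np.linalg.inv(C)
        except np.linalg.LinAlgError as exc:
            raise ValueError("degenerate scatter matrix") from exc
        d2 = np.einsum("ij,jk,ik->i", X - mu, Ci, X - mu)
        subset = np.sort(np.argsort(d2, kind="stable")[:h])
        if subset_prev is not None and np.array_equal(subset, subset_prev):
            break
        subset_prev = subset
        sub = X[subset]
        mu = sub.mean(axis=0)
        C = _condition(np.cov(sub, rowvar=False, ddof=0))
    # chi-square consistency rescaling so clean Gaussian data calibrates
    Ci = np.linalg.inv(C)
    d2 = np.einsum("ij,jk,ik->i", X - mu, Ci, X - mu)
    factor = np.median(d2) / stats.chi2.ppf(0.5, p)
    if factor <= 0 or not math.isfinite(factor):
        raise ValueError("degenerate scatter matrix")
    d2 /= factor
    return d2 > stats.chi2.ppf(quantile, p)
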