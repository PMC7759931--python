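"""Aligning blood-derived ctDNA measurements with imaging visits.

Blood draws rarely fall exactly on imaging dates, and the mutant allele
fraction (maf) can come from two assays with different detection limits:
shallow whole-genome sequencing (sWGS, reliable above a ~3% tumour fraction)
and tagged-amplicon deep sequencing (TAm-Seq, sensitive below it).  This
module picks the assay per sample, linearly interpolates maf to imaging
dates, quantifies assay agreement with Lin's concordance correlation
coefficient, and categorises lesion volume changes using RECIST-derived
volume thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SWGS_LOD = 0.03  # sWGS tumour-fraction limit of detection


@dataclass
class AssayChoice:
    maf: float
    assay: str           # "sWGS" | "TAmSeq"
    below_lod: bool = False


def choose_assay(swgs_maf: float | None, tamseq_maf: float | None) -> AssayChoice:
    """Prefer sWGS at or above its 3% detection limit, otherwise TAm-Seq.

    A below-limit sWGS value is only returned (flagged) when no TAm-Seq
    measurement exists.
    """
    has_swgs = swgs_maf is not None and not (isinstance(swgs_maf, float) and math.isnan(swgs_maf))
    has_tam = tamseq_maf is not None and not (isinstance(tamseq_maf, float) and math.isnan(tamseq_maf))
    if not has_swgs and not has_tam:
        raise ValueError("no assay value present")
    if has_swgs and float(swgs_maf) >= SWGS_LOD:
        return AssayChoice(float(swgs_maf), "sWGS")
    if has_tam:
        return AssayChoice(float(tamseq_maf), "TAmSeq")
    return AssayChoice(float(swgs_maf), "sWGS", below_lod=True)


def interpolate_maf(sample_days, sample_mafs, visit_day: float) -> tuple[float, bool]:
    """maf at an imaging date: exact match passes through, otherwise linear
    interpolation on the maf scale between the bracketing samples; outside the
    sampled range the nearest sample's value is used (flagged extrapolated).

    Returns ``(maf, extrapolated)``.
    """
    days = np.asarray(sample_days, dtype=float)
    mafs = np.asarray(sample_mafs, dtype=float)
    if days.size == 0:
        raise ValueError("no blood samples for this patient")
    order = np.argsort(days, kind="stable")
    days, mafs = days[order], mafs[order]
    extrapolated = visit_day < days[0] or visit_day > days[-1]
    return float(np.interp(visit_day, days, mafs)), bool(extrapolated)


def assemble_cohort(
    blood: pd.DataFrame,
    visits: pd.DataFrame,
    features: pd.DataFrame | None = None,
    maf_floor: float = 1e-6,
) -> pd.DataFrame:
    """Join blood-derived maf/LDH onto imaging visits.

    ``blood`` needs columns ``patient, day`` plus either ``maf`` or the assay
    pair ``swgs_maf``/``tamseq_maf`` (and optionally ``ldh``); ``visits``
    needs ``patient, day`` plus any volume columns; ``features`` rows must
    align one-to-one with visits on (patient, visit) or (patient, day).
    Zero maf values are floored at ``maf_floor`` so the log response is
    finite.
    """
    blood = blood.copy()
    if "maf" not in blood.columns:
        picks = [
            choose_assay(s, t)
            for s, t in zip(blood.get("swgs_maf"), blood.get("tamseq_maf"))
        ]
        blood["maf"] = [c.maf for c in picks]
        blood["assay"] = [c.assay for c in picks]
        blood["below_lod"] = [c.below_lod for c in picks]

    out = visits.copy().reset_index(drop=True)
    mafs, extrap, ldhs = [], [], []
    has_ldh = "ldh" in blood.columns
    for _, row in out.iterrows():
        grp = blood[blood["patient"] == row["patient"]]
        m, e = interpolate_maf(grp["day"], grp["maf"], row["day"])
        mafs.append(max(m, maf_floor))
        extrap.append(e)
        if has_ldh:
            l, _ = interpolate_maf(grp["day"], grp["ldh"], row["day"])
            ldhs.append(l)
    out["maf"] = mafs
    out["maf_extrapolated"] = extrap
    if has_ldh:
        out["ldh"] = ldhs
    if features is not None:
        keys = [k for k in ("patient", "visit", "day") if k in features.columns]
        feat_cols = [c for c in features.columns if c not in keys]
        out = out.merge(features, on=keys, how="left", suffixes=("", "_feat"))
        missing = out[feat_cols].isna().all(axis=1)
        if missing.any():
            raise ValueError(
                f"{int(missing.sum())} visit rows have no matching feature row"
            )
    return out


def lin_ccc(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), with
    moments on the 1/n scale; the confidence interval uses the asymptotic
    variance of the z-transformed estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("zero variance and equal means: CCC undefined")
    ccc = 2.0 * sxy / denom
    # asymptotic variance of atanh(CCC) (Lin 1989)
    r = sxy / math.sqrt(sx2 * sy2) if sx2 > 0 and sy2 > 0 else 0.0
    c = min(max(ccc, -0.999999), 0.999999)
    if abs(r) > 1e-12 and sx2 > 0 and sy2 > 0:
        u = (mx - my) / (sx2 * sy2) ** 0.25
        se2 = (
            (1 - r**2) * c**2 / ((1 - c**2) * r**2)
            + 2 * c**3 * (1 - c) * u**2 / (r * (1 - c**2) ** 2)
            - c**4 * u**4 / (2 * r**2 * (1 - c**2) ** 2)
        ) / (n - 2)
        se2 = max(se2, 0.0)
    else:
        se2 = 1.0 / max(n - 3, 1)
    z = math.atanh(c)
    q = stats.norm.ppf(1 - alpha / 2)
    half = q * math.sqrt(se2)
    return float(ccc), (math.tanh(z - half), math.tanh(z + half))


def diameter_to_volume_threshold(d: float) -> float:
    """Fractional volume change implied by a fractional diameter change:
    (1 + d)^3 - 1 (e.g. RECIST +20% diameter -> +72.8% volume)."""
    if d <= -1:
        raise ValueError("fractional diameter change must exceed -1")
    return (1.0 + d) ** 3 - 1.0


LARGE_INCREASE = diameter_to_volume_threshold(0.20)    # +0.728
LARGE_DECREASE = diameter_to_volume_threshold(-0.30)   # -0.657


def categorize_volume_change(baseline_vol: float, current_vol: float) -> str:
    """RECIST-derived descriptive category of a lesion volume change.

    >73% increase is "large increase"; >66% decrease is "large decrease";
    anything between is a small increase/decrease; zero change reports
    "no change".
    """
    if baseline_vol <= 0 or current_vol < 0:
        raise ValueError("volumes must be positive (baseline) / non-negative")
    r = current_vol / baseline_vol - 1.0
    if r > LARGE_INCREASE:
        return "large increase"
    if r > 0:
        return "small increase"
    if r == 0:
        return "no change"
    if r >= LARGE_DECREASE:
        return "small decrease"
    return "large decrease"
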