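"""Synthetic lesions and longitudinal cohorts.

Real CT volumes and patient tables for this kind of study are rarely shareable,
so every downstream stage is exercised on synthetic data with the statistical
structure the analysis assumes:

* phantom lesion volumes (constant / checkerboard / correlated-noise textures
  inside an ellipsoidal mask) for the feature-extraction stage;
* longitudinal cohorts of ~15 patients with 1-12 visits each, in which
  log(ctDNAmaf) is driven by log lesion volume plus a patient random
  intercept, radiomic-like features are multivariate Gaussian with a target
  correlation matrix that includes a volume column, serum LDH is quadratic in
  log(ctDNAmaf), and blood draws are offset from imaging dates by a
  discretised log-normal calibrated to a 10-day median (IQR 4-34 days);
* spike-in random predictor columns (the "[random...]" features) used to
  calibrate multiplicity corrections and selection stopping rules.

All generators are deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

RANDOM_PREFIX = "[random"

# log-normal for |blood - imaging| offsets: median 10 days, IQR ratio 34/4
_OFFSET_MU = math.log(10.0)
_OFFSET_SIGMA = math.log(34.0 / 4.0) / (2.0 * 0.67448975)


def default_feature_correlation(
    n_features: int = 8,
    rho_feature: float = 0.6,
    rho_volume: float = 0.8,
) -> pd.DataFrame:
    """Equicorrelated feature block with a common correlation to log-volume.

    Emulates the strong feature intercorrelation and feature-volume
    correlation observed in CT radiomics panels.  The last row/column is the
    (log) lesion volume.
    """
    k = n_features
    C = np.full((k + 1, k + 1), rho_feature)
    np.fill_diagonal(C, 1.0)
    C[-1, :-1] = rho_volume
    C[:-1, -1] = rho_volume
    names = [f"f{i + 1}" for i in range(k)] + ["volume"]
    return pd.DataFrame(C, index=names, columns=names)


@dataclass
class CohortSimConfig:
    """Generative settings for a longitudinal ctDNA/radiomics cohort.

    Defaults reflect the cohort scale the pipeline targets: 15 patients with
    1-12 visits each (about 70 visits in total), a strong volume effect on
    log(ctDNAmaf) (volume alone explains roughly half the marginal variance),
    a patient-level intraclass correlation of 0.4 among the random
    components, and LDH rising quadratically with log(ctDNAmaf).
    """

    n_patients: int = 15
    visits_range: tuple[int, int] = (1, 12)
    beta_volume: float = 0.55         # slope of log(maf) on log(volume mm^3)
    beta0: float = -8.6               # intercept of log(maf)
    icc_patient: float = 0.4          # Var(b)/(Var(b)+Var(e))
    sigma_resid: float = 0.6          # residual s.d. of log(maf)
    feature_cov: pd.DataFrame = field(default_factory=default_feature_correlation)
    ldh_quadratic_coefs: tuple[float, float, float] = (636.0, 112.0, 6.0)
    ldh_noise_sd: float = 70.0
    blood_offset_days: tuple[float, float] = (_OFFSET_MU, _OFFSET_SIGMA)
    log_volume_mean: float = 9.2      # mm^3 scale; exp(9.2) ~ 10 mL
    log_volume_sd: float = 1.5
    log_volume_walk_sd: float = 0.5
    visit_interval_days: float = 60.0
    maf_floor: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0.0 <= self.icc_patient < 1.0):
            raise ValueError("icc_patient must lie in [0, 1)")
        lo, hi = self.visits_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid visits_range")
        C = np.asarray(self.feature_cov, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("feature_cov must be square")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("feature_cov must be symmetric")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-10:
            raise ValueError(
                f"feature_cov is not positive semi-definite: "
                f"smallest eigenvalue {w.min():.6g}"
            )


@dataclass
class TruthRecord:
    """Realised generative quantities, for parameter-recovery tests."""

    beta0: float
    beta_volume: float
    sigma2_patient: float
    sigma2_resid: float
    patient_intercepts: pd.Series
    linpred: pd.Series  # noise-free log(maf) per visit (fixed + random intercept)
    seed: int


def generate_lesion_phantom(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    texture: dict,
    mask_radius: float,
    seed: int = 0,
):
    """Build a phantom HU volume and an ellipsoidal lesion mask.

    ``texture`` is one of
    ``{"kind": "constant", "value": hu}``,
    ``{"kind": "checker", "period": p, "low": hu, "high": hu}``,
    ``{"kind": "noise", "mean": hu, "sd": hu, "corr_len": voxels}``.
    ``mask_radius`` is in mm; the mask is a single connected ellipsoid.
    """
    from .radiomics import VoxelVolume  # local import to avoid a cycle

    shape = tuple(int(s) for s in shape)
    if any(s < 3 for s in shape):
        raise ValueError("shape must be >= 3 along every axis")
    spacing = tuple(float(s) for s in spacing)
    rng = np.random.default_rng(seed)

    kind = texture.get("kind", "constant")
    if kind == "constant":
        data = np.full(shape, float(texture.get("value", 50.0)))
    elif kind == "checker":
        period = int(texture.get("period", 1))
        low = float(texture.get("low", 0.0))
        high = float(texture.get("high", 100.0))
        ii, jj, kk = np.indices(shape)
        parity = ((ii // period) + (jj // period) + (kk // period)) % 2
        data = np.where(parity == 0, low, high)
    elif kind == "noise":
        sd = float(texture.get("sd", 30.0))
        mean = float(texture.get("mean", 50.0))
        corr_len = float(texture.get("corr_len", 0.0))
        data = rng.standard_normal(shape)
        if corr_len > 0:
            data = ndimage.gaussian_filter(data, sigma=corr_len)
            s = data.std()
            if s > 0:
                data = data / s
        data = mean + sd * data
    else:
        raise ValueError(f"unknown texture kind {kind!r}")
    data = np.clip(data.astype(float), -1000.0, 1000.0)

    center = (np.array(shape) - 1) / 2.0
    ii, jj, kk = np.indices(shape)
    d2 = (
        ((ii - center[0]) * spacing[0]) ** 2
        + ((jj - center[1]) * spacing[1]) ** 2
        + ((kk - center[2]) * spacing[2]) ** 2
    )
    mask = d2 <= mask_radius**2
    if not mask.any():
        raise ValueError("empty mask: mask_radius too small for grid spacing")
    return VoxelVolume(data=data, spacing=spacing), mask


def _interleaved_offsets(rng: np.random.Generator, n: int, mu: float, sigma: float):
    """Signed, day-rounded blood-draw offsets with |offset| ~ lognormal."""
    mag = np.rint(rng.lognormal(mean=mu, sigma=sigma, size=n)).astype(int)
    mag = np.maximum(mag, 0)
    sign = rng.choice([-1, 1], size=n)
    return sign * mag


def generate_cohort(cfg: CohortSimConfig):
    """Simulate a longitudinal cohort.

    Returns ``(cohort, features, blood, truth)`` where ``cohort`` is the
    per-visit table (patient, visit date, true maf, measured/interpolable maf,
    LDH, lesion volume in mm^3), ``features`` holds the correlated
    radiomic-like columns for the same rows, ``blood`` is the blood-sample
    table (offset dates, assay values), and ``truth`` records the generative
    parameters.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    C = np.asarray(cfg.feature_cov, dtype=float)
    names = list(cfg.feature_cov.columns)
    if names[-1] != "volume":
        raise ValueError("feature_cov must carry 'volume' as its last column")
    feat_names = names[:-1]
    k = len(feat_names)

    # visit counts: truncated-geometric over the configured range, so a
    # 15-patient cohort lands near 70 visits with most patients imaged a
    # handful of times and a few followed through 10+ visits
    lo, hi = cfg.visits_range
    n_visits = np.clip(lo - 1 + rng.geometric(p=0.2, size=cfg.n_patients), lo, hi)

    rows = []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:02d}"
        base_lv = rng.normal(cfg.log_volume_mean, cfg.log_volume_sd)
        lv = base_lv + np.concatenate(
            [[0.0], np.cumsum(rng.normal(0.0, cfg.log_volume_walk_sd, n_visits[p] - 1))]
        )
        gaps = np.rint(
            rng.lognormal(math.log(cfg.visit_interval_days), 0.25, n_visits[p] - 1)
        ).astype(int)
        days = np.concatenate([[0], np.cumsum(np.maximum(gaps, 1))])
        for v in range(n_visits[p]):
            rows.append((pid, v + 1, int(days[v]), float(lv[v])))
    visits = pd.DataFrame(rows, columns=["patient", "visit", "day", "log_volume"])
    n = len(visits)

    # response: log(maf) = beta0 + beta_v * log(volume) + b_patient + e
    sigma2_e = cfg.sigma_resid**2
    if cfg.icc_patient > 0:
        sigma2_b = sigma2_e * cfg.icc_patient / (1.0 - cfg.icc_patient)
    else:
        sigma2_b = 0.0
    b = rng.normal(0.0, math.sqrt(sigma2_b), cfg.n_patients)
    pid_codes = pd.factorize(visits["patient"])[0]
    linpred = cfg.beta0 + cfg.beta_volume * visits["log_volume"].to_numpy() + b[pid_codes]
    log_maf = linpred + rng.normal(0.0, cfg.sigma_resid, n)
    maf = np.clip(np.exp(log_maf), cfg.maf_floor, 1.0)

    # features: conditional multivariate Gaussian given the standardized
    # log-volume, so corr(feature_j, volume) matches the target matrix
    z_vol = (visits["log_volume"] - visits["log_volume"].mean()) / max(
        visits["log_volume"].std(ddof=0), 1e-12
    )
    Cff = C[:k, :k]
    cfv = C[:k, -1]
    cond_cov = Cff - np.outer(cfv, cfv)
    w, V = np.linalg.eigh(cond_cov)
    w = np.clip(w, 0.0, None)
    root = V * np.sqrt(w)
    noise = rng.standard_normal((n, k)) @ root.T
    F = np.outer(z_vol.to_numpy(), cfv) + noise
    features = pd.DataFrame(F, columns=feat_names)
    features.insert(0, "patient", visits["patient"].to_numpy())
    features.insert(1, "visit", visits["visit"].to_numpy())

    # LDH: quadratic in log(maf) plus noise, floored at a physiological minimum
    a0, a1, a2 = cfg.ldh_quadratic_coefs
    ldh = a0 + a1 * log_maf + a2 * log_maf**2 + rng.normal(0.0, cfg.ldh_noise_sd, n)
    ldh = np.maximum(ldh, 80.0)

    cohort = visits.copy()
    cohort["volume_mm3"] = np.exp(cohort["log_volume"])
    cohort["maf"] = maf
    cohort["ldh"] = ldh

    # blood samples: one draw per visit at an offset date; sWGS with a TAm-Seq
    # follow-up when the sWGS tumor fraction falls below its 3% detection limit
    mu, sigma = cfg.blood_offset_days
    offs = _interleaved_offsets(rng, n, mu, sigma)
    swgs = np.clip(maf * np.exp(rng.normal(0.0, 0.15, n)), 0.0, 1.0)
    tam = np.where(
        swgs < 0.03,
        np.clip(maf * np.exp(rng.normal(0.0, 0.05, n)), cfg.maf_floor, 1.0),
        np.nan,
    )
    blood = pd.DataFrame(
        {
            "patient": visits["patient"],
            "day": visits["day"] + offs,
            "swgs_maf": swgs,
            "tamseq_maf": tam,
            "ldh": ldh,
        }
    )

    truth = TruthRecord(
        beta0=cfg.beta0,
        beta_volume=cfg.beta_volume,
        sigma2_patient=sigma2_b,
        sigma2_resid=sigma2_e,
        patient_intercepts=pd.Series(
            b, index=[f"P{p + 1:02d}" for p in range(cfg.n_patients)]
        ),
        linpred=pd.Series(linpred, index=visits.index),
        seed=cfg.seed,
    )
    return cohort, features, blood, truth


def spike_random_features(
    n: int = 100,
    icc: float = 0.0,
    patient_ids=None,
    seed: int = 0,
    start: int = 1,
) -> pd.DataFrame:
    """Generate ``n`` spike-in Gaussian predictor columns named ``[random#]``.

    Columns are independent of every real feature and of the response.  With
    ``icc > 0`` each column carries a shared per-patient component so that its
    patient-level variance share is ``icc``, mimicking the within-patient
    dependence of real radiomic features.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if patient_ids is None:
        raise ValueError("patient_ids is required")
    pid = np.asarray(patient_ids)
    codes, uniques = pd.factorize(pid)
    rng = np.random.default_rng(seed)
    G = len(uniques)
    b = rng.standard_normal((G, n)) * math.sqrt(icc)
    e = rng.standard_normal((len(pid), n)) * math.sqrt(1.0 - icc)
    cols = b[codes] + e
    names = [f"{RANDOM_PREFIX}{start + j}]" for j in range(n)]
    return pd.DataFrame(cols, columns=names)


def is_random_feature(name: str) -> bool:
    return str(name).startswith(RANDOM_PREFIX)
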