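"""Correlation-matched Monte-Carlo null test.

Individually, volume-adjusted feature screens may find nothing after a
multiplicity correction, yet a *set* of features (or a PCA signature built
from them) can still predict log(ctDNAmaf) beyond lesion volume.  To test
that claim while honouring the selection step, many synthetic datasets of
random features are generated with the same correlation structure as the real
features — including their correlation with lesion volume — but, by
construction, zero population correlation with the response (the generator
never sees the response).  In every null dataset the same pipeline is re-run:
pick the five best features by likelihood-ratio test against the volume-only
model, fit the joint model (or rebuild the signature), and record its
marginal R² and LRT statistic.  The real data's pair is then located in the
null cloud; the empirical exceedance probability uses the add-one rule
(1 + #null >= real)/(n + 1) so it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mlm import fit_mlm, lrt, marginal_r2
from .signature import build_signature, evaluate_signature


@dataclass
class NullSimConfig:
    n_datasets: int = 2500       # scale down (200-500) for desk-size runs
    n_features: int = 38
    include_patient_dependence: bool = True
    icc: float = 0.5
    top_k: int = 5
    reselect_within_null: bool = True
    seed: int = 0

    def validate(self):
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.n_features < 5:
            raise ValueError("n_features must be >= 5")


@dataclass
class JointStructure:
    """Gaussian model of [features, volume] on the transformed scale."""

    names: list[str]             # feature names, then "volume" last
    mean: np.ndarray
    cov: np.ndarray
    clipped: bool = False        # PSD repair applied


@dataclass
class NullSimResult:
    real_r2: float
    real_lrt: float
    null_r2: np.ndarray
    null_lrt: np.ndarray
    p_r2: float
    p_lrt: float
    builder: str
    n_datasets: int

    def scatter_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "dataset": np.arange(1, self.n_datasets + 1),
                "r2": self.null_r2,
                "lrt": self.null_lrt,
                "real": False,
            }
        )
        real = pd.DataFrame(
            {"dataset": [0], "r2": [self.real_r2], "lrt": [self.real_lrt],
             "real": [True]}
        )
        return pd.concat([real, df], ignore_index=True)


def estimate_joint_structure(features: pd.DataFrame, volume) -> JointStructure:
    """Mean and covariance of [features, volume], PSD-repaired by eigenvalue
    clipping at 1e-10 when sampling noise or collinearity makes the estimate
    indefinite."""
    F = features.to_numpy(dtype=float)
    if np.isnan(F).any():
        raise ValueError("feature matrix contains missing values")
    v = np.asarray(volume, dtype=float)
    M = np.column_stack([F, v])
    mean = M.mean(axis=0)
    cov = np.cov(M, rowvar=False, ddof=1)
    w, V = np.linalg.eigh(cov)
    clipped = bool(w.min() < 1e-10)
    if clipped:
        w = np.clip(w, 1e-10, None)
        cov = (V * w) @ V.T
    names = [str(c) for c in features.columns] + ["volume"]
    return JointStructure(names=names, mean=mean, cov=cov, clipped=clipped)


def simulate_null_features(
    structure: JointStructure,
    volume_observed,
    cfg: NullSimConfig,
    rng: np.random.Generator | None = None,
    patient_ids=None,
):
    """Yield ``cfg.n_datasets`` feature matrices conditional on the observed
    volume column.

    Features are drawn from the conditional Gaussian given volume, so each
    column's correlation with volume matches the estimated structure while
    the correlation with the response is zero in population (the response is
    not an input).  With patient dependence enabled, the conditional noise is
    split into a shared per-patient component and a visit-level component at
    the configured intraclass correlation, leaving the marginal covariance
    unchanged.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    codes = (
        pd.factorize(np.asarray(patient_ids))[0] if patient_ids is not None else None
    )
    yield from _simulate_datasets(structure, volume_observed, cfg, codes, rng)


def _simulate_datasets(structure, volume_observed, cfg, patient_codes, rng):
    """Conditional-on-volume Gaussian draws, with the optional patient split."""
    v = np.asarray(volume_observed, dtype=float)
    n = len(v)
    k = len(structure.names) - 1
    mu_f = structure.mean[:k]
    mu_v = structure.mean[k]
    s_vv = structure.cov[k, k]
    s_fv = structure.cov[:k, k]
    beta = s_fv / s_vv
    cond_cov = structure.cov[:k, :k] - np.outer(s_fv, s_fv) / s_vv
    w, V = np.linalg.eigh(cond_cov)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    cond_mean = mu_f[None, :] + np.outer(v - mu_v, beta)
    icc = cfg.icc if cfg.include_patient_dependence else 0.0
    G = int(patient_codes.max()) + 1 if patient_codes is not None else 0
    names = structure.names[:-1]
    for _ in range(cfg.n_datasets):
        if icc > 0 and patient_codes is not None:
            b = (rng.standard_normal((G, k)) @ root.T) * np.sqrt(icc)
            e = (rng.standard_normal((n, k)) @ root.T) * np.sqrt(1.0 - icc)
            noise = b[patient_codes] + e
        else:
            noise = rng.standard_normal((n, k)) @ root.T
        yield pd.DataFrame(cond_mean + noise, columns=names)


def _top_k_by_lrt(y, logvol, features: pd.DataFrame, groups, k: int):
    n = len(y)
    Xr = pd.DataFrame({"intercept": np.ones(n), "log_volume": logvol})
    restricted = fit_mlm(y, Xr, groups, method="ML", compute_df=False)
    stats_ = []
    for c in features.columns:
        X = Xr.copy()
        X[c] = features[c].to_numpy(dtype=float)
        full = fit_mlm(y, X, groups, method="ML", compute_df=False)
        res = lrt(full, restricted)
        stats_.append((res.pvalue, str(c)))
    stats_.sort()
    return [name for _, name in stats_[:k]], restricted


def _joint_stats(y, logvol, features: pd.DataFrame, names, groups, restricted,
                 builder: str):
    n = len(y)
    X = pd.DataFrame({"intercept": np.ones(n), "log_volume": logvol})
    if builder == "five-features":
        for c in names:
            X[c] = features[c].to_numpy(dtype=float)
    elif builder == "signature":
        sub = features[names].copy()
        z = (sub - sub.mean()) / sub.std(ddof=0).replace(0.0, 1.0)
        C = np.corrcoef(z.to_numpy(), rowvar=False)
        w, V = np.linalg.eigh(C)
        load = V[:, -1]
        score = z.to_numpy() @ load
        if np.corrcoef(score, y)[0, 1] < 0:
            score = -score
        X["signature"] = score
    else:
        raise ValueError(f"unknown builder {builder!r}")
    full = fit_mlm(y, X, groups, method="ML", compute_df=False)
    res = lrt(full, restricted)
    return marginal_r2(full), res.statistic


def null_reference_test(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    cfg: NullSimConfig,
    builder: str = "five-features",
    allow_fixed_selection: bool = False,
) -> NullSimResult:
    """Locate the real (R², LRT) pair in the correlation-matched null cloud.

    ``features`` holds the transformed real feature columns (volume excluded)
    aligned with ``cohort`` rows.  The top-``cfg.top_k`` selection is re-run
    inside every null dataset so that the reference distribution carries the
    same selection bias as the real statistic; disabling re-selection is
    anti-conservative and rejected unless ``allow_fixed_selection`` is set.
    """
    cfg.validate()
    if not cfg.reselect_within_null and not allow_fixed_selection:
        raise ValueError(
            "re-selection within null datasets is required for a valid test; "
            "set allow_fixed_selection=True to override"
        )
    y = np.log(cohort["maf"].to_numpy(dtype=float))
    logvol = np.log(cohort["volume_mm3"].to_numpy(dtype=float))
    groups = cohort["patient"].to_numpy()
    codes = pd.factorize(groups)[0]
    rng = np.random.default_rng(cfg.seed)

    real_names, restricted = _top_k_by_lrt(y, logvol, features, groups, cfg.top_k)
    real_r2, real_lrt = _joint_stats(y, logvol, features, real_names, groups,
                                     restricted, builder)

    structure = estimate_joint_structure(features, logvol)
    null_r2 = np.empty(cfg.n_datasets)
    null_lrt = np.empty(cfg.n_datasets)
    for i, F in enumerate(_simulate_datasets(structure, logvol, cfg, codes, rng)):
        if cfg.reselect_within_null:
            names, _ = _top_k_by_lrt(y, logvol, F, groups, cfg.top_k)
        else:
            names = list(F.columns[: cfg.top_k])
        null_r2[i], null_lrt[i] = _joint_stats(y, logvol, F, names, groups,
                                               restricted, builder)
    p_r2 = (1.0 + np.sum(null_r2 >= real_r2)) / (cfg.n_datasets + 1.0)
    p_lrt = (1.0 + np.sum(null_lrt >= real_lrt)) / (cfg.n_datasets + 1.0)
    return NullSimResult(
        real_r2=real_r2,
        real_lrt=real_lrt,
        null_r2=null_r2,
        null_lrt=null_lrt,
        p_r2=float(p_r2),
        p_lrt=float(p_lrt),
        builder=builder,
        n_datasets=cfg.n_datasets,
    )
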