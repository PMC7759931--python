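"""The PCA radiomics signature.

After volume-adjusted screening, the five features with the smallest
likelihood-ratio-test p-values are transformed, z-scored, and summarised by
the first principal component of their correlation matrix.  The resulting
loading vector defines a scalar signature

    S = sum_k  w_k * z(t_k(f_k)),

an affine function of the transformed inputs that can be frozen (serialised
to JSON with its transforms, standardisation constants and loadings) and
applied to new feature tables.  The sign of the first principal axis is
arbitrary; it is fixed so the signature correlates positively with
|log(ctDNAmaf)| on the training rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .screening import TransformSpec, apply_transform
from .synthetic import is_random_feature


@dataclass
class SignatureModel:
    """Transform specs, standardisation constants and first-PC loadings."""

    features: list[str]
    transforms: list[TransformSpec]
    means: list[float]
    sds: list[float]
    loadings: list[float]
    sign_convention: str = "positive-correlation-with-|log(maf)|"

    def __post_init__(self):
        k = len(self.features)
        if not (len(self.transforms) == len(self.means) == len(self.sds)
                == len(self.loadings) == k):
            raise ValueError("inconsistent signature component lengths")

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": self.features,
                "transforms": [
                    {"kind": t.kind, "shift": t.shift} for t in self.transforms
                ],
                "means": self.means,
                "sds": self.sds,
                "loadings": self.loadings,
                "sign_convention": self.sign_convention,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        return cls(
            features=d["features"],
            transforms=[TransformSpec(t["kind"], t["shift"]) for t in d["transforms"]],
            means=d["means"],
            sds=d["sds"],
            loadings=d["loadings"],
            sign_convention=d.get("sign_convention", ""),
        )


def pick_top5(screen: pd.DataFrame, k: int = 5) -> list[str]:
    """The k real features with the smallest LRT p-values from the
    volume-adjusted screen; spiked random features are excluded even when
    their p-values are small.  Ties break by feature name."""
    if "lrt_p" not in screen.columns:
        raise ValueError("screen result lacks LRT p-values (run with volume adjustment)")
    real = screen[~screen["is_random"].astype(bool)].copy()
    real = real[~real["feature"].map(is_random_feature)]
    if len(real) < k:
        raise ValueError(f"need at least {k} real features, got {len(real)}")
    real = real.sort_values(["lrt_p", "feature"], kind="stable")
    return real["feature"].head(k).tolist()


def fit_pca_signature(
    Z: pd.DataFrame,
    response: np.ndarray | None = None,
    transforms: dict[str, TransformSpec] | None = None,
    means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
    eigengap_tol: float = 1e-8,
) -> SignatureModel:
    """First principal axis of the correlation matrix of the standardised
    feature matrix ``Z`` (columns must be z-scored).

    ``response`` (typically |log(ctDNAmaf)| on the training rows) fixes the
    sign; without it, the convention is a positive sum of loadings.
    """
    names = [str(c) for c in Z.columns]
    X = Z.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(np.abs(mu) > 1e-6) or np.any(np.abs(sd - 1.0) > 1e-3):
        raise ValueError("signature PCA expects z-scored columns")
    C = np.corrcoef(X, rowvar=False)
    w, V = np.linalg.eigh(C)
    if w[-1] - w[-2] < eigengap_tol:
        raise ValueError(
            f"ambiguous first principal axis (eigengap {w[-1] - w[-2]:.3g})"
        )
    load = V[:, -1]
    score = X @ load
    if response is not None:
        r = np.corrcoef(score, np.asarray(response, dtype=float))[0, 1]
        if r < 0:
            load = -load
    elif load.sum() < 0:
        load = -load
    tr = transforms or {}
    return SignatureModel(
        features=names,
        transforms=[tr.get(n, TransformSpec("identity")) for n in names],
        means=[float((means or {}).get(n, 0.0)) for n in names],
        sds=[float((sds or {}).get(n, 1.0)) for n in names],
        loadings=[float(v) for v in load],
    )


def build_signature(
    cohort: pd.DataFrame,
    feature_names: list[str],
    transforms: dict[str, TransformSpec] | None = None,
    response_col: str = "maf",
) -> SignatureModel:
    """Transform + z-score the named features of a cohort table, fit the
    first-PC signature, and store the training constants."""
    tr = transforms or {}
    cols, mu, sd = {}, {}, {}
    for n in feature_names:
        spec = tr.get(n, TransformSpec("identity"))
        t = apply_transform(cohort[n].to_numpy(dtype=float),
                            replace(spec, zscore=False), n)
        m, s = float(t.mean()), float(t.std(ddof=0)) or 1.0
        cols[n] = (t - m) / s
        mu[n], sd[n] = m, s
    Z = pd.DataFrame(cols)
    resp = np.abs(np.log(cohort[response_col].to_numpy(dtype=float)))
    return fit_pca_signature(Z, response=resp, transforms=tr, means=mu, sds=sd)


def evaluate_signature(model: SignatureModel, values) -> np.ndarray | float:
    """Evaluate sum_k w_k z(t_k(f_k)) using the stored constants.

    ``values`` may be a mapping feature -> scalar, or a DataFrame with one
    column per signature feature (vectorised).
    """
    scalar = isinstance(values, dict)
    if scalar:
        frame = pd.DataFrame({k: [v] for k, v in values.items()})
    else:
        frame = values
    missing = [f for f in model.features if f not in frame.columns]
    if missing:
        raise KeyError(f"missing signature feature(s): {', '.join(missing)}")
    total = np.zeros(len(frame))
    for name, spec, m, s, w in zip(
        model.features, model.transforms, model.means, model.sds, model.loadings
    ):
        t = apply_transform(frame[name].to_numpy(dtype=float),
                            replace(spec, zscore=False), name)
        total += w * (t - m) / s
    return float(total[0]) if scalar else total


def published_loadings_model() -> SignatureModel:
    """The study-style instance of the signature: five features ordered
    (Correlation, GLNUz, StdDev, LGRE, Coarseness) with display-rounded
    loadings and identity transforms/standardisation, so inputs are
    interpreted as already-standardised z-values (the form used in worked
    examples).  The display-rounded loading vector has norm ~0.9997 rather
    than exactly 1; it is kept verbatim."""
    return SignatureModel(
        features=["Correlation", "GLNUz", "StdDev", "LGRE", "Coarseness"],
        transforms=[TransformSpec("identity")] * 5,
        means=[0.0] * 5,
        sds=[1.0] * 5,
        loadings=[0.323, -0.528, 0.438, 0.383, 0.527],
    )
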