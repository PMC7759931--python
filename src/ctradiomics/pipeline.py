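"""End-to-end pipeline driver.

Chains the full analysis — (optionally) extract features from NIfTI pairs,
assemble the cohort, run both screens, select predictors, build the PCA
signature, run the Monte-Carlo null test, and fit the association triangle —
writing every artifact plus a manifest (seeds, config hash, versions) so a
run is reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import association_triangle
from .cohort import assemble_cohort
from .io import write_json, write_table
from .nulls import NullSimConfig, null_reference_test
from .screening import (TransformSpec, apply_transform,
                        default_transform_registry, detect_outliers_robust_cov,
                        screen_features)
from .selection import lasso_select, stepwise_r2
from .signature import build_signature, evaluate_signature, pick_top5
from .synthetic import (CohortSimConfig, generate_cohort, is_random_feature,
                        spike_random_features)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "ctradiomics_out"
    blood_csv: str | None = None     # if None, a synthetic cohort is simulated
    visits_csv: str | None = None
    features_csv: str | None = None
    sim: CohortSimConfig = field(default_factory=CohortSimConfig)
    fdr_level: float = 0.05
    n_random: int = 100
    n_null: int = 2500
    top_k: int = 5
    seed: int = 0


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(o):
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        return str(o)

    blob = json.dumps(asdict(cfg), sort_keys=True, default=enc)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage and return the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": [],
    }

    def _stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    # ---- cohort -----------------------------------------------------------
    _stage("assemble")
    if cfg.blood_csv and cfg.visits_csv and cfg.features_csv:
        blood = pd.read_csv(cfg.blood_csv)
        visits = pd.read_csv(cfg.visits_csv)
        features = pd.read_csv(cfg.features_csv)
        cohort = assemble_cohort(blood, visits, features)
    else:
        sim = cfg.sim
        sim.seed = cfg.seed
        cohort_raw, features, blood, _truth = generate_cohort(sim)
        visits = cohort_raw[["patient", "visit", "day", "volume_mm3"]]
        cohort = assemble_cohort(blood, visits, features)
        write_table(blood, out / "blood.csv")
    write_table(cohort, out / "cohort.csv")

    feat_cols = [
        c
        for c in cohort.columns
        if c not in {"patient", "visit", "day", "volume_mm3", "maf",
                     "maf_extrapolated", "ldh", "log_volume"}
    ]
    registry = default_transform_registry(feat_cols)

    # ---- screens ----------------------------------------------------------
    _stage("screen")
    unadj = screen_features(
        cohort, feat_cols, registry, n_random=cfg.n_random,
        fdr_level=cfg.fdr_level, adjust_volume=False, seed=cfg.seed,
    )
    write_table(unadj, out / "screen_unadjusted.csv")
    adj = screen_features(
        cohort, feat_cols, registry, n_random=cfg.n_random,
        fdr_level=cfg.fdr_level, adjust_volume=True, seed=cfg.seed + 1,
    )
    write_table(adj, out / "screen_volume_adjusted.csv")

    # ---- selection --------------------------------------------------------
    _stage("select")
    y = np.log(cohort["maf"].to_numpy(dtype=float))
    T = {}
    for c in feat_cols:
        t = apply_transform(cohort[c].to_numpy(dtype=float), registry[c], c)
        sd = t.std() or 1.0
        T[c] = (t - t.mean()) / sd
    X = pd.DataFrame(T)
    randoms = spike_random_features(
        n=len(feat_cols), icc=0.5, patient_ids=cohort["patient"], seed=cfg.seed + 2
    )
    rz = (randoms - randoms.mean()) / randoms.std(ddof=0)
    Xall = pd.concat([X, rz], axis=1)
    las = lasso_select(y, Xall, cohort["patient"])
    step = stepwise_r2(y, Xall, cohort["patient"])
    write_json({"lasso": las.to_dict(), "stepwise": step.to_dict()},
               out / "selection.json")

    # ---- outlier sensitivity ---------------------------------------------
    _stage("outliers")
    try:
        flags = detect_outliers_robust_cov(pd.concat(
            [pd.Series(y, name="log_maf"), X], axis=1))
        manifest["n_outliers_flagged"] = int(flags.sum())
    except ValueError as exc:
        manifest["n_outliers_flagged"] = None
        logger.warning("outlier step skipped: %s", exc)

    # ---- signature --------------------------------------------------------
    _stage("signature")
    top5 = pick_top5(adj, k=cfg.top_k)
    model = build_signature(cohort, top5, registry)
    (out / "signature.json").write_text(model.to_json())
    sig_vals = evaluate_signature(model, cohort)

    # ---- null test --------------------------------------------------------
    _stage("nulltest")
    ncfg = NullSimConfig(n_datasets=cfg.n_null, n_features=len(feat_cols),
                         top_k=cfg.top_k, seed=cfg.seed + 3)
    res = null_reference_test(cohort, X, ncfg, builder="five-features")
    write_table(res.scatter_frame(), out / "null_scatter.csv")
    write_json(
        {"builder": res.builder, "real_r2": res.real_r2, "real_lrt": res.real_lrt,
         "p_r2": res.p_r2, "p_lrt": res.p_lrt, "n_datasets": res.n_datasets},
        out / "null_summary.json",
    )

    # ---- association ------------------------------------------------------
    _stage("associate")
    report = association_triangle(cohort, sig_vals)
    write_json(
        {
            "r2": {k: v.r2 for k, v in report.pairs.items()},
            "chosen": {k: v.chosen for k, v in report.pairs.items()},
            "near_independent": {k: v.near_independent
                                 for k, v in report.pairs.items()},
            "n_ldh_above_uln": report.n_ldh_above_uln,
            "warnings": report.warnings,
        },
        out / "association.json",
    )

    write_json(manifest, out / "manifest.json")
    return out
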