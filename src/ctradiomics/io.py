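"""File I/O: NIfTI volume/mask pairs, cohort tables, and reports.

CSV is the interchange format for tables (dates ISO-8601, volumes in mm^3
internally), NIfTI for images, JSON for models and manifests.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .radiomics import VoxelVolume

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles


def read_nifti_pair(volume_path, mask_path) -> tuple[VoxelVolume, np.ndarray]:
    """Load a volume and its lesion mask; grids must match; mask values other
    than {0, 1} (e.g. 0/255 exports) are normalised with a warning."""
    vimg = nib.load(str(volume_path))
    mimg = nib.load(str(mask_path))
    vdata = np.asarray(vimg.get_fdata(), dtype=float)
    mdata = np.asarray(mimg.get_fdata())
    if vdata.shape != mdata.shape:
        raise ValueError(
            f"volume grid {vdata.shape} does not match mask grid {mdata.shape}"
        )
    spacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
    uniq = np.unique(mdata)
    if not np.all(np.isin(uniq, (0, 1))):
        logger.warning("mask values %s normalised to {0,1}", uniq[:5])
    mask = mdata > (mdata.max() / 2.0 if mdata.max() > 1 else 0.5)
    return VoxelVolume(vdata, spacing), mask


def write_nifti(data: np.ndarray, spacing, path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_table(path, date_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV, parsing ISO dates and reporting the offending row on
    failure."""
    df = pd.read_csv(path)
    for col in date_cols:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except ValueError:
            parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
            bad = int(np.argmax(parsed.isna().to_numpy()))
            raise ValueError(
                f"{path}: malformed date {df[col].iloc[bad]!r} in row {bad}"
            ) from None
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
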