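"""3D radiomic feature extraction from masked CT volumes.

The extraction dialect follows the absolute-bound, LIFEx-style configuration:
intensities are re-binned into 128 gray levels over a fixed [-400, 400] HU
range (32 levels for zone features, per IBSI recommendations for that family),
after resampling to 1 mm isotropic voxels.  Texture statistics are computed
from four matrix summaries of the discretised lesion:

* GLCM  - gray-level co-occurrence at distance 1 over the 13 unique 3D
          directions, symmetrised and pooled into one normalised matrix;
* GLRLM - gray-level run lengths pooled across the same 13 directions;
* GLZLM - gray-level zone sizes from 26-connected components of equal level;
* NGLDM - per-voxel absolute difference from the mean of the in-mask
          26-neighbourhood, accumulated per gray level.

Degenerate cases are handled explicitly: GLCM Correlation is undefined (NaN)
when only one gray level is occupied, and NGLDM Coarseness is capped at 1e6
when the neighbourhood differences sum to zero (a perfectly flat lesion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

COARSENESS_CAP = 1e6

# 13 unique displacement directions covering the 26-neighbourhood (d, -d pairs)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelVolume:
    """A 3D intensity grid (HU) with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DiscretizationSpec:
    """Absolute-bound gray-level binning (bin 1 at ``lo``; ``hi`` clips into
    the top bin)."""

    n_bins: int = 128
    lo: float = -400.0
    hi: float = 400.0

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError("hi must exceed lo")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_bins


SPEC_128 = DiscretizationSpec(128)
SPEC_32 = DiscretizationSpec(32)


@dataclass
class ExtractionConfig:
    spec: DiscretizationSpec = field(default_factory=lambda: DiscretizationSpec(128))
    zone_spec: DiscretizationSpec = field(default_factory=lambda: DiscretizationSpec(32))
    resample_mm: float | None = 1.0
    min_volume_ml: float = 1.0
    allow_small: bool = False


#: canonical 39-feature panel; the computed superset additionally carries
#: Min and Max with an inclusion flag of False
DEFAULT_FEATURES: tuple[str, ...] = (
    # histogram & shape
    "Mean", "StdDev", "Skewness", "Kurtosis", "Entropy_h", "Uniformity",
    "Volume", "Sphericity",
    # GLCM
    "Homogeneity", "Energy", "Contrast", "Correlation", "Entropy",
    "Dissimilarity",
    # GLRLM
    "SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
    "GLNUr", "RLNU", "RP",
    # NGLDM
    "Coarseness", "Busyness", "NGLDM_Contrast",
    # GLZLM
    "SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
    "GLNUz", "ZLNU", "ZP",
)

EXTRA_FEATURES: tuple[str, ...] = ("Min", "Max")

_SHAPE_FEATURES = frozenset({"Volume", "Sphericity"})


@dataclass
class FeatureVector:
    """Named feature values plus extraction provenance."""

    values: dict[str, float]
    provenance: dict

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self, default_only: bool = True) -> pd.Series:
        names = DEFAULT_FEATURES if default_only else DEFAULT_FEATURES + EXTRA_FEATURES
        return pd.Series({n: self.values[n] for n in names})


# ---------------------------------------------------------------------------
# geometry: resampling and discretisation
# ---------------------------------------------------------------------------

def resample_isotropic(
    volume: VoxelVolume, mask: np.ndarray, target: float = 1.0
) -> tuple[VoxelVolume, np.ndarray]:
    """Resample intensities (trilinear) and mask (trilinear + 0.5 threshold)
    to isotropic voxels of ``target`` mm."""
    if any(s <= 0 for s in volume.spacing):
        raise ValueError("voxel spacing must be positive on all axes")
    zoom = tuple(s / target for s in volume.spacing)
    if all(abs(z - 1.0) < 1e-12 for z in zoom):
        return VoxelVolume(volume.data.copy(), (target,) * 3), mask.astype(bool).copy()
    # grid_mode aligns cell edges (not centre-to-centre), preserving the
    # physical extent of the grid; nearest-neighbour for the mask keeps it
    # binary and carries the physical mask volume through unchanged
    data = ndimage.zoom(volume.data, zoom, order=1, mode="nearest", grid_mode=True)
    m = ndimage.zoom(mask.astype(float), zoom, order=0, mode="grid-constant",
                     cval=0.0, grid_mode=True)
    out_mask = m >= 0.5
    if not out_mask.any():
        raise ValueError("mask vanished during resampling (extreme anisotropy)")
    return VoxelVolume(data, (target,) * 3), out_mask


def discretize(
    volume: VoxelVolume | np.ndarray,
    mask: np.ndarray,
    spec: DiscretizationSpec,
) -> np.ndarray:
    """Integer gray-level labels 1..n_bins inside the mask, 0 outside.

    bin(v) = floor((v - lo) / width) + 1, clipped to [1, n_bins]; out-of-range
    intensities clip to the edge bins and v = hi maps to n_bins.
    """
    data = volume.data if isinstance(volume, VoxelVolume) else np.asarray(volume, float)
    raw = np.floor((data - spec.lo) / spec.width).astype(np.int64) + 1
    labels = np.clip(raw, 1, spec.n_bins)
    labels[~mask.astype(bool)] = 0
    return labels


# ---------------------------------------------------------------------------
# histogram & shape
# ---------------------------------------------------------------------------

def _surface_area(mask: np.ndarray, spacing) -> float:
    """Total exposed voxel-face area in mm^2 (no meshing; approximate)."""
    m = mask.astype(bool)
    face_areas = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    total = 0.0
    for axis, a in enumerate(face_areas):
        for shift in (1, -1):
            nb = np.roll(m, shift, axis=axis)
            # faces at the array border are always exposed
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            nb[tuple(sl)] = False
            total += a * np.count_nonzero(m & ~nb)
    return total


def histogram_shape_features(
    volume: VoxelVolume,
    mask: np.ndarray,
    spec: DiscretizationSpec = SPEC_128,
) -> dict[str, float]:
    mask = mask.astype(bool)
    vals = volume.data[mask]
    if vals.size < 2:
        raise ValueError("empty mask (need at least 2 in-mask voxels)")
    sd = float(vals.std(ddof=0))
    if sd > 0:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals, fisher=False))
    else:
        skew, kurt = 0.0, 0.0
    labels = discretize(volume, mask, spec)
    counts = np.bincount(labels[mask], minlength=spec.n_bins + 1)[1:]
    p = counts[counts > 0] / vals.size
    entropy_h = float(-(p * np.log(p)).sum())
    uniformity = float((p**2).sum())
    vol_mm3 = vals.size * volume.voxel_volume_mm3
    area = _surface_area(mask, volume.spacing)
    sphericity = math.pi ** (1 / 3) * (6.0 * vol_mm3) ** (2 / 3) / area
    return {
        "Mean": float(vals.mean()),
        "StdDev": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Entropy_h": entropy_h,
        "Uniformity": uniformity,
        "Min": float(vals.min()),
        "Max": float(vals.max()),
        "Volume": vol_mm3 / 1000.0,  # mL
        "Sphericity": float(sphericity),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    directions=DIRECTIONS_3D,
) -> np.ndarray:
    """Symmetrised co-occurrence counts pooled over ``directions``."""
    mask = labels > 0 if mask is None else (mask.astype(bool) & (labels > 0))
    L = int(labels.max())
    if L == 0:
        raise ValueError("empty mask")
    M = np.zeros((L + 1, L + 1))
    for d in directions:
        sl_a, sl_b = [], []
        ok = True
        for ax, step in enumerate(d):
            n = labels.shape[ax]
            if abs(step) >= n:
                ok = False
                break
            if step >= 0:
                sl_a.append(slice(0, n - step))
                sl_b.append(slice(step, n))
            else:
                sl_a.append(slice(-step, n))
                sl_b.append(slice(0, n + step))
        if not ok:
            continue
        a = labels[tuple(sl_a)]
        b = labels[tuple(sl_b)]
        valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        ai, bi = a[valid], b[valid]
        np.add.at(M, (ai, bi), 1.0)
        np.add.at(M, (bi, ai), 1.0)
    return M[1:, 1:]


def glcm_features(
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    directions=DIRECTIONS_3D,
) -> dict[str, float]:
    M = glcm_matrix(labels, mask, directions)
    total = M.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs inside the mask")
    P = M / total
    L = P.shape[0]
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = P.sum(axis=1)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    nz = P > 0
    entropy = float(-(P[nz] * np.log(P[nz])).sum())
    diff = np.abs(ii - jj)
    out = {
        "Homogeneity": float((P / (1.0 + diff)).sum()),
        "Energy": float((P**2).sum()),
        "Contrast": float((P * (ii - jj) ** 2).sum()),
        "Dissimilarity": float((P * diff).sum()),
        "Entropy": entropy,
    }
    if var > 0:
        out["Correlation"] = float(((ii - mu) * (jj - mu) * P).sum() / var)
    else:
        out["Correlation"] = float("nan")  # single occupied gray level
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    directions=DIRECTIONS_3D,
) -> np.ndarray:
    """Run counts r[level, length] pooled over directions.

    Out-of-mask voxels break runs; every in-mask voxel belongs to exactly one
    run per direction, so per direction sum(length * count) equals the number
    of in-mask voxels.
    """
    lab = labels.copy()
    if mask is not None:
        lab = np.where(mask.astype(bool), lab, 0)
    nvox = int(np.count_nonzero(lab))
    if nvox == 0:
        raise ValueError("empty mask")
    L = int(lab.max())
    max_len = max(lab.shape)
    R = np.zeros((L + 1, max_len + 1))
    shape = lab.shape
    coords = np.argwhere(lab > 0)
    vals_at = lab[tuple(coords.T)]
    for d in directions:
        dv = np.asarray(d)
        prev = coords - dv
        inside = np.all((prev >= 0) & (prev < shape), axis=1)
        prev_label = np.zeros(len(coords), dtype=lab.dtype)
        prev_label[inside] = lab[tuple(prev[inside].T)]
        is_start = prev_label != vals_at
        pos = coords[is_start]
        lev = vals_at[is_start]
        length = np.ones(len(pos), dtype=np.int64)
        while len(pos):
            nxt = pos + dv
            inside = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(len(pos), dtype=bool)
            if inside.any():
                cont[inside] = lab[tuple(nxt[inside].T)] == lev[inside]
            done = ~cont
            if done.any():
                np.add.at(R, (lev[done], length[done]), 1.0)
            pos = nxt[cont]
            lev = lev[cont]
            length = length[cont] + 1
    return R[1:, 1:]


def glrlm_features(
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    directions=DIRECTIONS_3D,
) -> dict[str, float]:
    lab = labels if mask is None else np.where(mask.astype(bool), labels, 0)
    R = glrlm_matrix(lab, None, directions)
    Nr = R.sum()
    nvox = int(np.count_nonzero(lab))
    i = np.arange(1, R.shape[0] + 1, dtype=float)[:, None]  # gray level
    j = np.arange(1, R.shape[1] + 1, dtype=float)[None, :]  # run length
    return {
        "SRE": float((R / j**2).sum() / Nr),
        "LRE": float((R * j**2).sum() / Nr),
        "LGRE": float((R / i**2).sum() / Nr),
        "HGRE": float((R * i**2).sum() / Nr),
        "SRLGE": float((R / (i**2 * j**2)).sum() / Nr),
        "SRHGE": float((R * i**2 / j**2).sum() / Nr),
        "LRLGE": float((R * j**2 / i**2).sum() / Nr),
        "LRHGE": float((R * i**2 * j**2).sum() / Nr),
        "GLNUr": float((R.sum(axis=1) ** 2).sum() / Nr),
        "RLNU": float((R.sum(axis=0) ** 2).sum() / Nr),
        "RP": float(Nr / (len(directions) * nvox)),
    }


# ---------------------------------------------------------------------------
# GLZLM
# ---------------------------------------------------------------------------

def glzlm_matrix(labels32: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Zone counts z[level, size]; zones are 26-connected components of equal
    gray level."""
    lab = labels32 if mask is None else np.where(mask.astype(bool), labels32, 0)
    nvox = int(np.count_nonzero(lab))
    if nvox == 0:
        raise ValueError("empty mask")
    L = int(lab.max())
    Z = np.zeros((L + 1, nvox + 1))
    for lev in np.unique(lab[lab > 0]):
        comp, ncomp = ndimage.label(lab == lev, structure=_STRUCT_26)
        if ncomp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        np.add.at(Z, (int(lev), sizes), 1.0)
    return Z[1:, 1:]


def glzlm_features(labels32: np.ndarray, mask: np.ndarray | None = None) -> dict[str, float]:
    lab = labels32 if mask is None else np.where(mask.astype(bool), labels32, 0)
    Z = glzlm_matrix(lab, None)
    Nz = Z.sum()
    nvox = int(np.count_nonzero(lab))
    i = np.arange(1, Z.shape[0] + 1, dtype=float)[:, None]  # gray level
    s = np.arange(1, Z.shape[1] + 1, dtype=float)[None, :]  # zone size
    return {
        "SZE": float((Z / s**2).sum() / Nz),
        "LZE": float((Z * s**2).sum() / Nz),
        "LGZE": float((Z / i**2).sum() / Nz),
        "HGZE": float((Z * i**2).sum() / Nz),
        "SZLGE": float((Z / (i**2 * s**2)).sum() / Nz),
        "SZHGE": float((Z * i**2 / s**2).sum() / Nz),
        "LZLGE": float((Z * s**2 / i**2).sum() / Nz),
        "LZHGE": float((Z * i**2 * s**2).sum() / Nz),
        "GLNUz": float((Z.sum(axis=1) ** 2).sum() / Nz),
        "ZLNU": float((Z.sum(axis=0) ** 2).sum() / Nz),
        "ZP": float(Nz / nvox),
    }


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

def ngldm_features(labels: np.ndarray, mask: np.ndarray | None = None) -> dict[str, float]:
    """Coarseness, Busyness and (NGLDM) Contrast from per-voxel absolute
    differences to the mean of the in-mask 26-neighbourhood."""
    lab = labels if mask is None else np.where(mask.astype(bool), labels, 0)
    m = lab > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(lab.astype(float) * m, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(m.astype(float), kernel, mode="constant", cval=0.0)
    valid = m & (nb_cnt > 0)
    if not valid.any():
        raise ValueError("no in-mask voxel has an in-mask neighbour")
    a = np.abs(lab[valid] - nb_sum[valid] / nb_cnt[valid])
    lev = lab[valid]
    L = int(lab.max())
    s = np.bincount(lev, weights=a, minlength=L + 1)[1:]
    n_i = np.bincount(lev, minlength=L + 1)[1:]
    n = int(valid.sum())
    p = n_i / n
    occ = n_i > 0
    Ng = int(occ.sum())
    denom_coarse = float((p * s).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)
    i = np.arange(1, L + 1, dtype=float)
    if Ng > 1:
        pi = p[occ]
        ii = i[occ]
        dmat = (ii[:, None] - ii[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * dmat).sum() / (Ng * (Ng - 1)) * (s.sum() / n)
        )
        busy_den = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
        busyness = float((p * s).sum() / busy_den) if busy_den > 0 else float("nan")
    else:
        contrast = 0.0
        busyness = float("nan")
    return {"Coarseness": float(coarseness), "Busyness": busyness,
            "NGLDM_Contrast": contrast}


# ---------------------------------------------------------------------------
# whole-lesion extraction and feature maps
# ---------------------------------------------------------------------------

def _region_features(
    volume: VoxelVolume,
    mask: np.ndarray,
    spec: DiscretizationSpec,
    zone_spec: DiscretizationSpec,
) -> dict[str, float]:
    feats = histogram_shape_features(volume, mask, spec)
    labels = discretize(volume, mask, spec)
    feats.update(glcm_features(labels, mask))
    feats.update(glrlm_features(labels, mask))
    feats.update(ngldm_features(labels, mask))
    labels32 = discretize(volume, mask, zone_spec)
    feats.update(glzlm_features(labels32, mask))
    return feats


def extract_all(
    volume: VoxelVolume,
    mask: np.ndarray,
    config: ExtractionConfig | None = None,
) -> FeatureVector:
    """Resample, discretise (128 and 32 levels) and extract the full panel.

    Lesions under the minimum-volume rule (default 1 cm^3, measured before
    resampling) are rejected unless ``config.allow_small`` is set.
    """
    cfg = config or ExtractionConfig()
    mask = mask.astype(bool)
    vol_ml = np.count_nonzero(mask) * volume.voxel_volume_mm3 / 1000.0
    if vol_ml < cfg.min_volume_ml and not cfg.allow_small:
        raise ValueError(
            f"lesion volume {vol_ml:.3f} mL is below the "
            f"{cfg.min_volume_ml:g} cm^3 inclusion threshold"
        )
    if cfg.resample_mm is not None:
        volume, mask = resample_isotropic(volume, mask, cfg.resample_mm)
    values = _region_features(volume, mask, cfg.spec, cfg.zone_spec)
    prov = {
        "n_bins": cfg.spec.n_bins,
        "zone_bins": cfg.zone_spec.n_bins,
        "range_hu": (cfg.spec.lo, cfg.spec.hi),
        "resample_mm": cfg.resample_mm,
        "volume_ml_pre_resample": vol_ml,
        "included": {n: True for n in DEFAULT_FEATURES}
        | {n: False for n in EXTRA_FEATURES},
    }
    return FeatureVector(values=values, provenance=prov)


def feature_map(
    volume: VoxelVolume,
    mask: np.ndarray,
    feature: str,
    radius: int = 1,
    spec: DiscretizationSpec = SPEC_128,
    zone_spec: DiscretizationSpec = SPEC_32,
) -> np.ndarray:
    """Sliding-window per-voxel feature map (window radius in voxels).

    Each in-mask voxel receives the feature computed on its (2r+1)^3 window
    intersected with the mask; windows with fewer than two in-mask voxels map
    to NaN.  Shape features are not mappable.
    """
    if feature in _SHAPE_FEATURES:
        raise ValueError(f"{feature} is a shape feature and not mappable")
    if feature not in DEFAULT_FEATURES + EXTRA_FEATURES:
        raise KeyError(f"unknown feature {feature!r}")
    mask = mask.astype(bool)
    out = np.full(volume.data.shape, np.nan)
    r = int(radius)
    for idx in np.argwhere(mask):
        sl = tuple(
            slice(max(c - r, 0), min(c + r + 1, volume.data.shape[ax]))
            for ax, c in enumerate(idx)
        )
        sub_mask = mask[sl]
        if np.count_nonzero(sub_mask) < 2:
            continue
        sub = VoxelVolume(volume.data[sl], volume.spacing)
        try:
            vals = _region_features(sub, sub_mask, spec, zone_spec)
            out[tuple(idx)] = vals[feature]
        except ValueError:
            pass  # degenerate window stays NaN
    return out


def select_largest_lesion(volumes: pd.DataFrame) -> object:
    """Pick the lesion to track: greatest volume at any visit.

    ``volumes`` is a long table with columns ``lesion``, ``visit`` (sortable)
    and ``volume``.  Ties on the maximum volume are broken by earliest
    attainment, then by lowest lesion id.
    """
    if volumes is None or len(volumes) == 0:
        raise ValueError("no lesion volume records supplied")
    df = volumes.sort_values(["visit", "lesion"]).reset_index(drop=True)
    vmax = df["volume"].max()
    hits = df[df["volume"] == vmax]
    return hits.iloc[0]["lesion"]
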