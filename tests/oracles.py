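"""Independent brute-force oracles for texture features.

Everything here is implemented with plain Python loops and explicit
enumeration (voxel pairs, run walks, flood-filled zones, neighbourhood
scans), deliberately sharing no code with the package implementation, so
equality between the two is a meaningful check.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
DIRS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(idx, shape):
    return all(0 <= idx[a] < shape[a] for a in range(3))


def oracle_glcm(labels, mask, directions=DIRS_13):
    """Pair enumeration -> symmetric normalised co-occurrence -> features."""
    shape = labels.shape
    counts = defaultdict(float)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for d in directions:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(q, shape) and mask[q]:
                        i, j = int(labels[x, y, z]), int(labels[q])
                        counts[(i, j)] += 1
                        counts[(j, i)] += 1
    total = sum(counts.values())
    assert total > 0
    p = {k: v / total for k, v in counts.items()}
    homog = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    energy = sum(v * v for v in p.values())
    contrast = sum(v * (i - j) ** 2 for (i, j), v in p.items())
    dissim = sum(v * abs(i - j) for (i, j), v in p.items())
    entropy = -sum(v * math.log(v) for v in p.values() if v > 0)
    pi = defaultdict(float)
    for (i, _j), v in p.items():
        pi[i] += v
    mu = sum(i * v for i, v in pi.items())
    var = sum((i - mu) ** 2 * v for i, v in pi.items())
    if var > 0:
        corr = sum((i - mu) * (j - mu) * v for (i, j), v in p.items()) / var
    else:
        corr = float("nan")
    return {
        "Homogeneity": homog,
        "Energy": energy,
        "Contrast": contrast,
        "Dissimilarity": dissim,
        "Entropy": entropy,
        "Correlation": corr,
    }


def oracle_glrlm(labels, mask, directions=DIRS_13):
    """Walk every maximal run of equal labels along each direction."""
    shape = labels.shape
    runs = defaultdict(float)  # (level, length) -> count
    nvox = int(np.count_nonzero(mask))
    for d in directions:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not mask[x, y, z]:
                        continue
                    lev = int(labels[x, y, z])
                    prev = (x - d[0], y - d[1], z - d[2])
                    if (
                        _inside(prev, shape)
                        and mask[prev]
                        and int(labels[prev]) == lev
                    ):
                        continue  # not a run start
                    length = 1
                    cur = (x + d[0], y + d[1], z + d[2])
                    while _inside(cur, shape) and mask[cur] and int(labels[cur]) == lev:
                        length += 1
                        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    runs[(lev, length)] += 1
    Nr = sum(runs.values())
    out = {
        "SRE": sum(c / j**2 for (_i, j), c in runs.items()) / Nr,
        "LRE": sum(c * j**2 for (_i, j), c in runs.items()) / Nr,
        "LGRE": sum(c / i**2 for (i, _j), c in runs.items()) / Nr,
        "HGRE": sum(c * i**2 for (i, _j), c in runs.items()) / Nr,
        "SRLGE": sum(c / (i**2 * j**2) for (i, j), c in runs.items()) / Nr,
        "SRHGE": sum(c * i**2 / j**2 for (i, j), c in runs.items()) / Nr,
        "LRLGE": sum(c * j**2 / i**2 for (i, j), c in runs.items()) / Nr,
        "LRHGE": sum(c * i**2 * j**2 for (i, j), c in runs.items()) / Nr,
        "RP": Nr / (len(directions) * nvox),
    }
    by_level = defaultdict(float)
    by_length = defaultdict(float)
    for (i, j), c in runs.items():
        by_level[i] += c
        by_length[j] += c
    out["GLNUr"] = sum(v**2 for v in by_level.values()) / Nr
    out["RLNU"] = sum(v**2 for v in by_length.values()) / Nr
    out["_voxel_conservation"] = {
        "total_run_voxels": sum(j * c for (_i, j), c in runs.items()),
        "expected": len(directions) * nvox,
    }
    return out


def oracle_glzlm(labels, mask):
    """Flood-fill (BFS, 26-connected) zones of equal label -> features."""
    shape = labels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = defaultdict(float)  # (level, size) -> count
    nvox = int(np.count_nonzero(mask))
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                lev = int(labels[x, y, z])
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    c = stack.pop()
                    size += 1
                    for d in DIRS_26:
                        q = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
                        if (
                            _inside(q, shape)
                            and mask[q]
                            and not seen[q]
                            and int(labels[q]) == lev
                        ):
                            seen[q] = True
                            stack.append(q)
                zones[(lev, size)] += 1
    Nz = sum(zones.values())
    out = {
        "SZE": sum(c / s**2 for (_i, s), c in zones.items()) / Nz,
        "LZE": sum(c * s**2 for (_i, s), c in zones.items()) / Nz,
        "LGZE": sum(c / i**2 for (i, _s), c in zones.items()) / Nz,
        "HGZE": sum(c * i**2 for (i, _s), c in zones.items()) / Nz,
        "SZLGE": sum(c / (i**2 * s**2) for (i, s), c in zones.items()) / Nz,
        "SZHGE": sum(c * i**2 / s**2 for (i, s), c in zones.items()) / Nz,
        "LZLGE": sum(c * s**2 / i**2 for (i, s), c in zones.items()) / Nz,
        "LZHGE": sum(c * i**2 * s**2 for (i, s), c in zones.items()) / Nz,
        "ZP": Nz / nvox,
    }
    by_level = defaultdict(float)
    by_size = defaultdict(float)
    for (i, s), c in zones.items():
        by_level[i] += c
        by_size[s] += c
    out["GLNUz"] = sum(v**2 for v in by_level.values()) / Nz
    out["ZLNU"] = sum(v**2 for v in by_size.values()) / Nz
    out["_voxel_conservation"] = {
        "total_zone_voxels": sum(s * c for (_i, s), c in zones.items()),
        "expected": nvox,
    }
    return out


def oracle_ngldm(labels, mask):
    """Neighbourhood scan: |level - mean(in-mask 26-neighbours)| per voxel."""
    shape = labels.shape
    s_i = defaultdict(float)
    n_i = defaultdict(int)
    n = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                neigh = []
                for d in DIRS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(q, shape) and mask[q]:
                        neigh.append(int(labels[q]))
                if not neigh:
                    continue
                lev = int(labels[x, y, z])
                s_i[lev] += abs(lev - sum(neigh) / len(neigh))
                n_i[lev] += 1
                n += 1
    assert n > 0
    p = {i: c / n for i, c in n_i.items()}
    levels = sorted(p)
    Ng = len(levels)
    denom = sum(p[i] * s_i[i] for i in levels)
    coarseness = min(1.0 / denom, 1e6) if denom > 0 else 1e6
    if Ng > 1:
        contrast = (
            sum(
                p[i] * p[j] * (i - j) ** 2
                for i in levels
                for j in levels
            )
            / (Ng * (Ng - 1))
            * (sum(s_i.values()) / n)
        )
        busy_den = sum(
            abs(i * p[i] - j * p[j]) for i in levels for j in levels
        )
        busyness = denom / busy_den if busy_den > 0 else float("nan")
    else:
        contrast = 0.0
        busyness = float("nan")
    return {
        "Coarseness": coarseness,
        "Busyness": busyness,
        "NGLDM_Contrast": contrast,
    }


def ols_fit(y, X):
    """Closed-form ordinary least squares (the zero-ICC limit of the MLM)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n, p = X.shape
    s2 = resid @ resid / (n - p)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov)), s2


def ccc_formula(x, y):
    """Lin's CCC from the definition, 1/n moments throughout."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx2 = sum((a - mx) ** 2 for a in x) / n
    sy2 = sum((b - my) ** 2 for b in y) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)
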