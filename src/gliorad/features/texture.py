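"""Gray-level co-occurrence and run-length texture features.

Both matrix families are computed over the in-mask voxels of a discretized
ROI along the 13 unique (antipodal-collapsed) directions of the 3D
26-neighborhood, then aggregated to a mean and a standard deviation across
directions. GLCM matrices are symmetric and normalized; offsets are
``distance x direction`` in voxel steps, so on the 1 mm isotropic analysis
grid a distance is also millimetres. GLRLM runs are maximal in-mask
sequences of a constant gray level along a direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .names import GLCM_FEATURES, GLRLM_FEATURES

__all__ = [
    "DIRECTIONS_13",
    "DiscretizedRoi",
    "discretize",
    "glcm_matrix",
    "glcm_matrix_features",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_matrix_features",
    "glrlm_features",
]

# Unique antipodal representatives of the 26-neighborhood offsets.
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass
class DiscretizedRoi:
    """Integer gray levels 1..n_bins for in-mask voxels (0 elsewhere)."""

    levels: np.ndarray  # int array, 0 outside mask
    bin_edges: np.ndarray
    n_bins: int
    degenerate: bool = False  # constant input collapsed to one level

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(values: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> DiscretizedRoi:
    """Equal-width binning of in-mask intensities into levels 1..n_bins.

    The maximum value is assigned bin ``n_bins``; a constant input maps
    everything to level 1 and is flagged degenerate.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    mask = np.asarray(mask) > 0.5
    if not mask.any():
        raise ValueError("empty mask")
    v = np.asarray(values, dtype=float)
    vmin = v[mask].min()
    vmax = v[mask].max()
    levels = np.zeros(v.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask] = 1
        edges = np.array([vmin, vmin + 1.0])
        return DiscretizedRoi(levels, edges, n_bins, degenerate=True)
    width = (vmax - vmin) / n_bins
    lev = np.floor((v[mask] - vmin) / width).astype(np.int32) + 1
    levels[mask] = np.clip(lev, 1, n_bins)
    edges = vmin + width * np.arange(n_bins + 1)
    return DiscretizedRoi(levels, edges, n_bins)


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(roi: DiscretizedRoi, offset: tuple[int, int, int]) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix at a voxel offset.

    Returns None when the offset yields no in-mask voxel pairs.
    """
    lev = roi.levels
    n = roi.n_bins
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, o in enumerate(offset):
        if o > 0:
            src[ax] = slice(0, lev.shape[ax] - o)
            dst[ax] = slice(o, lev.shape[ax])
        elif o < 0:
            src[ax] = slice(-o, lev.shape[ax])
            dst[ax] = slice(0, lev.shape[ax] + o)
    a = lev[tuple(src)]
    b = lev[tuple(dst)]
    both = (a > 0) & (b > 0)
    if not both.any():
        return None
    pairs = a[both].astype(np.int64) * (n + 1) + b[both]
    counts = np.bincount(pairs, minlength=(n + 1) ** 2).reshape(n + 1, n + 1)[1:, 1:]
    counts = counts + counts.T  # symmetric: count both (i,j) and (j,i)
    return counts / counts.sum()


def glcm_matrix_features(p: np.ndarray) -> dict[str, float]:
    """The 22 Haralick-style features of one normalized symmetric GLCM."""
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    # diagonal-sum and diagonal-difference distributions
    psum = np.zeros(2 * n + 1)  # index k = i + j, 2..2n
    np.add.at(psum, (ii + jj).ravel(), p.ravel())
    pdiff = np.zeros(n)  # index k = |i - j|, 0..n-1
    np.add.at(pdiff, np.abs(ii - jj).ravel(), p.ravel())
    ks = np.arange(2 * n + 1)
    kd = np.arange(n)

    def ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    sum_avg = float((ks * psum).sum())
    diff_avg = float((kd * pdiff).sum())
    entropy = ent(p.ravel())
    hx = ent(px)
    pxy = np.outer(px, px)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxy[nz])))
    nz2 = pxy > 0
    hxy2 = float(-np.sum(pxy[nz2] * np.log2(pxy[nz2])))
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    off = ii != jj
    inv_var = float(np.sum(p[off] / (ii[off] - jj[off]) ** 2.0))
    corr = float(((ii * jj * p).sum() - mu * mu) / sigma2) if sigma2 > 0 else 0.0

    out = {
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_prominence": float((((ii + jj) - 2 * mu) ** 4 * p).sum()),
        "cluster_shade": float((((ii + jj) - 2 * mu) ** 3 * p).sum()),
        "cluster_tendency": float((((ii + jj) - 2 * mu) ** 2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": corr,
        "difference_entropy": ent(pdiff),
        "difference_variance": float(((kd - diff_avg) ** 2 * pdiff).sum()),
        "dissimilarity": diff_avg,
        "energy": float((p**2).sum()),
        "entropy": entropy,
        "sum_entropy": ent(psum),
        "sum_average": sum_avg,
        "sum_variance": float(((ks - sum_avg) ** 2 * psum).sum()),
        "homogeneity1": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "homogeneity2": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "imc1": imc1,
        "imc2": imc2,
        "idn": float((p / (1.0 + np.abs(ii - jj) / n)).sum()),
        "idmn": float((p / (1.0 + (ii - jj) ** 2 / n**2)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(p.max()),
    }
    assert tuple(out) == GLCM_FEATURES
    return out


def _aggregate(per_direction: list[dict[str, float]], feature_names) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for f in feature_names:
        vals = np.array([d[f] for d in per_direction])
        out[(f, "mean")] = float(vals.mean())
        out[(f, "std")] = float(vals.std())
    return out


def glcm_features(roi: DiscretizedRoi, distance: int) -> dict[tuple[str, str], float]:
    """Direction-aggregated GLCM features at one distance (voxel steps)."""
    if distance not in (1, 2, 3):
        raise ValueError("GLCM distance must be 1, 2 or 3")
    if roi.n_voxels < 2:
        raise ValueError("need at least 2 in-mask voxels for GLCM")
    per_dir = []
    for direction in DIRECTIONS_13:
        offset = tuple(distance * d for d in direction)
        p = glcm_matrix(roi, offset)
        if p is not None:
            per_dir.append(glcm_matrix_features(p))
    if not per_dir:
        raise ValueError(f"no direction yields voxel pairs at distance {distance}")
    return _aggregate(per_dir, GLCM_FEATURES)


# ---------------------------------------------------------------------------
# GLRLM


def _runs_along_direction(levels: np.ndarray, direction: tuple[int, int, int]):
    """All maximal constant-level runs along one direction.

    Voxels are grouped into lattice lines via cross-product invariants of
    their integer coordinates with the direction vector, ordered along each
    line by the dot product, and runs are cut where the line, the level, or
    the position step changes. Runs of level 0 (outside the mask) are
    dropped. Returns ``(levels_of_runs, lengths_of_runs)``.
    """
    dx, dy, dz = direction
    idx = np.argwhere(levels >= 0)  # every voxel of the (cropped) block
    x, y, z = idx[:, 0], idx[:, 1], idx[:, 2]
    # line identity: p x d is constant along the line p + t*d
    k1 = y * dz - z * dy
    k2 = z * dx - x * dz
    k3 = x * dy - y * dx
    pos = x * dx + y * dy + z * dz
    order = np.lexsort((pos, k3, k2, k1))
    vals = levels[x[order], y[order], z[order]]
    step = dx * dx + dy * dy + dz * dz
    same_line = (np.diff(k1[order]) == 0) & (np.diff(k2[order]) == 0) & (np.diff(k3[order]) == 0)
    contiguous = np.diff(pos[order]) == step
    same_val = np.diff(vals) == 0
    # a new run starts wherever continuity or value breaks
    breaks = np.concatenate(([True], ~(same_line & contiguous & same_val)))
    run_id = np.cumsum(breaks) - 1
    lengths = np.bincount(run_id)
    run_levels = vals[breaks]
    keep = run_levels > 0
    return run_levels[keep], lengths[keep]


def glrlm_matrix(roi: DiscretizedRoi, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix r(g, l), shape (n_bins, max_len)."""
    g, l = _runs_along_direction(roi.levels, direction)
    if g.size == 0:
        return np.zeros((roi.n_bins, 1))
    max_len = int(l.max())
    r = np.zeros((roi.n_bins, max_len))
    np.add.at(r, (g - 1, l - 1), 1.0)
    return r


def glrlm_matrix_features(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 15 features of one run-length matrix."""
    nr = r.sum()
    if nr == 0:
        raise ValueError("empty run-length matrix")
    p = r / nr
    ng, nl = r.shape
    g = np.arange(1, ng + 1)[:, None].astype(float)
    l = np.arange(1, nl + 1)[None, :].astype(float)
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    gv = np.arange(1, ng + 1).astype(float)
    lv = np.arange(1, nl + 1).astype(float)
    mu_g = float((gv * pg).sum())
    mu_l = float((lv * pl).sum())
    pz = p[p > 0]
    # voxel-weighted run-length distribution (each run weighted by its length)
    w = lv * pl
    w = w / w.sum()
    mu_wl = float((lv * w).sum())
    out = {
        "sre": float((p / l**2).sum()),
        "lre": float((p * l**2).sum()),
        "gln": float(((r.sum(axis=1)) ** 2).sum() / nr),
        "rln": float(((r.sum(axis=0)) ** 2).sum() / nr),
        "rp": float(nr / n_voxels),
        "glv": float((((gv - mu_g) ** 2) * pg).sum()),
        "rlv": float((((lv - mu_l) ** 2) * pl).sum()),
        "run_entropy": float(-np.sum(pz * np.log2(pz))),
        "lgre": float((p / g**2).sum()),
        "hgre": float((p * g**2).sum()),
        "srlge": float((p / (g**2 * l**2)).sum()),
        "srhge": float((p * g**2 / l**2).sum()),
        "lrlge": float((p * l**2 / g**2).sum()),
        "lrhge": float((p * g**2 * l**2).sum()),
        "run_variance_by_length": float((((lv - mu_wl) ** 2) * w).sum()),
    }
    assert tuple(out) == GLRLM_FEATURES
    return out


def glrlm_features(roi: DiscretizedRoi) -> dict[tuple[str, str], float]:
    """Direction-aggregated GLRLM features over the 13 directions."""
    if roi.n_voxels < 1:
        raise ValueError("empty ROI")
    per_dir = [
        glrlm_matrix_features(glrlm_matrix(roi, direction), roi.n_voxels)
        for direction in DIRECTIONS_13
    ]
    return _aggregate(per_dir, GLRLM_FEATURES)
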