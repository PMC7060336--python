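"""Shape and volume features of a binary tumor mask."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .names import SHAPE_FEATURES

__all__ = ["shape_features"]


def _surface_area(mask: np.ndarray, spacing) -> float:
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def _max_diameter(mask: np.ndarray, spacing) -> float:
    """Largest center-to-center distance between mask voxels (mm)."""
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary) * np.asarray(spacing)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 12:
        try:  # pairwise distances only over hull vertices
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    return float(pdist(pts).max())


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """The 7 mask-derived features.

    Volume is voxel count times voxel volume; surface area comes from a
    marching-cubes mesh of the (padded) mask. Sphericity and the two
    compactness variants measure how close the region is to a ball:
    ``sphericity = pi^(1/3) (6V)^(2/3) / A``, ``compactness1 =
    V / (sqrt(pi) A^(3/2))``, ``compactness2 = 36 pi V^2 / A^3``.
    """
    mask = np.asarray(mask) > 0.5
    if not mask.any():
        raise ValueError("empty mask has no shape features")
    spacing = tuple(float(s) for s in spacing)
    volume = float(mask.sum() * np.prod(spacing))
    area = _surface_area(mask, spacing)
    out = {
        "volume": volume,
        "surface_area": area,
        "surface_to_volume_ratio": area / volume,
        "sphericity": float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area),
        "compactness1": float(volume / (np.sqrt(np.pi) * area ** 1.5)),
        "compactness2": float(36 * np.pi * volume**2 / area**3),
        "max_3d_diameter": _max_diameter(mask, spacing),
    }
    assert tuple(out) == SHAPE_FEATURES
    return out
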