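"""2D shape and size descriptors of the segmented lesion."""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = ["shape_features"]


def _perimeter_mm(mask: np.ndarray, spacing: tuple[float, float]) -> float:
    """Contour length via marching squares at the 0.5 iso-level."""
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        scaled = contour * np.asarray(spacing)
        total += float(np.sqrt((np.diff(scaled, axis=0) ** 2).sum(axis=1)).sum())
    return total


def shape_features(mask: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0),
                   prefix: str = "shape") -> dict[str, float]:
    """Area (mm^2), perimeter (mm), circularity, and maximum diameter (mm).

    Circularity is 4*pi*A/P^2 (1 for a perfect disk; the marching-squares
    perimeter is biased short on very small ROIs, so tiny lesions can
    exceed 1).  Maximum diameter is the largest pairwise distance between
    voxel centers, hence 0 for a single voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("shape features require a non-empty 2D mask")
    dy, dx = spacing
    area = float(mask.sum()) * dy * dx
    perimeter = _perimeter_mm(mask, spacing)
    circularity = 4.0 * math.pi * area / perimeter ** 2 if perimeter > 0 else 0.0
    coords = np.argwhere(mask) * np.asarray(spacing)
    max_diam = float(pdist(coords).max()) if coords.shape[0] > 1 else 0.0
    return {
        f"{prefix}_area_mm2": area,
        f"{prefix}_perimeter_mm": perimeter,
        f"{prefix}_circularity": circularity,
        f"{prefix}_max_diameter_mm": max_diam,
    }
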