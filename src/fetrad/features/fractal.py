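"""Box-counting fractal dimensions of the lesion boundary and its
intensity surface.

Both estimators regress log N(s) on log(1/s) over dyadic box sizes.  ROIs
are tiny in this application (a few dozen voxels), so these are coarse,
convention-bound estimates: the point is a reproducible heterogeneity
index, not a converged fractal dimension.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

__all__ = ["boundary_fractal_dimension", "differential_box_counting_dimension",
           "fractal_features"]

#: Fallback when a dimension is undefined (degenerate ROI): the value of the
#: corresponding trivial object (a smooth curve / a flat surface).
BOUNDARY_FALLBACK = 1.0
SURFACE_FALLBACK = 2.0


def _pad_square_pow2(arr: np.ndarray, min_side: int = 8, fill=0.0) -> np.ndarray:
    side = max(min_side, int(2 ** np.ceil(np.log2(max(arr.shape)))))
    out = np.full((side, side), fill, dtype=float)
    out[: arr.shape[0], : arr.shape[1]] = arr
    return out


def _dyadic_sizes(side: int) -> list[int]:
    sizes = []
    s = 1
    while s <= side // 2:
        sizes.append(s)
        s *= 2
    return sizes


def _block_view(arr: np.ndarray, s: int) -> np.ndarray:
    side = arr.shape[0]
    return arr.reshape(side // s, s, side // s, s)


def boundary_fractal_dimension(mask: np.ndarray) -> float:
    """Box-counting dimension of the ROI boundary (inner boundary pixels).

    Returns the documented fallback (1.0, a smooth curve) when fewer than
    4 boundary pixels are available.
    """
    mask = np.asarray(mask, dtype=bool)
    boundary = mask & ~ndi.binary_erosion(mask)
    if boundary.sum() < 4:
        return BOUNDARY_FALLBACK
    padded = _pad_square_pow2(boundary.astype(float)) > 0
    sizes = _dyadic_sizes(padded.shape[0])
    counts = [int(_block_view(padded, s).any(axis=(1, 3)).sum()) for s in sizes]
    # drop the coarsest scales where few boxes remain: the count saturates
    # there and flattens the slope regardless of the true dimension
    keep = [i for i, c in enumerate(counts) if c >= 4]
    if len(keep) >= 2:
        sizes = [sizes[i] for i in keep]
        counts = [counts[i] for i in keep]
    logs = np.log(np.asarray(sizes, dtype=float))
    logn = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(-logs, logn, 1)[0]
    return float(slope)


def differential_box_counting_dimension(values: np.ndarray,
                                        mask: np.ndarray | None = None) -> float:
    """Differential box-counting dimension of the intensity surface.

    The patch is treated as a height field scaled to 256 gray levels;
    outside-mask pixels are filled with the masked mean so they add no
    relief.  For each dyadic box size s the column height count is
    ``floor(max/h) - floor(min/h) + 1`` with ``h = s * G / M``; a constant
    surface yields exactly dimension 2.
    """
    values = np.asarray(values, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < 4:
            return SURFACE_FALLBACK
        filled = np.where(mask, values, values[mask].mean())
    else:
        filled = values
    vmin, vmax = float(filled.min()), float(filled.max())
    g = 256.0
    scaled = np.zeros_like(filled) if vmax == vmin else (filled - vmin) / (vmax - vmin) * (g - 1)
    padded = _pad_square_pow2(scaled, fill=float(scaled.mean()))
    side = padded.shape[0]
    sizes = [s for s in _dyadic_sizes(side) if s >= 2]
    if len(sizes) < 2:
        return SURFACE_FALLBACK
    counts = []
    for s in sizes:
        h = s * g / side
        blocks = _block_view(padded, s)
        bmax = blocks.max(axis=(1, 3))
        bmin = blocks.min(axis=(1, 3))
        n = np.floor(bmax / h) - np.floor(bmin / h) + 1
        counts.append(float(n.sum()))
    logs = np.log(np.asarray(sizes, dtype=float))
    logn = np.log(np.asarray(counts))
    slope = np.polyfit(-logs, logn, 1)[0]
    return float(slope)


def fractal_features(mask: np.ndarray, values: np.ndarray | None = None,
                     prefix: str = "fractal") -> dict[str, float]:
    out = {f"{prefix}_boundary_dimension": boundary_fractal_dimension(mask)}
    if values is not None:
        out[f"{prefix}_surface_dimension"] = differential_box_counting_dimension(
            values, mask)
    return out
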