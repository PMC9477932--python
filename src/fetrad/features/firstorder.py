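"""First-order (histogram) statistics of the lesion intensities."""

from __future__ import annotations

import numpy as np

from .texture import DiscretizedROI

__all__ = ["first_order_features"]


def first_order_features(values: np.ndarray,
                         droi: DiscretizedROI | None = None,
                         prefix: str = "firstorder") -> dict[str, float]:
    """Moments, extrema and discretized entropy/uniformity of ROI intensities.

    *values* are the raw (continuous) ROI intensities, TBR units by
    convention; entropy and uniformity are computed on the discretized
    histogram of *droi* when given.  Constant ROIs take the continuity
    limits skewness = kurtosis = 0, entropy = 0, uniformity = 1.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    d = x - mean
    m2 = float((d ** 2).mean())
    sd = float(np.sqrt(m2))
    # biased sample skewness m3/m2^1.5 and excess kurtosis m4/m2^2 - 3
    skew = float((d ** 3).mean() / m2 ** 1.5) if m2 > 0 else 0.0
    kurt = float((d ** 4).mean() / m2 ** 2 - 3.0) if m2 > 0 else 0.0
    out = {
        f"{prefix}_mean": mean,
        f"{prefix}_sd": sd,
        f"{prefix}_min": float(x.min()),
        f"{prefix}_max": float(x.max()),
        f"{prefix}_range": float(x.max() - x.min()),
        f"{prefix}_energy": float((x ** 2).sum()),
        f"{prefix}_skewness": skew,
        f"{prefix}_kurtosis": kurt,
    }
    if droi is not None:
        counts = np.bincount(droi.levels[droi.mask])
        p = counts[counts > 0] / droi.n_voxels
        out[f"{prefix}_entropy"] = float(-(p * np.log2(p)).sum())
        out[f"{prefix}_uniformity"] = float((p ** 2).sum())
    return out
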