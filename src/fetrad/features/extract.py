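"""Feature-extraction orchestrator: from a segmented lesion to the full
named feature vector.

Five families are computed on the segmented transversal slice: fractal,
first-order, shape/size, gray-level texture matrices (GLCM/GLRLM/GLSZM),
and the wavelet pass (fractal + first-order + texture per sub-band).  By
default intensities are analyzed on the TBR scale (SUV divided by the
healthy-background mean), which makes the fixed 0.1 bin width
scanner-independent, and no spatial resampling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..quantify import LesionSegmentation, PETVolume
from .firstorder import first_order_features
from .fractal import fractal_features
from .shape import shape_features
from .texture import (compute_glcm, compute_glrlm, compute_glszm, discretize,
                      glcm_features, glrlm_features, glszm_features)
from .wavelet import wavelet_features

__all__ = ["FeatureConfig", "extract_features"]

ALL_FAMILIES = ("fractal", "firstorder", "shape", "texture", "wavelet")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable extraction settings.

    ``bin_width`` is in TBR units (``intensity="tbr"``, default) or SUV
    (``intensity="suv"``); ``binning`` chooses the absolute origin-0 bins
    or min-anchored bins; ``glcm_distance`` is the co-occurrence offset in
    voxels.
    """

    families: tuple[str, ...] = ALL_FAMILIES
    bin_width: float = 0.1
    binning: str = "absolute"  # or "min"
    intensity: str = "tbr"  # or "suv"
    glcm_distance: int = 1
    wavelet: str = "db3"

    def __post_init__(self) -> None:
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        if self.binning not in ("absolute", "min"):
            raise ValueError("binning must be 'absolute' or 'min'")
        if self.intensity not in ("tbr", "suv"):
            raise ValueError("intensity must be 'tbr' or 'suv'")


def _bounding_patch(image: np.ndarray, mask: np.ndarray, pad: int = 1):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = max(0, rows[0] - pad), min(mask.shape[0], rows[-1] + 1 + pad)
    c0, c1 = max(0, cols[0] - pad), min(mask.shape[1], cols[-1] + 1 + pad)
    return image[r0:r1, c0:c1], mask[r0:r1, c0:c1]


def extract_features(volume: PETVolume, seg: LesionSegmentation,
                     background: float,
                     config: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """Extract the configured feature families for one segmented lesion.

    Returns an ordered name -> value mapping; the name set and order are
    deterministic for a fixed config, so cohort tables align by column.
    Family-level degeneracies surface as defined fallback values (and a
    flag column for the wavelet pass), never as missing entries.
    """
    if background <= 0:
        raise ValueError("background mean must be positive")
    sl: list[slice | int] = [slice(None)] * 3
    sl[seg.axis] = seg.slice_index
    plane = volume.data[tuple(sl)]
    if config.intensity == "tbr":
        plane = plane / background
    mask = seg.mask
    spacing2d = seg.in_plane_spacing(volume.spacing)
    values = plane[mask]
    origin = 0.0 if config.binning == "absolute" else "min"
    droi = discretize(plane, mask, bin_width=config.bin_width, origin=origin,
                      spacing=spacing2d)

    out: dict[str, float] = {}
    if "fractal" in config.families:
        out.update(fractal_features(mask, plane))
    if "firstorder" in config.families:
        out.update(first_order_features(values, droi))
    if "shape" in config.families:
        out.update(shape_features(mask, spacing2d))
    if "texture" in config.families:
        n = droi.n_voxels
        if n >= 2:
            out.update(glcm_features(compute_glcm(droi, config.glcm_distance)))
        else:  # single-voxel lesion: continuity fallbacks
            out.update({"glcm_energy": 1.0, "glcm_contrast": 0.0,
                        "glcm_correlation": 0.0, "glcm_homogeneity": 1.0,
                        "glcm_joint_entropy": 0.0, "glcm_imc1": 0.0,
                        "glcm_imc2": 0.0})
        out.update(glrlm_features(compute_glrlm(droi), n))
        out.update(glszm_features(compute_glszm(droi), n))
    if "wavelet" in config.families:
        patch, patch_mask = _bounding_patch(plane, mask)
        out.update(wavelet_features(patch, patch_mask, wavelet=config.wavelet,
                                    bin_width=config.bin_width))
    bad = {k: v for k, v in out.items() if not np.isfinite(v)}
    if bad:
        raise AssertionError(f"non-finite features produced: {sorted(bad)}")
    return out
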