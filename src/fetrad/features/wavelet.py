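"""One-level 2D wavelet decomposition of the lesion patch and sub-band
feature re-extraction.

The in-slice bounding-box patch is decomposed with a compactly supported
orthogonal wavelet (default ``db3``, 6-tap) into the LL/LH/HL/HH sub-bands.
Periodic extension ("periodization") is used at the patch border so every
sub-band has exactly half the patch size and aligns with a 2x-decimated ROI
mask (a sub-band coefficient is in-mask when any voxel of its 2x2 input
block is).  Fractal, first-order and texture features are then recomputed
on the mask-restricted coefficients of each sub-band; sub-band intensities
are signed, so their discretization is anchored at the sub-band minimum
rather than at zero.
"""

from __future__ import annotations

import numpy as np
import pywt

from .firstorder import first_order_features
from .fractal import differential_box_counting_dimension, SURFACE_FALLBACK
from .texture import (compute_glcm, compute_glrlm, compute_glszm, discretize,
                      glcm_features, glrlm_features, glszm_features)

__all__ = ["wavelet_subbands", "wavelet_features"]

SUBBAND_NAMES = ("LL", "LH", "HL", "HH")


def _decimate_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """2x block-OR decimation of the ROI mask, padded to the sub-band shape."""
    nr, nc = mask.shape
    pad = np.zeros((shape[0] * 2, shape[1] * 2), dtype=bool)
    pad[:nr, :nc] = mask
    return pad.reshape(shape[0], 2, shape[1], 2).any(axis=(1, 3))


def wavelet_subbands(patch: np.ndarray, mask: np.ndarray, wavelet: str = "db3",
                     ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Decompose *patch* and return ``{band: (coefficients, band_mask)}``."""
    patch = np.asarray(patch, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if patch.shape != mask.shape or patch.ndim != 2:
        raise ValueError("patch and mask must be matching 2D arrays")
    ll, (lh, hl, hh) = pywt.dwt2(patch, wavelet, mode="periodization")
    band_mask = _decimate_mask(mask, ll.shape)
    return {name: (band, band_mask)
            for name, band in zip(SUBBAND_NAMES, (ll, lh, hl, hh))}


def _degenerate_band(prefix: str) -> dict[str, float]:
    """Defined fallbacks for a sub-band too small for analysis."""
    out = {
        f"{prefix}_firstorder_mean": 0.0, f"{prefix}_firstorder_sd": 0.0,
        f"{prefix}_firstorder_min": 0.0, f"{prefix}_firstorder_max": 0.0,
        f"{prefix}_firstorder_range": 0.0, f"{prefix}_firstorder_energy": 0.0,
        f"{prefix}_firstorder_skewness": 0.0, f"{prefix}_firstorder_kurtosis": 0.0,
        f"{prefix}_firstorder_entropy": 0.0, f"{prefix}_firstorder_uniformity": 1.0,
        f"{prefix}_glcm_energy": 1.0, f"{prefix}_glcm_contrast": 0.0,
        f"{prefix}_glcm_correlation": 0.0, f"{prefix}_glcm_homogeneity": 1.0,
        f"{prefix}_glcm_joint_entropy": 0.0, f"{prefix}_glcm_imc1": 0.0,
        f"{prefix}_glcm_imc2": 0.0,
        f"{prefix}_glrlm_short_run_emphasis": 1.0,
        f"{prefix}_glrlm_long_run_emphasis": 1.0,
        f"{prefix}_glrlm_run_length_nonuniformity": 1.0,
        f"{prefix}_glrlm_gray_level_nonuniformity": 1.0,
        f"{prefix}_glrlm_run_percentage": 1.0,
        f"{prefix}_glszm_intensity_nonuniformity_normalized": 1.0,
        f"{prefix}_glszm_zone_size_nonuniformity_normalized": 1.0,
        f"{prefix}_glszm_small_zone_emphasis": 1.0,
        f"{prefix}_glszm_large_zone_emphasis": 1.0,
        f"{prefix}_glszm_zone_percentage": 1.0,
        f"{prefix}_fractal_surface_dimension": SURFACE_FALLBACK,
        f"{prefix}_degenerate": 1.0,
    }
    return out


def wavelet_features(patch: np.ndarray, mask: np.ndarray, wavelet: str = "db3",
                     bin_width: float = 0.1) -> dict[str, float]:
    """Fractal, first-order and texture features per wavelet sub-band.

    The shape family is deliberately absent here: the ROI mask is unchanged
    by intensity filtering, so sub-band shape features would duplicate the
    originals.  Sub-bands whose masked support is below 2 coefficients are
    returned with defined degenerate fallbacks and a ``*_degenerate`` flag.
    """
    min_support = pywt.Wavelet(wavelet).dec_len
    bands = wavelet_subbands(patch, mask, wavelet)
    out: dict[str, float] = {}
    roi_small = min(mask.shape) < min_support
    for name, (band, bmask) in bands.items():
        prefix = f"wavelet_{name}"
        n = int(bmask.sum())
        if roi_small or n < 2:
            out.update(_degenerate_band(prefix))
            continue
        values = band[bmask]
        droi = discretize(band, bmask, bin_width=bin_width, origin="min")
        out.update(first_order_features(values, droi,
                                        prefix=f"{prefix}_firstorder"))
        out.update({f"{prefix}_{k}": v for k, v in
                    glcm_features(compute_glcm(droi)).items()})
        out.update({f"{prefix}_{k}": v for k, v in
                    glrlm_features(compute_glrlm(droi), n).items()})
        out.update({f"{prefix}_{k}": v for k, v in
                    glszm_features(compute_glszm(droi), n).items()})
        out[f"{prefix}_fractal_surface_dimension"] = \
            differential_box_counting_dimension(band, bmask)
        out[f"{prefix}_degenerate"] = 0.0
    return out
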