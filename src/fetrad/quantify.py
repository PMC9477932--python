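"""SUV conversion, harmonization smoothing, background quantification,
2D auto-contour lesion segmentation, and tumor-to-brain ratios (TBR).

The quantification chain mirrors routine static amino-acid PET reading:
tissue activity is normalized to the standardized uptake value (SUV),
scanners are harmonized with a Gaussian filter quoted in mm, a background
region in the contralateral healthy hemisphere yields the reference uptake,
and the lesion is contoured in 2D as the connected supra-threshold region
(TBR >= 1.6) around the hottest voxel in its transversal slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "PETVolume",
    "SubjectMeta",
    "LesionSegmentation",
    "TBRSummary",
    "compute_suv",
    "harmonize",
    "background_mean",
    "autocontour_lesion",
    "compute_tbr",
    "FWHM_TO_SIGMA",
]

#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default auto-contour threshold in TBR units; separates vital tumor from
#: healthy brain parenchyma in FET PET.
DEFAULT_TBR_THRESHOLD = 1.6


@dataclass
class PETVolume:
    """A 3D PET scalar grid with voxel spacing and a unit flag.

    Parameters
    ----------
    data
        3D array of voxel values.
    spacing
        Voxel edge lengths in mm, one per axis.
    units
        ``"kBq/ml"`` (activity concentration) or ``"SUV"``.
    affine
        Optional 4x4 voxel-to-world matrix; defaults to a diagonal affine
        built from ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = "SUV"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("PETVolume requires a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if self.units not in ("kBq/ml", "SUV"):
            raise ValueError(f"unknown unit flag {self.units!r}")
        if self.affine is None:
            self.affine = np.diag((*self.spacing, 1.0))

    @classmethod
    def from_nifti(cls, path: str | Path, units: str = "SUV") -> "PETVolume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, spacing=spacing, units=units, affine=np.asarray(img.affine))

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    def with_data(self, data: np.ndarray, units: str | None = None) -> "PETVolume":
        return PETVolume(data, spacing=self.spacing,
                         units=self.units if units is None else units,
                         affine=self.affine)


@dataclass(frozen=True)
class SubjectMeta:
    """Injected activity (MBq), body weight (kg) and optional class label."""

    injected_mbq: float
    weight_kg: float
    label: int | None = None

    def __post_init__(self) -> None:
        if self.injected_mbq <= 0:
            raise ValueError("injected activity must be positive (MBq)")
        if self.weight_kg <= 0:
            raise ValueError("body weight must be positive (kg)")


@dataclass
class LesionSegmentation:
    """2D auto-contoured lesion: slice, in-slice mask, threshold, context.

    ``mask`` is a 2D boolean array over the transversal slice
    ``slice_index`` taken along ``axis``.  ``max_index`` is the 3D voxel
    index of the hottest voxel, which is always a member of the contour.
    """

    slice_index: int
    mask: np.ndarray
    threshold: float
    max_index: tuple[int, int, int]
    background: float
    axis: int = 2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("segmentation mask must be a non-empty 2D mask")
        if self.max_index[self.axis] != self.slice_index:
            raise ValueError("max voxel does not lie in the stated slice")
        if not self.mask[self.in_slice_index(self.max_index)]:
            raise ValueError("max voxel not contained in the segmentation")

    def in_slice_index(self, index3d: tuple[int, int, int]) -> tuple[int, int]:
        idx = list(index3d)
        del idx[self.axis]
        return tuple(idx)  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def mask3d(self, shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        sl: list[slice | int] = [slice(None)] * 3
        sl[self.axis] = self.slice_index
        out[tuple(sl)] = self.mask
        return out

    def in_plane_spacing(self, spacing: tuple[float, float, float]) -> tuple[float, float]:
        sp = list(spacing)
        del sp[self.axis]
        return tuple(sp)  # type: ignore[return-value]

    def values(self, volume: PETVolume) -> np.ndarray:
        """Lesion voxel values (1D) from the segmented slice of *volume*."""
        sl: list[slice | int] = [slice(None)] * 3
        sl[self.axis] = self.slice_index
        return volume.data[tuple(sl)][self.mask]

    def to_json(self, path: str | Path, summary: "TBRSummary | None" = None) -> None:
        payload = {
            "slice_index": self.slice_index,
            "axis": self.axis,
            "threshold": self.threshold,
            "max_index": list(self.max_index),
            "background_mean_suv": self.background,
            "n_voxels": self.n_voxels,
        }
        if summary is not None:
            payload["tbr_mean"] = summary.tbr_mean
            payload["tbr_max"] = summary.tbr_max
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class TBRSummary:
    """Mean and maximum tumor-to-brain ratio of a segmented lesion."""

    tbr_mean: float
    tbr_max: float
    threshold: float = DEFAULT_TBR_THRESHOLD

    def __post_init__(self) -> None:
        # TBR_max >= TBR_mean >= threshold by construction of the contour;
        # a tiny tolerance absorbs float round-off at the threshold boundary.
        tol = 1e-9
        if not (self.tbr_max >= self.tbr_mean - tol >= self.threshold - tol):
            raise ValueError(
                f"invalid TBR summary: max={self.tbr_max}, mean={self.tbr_mean}, "
                f"threshold={self.threshold}"
            )


def compute_suv(volume: PETVolume, meta: SubjectMeta) -> PETVolume:
    """Convert activity concentration (kBq/ml) to SUV.

    SUV = tissue activity (kBq/ml) / (injected activity (kBq) per gram of
    body weight).  With injected activity in MBq and weight in kg the
    denominator reduces to ``injected_mbq / weight_kg`` (kBq/g).
    """
    if volume.units == "SUV":
        raise ValueError("volume is already in SUV; refusing double conversion")
    dose_per_gram = meta.injected_mbq / meta.weight_kg  # kBq/g == MBq/kg
    return volume.with_data(volume.data / dose_per_gram, units="SUV")


def harmonize(volume: PETVolume, fwhm_mm: float,
              kernel_interpretation: str = "fwhm") -> PETVolume:
    """3D Gaussian smoothing with the kernel size stated in mm.

    PET harmonization filters are conventionally quoted as FWHM, so
    ``kernel_interpretation="fwhm"`` (default) converts via
    sigma = FWHM / (2 sqrt(2 ln 2)); ``"sigma"`` treats the number as the
    standard deviation directly.  Smoothing conserves total intensity up
    to boundary truncation (zero-padded borders).
    """
    if fwhm_mm <= 0:
        raise ValueError("kernel size must be positive (mm)")
    if kernel_interpretation == "fwhm":
        sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    elif kernel_interpretation == "sigma":
        sigma_mm = fwhm_mm
    else:
        raise ValueError("kernel_interpretation must be 'fwhm' or 'sigma'")
    sigma_vox = [sigma_mm / s for s in volume.spacing]
    return volume.with_data(ndi.gaussian_filter(volume.data, sigma=sigma_vox,
                                                mode="constant", cval=0.0))


def background_mean(volume: PETVolume, roi: np.ndarray) -> float:
    """Mean SUV over the healthy-brain background region of interest."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != volume.data.shape:
        raise ValueError("ROI mask shape does not match the volume")
    if not roi.any():
        raise ValueError("background ROI is empty")
    return float(volume.data[roi].mean())


# 8-connected in-plane structure for the contour flood fill
_STRUCT8 = np.ones((3, 3), dtype=bool)


def autocontour_lesion(volume: PETVolume, background: float,
                       threshold: float = DEFAULT_TBR_THRESHOLD,
                       search_mask: np.ndarray | None = None,
                       axis: int = 2) -> LesionSegmentation | None:
    """2D auto-contour of the lesion at TBR >= *threshold*.

    Finds the hottest voxel (inside *search_mask* if given; ties resolved
    to the lowest linear index), takes its transversal slice along *axis*,
    and returns the 8-connected component of supra-threshold voxels that
    contains it.  Returns ``None`` when no voxel reaches the threshold
    ("no lesion"), which is a valid clinical outcome, not an error.
    """
    if background <= 0:
        raise ValueError("background mean must be positive")
    data = volume.data
    if search_mask is not None:
        search_mask = np.asarray(search_mask, dtype=bool)
        if search_mask.shape != data.shape:
            raise ValueError("search mask shape does not match the volume")
        if not search_mask.any():
            raise ValueError("search mask is empty")
        masked = np.where(search_mask, data, -np.inf)
    else:
        masked = data
    flat_max = int(np.argmax(masked))  # lowest linear index wins ties
    max_index = tuple(int(i) for i in np.unravel_index(flat_max, data.shape))
    cutoff = threshold * background
    if data[max_index] < cutoff:
        return None

    sl: list[slice | int] = [slice(None)] * 3
    sl[axis] = max_index[axis]
    plane = data[tuple(sl)]
    supra = plane >= cutoff
    if search_mask is not None:
        supra &= search_mask[tuple(sl)]
    labels, _ = ndi.label(supra, structure=_STRUCT8)
    in_plane = list(max_index)
    del in_plane[axis]
    component = labels == labels[tuple(in_plane)]
    return LesionSegmentation(slice_index=max_index[axis], mask=component,
                              threshold=threshold, max_index=max_index,
                              background=background, axis=axis)


def compute_tbr(seg: LesionSegmentation, volume: PETVolume,
                background: float) -> TBRSummary:
    """TBR_max and TBR_mean of a segmented lesion.

    Both ratios divide lesion SUV statistics by the healthy-brain mean SUV.
    Every member voxel must satisfy the contour's TBR threshold; violating
    values indicate a segmentation/volume mismatch and raise.
    """
    if background <= 0:
        raise ValueError("background mean must be positive")
    values = seg.values(volume)
    if values.size == 0:
        raise ValueError("empty segmentation")
    if np.min(values) < seg.threshold * background - 1e-9:
        raise ValueError(
            "segmentation contains voxels below threshold x background; "
            "volume/background do not match the contour"
        )
    return TBRSummary(tbr_mean=float(values.mean() / background),
                      tbr_max=float(values.max() / background),
                      threshold=seg.threshold)
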