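"""Synthetic FET PET phantoms, cohorts, and raw feature tables.

Patient scans behind the study design are not publicly available, so this
module generates seeded stand-ins that reproduce the statistical structure
the analysis assumes: a brain-like constant background with independent
voxel noise, an ellipsoidal lesion whose tumor-to-brain ratio (TBR) targets
are drawn per class, an optional spatially correlated texture field inside
the lesion (tumor progression lesions are texturally heterogeneous,
treatment-related changes nearly homogeneous), and a background reference
region mirrored into the contralateral hemisphere.

Nothing here attempts anatomical realism or PET physics (no point-spread
function, scatter, or randoms); the phantoms exist so that segmentation,
quantification, feature extraction and model building can be exercised and
verified at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .quantify import PETVolume

__all__ = [
    "PhantomSpec",
    "ClassDistribution",
    "CohortSpec",
    "Subject",
    "generate_phantom",
    "generate_cohort",
    "generate_feature_table",
    "save_cohort",
]

#: Detectability threshold in TBR units shared with the quantification chain.
DETECTION_TBR = 1.6


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a single synthetic lesion phantom.

    All lengths are in mm; intensities are in SUV units (phantoms are
    generated directly in SUV — dose/weight bookkeeping is exercised
    separately by the SUV conversion of the quantification module).
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_mean: float = 1.0
    noise_sd: float = 0.05
    lesion_center_mm: tuple[float, float, float] = (20.0, 32.0, 16.0)
    lesion_semiaxes_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    label: int = 1  # 1 = tumor progression (TP), 0 = treatment-related changes (TRC)
    tbr_max: float = 3.2
    tbr_mean: float = 2.0
    texture_amplitude: float = 0.0  # SD of the intra-lesion texture field, SUV
    texture_corr_mm: float = 4.0
    background_roi_center_mm: tuple[float, float, float] | None = None
    background_roi_semiaxes_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tbr_max < self.tbr_mean:
            raise ValueError("target TBR_max must be >= target TBR_mean")
        if self.tbr_mean < DETECTION_TBR:
            raise ValueError(
                f"detectable lesion requires TBR_mean >= {DETECTION_TBR}"
            )
        if self.background_mean <= 0:
            raise ValueError("background mean uptake must be positive")
        if self.noise_sd < 0 or self.texture_amplitude < 0:
            raise ValueError("noise SD and texture amplitude must be >= 0")
        extent_mm = [n * s for n, s in zip(self.shape, self.spacing)]
        for c, a, e in zip(self.lesion_center_mm, self.lesion_semiaxes_mm, extent_mm):
            if a <= 0:
                raise ValueError("lesion semi-axes must be positive")
            if c - a < 0 or c + a > e:
                raise ValueError("lesion does not fit inside the grid")


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semiaxes_mm))
    return q <= 1.0


def _center_voxel(shape, spacing, center_mm) -> tuple[int, int, int]:
    idx = tuple(int(np.clip(round(c / s - 0.5), 0, n - 1))
                for c, s, n in zip(center_mm, spacing, shape))
    return idx


def generate_phantom(spec: PhantomSpec) -> tuple[PETVolume, np.ndarray, np.ndarray]:
    """Generate one phantom volume with its truth lesion and background masks.

    Returns ``(volume, truth_mask, background_roi)`` where ``truth_mask``
    marks the voxels whose *noise-free* TBR is >= 1.6 and the background
    region is an ellipsoid mirrored through the mid-sagittal plane (first
    axis) of the grid, emulating a reference region in the semioval center
    of the unaffected hemisphere.

    Construction of the noise-free lesion: a constant plateau at the target
    TBR_mean, plus a zero-mean unit-SD Gaussian random field (smoothed white
    noise with the stated correlation length) scaled by the texture
    amplitude; values are clipped at the target TBR_max and the center voxel
    is set to attain TBR_max exactly.  Independent Gaussian voxel noise is
    added on top; the result is clipped at zero (SUV is non-negative).
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    bg = spec.background_mean

    lesion = _ellipsoid_mask(shape, spacing, spec.lesion_center_mm,
                             spec.lesion_semiaxes_mm)
    if not lesion.any():
        raise ValueError("lesion ellipsoid contains no voxel centers")

    clean = np.full(shape, bg, dtype=float)
    tbr = np.full(shape, np.nan)
    tbr[lesion] = spec.tbr_mean
    if spec.texture_amplitude > 0 and lesion.sum() > 1:
        white = rng.standard_normal(shape)
        sigma_vox = [spec.texture_corr_mm / s for s in spacing]
        fieldv = ndi.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
        inside = fieldv[lesion]
        sd = inside.std()
        if sd > 0:
            fieldv = (fieldv - inside.mean()) / sd
            tbr[lesion] = spec.tbr_mean + spec.texture_amplitude / bg * fieldv[lesion]
    np.clip(tbr, None, spec.tbr_max, out=tbr)
    cvox = _center_voxel(shape, spacing, spec.lesion_center_mm)
    if not lesion[cvox]:
        raise ValueError("lesion center voxel falls outside the ellipsoid")
    tbr[cvox] = spec.tbr_max
    clean[lesion] = bg * tbr[lesion]

    truth = lesion & (np.nan_to_num(tbr, nan=0.0) >= DETECTION_TBR)

    roi_center = spec.background_roi_center_mm
    if roi_center is None:
        extent0 = shape[0] * spacing[0]
        roi_center = (extent0 - spec.lesion_center_mm[0],
                      spec.lesion_center_mm[1], spec.lesion_center_mm[2])
    roi = _ellipsoid_mask(shape, spacing, roi_center, spec.background_roi_semiaxes_mm)
    if not roi.any():
        raise ValueError("background ROI contains no voxel centers")
    if (roi & lesion).any():
        raise ValueError("background ROI overlaps the lesion; move the lesion "
                         "off the mid-sagittal plane or supply an ROI center")

    data = clean + rng.normal(0.0, spec.noise_sd, shape) if spec.noise_sd > 0 else clean
    np.clip(data, 0.0, None, out=data)
    vol = PETVolume(data, spacing=spacing, units="SUV")
    return vol, truth, roi


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class sampling distributions of the lesion parameters (mean, SD)."""

    tbr_mean: tuple[float, float] = (2.0, 0.25)
    tbr_max: tuple[float, float] = (3.2, 0.7)
    texture_amplitude: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class CohortSpec:
    """A two-class cohort: counts, class distributions, shared phantom defaults."""

    n_tp: int = 75
    n_trc: int = 25
    tp: ClassDistribution = field(default_factory=lambda: ClassDistribution(
        tbr_mean=(2.1, 0.3), tbr_max=(3.7, 0.9), texture_amplitude=(0.30, 0.10)))
    trc: ClassDistribution = field(default_factory=lambda: ClassDistribution(
        tbr_mean=(1.9, 0.3), tbr_max=(2.8, 0.7), texture_amplitude=(0.10, 0.05)))
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tp < 1 or self.n_trc < 1:
            raise ValueError("both class counts must be positive")


@dataclass
class Subject:
    subject_id: str
    label: int
    volume: PETVolume
    truth_mask: np.ndarray
    background_roi: np.ndarray
    spec: PhantomSpec


def _draw_lesion_params(rng: np.random.Generator, dist: ClassDistribution):
    """Draw (tbr_mean, tbr_max, amplitude) with validity truncation.

    TBR_mean is kept above the detection threshold (plus a small margin so
    the plateau survives voxel noise) and TBR_max at least 0.2 above
    TBR_mean; amplitudes are non-negative.
    """
    tbr_mean = max(DETECTION_TBR + 0.1, rng.normal(*dist.tbr_mean))
    tbr_max = max(tbr_mean + 0.2, rng.normal(*dist.tbr_max))
    amp = max(0.0, rng.normal(*dist.texture_amplitude))
    return tbr_mean, tbr_max, amp


def generate_cohort(cohort: CohortSpec) -> list[Subject]:
    """Generate all subjects of a cohort, TP first then TRC, reproducibly.

    Per-subject phantom seeds are spawned deterministically from the master
    seed via ``numpy.random.SeedSequence``, so any subject can be
    regenerated in isolation from the manifest.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cohort.seed))
    children = np.random.SeedSequence(cohort.seed).spawn(cohort.n_tp + cohort.n_trc)
    subjects: list[Subject] = []
    labels = [1] * cohort.n_tp + [0] * cohort.n_trc
    for i, (label, child) in enumerate(zip(labels, children)):
        dist = cohort.tp if label == 1 else cohort.trc
        tbr_mean, tbr_max, amp = _draw_lesion_params(rng, dist)
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        spec = replace(cohort.phantom, label=label, tbr_mean=tbr_mean,
                       tbr_max=tbr_max, texture_amplitude=amp, seed=sub_seed)
        vol, truth, roi = generate_phantom(spec)
        subjects.append(Subject(subject_id=f"sub-{i:04d}", label=label,
                                volume=vol, truth_mask=truth,
                                background_roi=roi, spec=spec))
    return subjects


def save_cohort(subjects: list[Subject], directory) -> pd.DataFrame:
    """Write NIfTI volumes/masks plus a manifest CSV; returns the manifest."""
    import nibabel as nib
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        base = directory / s.subject_id
        s.volume.to_nifti(f"{base}_suv.nii")
        affine = s.volume.affine
        nib.save(nib.Nifti1Image(s.truth_mask.astype(np.uint8), affine),
                 f"{base}_truth.nii")
        nib.save(nib.Nifti1Image(s.background_roi.astype(np.uint8), affine),
                 f"{base}_bgroi.nii")
        rows.append({"subject_id": s.subject_id, "label": s.label,
                     "seed": s.spec.seed,
                     "tbr_mean_target": s.spec.tbr_mean,
                     "tbr_max_target": s.spec.tbr_max,
                     "texture_amplitude": s.spec.texture_amplitude,
                     "suv_path": f"{base}_suv.nii",
                     "truth_path": f"{base}_truth.nii",
                     "bgroi_path": f"{base}_bgroi.nii"})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def generate_feature_table(n_subjects: int, n_features: int,
                           n_informative: int = 0, effect_size: float = 0.0,
                           correlation: float = 0.0, seed: int = 0,
                           n_constant: int = 0,
                           n_duplicate: int = 0) -> pd.DataFrame:
    """Simulate a raw subjects-by-features table for selection-stage tests.

    Features are unit-variance Gaussians with optional equicorrelation
    (shared latent factor); the first *n_informative* columns are shifted by
    *effect_size* in the positive class.  ``n_constant`` constant columns and
    ``n_duplicate`` exact copies of the leading columns can be injected to
    exercise the variance and correlation filters.  Labels are balanced
    (ceil(n/2) positives) and the DataFrame carries a ``label`` column with
    subject ids as index.
    """
    if not 0 <= n_informative <= n_features:
        raise ValueError("n_informative must lie in [0, n_features]")
    if not -1.0 < correlation < 1.0:
        raise ValueError("|pairwise correlation| must be < 1")
    rng = np.random.default_rng(seed)
    n_pos = (n_subjects + 1) // 2
    y = np.array([1] * n_pos + [0] * (n_subjects - n_pos))
    common = rng.standard_normal((n_subjects, 1))
    X = (np.sqrt(correlation) * common
         + np.sqrt(1.0 - correlation) * rng.standard_normal((n_subjects, n_features))
         if correlation > 0 else rng.standard_normal((n_subjects, n_features)))
    X[:, :n_informative] += effect_size * y[:, None]
    cols = {f"feat_{i:03d}": X[:, i] for i in range(n_features)}
    for k in range(n_constant):
        cols[f"const_{k}"] = np.zeros(n_subjects)
    for k in range(min(n_duplicate, n_features)):
        cols[f"dup_of_feat_{k:03d}"] = X[:, k].copy()
    frame = pd.DataFrame(cols, index=[f"sub-{i:04d}" for i in range(n_subjects)])
    frame.insert(0, "label", y)
    return frame
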