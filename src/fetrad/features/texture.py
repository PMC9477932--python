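"""Gray-level texture matrices (GLCM, GLRLM, GLSZM) and their features.

All texture analysis is 2D in the segmented transversal slice, following
the 2D auto-contour segmentation: co-occurrence and run-length matrices use
the four in-plane directions at distance 1 (features averaged over
directions), and size zones use 8-connectivity.  Intensities are
discretized with a fixed absolute bin width (default 0.1 in TBR units,
origin 0), so bins are comparable across subjects and scanners.

Matrices are stored over the *occupied* gray levels only (with the actual
level values attached); empty levels contribute nothing to any feature
defined here, so this is equivalent to, and far smaller than, carrying the
full 1..N_g range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "DiscretizedROI",
    "TextureMatrix",
    "discretize",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "compute_glszm",
    "glszm_features",
    "IN_PLANE_DIRECTIONS",
]

#: The four unique in-plane directions (0, 45, 90, 135 degrees).
IN_PLANE_DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class DiscretizedROI:
    """Integer gray levels over a 2D in-slice ROI.

    ``levels`` is 0 outside the mask; inside, level ``g`` covers the
    intensity interval ``[origin + (g-1) w, origin + g w)``.  ``n_levels``
    is the maximum level present (absolute binning is *not* relabeled to
    start at 1).
    """

    levels: np.ndarray
    mask: np.ndarray
    bin_width: float
    origin: float
    n_levels: int
    spacing: tuple[float, float] = (1.0, 1.0)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def occupied_levels(self) -> np.ndarray:
        return np.unique(self.levels[self.mask])


def discretize(values: np.ndarray, mask: np.ndarray, bin_width: float = 0.1,
               origin: float | str = 0.0,
               spacing: tuple[float, float] = (1.0, 1.0)) -> DiscretizedROI:
    """Fixed-bin-width discretization of an in-slice ROI.

    *values* holds the intensities (TBR by convention) on the 2D slice and
    *mask* the ROI.  ``origin`` is the absolute binning origin (default 0);
    passing ``"min"`` anchors bins at the ROI minimum instead (used for
    wavelet sub-bands whose coefficients are signed).  Level assignment is
    ``floor((x - origin)/w) + 1``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values, dtype=float)
    if values.shape != mask.shape or values.ndim != 2:
        raise ValueError("values and mask must be matching 2D arrays")
    if not mask.any():
        raise ValueError("empty ROI")
    org = float(values[mask].min()) if origin == "min" else float(origin)
    levels = np.zeros(mask.shape, dtype=np.int64)
    levels[mask] = np.floor((values[mask] - org) / bin_width).astype(np.int64) + 1
    if levels[mask].min() < 1:
        raise ValueError("intensities below the binning origin")
    return DiscretizedROI(levels=levels, mask=mask, bin_width=bin_width,
                          origin=org, n_levels=int(levels[mask].max()),
                          spacing=tuple(spacing))


@dataclass
class TextureMatrix:
    """A texture matrix over occupied gray levels.

    For GLCM, ``counts`` is square over ``gray_levels`` x ``gray_levels``;
    for GLRLM/GLSZM the columns are run lengths / zone sizes listed in
    ``col_values``.
    """

    kind: str
    counts: np.ndarray
    gray_levels: np.ndarray
    col_values: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        t = self.total
        if t == 0:
            raise ValueError(f"empty {self.kind} matrix")
        return self.counts / t


# ---------------------------------------------------------------------------
# GLCM

def compute_glcm(droi: DiscretizedROI, distance: int = 1,
                 directions: tuple[tuple[int, int], ...] = IN_PLANE_DIRECTIONS,
                 ) -> list[TextureMatrix]:
    """Per-direction symmetric gray-level co-occurrence matrices.

    Counts every ordered in-ROI voxel pair at offset ``distance * d`` and
    its reverse (symmetrization), one matrix per direction, for later
    direction-averaging of the features.
    """
    if droi.n_voxels < 2:
        raise ValueError("GLCM requires at least two ROI voxels")
    levels = droi.levels
    mask = droi.mask
    glv = droi.occupied_levels
    index = {g: i for i, g in enumerate(glv)}
    out = []
    nr, nc = mask.shape
    for d in directions:
        dr, dc = d[0] * distance, d[1] * distance
        counts = np.zeros((glv.size, glv.size), dtype=float)
        r0s, r0e = max(0, -dr), min(nr, nr - dr)
        c0s, c0e = max(0, -dc), min(nc, nc - dc)
        a_mask = mask[r0s:r0e, c0s:c0e] & mask[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        a = levels[r0s:r0e, c0s:c0e][a_mask]
        b = levels[r0s + dr:r0e + dr, c0s + dc:c0e + dc][a_mask]
        for x, y in zip(a, b):
            counts[index[x], index[y]] += 1
            counts[index[y], index[x]] += 1
        out.append(TextureMatrix(kind="GLCM", counts=counts, gray_levels=glv,
                                 col_values=glv,
                                 params={"direction": d, "distance": distance}))
    return out


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _glcm_features_single(P: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    i = levels.astype(float)[:, None]
    j = levels.astype(float)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((px * levels).sum())
    mu_y = float((py * levels).sum())
    sd_x = math.sqrt(max(0.0, float((px * (levels - mu_x) ** 2).sum())))
    sd_y = math.sqrt(max(0.0, float((py * (levels - mu_y) ** 2).sum())))

    energy = float((P ** 2).sum())
    contrast = float((P * (i - j) ** 2).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    hxy = _entropy(P.ravel())
    if sd_x > 0 and sd_y > 0:
        correlation = float((P * (i - mu_x) * (j - mu_y)).sum() / (sd_x * sd_y))
    else:
        correlation = 0.0  # degenerate marginal: no linear dependence defined

    pxpy = np.outer(px, py)
    hx = _entropy(px)
    hy = _entropy(py)
    # cross entropies of P against the marginal-product distribution
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(P * log_pxpy).sum())
    hxy2 = _entropy(pxpy.ravel())
    hmax = max(hx, hy)
    imc1 = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "homogeneity": homogeneity,
        "joint_entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
    }


def glcm_features(matrices: list[TextureMatrix]) -> dict[str, float]:
    """Direction-averaged GLCM features.

    Includes the Informational Measures of Correlation:
    ``IMC2 = sqrt(1 - exp(-2 (HXY2 - HXY)))`` with HXY the joint entropy of
    the co-occurrence distribution and HXY2 the entropy of the product of
    its marginals (log base 2).  A single-level ROI takes the continuity
    fallbacks IMC1 = IMC2 = correlation = 0, entropy 0.
    """
    per_dir = [_glcm_features_single(m.probabilities, m.gray_levels.astype(float))
               for m in matrices if m.total > 0]
    if not per_dir:  # no in-ROI pair in any direction: featureless
        return {"glcm_energy": 1.0, "glcm_contrast": 0.0,
                "glcm_correlation": 0.0, "glcm_homogeneity": 1.0,
                "glcm_joint_entropy": 0.0, "glcm_imc1": 0.0, "glcm_imc2": 0.0}
    names = per_dir[0].keys()
    return {f"glcm_{k}": float(np.mean([d[k] for d in per_dir])) for k in names}


# ---------------------------------------------------------------------------
# GLRLM

def _runs_in_direction(droi: DiscretizedROI, d: tuple[int, int]) -> dict[tuple[int, int], int]:
    """Enumerate maximal equal-level in-ROI runs along direction *d*."""
    mask, levels = droi.mask, droi.levels
    nr, nc = mask.shape
    dr, dc = d
    runs: dict[tuple[int, int], int] = {}
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            pr, pc = r - dr, c - dc
            if 0 <= pr < nr and 0 <= pc < nc and mask[pr, pc] \
                    and levels[pr, pc] == levels[r, c]:
                continue  # not a run start
            g = levels[r, c]
            length = 1
            rr, cc = r + dr, c + dc
            while 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] \
                    and levels[rr, cc] == g:
                length += 1
                rr += dr
                cc += dc
            runs[(int(g), length)] = runs.get((int(g), length), 0) + 1
    return runs


def compute_glrlm(droi: DiscretizedROI,
                  directions: tuple[tuple[int, int], ...] = IN_PLANE_DIRECTIONS,
                  ) -> list[TextureMatrix]:
    """Per-direction gray-level run-length matrices r(g, l)."""
    if droi.n_voxels < 1:
        raise ValueError("empty ROI")
    glv = droi.occupied_levels
    gidx = {int(g): i for i, g in enumerate(glv)}
    out = []
    for d in directions:
        runs = _runs_in_direction(droi, d)
        max_len = max(l for (_, l) in runs)
        lengths = np.arange(1, max_len + 1)
        counts = np.zeros((glv.size, max_len), dtype=float)
        for (g, l), n in runs.items():
            counts[gidx[g], l - 1] += n
        out.append(TextureMatrix(kind="GLRLM", counts=counts, gray_levels=glv,
                                 col_values=lengths, params={"direction": d}))
    return out


def _glrlm_features_single(m: TextureMatrix, n_voxels: int) -> dict[str, float]:
    r = m.counts
    lengths = m.col_values.astype(float)
    nr = r.sum()
    by_len = r.sum(axis=0)
    by_gray = r.sum(axis=1)
    return {
        "short_run_emphasis": float((by_len / lengths ** 2).sum() / nr),
        "long_run_emphasis": float((by_len * lengths ** 2).sum() / nr),
        "run_length_nonuniformity": float((by_len ** 2).sum() / nr ** 2),
        "gray_level_nonuniformity": float((by_gray ** 2).sum() / nr ** 2),
        "run_percentage": float(nr / n_voxels),
    }


def glrlm_features(matrices: list[TextureMatrix], n_voxels: int) -> dict[str, float]:
    """Direction-averaged run-length features (non-uniformities normalized)."""
    per_dir = [_glrlm_features_single(m, n_voxels) for m in matrices]
    names = per_dir[0].keys()
    return {f"glrlm_{k}": float(np.mean([d[k] for d in per_dir])) for k in names}


# ---------------------------------------------------------------------------
# GLSZM

def compute_glszm(droi: DiscretizedROI) -> TextureMatrix:
    """Gray-level size-zone matrix s(g, z) with 8-connected zones."""
    if droi.n_voxels < 1:
        raise ValueError("empty ROI")
    glv = droi.occupied_levels
    zones: dict[tuple[int, int], int] = {}
    max_size = 1
    for g in glv:
        labels, n = ndi.label(droi.mask & (droi.levels == g), structure=_STRUCT8)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        for z in sizes:
            zones[(int(g), int(z))] = zones.get((int(g), int(z)), 0) + 1
            max_size = max(max_size, int(z))
    counts = np.zeros((glv.size, max_size), dtype=float)
    gidx = {int(g): i for i, g in enumerate(glv)}
    for (g, z), n in zones.items():
        counts[gidx[g], z - 1] += n
    return TextureMatrix(kind="GLSZM", counts=counts, gray_levels=glv,
                         col_values=np.arange(1, max_size + 1),
                         params={"connectivity": 8})


def glszm_features(matrix: TextureMatrix, n_voxels: int) -> dict[str, float]:
    """Size-zone features, led by the gray-level Intensity Non-Uniformity
    Normalized ``INN = sum_g (sum_z s(g,z))^2 / N_z^2``."""
    s = matrix.counts
    nz = s.sum()
    if nz == 0:
        raise ValueError("GLSZM has zero zones")
    sizes = matrix.col_values.astype(float)
    by_gray = s.sum(axis=1)
    by_size = s.sum(axis=0)
    return {
        "glszm_intensity_nonuniformity_normalized": float((by_gray ** 2).sum() / nz ** 2),
        "glszm_zone_size_nonuniformity_normalized": float((by_size ** 2).sum() / nz ** 2),
        "glszm_small_zone_emphasis": float((by_size / sizes ** 2).sum() / nz),
        "glszm_large_zone_emphasis": float((by_size * sizes ** 2).sum() / nz),
        "glszm_zone_percentage": float(nz / n_voxels),
    }
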