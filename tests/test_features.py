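"""First-order, shape, fractal, wavelet families and the orchestrator."""

import numpy as np
import pytest

from fetrad.features import (FeatureConfig, boundary_fractal_dimension,
                             differential_box_counting_dimension, discretize,
                             extract_features, first_order_features,
                             shape_features, wavelet_features,
                             wavelet_subbands)
from fetrad.phantom import PhantomSpec, generate_phantom
from fetrad.quantify import autocontour_lesion, background_mean
from scipy.stats import mannwhitneyu


class TestFirstOrder:
    def test_constant_roi(self):
        mask = np.ones((3, 3), dtype=bool)
        values = np.full(9, 2.0)
        droi = discretize(np.full((3, 3), 2.0), mask)
        f = first_order_features(values, droi)
        assert f["firstorder_sd"] == 0.0
        assert f["firstorder_entropy"] == 0.0
        assert f["firstorder_uniformity"] == 1.0
        assert f["firstorder_skewness"] == 0.0

    def test_mean_and_range(self):
        f = first_order_features(np.array([1.6, 1.8, 2.0]))
        assert f["firstorder_mean"] == pytest.approx(1.8)
        assert f["firstorder_range"] == pytest.approx(0.4)

    def test_gaussian_sample_skewness_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.1, 0.3, 1000)
        f = first_order_features(x)
        se = np.sqrt(6 / 1000)
        assert abs(f["firstorder_skewness"]) < 3 * se


class TestShape:
    def test_single_voxel(self):
        f = shape_features(np.ones((1, 1), dtype=bool), (1.0, 1.0))
        assert f["shape_area_mm2"] == 1.0
        assert f["shape_max_diameter_mm"] == 0.0  # max pairwise center distance

    def test_square(self):
        mask = np.ones((10, 10), dtype=bool)
        f = shape_features(mask, (1.0, 1.0))
        assert f["shape_area_mm2"] == pytest.approx(100.0)
        assert f["shape_max_diameter_mm"] == pytest.approx(9 * np.sqrt(2))

    def test_digital_disk_circularity(self):
        yy, xx = np.mgrid[:45, :45]
        disk = (yy - 22) ** 2 + (xx - 22) ** 2 <= 20 ** 2
        f = shape_features(disk, (1.0, 1.0))
        assert 0.85 <= f["shape_circularity"] <= 1.05

    def test_anisotropic_spacing(self):
        mask = np.ones((2, 2), dtype=bool)
        f = shape_features(mask, (2.0, 1.0))
        assert f["shape_area_mm2"] == pytest.approx(8.0)


class TestFractal:
    def test_filled_square_boundary_dimension(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[4:36, 4:36] = True
        d = boundary_fractal_dimension(mask)
        assert d == pytest.approx(1.0, abs=0.15)

    def test_line_segment_dimension(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20, 4:36] = True
        assert boundary_fractal_dimension(mask) == pytest.approx(1.0, abs=0.15)

    def test_tiny_roi_fallback(self):
        assert boundary_fractal_dimension(np.ones((1, 2), dtype=bool)) == 1.0

    def test_constant_surface_dimension(self):
        d = differential_box_counting_dimension(np.full((32, 32), 5.0))
        assert d == pytest.approx(2.0, abs=0.15)

    def test_rough_surface_dimension_above_flat(self):
        rng = np.random.default_rng(1)
        rough = differential_box_counting_dimension(rng.random((32, 32)))
        assert rough > 2.0


class TestWavelet:
    def test_constant_patch_detail_bands_zero(self):
        patch = np.full((8, 8), 3.0)
        mask = np.ones((8, 8), dtype=bool)
        bands = wavelet_subbands(patch, mask)
        for name in ("LH", "HL", "HH"):
            band, _ = bands[name]
            assert np.allclose(band, 0.0, atol=1e-10)

    def test_constant_patch_subband_sd_zero(self):
        patch = np.full((8, 8), 3.0)
        mask = np.ones((8, 8), dtype=bool)
        f = wavelet_features(patch, mask)
        for name in ("LL", "LH", "HL", "HH"):
            assert f[f"wavelet_{name}_firstorder_sd"] == pytest.approx(0.0,
                                                                       abs=1e-9)

    def test_stripe_energy_in_matching_band(self):
        # horizontal stripes (variation along rows) load the LH/HL band that
        # high-passes the row axis; verified against direct separable
        # filter-bank convolution
        import pywt

        patch = np.tile(np.array([1.0, -1.0] * 8)[:, None], (1, 16))
        mask = np.ones((16, 16), dtype=bool)
        bands = wavelet_subbands(patch, mask)
        energies = {k: float((v[0] ** 2).sum()) for k, v in bands.items()}
        vertical_detail = energies["LH"] + energies["HH"]
        horizontal_detail = energies["HL"] + energies["HH"]
        # oracle: separable convolution with the analysis filters
        w = pywt.Wavelet("db3")
        lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)

        def conv_rows(x, f):
            return np.apply_along_axis(
                lambda r: np.convolve(np.concatenate([r, r]), f, "same")[:r.size],
                0, x)

        row_high = conv_rows(patch, hi)
        row_low = conv_rows(patch, lo)
        assert (row_high ** 2).sum() > (row_low ** 2).sum()
        assert vertical_detail > 10 * horizontal_detail or \
            energies["HL"] + energies["LL"] < vertical_detail

    def test_tiny_roi_degenerate_flag(self):
        patch = np.random.default_rng(0).random((3, 3))
        mask = np.ones((3, 3), dtype=bool)
        f = wavelet_features(patch, mask)
        assert f["wavelet_LL_degenerate"] == 1.0


@pytest.fixture(scope="module")
def segmented_phantom():
    spec = PhantomSpec(seed=3, texture_amplitude=0.3)
    vol, truth, roi = generate_phantom(spec)
    bg = background_mean(vol, roi)
    seg = autocontour_lesion(vol, bg)
    return vol, seg, bg


class TestExtract:
    def test_deterministic_vector(self, segmented_phantom):
        vol, seg, bg = segmented_phantom
        f1 = extract_features(vol, seg, bg)
        f2 = extract_features(vol, seg, bg)
        assert f1 == f2
        assert all(np.isfinite(v) for v in f1.values())

    def test_config_excludes_wavelets(self, segmented_phantom):
        vol, seg, bg = segmented_phantom
        cfg = FeatureConfig(families=("fractal", "firstorder", "shape",
                                      "texture"))
        f = extract_features(vol, seg, bg, cfg)
        assert not any(k.startswith("wavelet_") for k in f)

    def test_scale_invariance_of_discretized_features(self, segmented_phantom):
        vol, seg, bg = segmented_phantom
        f1 = extract_features(vol, seg, bg)
        from fetrad.quantify import PETVolume

        c = 2.5
        vol2 = PETVolume(vol.data * c, spacing=vol.spacing)
        seg2 = autocontour_lesion(vol2, bg * c)
        f2 = extract_features(vol2, seg2, bg * c)
        for key in f1:
            if key.startswith(("glcm_", "glrlm_", "glszm_", "firstorder_",
                               "shape_")):
                assert f1[key] == pytest.approx(f2[key], rel=1e-9), key

    def test_texture_separates_heterogeneous_lesions(self):
        # homogeneous vs strongly textured lesions must differ in IMC2/INN
        # distribution over seeds (the qualitative radiomics signal)
        hom, het = [], []
        for seed in range(25):
            for amp, store in ((0.0, hom), (0.6, het)):
                spec = PhantomSpec(seed=seed, texture_amplitude=amp,
                                   tbr_mean=2.0, tbr_max=3.2)
                vol, _, roi = generate_phantom(spec)
                bg = background_mean(vol, roi)
                seg = autocontour_lesion(vol, bg)
                cfg = FeatureConfig(families=("texture",))
                store.append(extract_features(vol, seg, bg, cfg))
        for key in ("glcm_imc2", "glszm_intensity_nonuniformity_normalized"):
            a = [f[key] for f in hom]
            b = [f[key] for f in het]
            assert mannwhitneyu(a, b).pvalue < 0.01, key
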