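"""Quantification chain: SUV conversion, smoothing, segmentation, TBR."""

import numpy as np
import pytest

from fetrad.phantom import PhantomSpec, generate_phantom
from fetrad.quantify import (PETVolume, SubjectMeta, autocontour_lesion,
                             background_mean, compute_suv, compute_tbr,
                             harmonize, FWHM_TO_SIGMA)


class TestComputeSUV:
    def test_arithmetic_identity(self):
        vol = PETVolume(np.full((4, 4, 4), 3.0), units="kBq/ml")
        suv = compute_suv(vol, SubjectMeta(injected_mbq=210, weight_kg=70))
        assert np.allclose(suv.data, 1.0)
        assert suv.units == "SUV"

    def test_zero_volume(self):
        vol = PETVolume(np.zeros((3, 3, 3)), units="kBq/ml")
        assert np.all(compute_suv(vol, SubjectMeta(100, 80)).data == 0)

    @pytest.mark.parametrize("weight", [50.0, 70.0, 95.0])
    def test_weight_cancels_under_per_kg_dosing(self, weight):
        # 3 MBq/kg dosing: tissue at 6.3 kBq/ml gives SUV 2.1 at any weight
        vol = PETVolume(np.full((3, 3, 3), 6.3), units="kBq/ml")
        meta = SubjectMeta(injected_mbq=3.0 * weight, weight_kg=weight)
        assert np.allclose(compute_suv(vol, meta).data, 2.1)

    def test_double_conversion_rejected(self):
        vol = PETVolume(np.ones((3, 3, 3)), units="SUV")
        with pytest.raises(ValueError, match="already in SUV"):
            compute_suv(vol, SubjectMeta(100, 70))


class TestHarmonize:
    def test_impulse_normalization(self):
        data = np.zeros((41, 41, 41))
        data[20, 20, 20] = 1.0
        out = harmonize(PETVolume(data), 2.5)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_impulse_peak_matches_closed_form(self):
        # fine grid: discrete peak ~ continuous Gaussian density * voxel volume
        spacing = 0.25
        data = np.zeros((81, 81, 81))
        data[40, 40, 40] = 1.0
        out = harmonize(PETVolume(data, spacing=(spacing,) * 3), 2.5)
        sigma = 2.5 * FWHM_TO_SIGMA
        expected = (2 * np.pi * sigma ** 2) ** -1.5 * spacing ** 3
        assert out.data[40, 40, 40] == pytest.approx(expected, rel=0.01)

    def test_constant_volume_unchanged_interior(self):
        out = harmonize(PETVolume(np.ones((21, 21, 21))), 2.5)
        assert out.data[10, 10, 10] == pytest.approx(1.0, abs=1e-9)

    def test_invalid_kernel(self):
        with pytest.raises(ValueError):
            harmonize(PETVolume(np.ones((3, 3, 3))), 0.0)


class TestBackgroundMean:
    def test_mean_over_roi(self):
        data = np.ones((3, 3, 3))
        data[0, 0, 0], data[0, 0, 1], data[0, 0, 2] = 0.8, 1.0, 1.2
        roi = np.zeros((3, 3, 3), dtype=bool)
        roi[0, 0, :] = True
        assert background_mean(PETVolume(data), roi) == pytest.approx(1.0)

    def test_large_roi_recovers_population_mean(self):
        rng = np.random.default_rng(7)
        data = rng.normal(1.05, 0.1, (10, 10, 10))
        roi = np.ones((10, 10, 10), dtype=bool)
        se = 0.1 / np.sqrt(1000)
        assert abs(background_mean(PETVolume(data), roi) - 1.05) < 3 * se

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            background_mean(PETVolume(np.ones((3, 3, 3))),
                            np.zeros((3, 3, 3), dtype=bool))


class TestAutocontour:
    def test_plateau_component(self, volume_factory):
        plane = np.ones((5, 5))
        plane[1:3, 1:3] = 2.0
        vol = volume_factory(plane)
        seg = autocontour_lesion(vol, background=1.0)
        assert seg.n_voxels == 4
        assert seg.threshold == 1.6
        assert seg.slice_index == 1

    def test_disjoint_blob_excluded(self, volume_factory):
        # two supra-threshold blobs; only the one holding the max is returned
        plane = np.ones((7, 7))
        plane[1, 1] = 2.5            # blob A holds the global max
        plane[5, 5:7] = 2.0          # blob B
        vol = volume_factory(plane)
        seg = autocontour_lesion(vol, background=1.0)
        assert seg.n_voxels == 1
        assert seg.mask[3, 3]  # plane offset by 2 in the padded grid
        values = seg.values(vol)
        assert values.tolist() == [2.5]

    def test_no_lesion_signal(self):
        vol = PETVolume(np.ones((4, 4, 4)))
        assert autocontour_lesion(vol, background=1.0) is None

    def test_max_tie_lowest_linear_index(self):
        data = np.ones((4, 4, 4))
        data[1, 1, 1] = 2.0
        data[2, 2, 2] = 2.0
        seg = autocontour_lesion(PETVolume(data), background=1.0)
        assert seg.max_index == (1, 1, 1)

    def test_scale_equivariance(self, volume_factory):
        rng = np.random.default_rng(3)
        plane = 1.0 + rng.random((6, 6))
        plane[2:4, 2:4] += 1.5
        vol = volume_factory(plane)
        seg1 = autocontour_lesion(vol, background=1.0)
        vol2 = PETVolume(vol.data * 3.7, spacing=vol.spacing)
        seg2 = autocontour_lesion(vol2, background=3.7)
        assert np.array_equal(seg1.mask, seg2.mask)
        t1 = compute_tbr(seg1, vol, 1.0)
        t2 = compute_tbr(seg2, vol2, 3.7)
        assert t1.tbr_mean == pytest.approx(t2.tbr_mean)
        assert t1.tbr_max == pytest.approx(t2.tbr_max)

    def test_threshold_monotonicity(self, volume_factory):
        rng = np.random.default_rng(5)
        plane = 1.0 + rng.random((8, 8)) * 2.0
        plane[4, 4] = 4.0
        vol = volume_factory(plane)
        prev = None
        for thr in (1.6, 1.8, 2.0, 2.4):
            seg = autocontour_lesion(vol, background=1.0, threshold=thr)
            if prev is not None:
                assert seg.mask.sum() <= prev
                # raising the threshold never adds voxels
            prev = seg.mask.sum()


class TestComputeTBR:
    def test_mean_and_max(self, volume_factory):
        plane = np.ones((4, 4))
        plane[1, 1], plane[1, 2] = 2.0, 3.2
        vol = volume_factory(plane)
        seg = autocontour_lesion(vol, background=1.0)
        t = compute_tbr(seg, vol, 1.0)
        assert t.tbr_mean == pytest.approx(2.6)
        assert t.tbr_max == pytest.approx(3.2)

    def test_threshold_boundary(self, volume_factory):
        plane = np.ones((4, 4))
        plane[1:3, 1] = 1.6
        vol = volume_factory(plane)
        seg = autocontour_lesion(vol, background=1.0)
        t = compute_tbr(seg, vol, 1.0)
        assert t.tbr_mean == pytest.approx(1.6)
        assert t.tbr_max == pytest.approx(1.6)

    def test_member_below_threshold_rejected(self, volume_factory):
        plane = np.ones((4, 4))
        plane[1, 1], plane[1, 2] = 2.0, 4.0
        vol = volume_factory(plane)
        seg = autocontour_lesion(vol, background=1.0)
        # re-evaluating the same contour against double the background
        # violates the membership invariant and must raise
        with pytest.raises(ValueError, match="below threshold"):
            compute_tbr(seg, vol, background=2.0)

    def test_summary_invariant(self):
        from fetrad.quantify import TBRSummary

        with pytest.raises(ValueError):
            TBRSummary(tbr_mean=2.0, tbr_max=1.8)
        with pytest.raises(ValueError):
            TBRSummary(tbr_mean=1.2, tbr_max=1.4)


class TestPhantomRoundTrip:
    def test_noise_free_contour_equals_truth_slice(self):
        spec = PhantomSpec(seed=11, noise_sd=0.0, texture_amplitude=0.4)
        vol, truth, roi = generate_phantom(spec)
        bg = background_mean(vol, roi)
        seg = autocontour_lesion(vol, bg)
        assert np.array_equal(seg.mask3d(vol.data.shape),
                              truth & seg.mask3d(vol.data.shape))
        sl = [slice(None)] * 3
        sl[seg.axis] = seg.slice_index
        assert np.array_equal(seg.mask, truth[tuple(sl)])

    def test_target_tbr_recovered(self):
        spec = PhantomSpec(seed=2, noise_sd=0.0, tbr_max=3.0, tbr_mean=2.0,
                           texture_amplitude=0.0)
        vol, truth, roi = generate_phantom(spec)
        assert vol.data.max() == pytest.approx(3.0)
        bg = background_mean(vol, roi)
        seg = autocontour_lesion(vol, bg)
        t = compute_tbr(seg, vol, bg)
        assert t.tbr_max == pytest.approx(3.0)
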