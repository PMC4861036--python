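"""The six metabolic metrics: exact cases, oracles and scaling properties."""

import numpy as np
import pytest

import petresponse as pr
from petresponse.metrics import peak_sphere_offsets
from petresponse.volume import LesionVOI

from conftest import make_sphere_pair, true_sphere_mask


def voi_from_mask(mask, seed, lesion_id="L1"):
    return LesionVOI(lesion_id=lesion_id, organ="node", seed=seed, mask=mask)


@pytest.fixture
def segmented_sphere(sphere_pair, center_seed):
    baseline, _, _ = sphere_pair
    return baseline, pr.segment_lesion(baseline, center_seed)


class TestSuvMax:
    def test_uniform_lesion(self, segmented_sphere):
        baseline, voi = segmented_sphere
        assert pr.suv_max(baseline, voi) == pytest.approx(10.0)

    def test_matches_brute_force_on_noisy_volume(self, rng):
        baseline, _, _ = make_sphere_pair(noise_sigma=0.2, psf_fwhm=6.0, seed=5)
        voi = pr.segment_lesion(baseline, (23, 23, 23))
        brute = max(baseline.values[i, j, k] for i, j, k in np.argwhere(voi.mask))
        assert pr.suv_max(baseline, voi) == pytest.approx(brute)

    def test_single_voxel_mask(self):
        values = np.full((31, 31, 31), 1.0)
        values[15, 15, 15] = 11.8
        vol = pr.PETVolume(values, spacing=(2, 2, 2))
        mask = np.zeros_like(values, dtype=bool)
        mask[15, 15, 15] = True
        assert pr.suv_max(vol, voi_from_mask(mask, (15, 15, 15))) == pytest.approx(11.8)


class TestSuvPeak:
    def test_constant_field_returns_constant(self):
        values = np.full((31, 31, 31), 5.0)
        vol = pr.PETVolume(values, spacing=(2, 2, 2))
        mask = np.zeros_like(values, dtype=bool)
        mask[15, 15, 15] = True
        assert pr.suv_peak(vol, voi_from_mask(mask, (15, 15, 15))) == pytest.approx(5.0)

    def test_single_hot_voxel_matches_rasterization_oracle(self):
        # peak = hot value diluted over the rasterized 1 cm^3 sphere
        values = np.zeros((31, 31, 31))
        values[15, 15, 15] = 100.0
        vol = pr.PETVolume(values, spacing=(2, 2, 2))
        mask = np.zeros_like(values, dtype=bool)
        mask[15, 15, 15] = True
        n_sphere = len(peak_sphere_offsets((2, 2, 2)))
        expected = 100.0 / n_sphere  # ~0.8 for 2 mm voxels
        peak = pr.suv_peak(vol, voi_from_mask(mask, (15, 15, 15)))
        assert peak == pytest.approx(expected)
        assert peak == pytest.approx(0.8, abs=0.02)

    def test_peak_never_exceeds_volume_max_on_random_fields(self, rng):
        # the peak sphere may extend beyond the mask, so the bound is the
        # volume-wide maximum; the mask-wise ordering holds for lesions that
        # contain the sphere (covered by the phantom ordering test)
        for _ in range(25):
            values = rng.gamma(2.0, 1.5, size=(24, 24, 24))
            vol = pr.PETVolume(values, spacing=(3, 3, 3))
            mask = np.zeros_like(values, dtype=bool)
            center = tuple(rng.integers(8, 16, size=3))
            mask[center] = True
            voi = voi_from_mask(mask, center)
            assert pr.suv_peak(vol, voi) <= values.max() + 1e-12

    def test_peak_below_mask_max_when_sphere_inside_lesion(self):
        baseline, _, _ = make_sphere_pair(psf_fwhm=6.0, noise_sigma=0.1, seed=11)
        voi = pr.segment_lesion(baseline, (23, 23, 23))
        assert pr.suv_peak(baseline, voi) <= pr.suv_max(baseline, voi) + 1e-12

    def test_sphere_larger_than_volume_rejected(self):
        vol = pr.PETVolume(np.ones((4, 4, 4)), spacing=(2, 2, 2))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[2, 2, 2] = True
        with pytest.raises(ValueError, match="sphere"):
            pr.suv_peak(vol, voi_from_mask(mask, (2, 2, 2)))


class TestMeanMvTlg:
    def test_mv_from_voxel_count(self):
        values = np.full((20, 20, 20), 1.0)
        vol = pr.PETVolume(values, spacing=(2, 2, 2))
        mask = np.zeros_like(values, dtype=bool)
        mask[5:10, 5:10, 5:9] = True  # 100 voxels at 8 mm^3
        mean, mv, tlg = pr.suv_mean_mv_tlg(vol, voi_from_mask(mask, (5, 5, 5)))
        assert mv == pytest.approx(0.8)
        assert tlg == pytest.approx(mean * mv)

    def test_uniform_lesion_mean_equals_max(self, segmented_sphere):
        baseline, voi = segmented_sphere
        mean, _, _ = pr.suv_mean_mv_tlg(baseline, voi)
        assert mean == pytest.approx(pr.suv_max(baseline, voi))


class TestSam:
    def test_closed_form_on_noiseless_sphere(self, segmented_sphere):
        baseline, voi = segmented_sphere
        sphere_ml = voi.n_voxels * baseline.voxel_volume_ml
        expected = (10.0 - 2.0) * sphere_ml
        assert pr.sam(baseline, voi) == pytest.approx(expected, rel=1e-6)

    def test_background_only_region_is_near_zero(self):
        baseline, _, _ = make_sphere_pair(grid=64, noise_sigma=0.1, psf_fwhm=0.0, seed=2)
        mask = np.zeros(baseline.shape, dtype=bool)
        mask[8:12, 8:12, 8:12] = True  # far from the lesion
        value = pr.sam(baseline, voi_from_mask(mask, (9, 9, 9)))
        assert abs(value) < 0.5  # SUV*mL, pure noise scale

    def test_sam_margin_insensitive_once_psf_captured(self, center_seed):
        # partial-volume robustness: SAM barely moves with the dilation margin
        # provided the margin reaches the PSF footprint (FWHM 6 mm here)
        baseline, _, _ = make_sphere_pair(radius=8.0, psf_fwhm=6.0)
        voi = pr.segment_lesion(baseline, center_seed)
        sams = [pr.sam(baseline, voi, margin_mm=m) for m in (6.0, 8.0, 10.0, 12.0)]
        spread = (max(sams) - min(sams)) / abs(sams[1])
        assert spread < 0.05

    def test_partial_volume_bias_smaller_than_tlg(self):
        # lesion diameter 16 mm vs FWHM 6 mm; truth from the unblurred scene
        radius, suv, bg = 8.0, 10.0, 2.0
        sharp, _, _ = make_sphere_pair(radius=radius, suv_t1=suv, psf_fwhm=0.0)
        blurred, _, _ = make_sphere_pair(radius=radius, suv_t1=suv, psf_fwhm=6.0)
        true_mask = true_sphere_mask(sharp, sharp.physical_center, radius)
        true_excess = (suv - bg) * true_mask.sum() * sharp.voxel_volume_ml
        true_tlg = suv * true_mask.sum() * sharp.voxel_volume_ml
        voi = pr.segment_lesion(blurred, (23, 23, 23))
        _, _, tlg = pr.suv_mean_mv_tlg(blurred, voi)
        sam_val = pr.sam(blurred, voi)
        sam_err = abs(sam_val - true_excess) / true_excess
        tlg_err = abs(tlg - true_tlg) / true_tlg
        assert sam_err < tlg_err


class TestComputeAll:
    def test_fields_match_individual_operations(self, segmented_sphere):
        baseline, voi = segmented_sphere
        m = pr.compute_all(baseline, voi)
        mean, mv, tlg = pr.suv_mean_mv_tlg(baseline, voi)
        assert m.suv_max == pytest.approx(pr.suv_max(baseline, voi))
        assert m.suv_peak == pytest.approx(pr.suv_peak(baseline, voi))
        assert m.suv_mean == pytest.approx(mean)
        assert m.mv == pytest.approx(mv)
        assert m.tlg == pytest.approx(tlg)
        assert m.sam == pytest.approx(pr.sam(baseline, voi))

    def test_ordering_invariant_on_phantom_lesions(self):
        baseline, _, _ = make_sphere_pair(psf_fwhm=6.0, noise_sigma=0.1, seed=7)
        voi = pr.segment_lesion(baseline, (23, 23, 23))
        m = pr.compute_all(baseline, voi)
        assert m.suv_mean <= m.suv_peak <= m.suv_max

    def test_intensity_scaling_equivariance(self):
        baseline, _, _ = make_sphere_pair(psf_fwhm=6.0, noise_sigma=0.1, seed=3)
        voi = pr.segment_lesion(baseline, (23, 23, 23))
        m1 = pr.compute_all(baseline, voi)
        k = 2.5
        m2 = pr.compute_all(baseline.with_values(baseline.values * k), voi)
        for name in ("suv_max", "suv_peak", "suv_mean", "tlg", "sam"):
            assert m2.value(name) == pytest.approx(k * m1.value(name), rel=1e-9)
        assert m2.mv == pytest.approx(m1.mv)

    def test_invalid_metrics_rejected(self):
        with pytest.raises(ValueError, match="SUVpeak"):
            pr.LesionMetrics("a", "f", suv_max=5.0, suv_peak=6.0, suv_mean=4.0,
                             mv=1.0, tlg=4.0, sam=1.0)
        with pytest.raises(ValueError, match="TLG"):
            pr.LesionMetrics("a", "f", suv_max=5.0, suv_peak=5.0, suv_mean=4.0,
                             mv=2.0, tlg=7.0, sam=1.0)
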