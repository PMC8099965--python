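import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hybridose.calibration import CameraConfig
from hybridose.phantom import PhantomSpec, build_phantom, simulate_planar_study
from hybridose.planar import (
    TransmissionMap,
    background_correct,
    conjugate_view_activity,
    coregister_planar,
    partial_organ_extrapolate,
    quantify_planar_study,
    scatter_correct,
    self_attenuation_factor,
    threshold_segment,
)
from hybridose.workbench import make_planar_rois

from conftest import box_organ


class TestScatterCorrect:
    def test_zero_scatter_is_identity(self):
        pk = np.full((4, 4), 123.0)
        assert np.array_equal(scatter_correct(pk, np.zeros((4, 4)), 41.6, 28.05), pk)

    def test_dual_energy_window_arithmetic(self, camera):
        # 1000 - 100 * (41.6 / 28.05)
        out = scatter_correct(
            np.array([[1000.0]]), np.array([[100.0]]),
            camera.photopeak_width_kev, camera.scatter_width_kev,
        )
        assert out[0, 0] == pytest.approx(1000.0 - 100.0 * 41.6 / 28.05, rel=1e-12)
        assert out[0, 0] == pytest.approx(851.69, abs=0.01)

    def test_floored_at_zero_and_validates(self):
        out = scatter_correct(np.array([[10.0]]), np.array([[100.0]]), 41.6, 28.05)
        assert out[0, 0] == 0.0
        with pytest.raises(ValueError):
            scatter_correct(np.array([[-1.0]]), np.array([[0.0]]), 41.6, 28.05)

    def test_simulated_scatter_removed_exactly(self, slab_phantom):
        cam = CameraConfig(planar_psf_sigma_mm=0.0)  # scatter on, blur off
        study = simulate_planar_study(slab_phantom, [24.0], cam, noise=False)
        fr = study.frames[0]
        primary = scatter_correct(
            fr.anterior_pk, fr.anterior_sc, cam.photopeak_width_kev, cam.scatter_width_kev
        )
        clean = simulate_planar_study(
            slab_phantom, [24.0],
            CameraConfig(planar_psf_sigma_mm=0.0, scatter_fraction=0.0), noise=False,
        ).frames[0].anterior_pk
        assert primary == pytest.approx(clean, rel=1e-9)


class TestThresholdSegment:
    def test_uniform_organ_on_zero_background(self):
        img = np.zeros((20, 20))
        img[5:10, 5:10] = 7.0
        boundary = np.zeros((20, 20), bool)
        boundary[3:12, 3:12] = True
        mask = threshold_segment(img, img, boundary, 0.5)
        assert np.array_equal(mask, img > 0)

    def test_mask_shrinks_monotonically_with_fraction(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 10, (16, 16))
        boundary = np.ones((16, 16), bool)
        sizes = [threshold_segment(img, img, boundary, f).sum() for f in (0.2, 0.5, 0.8)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_blurred_disc_half_threshold_area(self):
        from scipy.ndimage import gaussian_filter

        n = 64
        rr, cc = np.ogrid[:n, :n]
        disc = ((rr - 32) ** 2 + (cc - 32) ** 2 <= 10**2).astype(float)
        img = gaussian_filter(disc, 2.0)
        mask = threshold_segment(img, img, np.ones((n, n), bool), 0.5)
        assert mask.sum() == pytest.approx(disc.sum(), rel=0.10)

    def test_empty_result_rejected(self):
        img = np.zeros((4, 4))
        img[0, 0] = 1.0
        boundary = np.zeros((4, 4), bool)
        boundary[3, 3] = True
        with pytest.raises(ValueError):
            threshold_segment(img, img, boundary, 0.5)


class TestBackgroundCorrect:
    def test_zero_background_identity(self):
        assert background_correct(1000.0, 0.0, 10, 100) == 1000.0

    def test_scaling_to_organ_pixels(self):
        assert background_correct(10000.0, 50.0, 50, 100) == 9900.0

    def test_floor_at_zero(self):
        assert background_correct(10.0, 1000.0, 10, 100) == 0.0


class TestConjugateView:
    def test_no_attenuation_limit(self):
        tmap = TransmissionMap(np.ones((4, 4)), np.zeros((4, 4)), 0.11)
        mask = np.ones((4, 4), bool)
        a = conjugate_view_activity(400.0, 100.0, tmap, mask, 0.0, 0.11, 1.0)
        assert a == pytest.approx(np.sqrt(400.0 * 100.0), rel=1e-12)

    def test_self_attenuation_factor_value(self):
        # f(mu=0.11/cm, t=4cm) = 0.22/sinh(0.22)
        assert self_attenuation_factor(0.11, 4.0) == pytest.approx(0.992, abs=5e-4)
        assert self_attenuation_factor(0.11, 1e-12) == 1.0

    def test_slab_phantom_recovery_within_1pct(self, slab_phantom, sharp_camera):
        study = simulate_planar_study(slab_phantom, [24.0, 48.0, 96.0], sharp_camera,
                                      noise=False)
        rois, thick = make_planar_rois(slab_phantom, ["slab"])
        tacs = quantify_planar_study(study, rois, thick, register=False)
        for i, t in enumerate([24.0, 48.0, 96.0]):
            truth = slab_phantom.organ_activity_mbq("slab", t)
            assert tacs["slab"].activities_mbq[i] == pytest.approx(truth, rel=0.01)

    def test_estimate_invariant_to_source_depth(self, sharp_camera):
        # geometric-mean property: only total body thickness matters
        estimates = []
        for depth in (4.0, 8.0, 12.0):
            organ = box_organ("s", 200.0, 100.0, 18.0, 15.0, depth=depth, thickness=4.0)
            ph = build_phantom(PhantomSpec(organs=(organ,), background_density_mbq_ml=0.0,
                                           seed=0))
            study = simulate_planar_study(ph, [24.0, 48.0], sharp_camera, noise=False)
            rois, thick = make_planar_rois(ph, ["s"])
            tacs = quantify_planar_study(study, rois, thick, register=False)
            estimates.append(tacs["s"].activities_mbq[0])
        assert np.ptp(estimates) / np.mean(estimates) < 0.002

    def test_nonpositive_transmission_rejected(self):
        tmap = TransmissionMap(np.zeros((2, 2)), np.zeros((2, 2)), 0.11)
        with pytest.raises(ValueError):
            conjugate_view_activity(1.0, 1.0, tmap, np.ones((2, 2), bool), 1.0, 0.11, 1.0)


class TestPartialOrganExtrapolation:
    def test_identity_and_arithmetic(self):
        assert partial_organ_extrapolate(4500.0, 1.0) == 4500.0
        assert partial_organ_extrapolate(4500.0, 0.75) == 6000.0

    @given(st.floats(1e-3, 1.0), st.floats(0.0, 1e6))
    def test_scales_inversely_with_fraction(self, vf, counts):
        assert partial_organ_extrapolate(counts, vf) == pytest.approx(counts / vf)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            partial_organ_extrapolate(1.0, 0.0)

    def test_overlapped_organ_recovered_within_5pct(self, sharp_camera):
        organs = (
            box_organ("kidney", 150.0, 100.0, 26.0, 21.5, depth=11.0),
            box_organ("gut", 120.0, 80.0, 26.0, 21.5, depth=5.0,
                      overlap_partner=("kidney", 0.3)),
        )
        ph = build_phantom(PhantomSpec(organs=organs, background_density_mbq_ml=0.0, seed=1))
        study = simulate_planar_study(ph, [24.0, 48.0], sharp_camera, noise=False)
        rois, thick = make_planar_rois(ph, ["kidney"])
        tacs = quantify_planar_study(study, rois, thick, register=False)
        truth = ph.organ_activity_mbq("kidney", 24.0)
        assert tacs["kidney"].activities_mbq[0] == pytest.approx(truth, rel=0.05)


class TestCoregistration:
    def test_known_shift_recovered(self, slab_phantom, camera):
        study = simulate_planar_study(
            slab_phantom, [24.0, 48.0], camera, noise=False, shifts=[(0, 0), (3, -2)]
        )
        _, shifts = coregister_planar(study)
        assert shifts == [(0, 0), (-3, 2)]

    def test_zero_shift_identity(self, slab_phantom, camera):
        study = simulate_planar_study(slab_phantom, [24.0, 48.0], camera, noise=False)
        aligned, shifts = coregister_planar(study)
        assert shifts == [(0, 0), (0, 0)]
        assert np.array_equal(aligned.frames[1].anterior_pk, study.frames[1].anterior_pk)

    def test_shift_recovered_within_one_pixel_under_noise(self, slab_phantom, camera):
        study = simulate_planar_study(
            slab_phantom, [24.0, 48.0], camera, noise=True, seed=9, shifts=[(0, 0), (4, 5)]
        )
        _, shifts = coregister_planar(study)
        # the correction undoes the applied (4, 5) repositioning
        assert abs(shifts[1][0] + 4) <= 1 and abs(shifts[1][1] + 5) <= 1


class TestFullChain:
    def test_overlap_free_noiseless_recovery_within_2pct(self, multi_organ_box_phantom,
                                                         sharp_camera):
        ph = multi_organ_box_phantom
        study = simulate_planar_study(ph, [24.0, 48.0, 96.0], sharp_camera, noise=False)
        regions = list(ph.organs)
        rois, thick = make_planar_rois(ph, regions)
        tacs = quantify_planar_study(study, rois, thick, register=False)
        for name in regions:
            for i, t in enumerate([24.0, 48.0, 96.0]):
                truth = ph.organ_activity_mbq(name, t)
                assert tacs[name].activities_mbq[i] == pytest.approx(truth, rel=0.02), name

    def test_overlapping_lesions_excluded_from_2d(self):
        from hybridose.workbench import _eligible_for_2d

        organs = (
            box_organ("liver", 1500.0, 150.0, 10.0, 19.0, depth=2.5, thickness=10.0,
                      region_class="liver"),
            box_organ("lesion_0", 6.0, 12.0, 10.0, 19.0, depth=14.0, thickness=2.0,
                      overlap_partner=("liver", 0.7), region_class="lesion"),
            box_organ("lesion_1", 6.0, 12.0, 33.0, 15.0, depth=14.0, thickness=2.0,
                      region_class="lesion"),
        )
        ph = build_phantom(PhantomSpec(organs=organs, seed=0))
        assert not _eligible_for_2d(ph, "lesion_0")
        assert _eligible_for_2d(ph, "lesion_1")
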