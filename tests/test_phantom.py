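import numpy as np
import pytest

from hybridose.calibration import CameraConfig, recovery_coefficient
from hybridose.dosimetry import default_dose_factor_table
from hybridose.nuclide import LU177_LAMBDA_PHYS
from hybridose.phantom import (
    ConfigurationError,
    OrganSpec,
    PhantomSpec,
    build_phantom,
    measure_system_rc_table,
    simulate_planar_study,
    simulate_spect_study,
    true_absorbed_dose,
)
from hybridose.workbench import DEFAULT_SPECT_PSF_SIGMA_MM

from conftest import box_organ

LAM = LU177_LAMBDA_PHYS


def single_sphere_spec(volume_ml=20.0, uptake=100.0, bg=0.0, seed=0, lam=LAM):
    organ = OrganSpec("sphere", volume_ml, uptake, lam, 8.0, 18.0, 15.0,
                      region_class="lesion")
    return PhantomSpec(
        organs=(organ,), grid_shape=(48, 80, 64), background_density_mbq_ml=bg, seed=seed
    )


class TestBuildPhantom:
    def test_volume_conservation_within_discretisation(self):
        ph = build_phantom(single_sphere_spec(20.0))
        vol = ph.organs["sphere"].volume_ml
        # voxelised sphere volume matches the requested volume up to the
        # surface-voxel quantisation at 4.66 mm
        assert vol == pytest.approx(20.0, rel=0.10)
        # uptake is exact regardless of quantisation
        assert ph.organ_activity_mbq("sphere", 0.0) == pytest.approx(100.0, rel=1e-12)

    def test_seeded_determinism_bit_identical(self):
        spec = single_sphere_spec(bg=0.01, seed=5)
        a, b = build_phantom(spec), build_phantom(spec)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.background_mbq_per_voxel, b.background_mbq_per_voxel)

    def test_declared_overlap_shares_requested_footprint_fraction(self):
        organs = (
            box_organ("kidney", 150.0, 100.0, 26.0, 21.5, depth=11.0),
            box_organ("gut", 120.0, 80.0, 26.0, 21.5, depth=5.0,
                      overlap_partner=("kidney", 0.3)),
        )
        ph = build_phantom(PhantomSpec(organs=organs, seed=1))
        fp_k = ph.organs["kidney"].footprint
        fp_g = ph.organs["gut"].footprint
        shared = (fp_k & fp_g).sum()
        smaller = min(fp_k.sum(), fp_g.sum())
        assert shared / smaller == pytest.approx(0.3, abs=0.05)
        assert ph.organs["kidney"].visible_fraction == pytest.approx(
            1 - shared / fp_k.sum(), abs=1e-9
        )

    def test_undeclared_3d_collision_rejected(self):
        organs = (
            box_organ("a", 100.0, 10.0, 18.0, 15.0, depth=6.0),
            box_organ("b", 100.0, 10.0, 18.0, 15.0, depth=6.0),
        )
        with pytest.raises(ConfigurationError, match="collides"):
            build_phantom(PhantomSpec(organs=organs, seed=0))

    def test_lambda_slower_than_physical_rejected(self):
        with pytest.raises(ConfigurationError, match="physical decay"):
            OrganSpec("x", 10.0, 1.0, LAM / 2, 5.0, 10.0, 10.0)

    def test_activity_conservation(self):
        spec = single_sphere_spec(bg=0.01, lam=2 * LAM, seed=2)
        ph = build_phantom(spec)
        for t in (0.0, 24.0, 96.0):
            expected = 100.0 * np.exp(-2 * LAM * t) + ph.background_activity_mbq(t)
            assert ph.activity_at(t).sum() == pytest.approx(expected, rel=1e-9)
            assert ph.total_activity_mbq(t) == pytest.approx(expected, rel=1e-9)


class TestPlanarSimulation:
    def test_symmetric_phantom_equal_ap_counts(self, sharp_camera):
        # organ centred in body depth: anterior and posterior views identical
        organ = box_organ("c", 100.0, 50.0, 18.0, 15.0, depth=8.0, thickness=4.0)
        ph = build_phantom(PhantomSpec(organs=(organ,), body_thickness_cm=20.0,
                                       background_density_mbq_ml=0.0, seed=0))
        study = simulate_planar_study(ph, [24.0], sharp_camera, noise=False)
        assert study.frames[0].anterior_pk.sum() == pytest.approx(
            study.frames[0].posterior_pk.sum(), rel=1e-12
        )

    def test_physical_decay_ratio_between_time_points(self):
        cam = CameraConfig(scan_speed_cm_min=(15.0, 15.0, 15.0), scatter_fraction=0.0,
                           planar_psf_sigma_mm=0.0)
        ph = build_phantom(single_sphere_spec(lam=LAM))
        study = simulate_planar_study(ph, [24.0, 48.0, 96.0], cam, noise=False)
        r = study.frames[2].anterior_pk.sum() / study.frames[0].anterior_pk.sum()
        assert r == pytest.approx(np.exp(-LAM * 72.0), rel=1e-9)

    def test_geometric_mean_proportional_to_activity_without_attenuation(self):
        organs = (
            box_organ("a", 100.0, 30.0, 10.0, 15.0, depth=4.0),
            box_organ("b", 100.0, 90.0, 26.0, 15.0, depth=12.0),
        )
        spec = PhantomSpec(organs=organs, mu_208_per_cm=0.0,
                           background_density_mbq_ml=0.0, seed=0)
        ph = build_phantom(spec)
        cam = CameraConfig(scatter_fraction=0.0, planar_psf_sigma_mm=0.0)
        study = simulate_planar_study(ph, [24.0], cam, noise=False)
        gm = np.sqrt(study.frames[0].anterior_pk * study.frames[0].posterior_pk)
        sums = [gm[ph.organs[n].footprint].sum() for n in ("a", "b")]
        assert sums[1] / sums[0] == pytest.approx(3.0, rel=1e-9)

    def test_uniform_slab_attenuation_product(self, slab_phantom, sharp_camera):
        # anterior x posterior counts carry exactly exp(-mu * D)
        study = simulate_planar_study(slab_phantom, [24.0], sharp_camera, noise=False)
        fr = study.frames[0]
        fp = slab_phantom.organs["slab"].footprint
        c_a, c_p = fr.anterior_pk[fp].sum(), fr.posterior_pk[fp].sum()
        mu = slab_phantom.spec.mu_208_per_cm
        d_total = slab_phantom.body_thickness_actual_cm
        a_true = slab_phantom.organ_activity_mbq("slab", 24.0)
        cf = sharp_camera.planar_sensitivity_cps_per_mbq * sharp_camera.dwell_time_s(0)
        t_o = slab_phantom.organs["slab"].thickness_cm
        x = mu * t_o / 2
        f_src = np.sinh(x) / x  # extended-source factor picked up by the GM
        assert c_a * c_p == pytest.approx(
            (cf * a_true * f_src) ** 2 * np.exp(-mu * d_total), rel=1e-3
        )

    def test_empty_times_rejected(self, slab_phantom, camera):
        with pytest.raises(ValueError):
            simulate_planar_study(slab_phantom, [], camera)

    def test_seeded_noise_determinism(self, slab_phantom, camera):
        s1 = simulate_planar_study(slab_phantom, [24.0, 48.0], camera, noise=True, seed=3)
        s2 = simulate_planar_study(slab_phantom, [24.0, 48.0], camera, noise=True, seed=3)
        assert np.array_equal(s1.frames[1].anterior_pk, s2.frames[1].anterior_pk)
        assert np.array_equal(s1.blank, s2.blank)


class TestSpectSimulation:
    def test_no_blur_recovers_truth_exactly(self, camera):
        ph = build_phantom(single_sphere_spec())
        study = simulate_spect_study(ph, [24.0], 0.0, camera, noise=False)
        act = study.volumes_cps[0] / camera.spect_sensitivity_cps_per_mbq
        mask = ph.organs["sphere"].mask
        assert act[mask].sum() == pytest.approx(ph.organ_activity_mbq("sphere", 24.0), rel=1e-12)

    def test_linearity_in_activity(self, camera):
        ph1 = build_phantom(single_sphere_spec(uptake=100.0))
        ph2 = build_phantom(single_sphere_spec(uptake=200.0))
        s1 = simulate_spect_study(ph1, [24.0], 5.0, camera, noise=False)
        s2 = simulate_spect_study(ph2, [24.0], 5.0, camera, noise=False)
        assert s2.volumes_cps[0].sum() == pytest.approx(2 * s1.volumes_cps[0].sum(), rel=1e-12)

    def test_blur_recovery_consistent_with_system_rc_table(self, camera):
        """A 20 ml sphere measured through the pipeline matches the system
        RC table entry at its estimated volume (the fixture calibration
        contract) within +/-0.03."""
        from hybridose.spect import segment_voi_adaptive

        table = measure_system_rc_table(DEFAULT_SPECT_PSF_SIGMA_MM)
        ph = build_phantom(single_sphere_spec(20.0))
        study = simulate_spect_study(ph, [24.0], DEFAULT_SPECT_PSF_SIGMA_MM, camera, noise=False)
        act = study.volumes_cps[0] / camera.spect_sensitivity_cps_per_mbq
        from scipy.ndimage import binary_dilation

        boundary = binary_dilation(ph.organs["sphere"].mask, iterations=3)
        seg, vol_est = segment_voi_adaptive(act, boundary, study.voxel_mm)
        recovery = act[seg].sum() / ph.organ_activity_mbq("sphere", 24.0)
        assert recovery == pytest.approx(recovery_coefficient(vol_est, table), abs=0.03)


class TestSystemRcTable:
    def test_monotone_and_bounded(self):
        table = measure_system_rc_table(DEFAULT_SPECT_PSF_SIGMA_MM)
        recs = np.asarray(table.recoveries)
        assert np.all(np.diff(recs) >= 0)
        assert np.all((recs > 0) & (recs <= 1.0))
        vols = np.asarray(table.volumes_ml)
        assert np.all(np.diff(vols) > 0)

    def test_self_consistency_on_fresh_spheres(self):
        """Re-measuring independently placed spheres reproduces the table
        within +/-0.03 at each volume."""
        from scipy.ndimage import gaussian_filter

        from hybridose.spect import segment_voi_adaptive

        sigma = DEFAULT_SPECT_PSF_SIGMA_MM
        table = measure_system_rc_table(sigma)
        vox = 4.66
        for v in (6.0, 20.0, 150.0):
            radius = (3 * v * 1000 / (4 * np.pi)) ** (1 / 3)
            half = radius + 4 * sigma + 15.0
            n = 2 * int(np.ceil(half / vox)) + 3
            c = (n - 1) / 2.0
            ax = np.arange(n)
            zz = (ax[:, None, None] - c - 0.13) * vox
            yy = (ax[None, :, None] - c + 0.41) * vox
            xx = (ax[None, None, :] - c - 0.35) * vox
            r = np.sqrt(zz**2 + yy**2 + xx**2)
            mask = r <= radius
            blurred = gaussian_filter(mask.astype(float), sigma / vox)
            seg, vol_est = segment_voi_adaptive(blurred, r <= radius + 15.0, vox)
            rec = blurred[seg].sum() / mask.sum()
            assert rec == pytest.approx(recovery_coefficient(vol_est, table), abs=0.03)

    def test_zero_blur_gives_unit_recovery(self):
        table = measure_system_rc_table(0.0)
        assert table.recoveries == (1.0,)


class TestGroundTruth:
    def test_analytic_tia(self):
        ph = build_phantom(single_sphere_spec(uptake=100.0, lam=0.01))
        gt = true_absorbed_dose(ph, default_dose_factor_table())
        assert gt.tia_mbq_h["sphere"] == pytest.approx(10000.0, rel=1e-12)

    def test_physical_decay_only_tia_factor(self):
        ph = build_phantom(single_sphere_spec(uptake=1.0, lam=LAM))
        gt = true_absorbed_dose(ph, default_dose_factor_table())
        assert gt.tia_mbq_h["sphere"] == pytest.approx(230.150, rel=1e-4)

    def test_dose_inverse_in_mass_for_fixed_tia(self):
        table = default_dose_factor_table()
        small = build_phantom(single_sphere_spec(6.0, uptake=10.0, lam=0.01))
        large = build_phantom(single_sphere_spec(12.0, uptake=10.0, lam=0.01))
        gs, gl = true_absorbed_dose(small, table), true_absorbed_dose(large, table)
        ratio = gs.dose_gy["sphere"] / gl.dose_gy["sphere"]
        assert ratio == pytest.approx(
            gl.mass_g["sphere"] / gs.mass_g["sphere"], rel=1e-9
        )
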