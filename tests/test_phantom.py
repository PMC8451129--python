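"""Phantom geometry, ground-truth maps and forward simulators."""

import numpy as np
import pytest

from cardiomicro import relaxometry
from cardiomicro.config import default_phantom_config
from cardiomicro.diffusion import DiffusionProtocol, default_protocol, tensor_metrics
from cardiomicro.phantom import (
    build_phantom,
    contraction_activation,
    make_tensor_field,
    simulate_contour_motion,
    simulate_dwi,
    simulate_lge,
    simulate_molli,
    simulate_multiecho,
)


class TestGeometry:
    def test_annulus_voxel_count_matches_analytic_area(self):
        cfg = default_phantom_config(grid_size=64, n_slices=1, infarct_slices=(0, 1))
        gt = build_phantom(cfg, "baseline")
        expected = np.pi * (30**2 - 20**2) / 2.0**2
        assert abs(gt.myocardium.sum() - expected) / expected < 0.05

    def test_grid_too_small_for_epi_radius_rejected(self):
        with pytest.raises(ValueError, match="grid too small"):
            default_phantom_config(grid_size=16)

    def test_region_masks_are_a_partition_of_myocardium(self, gt_day6):
        assert not (gt_day6.infarct & ~gt_day6.myocardium).any()
        assert ((gt_day6.infarct | gt_day6.remote) == gt_day6.myocardium).all()
        assert not (gt_day6.infarct & gt_day6.remote).any()

    def test_septal_segments_disjoint_from_infarct_sector(self, gt_day6):
        assert not (gt_day6.septum & gt_day6.infarct).any()

    def test_empty_infarct_sector_leaves_all_myocardium_remote(self):
        cfg = default_phantom_config("infarct", grid_size=48, n_slices=3,
                                     infarct_sector_deg=None)
        gt = build_phantom(cfg, "day6")
        assert gt.infarct.sum() == 0
        assert (gt.remote == gt.myocardium).all()

    def test_helix_angle_is_linear_in_depth_and_bounded(self, gt_day6):
        tp = gt_day6.timepoint
        m = gt_day6.myocardium
        expected = tp.ha_endo_deg + gt_day6.depth_pct[m] / 100.0 * (
            tp.ha_epi_deg - tp.ha_endo_deg)
        assert np.allclose(gt_day6.ha[m], expected)
        assert np.nanmax(np.abs(gt_day6.ha)) <= 90.0

    def test_helix_angle_antisymmetric_about_midwall(self, gt_day6):
        # ha_endo = -ha_epi: HA at depth d mirrors HA at 100-d
        m = gt_day6.myocardium
        ha = gt_day6.ha[m]
        d = gt_day6.depth_pct[m]
        mid = gt_day6.timepoint.ha_endo_deg * (1 - 2 * d / 100.0)
        assert np.allclose(ha, mid)

    def test_infarct_values_override_remote_at_post_mi_timepoints(self, gt_day6):
        tp = gt_day6.timepoint
        assert np.allclose(gt_day6.t2[gt_day6.infarct], tp.infarct.t2_ms)
        assert np.allclose(gt_day6.t2[gt_day6.remote], tp.remote.t2_ms)
        assert gt_day6.scar[gt_day6.infarct].all()


class TestTensorConstruction:
    def test_zero_fa_gives_isotropic_tensor(self, gt_baseline):
        cfg = gt_baseline.config
        tps = [t.model_copy(update={
            "remote": t.remote.model_copy(update={"fa": 0.0}),
            "infarct": None}) for t in cfg.timepoints]
        gt = build_phantom(cfg.model_copy(update={"timepoints": tps}), "baseline")
        tf = make_tensor_field(gt, include_blood=False)
        m = gt.myocardium
        iso = gt.md[m][:, None, None] * np.eye(3)[None]
        assert np.allclose(tf.tensor[m], iso)

    def test_prescribed_fa_md_yield_expected_eigenvalues(self):
        # FA = 1/sqrt(6) ~ 0.408 and MD = 4/3 e-3 correspond to (2, 1, 1) e-3
        fa = 1 / np.sqrt(6)
        md = (2e-3 + 1e-3 + 1e-3) / 3
        delta = fa / np.sqrt(3 - 2 * fa**2)
        lam1, lam2 = md * (1 + 2 * delta), md * (1 - delta)
        assert np.allclose([lam1, lam2], [2e-3, 1e-3], rtol=1e-12)

    def test_metrics_round_trip_prescribed_md_fa(self, gt_day6):
        tf = make_tensor_field(gt_day6)
        md, fa = tensor_metrics(tf)
        m = gt_day6.myocardium
        assert np.allclose(md[m], gt_day6.md[m], rtol=1e-9)
        assert np.allclose(fa[m], gt_day6.fa[m], rtol=1e-9, atol=1e-12)

    def test_fa_of_one_rejected(self, gt_day6):
        import dataclasses

        bad = gt_day6.fa.copy()
        bad[gt_day6.myocardium] = 1.0
        gt = dataclasses.replace(gt_day6, fa=bad)
        with pytest.raises(ValueError, match="FA >= 1"):
            make_tensor_field(gt)


class TestSimulateDwi:
    def test_b0_volume_returns_s0_in_mask(self, gt_day6):
        tf = make_tensor_field(gt_day6)
        # append a synthetic b=0 check volume to the standard scheme
        full = default_protocol(averages=1)
        bvals = np.r_[0.0, full.bvals]
        bvecs = np.vstack([[1.0, 0, 0], full.bvecs])
        proto = DiffusionProtocol(bvals=bvals, bvecs=bvecs, averages=1)
        series = simulate_dwi(tf, proto, s0=1000.0, noise_sigma=0.0, seed=0)
        assert np.allclose(series.data[0][tf.mask], 1000.0)

    def test_isotropic_tensor_decays_identically_in_all_directions(self, gt_day6):
        d = 1.5e-3
        tensor = np.zeros(gt_day6.myocardium.shape + (3, 3))
        tensor[gt_day6.myocardium] = d * np.eye(3)
        from cardiomicro.diffusion import TensorField

        tf = TensorField(tensor=tensor, mask=gt_day6.myocardium)
        proto = default_protocol(averages=1)
        series = simulate_dwi(tf, proto, s0=1000.0, noise_sigma=0.0, seed=0)
        for i, b in enumerate(proto.bvals):
            assert np.allclose(series.data[i][tf.mask], 1000.0 * np.exp(-b * d))

    def test_rician_background_mean_is_rayleigh(self):
        cfg = default_phantom_config("infarct", grid_size=64, n_slices=3)
        gt = build_phantom(cfg, "day6")
        tf = make_tensor_field(gt)
        sigma = 30.0
        proto = default_protocol(averages=1)
        series = simulate_dwi(tf, proto, s0=1000.0, noise_sigma=sigma, seed=5)
        bg = ~(gt.myocardium | gt.blood)
        vals = series.data[0][bg]
        assert vals.size > 1e4
        expected = sigma * np.sqrt(np.pi / 2)
        assert abs(vals.mean() - expected) < 3 * sigma * np.sqrt((2 - np.pi / 2) / vals.size)

    def test_seeded_simulation_is_reproducible(self, gt_day6):
        tf = make_tensor_field(gt_day6)
        proto = default_protocol(averages=2)
        a = simulate_dwi(tf, proto, noise_sigma=20.0, seed=42)
        b = simulate_dwi(tf, proto, noise_sigma=20.0, seed=42)
        c = simulate_dwi(tf, proto, noise_sigma=20.0, seed=43)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            DiffusionProtocol(bvals=[100.0] * 7, bvecs=np.full((7, 3), 0.9))


class TestSimulateRelaxometrySeries:
    def test_molli_signal_values(self):
        t1 = np.full((1, 4, 4), 1100.0)
        tis = [200.0, 800.0, 1500.0, 3000.0, 5000.0]
        s = simulate_molli(t1, tis, a=1000.0)
        # |A - 2A exp(-TI/T1)| at TI=200, T1=1100
        assert np.allclose(s.data[0], abs(1000 - 2000 * np.exp(-200 / 1100)))
        assert abs(s.data[0, 0, 0, 0] - 667.506) < 0.01
        # long TI converges to A
        assert np.allclose(s.data[-1], 1000.0, rtol=0.03)

    def test_molli_null_point_is_zero(self):
        t1 = np.full((1, 2, 2), 900.0)
        null_ti = 900.0 * np.log(2.0)
        s = simulate_molli(t1, [100.0, 300.0, null_ti, 2000.0], a=1000.0)
        assert np.allclose(s.data[2], 0.0, atol=1e-9)

    def test_molli_rejects_too_few_inversion_times(self):
        with pytest.raises(ValueError, match=">= 4"):
            simulate_molli(np.ones((1, 2, 2)), [100.0, 200.0, 300.0])

    def test_multiecho_single_time_constant(self):
        t2 = np.full((1, 2, 2), 60.0)
        s = simulate_multiecho(t2, [60.0], s0=1000.0)
        assert np.allclose(s.data[0], 1000.0 / np.e)

    def test_multiecho_rejects_nonpositive_te(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_multiecho(np.ones((1, 2, 2)), [0.0, 8.8])


class TestSimulateLge:
    def test_scar_mean_elevated_by_contrast_times_sd(self, gt_day6):
        lge = simulate_lge(gt_day6, remote_mean=100.0, remote_sd=10.0,
                           scar_contrast=15.0, seed=0)
        img = lge.data[0]
        scar_mean = img[gt_day6.scar].mean()
        remote_mean = img[gt_day6.remote].mean()
        assert abs((scar_mean - remote_mean) - 150.0) < 3.0

    def test_zero_contrast_makes_scar_indistinguishable(self, gt_day6):
        lge = simulate_lge(gt_day6, scar_contrast=0.0, seed=0)
        img = lge.data[0]
        from cardiomicro.scar import segment_scar_5sd

        res = segment_scar_5sd(lge, gt_day6.myocardium, gt_day6.septum & gt_day6.remote)
        assert res.scar_fraction_pct < 0.5

    def test_remote_tail_above_5sd_is_negligible(self, gt_day6):
        lge = simulate_lge(gt_day6, seed=1)
        img = lge.data[0]
        remote = img[gt_day6.remote]
        thr = 100.0 + 5 * 10.0
        # Gaussian tail probability at 5 SD ~ 2.9e-7; expect ~0 of ~1000 voxels
        assert (remote > thr).sum() <= 1

    def test_nonpositive_remote_sd_rejected(self, gt_day6):
        with pytest.raises(ValueError, match="remote_sd"):
            simulate_lge(gt_day6, remote_sd=0.0)


class TestContourMotion:
    def test_zero_torsion_gives_identical_rotation(self, gt_day6):
        tc = simulate_contour_motion(gt_day6, torsion_slope_deg_per_mm=0.0,
                                     strain_params={"gcs_pct": -10.0})
        from cardiomicro.mechanics import torsion_from_contours

        curve, peak = torsion_from_contours(tc)
        assert np.allclose(curve, 0.0, atol=1e-12)
        assert peak == 0.0

    def test_peak_phase_rotation_is_linear_ramp(self, gt_baseline):
        tc = simulate_contour_motion(gt_baseline, torsion_slope_deg_per_mm=0.2)
        from cardiomicro.mechanics import _slice_rotations_deg

        rot = _slice_rotations_deg(tc)
        peak_phase = np.argmax(np.abs(rot).sum(axis=1))
        assert np.allclose(rot[peak_phase], 0.2 * gt_baseline.z_mm, atol=1e-9)

    def test_activation_peaks_at_unity_and_vanishes_at_ends(self):
        w = contraction_activation(26, 0.35)
        assert w[0] == 0.0 and abs(w[-1]) < 1e-12
        assert w.max() == 1.0

    def test_too_few_phases_rejected(self, gt_baseline):
        with pytest.raises(ValueError, match="phases"):
            simulate_contour_motion(gt_baseline, phases=1)


class TestNoisePropagation:
    def test_changing_seed_moves_roi_mean_within_noise_bound(self, gt_day6):
        """ROI means across noise realisations stay within 3 sigma/sqrt(N)."""
        m = gt_day6.myocardium
        sigma = 1000.0 / 30.0
        means = []
        for seed in range(4):
            s = simulate_multiecho(gt_day6.t2, mask=m, s0=1000.0,
                                   noise_sigma=sigma, seed=seed)
            t2 = relaxometry.fit_t2_map(s, m)
            means.append(np.nanmean(t2[gt_day6.infarct]))
        n = gt_day6.infarct.sum()
        # fitted-T2 SD per voxel is a few ms at SNR 30; means agree to ~SD/sqrt(N)
        assert np.ptp(means) < 3 * 5.0 / np.sqrt(n) * 2
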