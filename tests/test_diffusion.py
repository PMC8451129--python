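"""Tensor fitting, MD/FA metrics, LV frames, helix angle and HA gradient."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from cardiomicro.diffusion import (
    DiffusionProtocol,
    LVFrameField,
    TensorField,
    default_protocol,
    fit_diffusion_tensor,
    helix_angle_map,
    local_coordinate_frame,
    tensor_metrics,
    transmural_ha_gradient,
)
from cardiomicro.phantom import make_tensor_field, simulate_dwi


def _signals(D, protocol, s0=1000.0):
    g = protocol.bvecs
    quad = np.einsum("ni,ij,nj->n", g, D, g)
    return s0 * np.exp(-protocol.bvals * quad)


def _field_from_signals(sig, shape=(1, 2, 2)):
    data = np.tile(sig[:, None, None, None], (1, *shape))
    return data


class TestTensorFit:
    def test_recovers_diagonal_tensor_exactly(self):
        protocol = default_protocol(averages=1)
        D = np.diag([2e-3, 1e-3, 1e-3])
        data = _field_from_signals(_signals(D, protocol))
        tf = fit_diffusion_tensor(data, protocol, np.ones((1, 2, 2), bool))
        assert np.allclose(tf.tensor[0, 0, 0], D, atol=1e-10)

    def test_recovers_random_spd_tensor(self, rng):
        protocol = default_protocol(averages=1)
        A = rng.normal(size=(3, 3)) * 5e-4
        D = A @ A.T / 3 + 8e-4 * np.eye(3)
        data = _field_from_signals(_signals(D, protocol))
        tf = fit_diffusion_tensor(data, protocol, np.ones((1, 2, 2), bool))
        assert np.allclose(tf.tensor[0, 0, 0], D, atol=1e-10)

    def test_matches_brute_force_nonlinear_least_squares(self, rng):
        """WLLS on noiseless data equals direct NLS on the exponential model."""
        protocol = default_protocol(averages=1)
        A = rng.normal(size=(3, 3)) * 4e-4
        D = A @ A.T / 4 + 1e-3 * np.eye(3)
        sig = _signals(D, protocol)
        X = protocol.design_matrix()

        def resid(p):
            return np.exp(X @ p) - sig

        p0 = np.r_[np.log(1000.0), np.full(6, 1e-3)]
        nls = least_squares(resid, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15).x
        data = _field_from_signals(sig, (1, 1, 1))
        tf = fit_diffusion_tensor(data, protocol, np.ones((1, 1, 1), bool))
        d = tf.tensor[0, 0, 0]
        nls_D = np.array([[nls[1], nls[4], nls[5]],
                          [nls[4], nls[2], nls[6]],
                          [nls[5], nls[6], nls[3]]])
        assert np.allclose(d, nls_D, atol=1e-9)
        assert np.allclose(d, D, atol=1e-9)

    def test_constant_signal_across_shells_gives_zero_tensor(self):
        protocol = default_protocol(averages=1)
        data = np.full((protocol.n_volumes, 1, 2, 2), 800.0)
        tf = fit_diffusion_tensor(data, protocol, np.ones((1, 2, 2), bool))
        md, fa = tensor_metrics(tf)
        assert np.allclose(tf.tensor, 0.0, atol=1e-12)
        assert np.allclose(md[tf.mask], 0.0, atol=1e-12)

    def test_rank_deficient_protocol_rejected_at_validation(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            DiffusionProtocol(bvals=[100.0, 200.0, 450.0],
                              bvecs=np.tile([1.0, 0, 0], (3, 1)))


class TestMetrics:
    def test_eigenvalue_formula_example(self):
        lam = np.array([2e-3, 1e-3, 1e-3])
        tensor = np.diag(lam)[None, None, None]
        tf = TensorField(tensor=tensor, mask=np.ones((1, 1, 1), bool))
        md, fa = tensor_metrics(tf)
        assert np.isclose(md[0, 0, 0], 4e-3 / 3)
        assert np.isclose(fa[0, 0, 0], 1 / np.sqrt(6), atol=1e-12)

    @pytest.mark.parametrize("lam,expected_fa", [
        ((1e-3, 1e-3, 1e-3), 0.0),
        ((1e-3, 0.0, 0.0), 1.0),
    ])
    def test_isotropic_and_stick_limits(self, lam, expected_fa):
        tf = TensorField(tensor=np.diag(lam)[None, None, None],
                         mask=np.ones((1, 1, 1), bool))
        _, fa = tensor_metrics(tf)
        assert np.isclose(fa[0, 0, 0], expected_fa)

    def test_md_fa_invariant_under_rotation(self, rng):
        base = np.diag([1.8e-3, 0.9e-3, 0.6e-3])
        tensors = []
        for _ in range(10):
            R = Rotation.random(random_state=rng.integers(1 << 31)).as_matrix()
            tensors.append(R @ base @ R.T)
        tensor = np.stack(tensors)[None, None]  # (1, 1, 10, 3, 3)
        tf = TensorField(tensor=tensor, mask=np.ones((1, 1, 10), bool))
        md, fa = tensor_metrics(tf)
        assert np.allclose(md, md.flat[0], rtol=1e-10)
        assert np.allclose(fa, fa.flat[0], rtol=1e-10)


class TestLocalFrame:
    def _ring_frames(self, grid=32, endo=8.0, epi=14.0, px=1.0):
        ax = (np.arange(grid) - (grid - 1) / 2) * px
        X, Y = np.meshgrid(ax, ax)
        R = np.hypot(X, Y)
        mask = ((R >= endo) & (R < epi))[None]
        th = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        endo_c = np.column_stack([endo * np.cos(th), endo * np.sin(th)])
        epi_c = np.column_stack([epi * np.cos(th), epi * np.sin(th)])
        return mask, local_coordinate_frame(mask, [endo_c], [epi_c], px)

    def test_east_voxel_frame_orientation(self):
        mask, frames = self._ring_frames()
        # voxel due east of the centroid: r = +x, c = +y, l = +z
        iy = 15  # row at y ~ -0.5... use the row closest to y=0
        grid = 32
        ax = (np.arange(grid) - (grid - 1) / 2)
        iy = int(np.argmin(np.abs(ax)))
        ix = int(np.argmin(np.abs(ax - 11.0)))
        assert mask[0, iy, ix]
        np.testing.assert_allclose(frames.r_hat[0, iy, ix], [1, 0, 0], atol=0.06)
        np.testing.assert_allclose(frames.c_hat[0, iy, ix], [0, 1, 0], atol=0.06)
        np.testing.assert_allclose(frames.l_hat[0, iy, ix], [0, 0, 1])

    def test_triad_right_handed_orthonormal(self):
        mask, frames = self._ring_frames()
        m = mask & frames.valid
        r, c, l = frames.r_hat[m], frames.c_hat[m], frames.l_hat[m]
        assert np.allclose(np.cross(l, r), c, atol=1e-12)
        assert np.allclose((r * c).sum(1), 0.0, atol=1e-12)
        assert np.allclose(np.linalg.norm(r, axis=1), 1.0)

    def test_depth_zero_at_endo_and_fifty_at_midwall(self):
        mask, frames = self._ring_frames()
        grid, endo, epi = 32, 8.0, 14.0
        ax = np.arange(grid) - (grid - 1) / 2
        X, Y = np.meshgrid(ax, ax)
        R = np.hypot(X, Y)[None]
        near_endo = mask & (np.abs(R - endo) < 0.4)
        mid = mask & (np.abs(R - (endo + epi) / 2) < 0.3)
        assert np.nanmax(frames.depth_pct[near_endo]) < 10.0
        assert abs(np.nanmean(frames.depth_pct[mid]) - 50.0) < 5.0

    def test_open_contour_rejected(self):
        mask = np.ones((1, 4, 4), bool)
        with pytest.raises(ValueError, match="contour"):
            local_coordinate_frame(mask, [np.zeros((2, 2))], [np.zeros((2, 2))], 1.0)


class TestHelixAngle:
    def _uniform_frames(self, n):
        shape = (1, 1, n)
        r = np.tile([1.0, 0, 0], shape + (1,)).reshape(shape + (3,))
        c = np.tile([0.0, 1, 0], shape + (1,)).reshape(shape + (3,))
        l = np.tile([0.0, 0, 1], shape + (1,)).reshape(shape + (3,))
        return LVFrameField(r_hat=r, c_hat=c, l_hat=l,
                            depth_pct=np.full(shape, 50.0),
                            valid=np.ones(shape, bool))

    def _tf_with_e1(self, e1s):
        e1s = np.asarray(e1s, dtype=float)
        n = len(e1s)
        tensor = np.zeros((1, 1, n, 3, 3))
        for i, e in enumerate(e1s):
            e = e / np.linalg.norm(e)
            tensor[0, 0, i] = 1e-3 * np.eye(3) + 1e-3 * np.outer(e, e)
        return TensorField(tensor=tensor, mask=np.ones((1, 1, n), bool))

    def test_circumferential_longitudinal_and_antipodal_cases(self):
        s = 1 / np.sqrt(2)
        tf = self._tf_with_e1([[0, 1, 0], [0, s, s], [0, -s, -s], [0, 0, 1]])
        ha = helix_angle_map(tf, self._uniform_frames(4))
        np.testing.assert_allclose(ha[0, 0], [0.0, 45.0, 45.0, 90.0], atol=1e-9)

    def test_radial_eigenvector_masked_invalid(self):
        tf = self._tf_with_e1([[1, 0, 0], [0.99, 0.1, 0.1]])
        ha = helix_angle_map(tf, self._uniform_frames(2))
        assert np.isnan(ha[0, 0, 0])
        assert np.isnan(ha[0, 0, 1])  # projection norm ~ 0.14 < 0.2


class TestHaGradient:
    def test_linear_field_recovered_exactly(self, gt_day6):
        tf = make_tensor_field(gt_day6)
        ha = helix_angle_map(tf, gt_day6.frames)
        res = transmural_ha_gradient(ha, gt_day6.frames, gt_day6.aha)
        tp = gt_day6.timepoint
        truth = (tp.ha_epi_deg - tp.ha_endo_deg) / 100.0
        assert abs(res.slope_deg_per_pct - truth) < 1e-9
        assert res.r_squared > 0.999999

    def test_constant_field_has_zero_slope(self, gt_day6):
        ha = np.where(gt_day6.myocardium, 30.0, np.nan)
        res = transmural_ha_gradient(ha, gt_day6.frames, gt_day6.aha)
        assert abs(res.slope_deg_per_pct) < 1e-12

    def test_insufficient_voxels_error_names_segments(self, gt_day6):
        ha = np.full(gt_day6.ha.shape, np.nan)
        with pytest.raises(ValueError, match=r"segments \(8, 9\)"):
            transmural_ha_gradient(ha, gt_day6.frames, gt_day6.aha)

    def test_estimator_unbiased_on_noisy_linear_fields(self, gt_day6, rng):
        """Mean slope over 50 noisy HA realisations within 1 SE of truth."""
        tf = make_tensor_field(gt_day6)
        ha0 = helix_angle_map(tf, gt_day6.frames)
        tp = gt_day6.timepoint
        truth = (tp.ha_epi_deg - tp.ha_endo_deg) / 100.0
        slopes = [
            transmural_ha_gradient(
                np.clip(ha0 + rng.normal(0, 5.0, ha0.shape), -90, 90),
                gt_day6.frames, gt_day6.aha).slope_deg_per_pct
            for _ in range(50)
        ]
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        # one-sample test of zero bias at the 1% level (2.68 SE for df=49)
        assert abs(np.mean(slopes) - truth) < 2.7 * se


class TestEndToEndRecovery:
    def test_noisy_dwi_pipeline_recovers_md_fa_within_tolerance(self, gt_day6):
        tensors = make_tensor_field(gt_day6)
        protocol = default_protocol()
        dwi = simulate_dwi(tensors, protocol, s0=1000.0, noise_sigma=30.0, seed=2)
        tf = fit_diffusion_tensor(dwi, protocol, gt_day6.myocardium)
        md, fa = tensor_metrics(tf)
        inf = gt_day6.infarct
        assert abs(np.mean(md[inf]) / gt_day6.timepoint.infarct.md_mm2s - 1) < 0.03
        assert abs(np.mean(fa[inf]) - gt_day6.timepoint.infarct.fa) < 0.03
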