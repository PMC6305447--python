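"""Tensor estimation (D_w, R_w) and scalar maps (FA, MD, trace ratio, DC)."""

import numpy as np
import pytest

from cedsim import compute_dc, estimate_R, fa, fit_dt, md, synthesize_signals, trace_ratio
from cedsim.fields import SymmetricTensorField, mat_to_vec6, repair_spd, vec6_to_mat
from cedsim.phantom import GM, WM, AcquisitionScheme, ground_truth_moments

from conftest import DELTA, single_voxel_propagators


def tensor_field(mat):
    return SymmetricTensorField(mat_to_vec6(np.asarray(mat))[None, None, None, :])


class TestDTFit:
    def test_exact_recovery_single_gaussian(self, scheme, gaussian_voxel):
        sig = synthesize_signals(gaussian_voxel, scheme)
        d = fit_dt(sig, scheme)
        expect = mat_to_vec6(np.diag([1.7e-3, 0.3e-3, 0.3e-3]))
        assert np.abs(d.data[0, 0, 0] - expect).max() < 1e-9
        np.testing.assert_allclose(d.meta_s0.data[0, 0, 0], 1.0, rtol=1e-12)

    def test_isotropic_voxel_has_zero_fa(self, scheme):
        props = single_voxel_propagators([1.0], [0.8e-3 * np.eye(3)])
        d = fit_dt(synthesize_signals(props, scheme), scheme)
        assert fa(d).data[0, 0, 0] < 1e-10

    def test_kurtosis_biases_trace_low(self, scheme, mixture_voxel):
        # the monoexponential fit underestimates the true second moment
        sig = synthesize_signals(mixture_voxel, scheme)
        d = fit_dt(sig, scheme)
        tr_fit = d.data[0, 0, 0, [0, 3, 5]].sum()
        tr_true = ground_truth_moments(mixture_voxel).data[0, 0, 0, [0, 3, 5]].sum()
        assert tr_fit < tr_true

    def test_nonpositive_signal_excluded_from_mask(self, scheme, gaussian_voxel):
        sig = synthesize_signals(gaussian_voxel, scheme)
        sig.signals[0, 0, 0, 5] = 0.0
        d = fit_dt(sig, scheme)
        assert not d.mask[0, 0, 0]

    def test_too_few_directions_raises(self, gaussian_voxel):
        sch = AcquisitionScheme(
            [0.0, 1200.0, 1200.0],
            [[0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0]],
            n_b0=1,
        )
        sig = synthesize_signals(gaussian_voxel, sch)
        with pytest.raises(ValueError):
            fit_dt(sig, sch)


class TestEstimateR:
    def test_gaussian_voxel_both_modes_equal_d(self, scheme, gaussian_voxel):
        d_true = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        r_gt = estimate_R(gaussian_voxel, mode="ground_truth")
        np.testing.assert_allclose(vec6_to_mat(r_gt.data[0, 0, 0]), d_true, atol=1e-18)
        sig = synthesize_signals(gaussian_voxel, scheme)
        r_cu = estimate_R(sig, scheme, mode="cumulant")
        np.testing.assert_allclose(vec6_to_mat(r_cu.data[0, 0, 0]), d_true, atol=1e-12)

    def test_mixture_ground_truth_closed_form(self, mixture_voxel):
        r = estimate_R(mixture_voxel, mode="ground_truth")
        np.testing.assert_allclose(
            vec6_to_mat(r.data[0, 0, 0]), np.diag([1.5e-3, 1.5e-3, 1.0e-3]), atol=1e-18
        )

    def test_cumulant_within_5pc_of_ground_truth(self, scheme, mixture_voxel):
        sig = synthesize_signals(mixture_voxel, scheme)
        r_cu = estimate_R(sig, scheme, mode="cumulant").data[0, 0, 0]
        r_gt = estimate_R(mixture_voxel, mode="ground_truth").data[0, 0, 0]
        scale = np.abs(r_gt).max()
        assert (np.abs(r_cu - r_gt) / scale < 0.05).all()

    def test_mode_input_mismatch_raises(self, scheme, gaussian_voxel):
        sig = synthesize_signals(gaussian_voxel, scheme)
        with pytest.raises(TypeError):
            estimate_R(sig, scheme, mode="ground_truth")
        with pytest.raises(TypeError):
            estimate_R(gaussian_voxel, scheme, mode="cumulant")


class TestScalarMaps:
    def test_fa_md_identity_and_rank1(self):
        assert fa(tensor_field(np.eye(3))).data[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert md(tensor_field(np.eye(3))).data[0, 0, 0] == pytest.approx(1.0)
        assert fa(tensor_field(np.diag([1.0, 0, 0]))).data[0, 0, 0] == pytest.approx(1.0)

    def test_fa_closed_form_cross_check(self):
        lam = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        # standard eigenvalue formula, written independently of the code path
        lbar = lam.mean()
        expect = np.sqrt(1.5 * ((lam - lbar) ** 2).sum() / (lam**2).sum())
        got = fa(tensor_field(np.diag(lam))).data[0, 0, 0]
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_zero_tensor_fa_defined_as_zero(self):
        assert fa(tensor_field(np.zeros((3, 3)))).data[0, 0, 0] == 0.0

    def test_trace_ratio_gaussian_limit_and_scaling(self, scheme, gaussian_voxel):
        sig = synthesize_signals(gaussian_voxel, scheme)
        d = fit_dt(sig, scheme)
        r = estimate_R(sig, scheme, mode="cumulant")
        assert trace_ratio(r, d).data[0, 0, 0] == pytest.approx(1.0, abs=1e-8)
        r2 = SymmetricTensorField(2.0 * d.data, d.voxel_size, d.mask)
        assert trace_ratio(r2, d).data[0, 0, 0] == pytest.approx(2.0, rel=1e-12)

    def test_trace_ratio_masks_zero_trace(self):
        r = tensor_field(np.eye(3))
        d = tensor_field(np.zeros((3, 3)))
        out = trace_ratio(r, d)
        assert not out.mask[0, 0, 0]
        assert out.meta["n_masked_zero_trace"] == 1


class TestDC:
    def test_gaussian_voxel_dc_zero(self, scheme, gaussian_voxel):
        sig = synthesize_signals(gaussian_voxel, scheme)
        d = fit_dt(sig, scheme)
        r = estimate_R(sig, scheme, mode="cumulant")
        assert abs(compute_dc(r, d, DELTA).data[0, 0, 0]) < 1e-10

    def test_commuting_closed_form(self):
        # Sigma_R = 4 Sigma_D isotropic: DC = sum (sqrt(4 s) - sqrt(s))^2 = Tr Sigma_D
        d = 1e-3 * np.eye(3)
        dc = compute_dc(tensor_field(4 * d), tensor_field(d), DELTA).data[0, 0, 0]
        np.testing.assert_allclose(dc, 3 * 2 * DELTA * 1e-3, rtol=1e-10)

    def test_nonnegative_and_zero_iff_equal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.standard_normal((3, 3))
            m = 1e-3 * (a @ a.T / 3 + 0.2 * np.eye(3))
            b = rng.standard_normal((3, 3))
            m2 = 1e-3 * (b @ b.T / 3 + 0.2 * np.eye(3))
            dc = compute_dc(tensor_field(m), tensor_field(m2), DELTA).data[0, 0, 0]
            assert dc >= 0
            assert dc > 1e-9  # distinct random tensors stay separated
        same = compute_dc(tensor_field(m), tensor_field(m), DELTA).data[0, 0, 0]
        assert same < 1e-18

    def test_matches_grid_optimal_transport_oracle(self):
        # DC is the minimal mean-squared displacement discrepancy over
        # couplings; check against entropy-debiased OT on a discretized grid
        rng = np.random.default_rng(42)

        def rand_spd():
            a = rng.standard_normal((3, 3))
            return 1e-3 * (a @ a.T / 3 + 0.3 * np.eye(3))

        def gauss_on_grid(sig, pts):
            si = np.linalg.inv(sig)
            w = np.exp(-0.5 * np.einsum("ni,ij,nj->n", pts, si, pts))
            return w / w.sum()

        def sinkhorn_ot(a, b, cost, eps, iters=400):
            kern = np.exp(-cost / eps)
            u = np.ones_like(a)
            v = np.ones_like(b)
            for _ in range(iters):
                u = a / (kern @ v)
                v = b / (kern.T @ u)
            return ((u[:, None] * kern * v[None, :]) * cost).sum()

        for _ in range(2):
            rm, dm = rand_spd(), rand_spd()
            dc = compute_dc(tensor_field(rm), tensor_field(dm), DELTA).data[0, 0, 0]
            sr, sd = 2 * DELTA * rm, 2 * DELTA * dm
            smax = np.sqrt(
                max(np.linalg.eigvalsh(sr).max(), np.linalg.eigvalsh(sd).max())
            )
            g = np.linspace(-3.5 * smax, 3.5 * smax, 13)
            pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
            a, b = gauss_on_grid(sr, pts), gauss_on_grid(sd, pts)
            cost = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            eps = 0.05 * cost.mean()
            est = (
                sinkhorn_ot(a, b, cost, eps)
                - 0.5 * sinkhorn_ot(a, a, cost, eps)
                - 0.5 * sinkhorn_ot(b, b, cost, eps)
            )
            np.testing.assert_allclose(est, dc, rtol=0.10)  # grid error

    def test_rejects_nonpositive_delta(self):
        with pytest.raises(ValueError):
            compute_dc(tensor_field(np.eye(3)), tensor_field(np.eye(3)), 0.0)


class TestRotationEquivariance:
    def test_fa_md_dc_invariant_under_common_rotation(self, scheme, mixture_voxel):
        """Rotating gradients and propagator tensors together must leave the
        estimated scalar maps unchanged."""
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [31.0, -12.0, 57.0], degrees=True).as_matrix()

        def run(props, sch):
            sig = synthesize_signals(props, sch)
            d = fit_dt(sig, sch)
            r = estimate_R(sig, sch, mode="cumulant")
            return (
                fa(d).data[0, 0, 0],
                md(d).data[0, 0, 0],
                compute_dc(r, d, DELTA).data[0, 0, 0],
            )

        base = run(mixture_voxel, scheme)
        t6 = mixture_voxel.tensors[0, 0, 0]
        rotated = single_voxel_propagators(
            mixture_voxel.weights[0, 0, 0],
            [rot @ vec6_to_mat(t) @ rot.T for t in t6],
        )
        sch_rot = AcquisitionScheme(
            scheme.b_values, scheme.directions @ rot.T, scheme.n_b0, scheme.delta_diffusion
        )
        other = run(rotated, sch_rot)
        np.testing.assert_allclose(base, other, rtol=0, atol=1e-8)


class TestPhantomContrasts:
    """The qualitative tissue contrasts the default phantom is built to show."""

    def test_dc_concentrated_in_wm(self, default_phantom, default_water):
        lab = default_phantom.labels.labels
        dc = default_water.dc.data
        assert dc[lab == WM].mean() > dc[lab == GM].mean()
        assert np.percentile(dc[lab == WM], 75) > np.percentile(dc[lab == GM], 75)

    def test_fa_of_r_exceeds_fa_of_d_in_wm(self, default_phantom, default_water):
        lab = default_phantom.labels.labels
        gain = default_water.fa_r.data - default_water.fa_d.data
        assert (gain[lab == WM] >= 0).mean() >= 0.90

    def test_wm_trace_ratio_above_one(self, default_phantom, default_water):
        lab = default_phantom.labels.labels
        ratio = default_water.trace_ratio.data
        assert (ratio[lab == WM] > 1.0).all()

    def test_gaussian_phantom_collapses(self, scheme):
        """All-CSF (single-Gaussian) phantom: R = D, DC = 0, ratio = 1."""
        from cedsim import generate_labels, generate_propagators
        from cedsim.phantom import PhantomTissueParams

        lab = generate_labels((12, 12, 12), "uniform_gm", seed=0)
        params = PhantomTissueParams(
            gm_fast=0.8e-3, gm_slow=0.8e-3, diffusivity_jitter=0.0
        )  # both pools identical -> strictly Gaussian voxels
        props = generate_propagators(lab, params, seed=0)
        sig = synthesize_signals(props, scheme)
        d = fit_dt(sig, scheme)
        r = estimate_R(sig, scheme, mode="cumulant")
        m = lab.mask
        assert np.abs(r.data[m] - d.data[m]).max() < 1e-9
        assert np.abs(compute_dc(r, d, DELTA).data[m]).max() < 1e-10
        np.testing.assert_allclose(trace_ratio(r, d).data[m], 1.0, atol=1e-8)


def test_repair_spd_clamps_negative_eigenvalues():
    m = np.diag([1.0, 1.0, -0.5])
    fixed = vec6_to_mat(repair_spd(mat_to_vec6(m)))
    lam = np.linalg.eigvalsh(fixed)
    assert lam.min() >= 0
    np.testing.assert_allclose(lam.max(), 1.0)
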