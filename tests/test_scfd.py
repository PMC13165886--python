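"""Frequency-domain continuity diffusion: gradients, gates, kernels,
DCT filtering, and the independent heat-PDE oracle."""

import numpy as np
import pytest
from scipy.fft import dctn
from sklearn.base import clone

from structseg import autodiff as ad
from structseg.scfd import (DiffusionConfig, FrequencyDiffusion, FrequencyEmbedding,
                            SCFDModule, apply_diffusion, boundary_gate,
                            diffusion_kernel, frequency_grid, gradient_magnitude,
                            heat_oracle, scfd_residual, uniform_kernel)


class TestGradientMagnitude:
    def test_constant_image_zero(self):
        np.testing.assert_array_equal(gradient_magnitude(np.full((5, 5), 3.0)), 0.0)

    def test_horizontal_ramp_closed_form(self):
        src = np.tile(np.arange(6.0), (4, 1))
        g = gradient_magnitude(src)
        np.testing.assert_allclose(g[:, :-1], 1.0, rtol=1e-12)  # interior cols
        np.testing.assert_array_equal(g[:, -1], 0.0)            # replicate pad

    def test_double_loop_oracle(self, rng):
        src = rng.normal(size=(4, 4))
        got = gradient_magnitude(src)
        for i in range(4):
            for j in range(4):
                gx = src[i, j + 1] - src[i, j] if j < 3 else 0.0
                gy = src[i + 1, j] - src[i, j] if i < 3 else 0.0
                assert got[i, j] == pytest.approx(np.hypot(gx, gy), abs=1e-12)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            gradient_magnitude(np.zeros((1, 8)))


class TestBoundaryGate:
    def test_gate_off(self, rng):
        np.testing.assert_array_equal(boundary_gate(rng.normal(size=(4, 4)), 0.0), 1.0)

    def test_constant_source_closed_form(self):
        G = boundary_gate(np.full((6, 6), 2.0), 0.8)
        np.testing.assert_allclose(G, 1.0 - 0.8 * 0.5, rtol=1e-12)

    def test_step_by_step_oracle(self, rng):
        src = rng.normal(size=(5, 5))
        lam = 0.5
        spec = dctn(gradient_magnitude(src), norm="ortho")
        want = 1.0 - lam / (1.0 + np.exp(-spec))
        np.testing.assert_allclose(boundary_gate(src, lam), want, rtol=1e-12)

    def test_bounds_and_validation(self, rng):
        G = boundary_gate(rng.normal(size=(3, 8, 8)), 0.7)
        assert G.shape == (8, 8)  # channels reduced by mean
        assert np.all(G > 0.3 - 1e-12) and np.all(G < 1.0 + 1e-12)
        with pytest.raises(ValueError):
            boundary_gate(np.zeros((4, 4)), 1.3)


class TestDiffusionKernel:
    def test_zero_coefficient_keeps_everything(self):
        # Softplus(-40) ~ 4e-18: effectively zero diffusion
        w = diffusion_kernel(np.full((4, 4), -40.0), 1.0, 1.0, 4, 4)
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_dc_weight_is_one_for_any_coefficients(self, rng):
        w = diffusion_kernel(rng.normal(size=(6, 6)), 1.0, 0.7, 6, 6)
        assert w[0, 0] == pytest.approx(1.0, abs=1e-15)
        assert np.all(w > 0) and np.all(w <= 1.0)

    def test_continuum_closed_form_at_half_pi(self):
        """K=1, τ=1 at ω_x = ω_y = π/2 gives exp(−π²/2) under the
        continuum frequency map."""
        H = 8
        kb = np.full((H, H), DiffusionConfig.tau_raw_for(1.0))  # Softplus→1
        w = diffusion_kernel(kb, 1.0, 1.0, H, H, freq_map="continuum")
        assert w[H // 2, H // 2] == pytest.approx(np.exp(-np.pi ** 2 / 2), rel=1e-10)

    def test_temperature_monotonicity(self, rng):
        kb = rng.normal(size=(5, 5))
        w1 = diffusion_kernel(kb, 1.0, 0.8, 5, 5)
        w2 = diffusion_kernel(kb, 1.0, 1.6, 5, 5)
        assert np.all(w2 >= w1)  # larger τ, weaker smoothing


class TestApplyDiffusion:
    def test_unit_weights_roundtrip_identity(self, rng):
        x = rng.normal(size=(3, 8, 8))
        np.testing.assert_allclose(apply_diffusion(x, np.ones((8, 8))), x, atol=1e-6)

    def test_constant_input_preserved(self, rng):
        x = np.full((2, 6, 6), 1.7)
        w = uniform_kernel(0.8, (6, 6))
        np.testing.assert_allclose(apply_diffusion(x, w), 1.7, rtol=1e-10)

    def test_mean_preserved_for_arbitrary_kernel(self, rng):
        x = rng.normal(size=(8, 8))
        w = rng.uniform(0.1, 1.0, size=(8, 8))
        w[0, 0] = 1.0
        assert apply_diffusion(x, w).mean() == pytest.approx(x.mean(), abs=1e-6)

    def test_energy_never_increases(self, rng):
        x = rng.normal(size=(8, 8))
        w = rng.uniform(0.0, 1.0, size=(8, 8))
        out = apply_diffusion(x, w)
        assert (dctn(out, norm="ortho") ** 2).sum() <= \
            (dctn(x, norm="ortho") ** 2).sum() + 1e-9

    def test_variance_monotone_in_coefficient(self, rng):
        x = rng.normal(size=(12, 12))
        variances = [apply_diffusion(x, uniform_kernel(k, (12, 12))).var()
                     for k in (0.1, 0.5, 1.0, 2.0)]
        assert all(b <= a + 1e-12 for a, b in zip(variances, variances[1:]))

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            apply_diffusion(rng.normal(size=(4, 4)), np.ones((5, 5)))


class TestScfdResidual:
    def test_zero_gain_identity(self, rng):
        x = rng.normal(size=(2, 3, 3))
        np.testing.assert_array_equal(scfd_residual(x, rng.normal(size=x.shape), 0.0), x)

    def test_unit_gain_doubles(self, rng):
        x = rng.normal(size=(2, 3, 3))
        np.testing.assert_allclose(scfd_residual(x, x, 1.0), 2 * x, rtol=1e-12)

    def test_elementwise_oracle(self, rng):
        x, s = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        np.testing.assert_allclose(scfd_residual(x, s, 0.37), x + 0.37 * s, rtol=1e-12)


class TestHeatOracle:
    def test_zero_kappa_identity(self, rng):
        f = rng.normal(size=(6, 6))
        np.testing.assert_array_equal(heat_oracle(f, 0.0, 1.0, 100), f)

    def test_long_time_converges_to_mean(self, rng):
        f = rng.normal(size=(8, 8))
        out = heat_oracle(f, 1.0, 50.0, 5000)
        np.testing.assert_allclose(out, f.mean(), atol=1e-3)
        assert out.var() <= f.var()

    def test_unstable_step_raises(self):
        with pytest.raises(ValueError):
            heat_oracle(np.zeros((4, 4)), kappa=10.0, total_time=1.0, n_steps=10)

    @pytest.mark.parametrize("kappa", [0.1, 1.0])
    def test_agrees_with_spectral_diffusion(self, kappa, rng):
        """Headline cross-validation: DCT-kernel diffusion equals explicit
        Neumann finite-difference integration for uniform coefficients."""
        f = rng.random((16, 16))
        ref = heat_oracle(f, kappa, 1.0, 10_000)
        got = apply_diffusion(f, uniform_kernel(kappa, (16, 16)))
        scale = f.max() - f.min()
        assert np.abs(got - ref).max() / scale < 1e-2


class TestSCFDModule:
    def test_inert_at_init(self, rng):
        m = SCFDModule(6, 6, np.random.default_rng(0))
        x = rng.normal(size=(2, 3, 6, 6))
        out = m(ad.Tensor(x))
        np.testing.assert_array_equal(out.data, x)  # γ = 0

    def test_gradients_reach_all_parameters(self, rng):
        m = SCFDModule(4, 4, np.random.default_rng(0))
        m.gamma.data = np.array(0.5)
        x = ad.Tensor(rng.normal(size=(1, 2, 4, 4)), requires_grad=True)
        out = m(x)
        ad.tsum(ad.mul(out, out)).backward()
        assert m.embedding.fve.grad is not None
        assert m.tau_raw.grad is not None
        assert m.gamma.grad is not None
        assert x.grad is not None


class TestFrequencyDiffusionEstimator:
    def test_sklearn_clone_and_roundtrip(self, rng):
        est = FrequencyDiffusion(kappa=0.3, tau=1.2)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()
        img = rng.random((12, 12))
        out = est.fit(img).transform(img)
        np.testing.assert_allclose(out.mean(), img.mean(), atol=1e-9)
        assert out.var() <= img.var()

    def test_batch_matches_single(self, rng):
        imgs = rng.random((3, 8, 8))
        est = FrequencyDiffusion(kappa=0.5).fit(imgs)
        batch = est.transform(imgs)
        for i in range(3):
            np.testing.assert_allclose(batch[i], est.transform(imgs[i]), rtol=1e-12)

    def test_deterministic_given_fixed_inputs(self, rng):
        img = rng.random((10, 10))
        est = FrequencyDiffusion(kappa=0.4, lambda_gate=0.3).fit(img)
        np.testing.assert_array_equal(est.transform(img), est.transform(img))
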