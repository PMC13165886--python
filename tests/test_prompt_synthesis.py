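"""Prompt branch: pooling, dictionary matching, Top-λ selection,
entropy confidence, refinement and activation-map fusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from structseg import autodiff as ad
from structseg.prompt_synthesis import (RefinementMLP, SelectionConfig,
                                        build_prompt_embedding, confidence_feature,
                                        cosine_map, hard_k, identity_fusion_conv,
                                        match_dictionary, pool_prototype,
                                        refine_prototype, select_top_lambda,
                                        selection_mask)


class TestPoolPrototype:
    def test_constant_map(self):
        fmap = np.full((3, 4, 4), 0.7)
        np.testing.assert_allclose(pool_prototype(fmap), 0.7, rtol=1e-12)

    def test_two_pixel_average(self):
        fmap = np.array([[[1.0, 3.0]]])
        assert pool_prototype(fmap)[0] == pytest.approx(2.0)

    def test_matches_per_channel_mean_and_max(self, rng):
        fmap = rng.normal(size=(5, 3, 4))
        np.testing.assert_allclose(pool_prototype(fmap, "average"),
                                   fmap.mean(axis=(1, 2)), rtol=1e-10)
        np.testing.assert_allclose(pool_prototype(fmap, "max"),
                                   fmap.max(axis=(1, 2)), rtol=1e-10)
        with pytest.raises(ValueError):
            pool_prototype(fmap, "median")


class TestMatchDictionary:
    def test_zero_tokens_uniform(self, rng):
        w = match_dictionary(rng.normal(size=4), np.zeros((6, 4)))
        np.testing.assert_allclose(w, 1 / 6, atol=1e-12)

    def test_simplex(self, rng):
        w = match_dictionary(rng.normal(size=5), rng.normal(size=(7, 5)))
        assert w.sum() == pytest.approx(1.0) and np.all(w >= 0)

    def test_hand_case_against_brute_force(self):
        p = np.array([1.0, -1.0])
        T = np.array([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        logits = T @ p / math.sqrt(2)
        e = np.exp(logits - logits.max())
        np.testing.assert_allclose(match_dictionary(p, T), e / e.sum(), rtol=1e-12)

    def test_cosine_metric_scale_invariant(self, rng):
        p = rng.normal(size=4)
        T = rng.normal(size=(5, 4))
        np.testing.assert_allclose(match_dictionary(p, T, metric="cosine"),
                                   match_dictionary(3.0 * p, T, metric="cosine"),
                                   rtol=1e-10)


class TestTopLambdaSelection:
    def test_lambda_one_equals_full_structural_sum(self, rng):
        T = rng.normal(size=(6, 4))
        w = rng.dirichlet(np.ones(6))
        cfg = SelectionConfig(lambda_raw=50.0)  # clipped logistic → λ = 1
        assert cfg.lambda_sel == 1.0
        got = select_top_lambda(w, T, cfg)
        np.testing.assert_allclose(got, w[1:] @ T[1:], rtol=1e-10)

    def test_initial_half_ratio_count(self):
        cfg = SelectionConfig(lambda_raw=SelectionConfig.raw_for(0.5))
        assert cfg.lambda_sel == pytest.approx(0.5, abs=1e-9)
        assert hard_k(cfg.lambda_sel, 64) == 32  # M=65 structural tokens

    def test_sort_and_sum_oracle(self):
        T = np.arange(20.0).reshape(5, 4)
        w = np.array([0.1, 0.05, 0.4, 0.15, 0.3])
        cfg = SelectionConfig(lambda_raw=SelectionConfig.raw_for(0.4))
        assert hard_k(cfg.lambda_sel, 4) == 2
        got = select_top_lambda(w, T, cfg)
        # top-2 structural tokens by weight: indices 2 (0.4) and 4 (0.3)
        want = w[2] * T[2] + w[4] * T[4]
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_ties_break_toward_lower_index(self):
        w = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
        mask = selection_mask(w[1:], lambda_sel=0.3, relax_temp=0.05, hard=True)
        np.testing.assert_array_equal(mask, [1, 0, 0, 0])

    def test_soft_mask_converges_to_hard(self, rng):
        """Convergence holds for λ away from the rank-percentile knots
        (q_i = (i+0.5)/m), where the limit itself is discontinuous."""
        m = 8
        for _ in range(20):
            w = rng.dirichlet(np.ones(m + 1))
            lam = rng.integers(1, m) / m  # midway between adjacent knots
            with np.errstate(over="ignore"):
                soft = selection_mask(w[1:], lam, relax_temp=1e-3, hard=False)
            hard = selection_mask(w[1:], lam, relax_temp=1e-3, hard=True)
            assert np.abs(soft - hard).max() < 1e-4

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 5000))
    def test_selected_set_monotone_in_lambda(self, seed):
        r = np.random.default_rng(seed)
        w = r.dirichlet(np.ones(8))
        lam1, lam2 = sorted(r.uniform(0.05, 1.0, size=2))
        m1 = selection_mask(w[1:], lam1, 0.05, hard=True)
        m2 = selection_mask(w[1:], lam2, 0.05, hard=True)
        assert np.all(m2 >= m1)  # larger λ keeps a superset


class TestConfidenceFeature:
    def test_uniform_is_zero(self):
        assert confidence_feature(np.full(8, 1 / 8)) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_is_one(self):
        w = np.zeros(5)
        w[2] = 1.0
        assert confidence_feature(w) == pytest.approx(1.0)

    def test_entropy_formula_oracle(self):
        w = np.array([0.9, 0.1])
        H = -0.9 * math.log(0.9) - 0.1 * math.log(0.1)
        assert confidence_feature(w) == pytest.approx(1 - H / math.log(2), rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 5000))
    def test_bounded_and_permutation_invariant(self, seed):
        r = np.random.default_rng(seed)
        w = r.dirichlet(np.ones(r.integers(2, 10)))
        s = confidence_feature(w)
        assert -1e-12 <= s <= 1.0 + 1e-12
        assert confidence_feature(r.permutation(w)) == pytest.approx(s, abs=1e-10)


class TestRefinePrototype:
    def test_identity_at_init(self, rng):
        mlp = RefinementMLP(6, rng)
        p = rng.normal(size=6)
        out = refine_prototype(p, rng.normal(size=6), 0.4, mlp)
        np.testing.assert_array_equal(np.asarray(out.data), p)
        assert np.asarray(out.data).shape == (6,)

    def test_single_hidden_unit_hand_computation(self, rng):
        mlp = RefinementMLP(2, rng, activation="identity")
        mlp.hidden.weight.data[:] = 0.0
        mlp.hidden.weight.data[4, 0] = 2.0   # picks up s
        mlp.hidden.bias.data[:] = 0.0
        mlp.out.weight.data[:] = 0.0
        mlp.out.weight.data[0, 1] = 3.0
        p, f = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        out = refine_prototype(p, f, 0.5, mlp)
        # hidden unit 0 = 2*s = 1; output channel 1 += 3*1
        np.testing.assert_allclose(np.asarray(out.data), [1.0, 4.0], rtol=1e-12)

    def test_width_mismatch_raises(self, rng):
        mlp = RefinementMLP(4, rng)
        with pytest.raises(ValueError):
            refine_prototype(np.zeros(3), np.zeros(3), 0.1, mlp)


class TestCosineActivationMap:
    def test_identical_vector_gives_one(self):
        v = np.array([1.0, 2.0])
        fmap = np.tile(v[:, None, None], (1, 2, 2))
        np.testing.assert_allclose(cosine_map(v, fmap), 1.0, rtol=1e-6)

    def test_orthogonal_gives_zero(self):
        v = np.array([1.0, 0.0])
        fmap = np.zeros((2, 2, 2))
        fmap[1] = 1.0
        np.testing.assert_allclose(cosine_map(v, fmap), 0.0, atol=1e-12)

    def test_zero_feature_vector_convention(self):
        v = np.array([1.0, 1.0])
        assert cosine_map(v, np.zeros((2, 1, 1)))[0, 0] == 0.0

    def test_per_pixel_oracle(self, rng):
        v = rng.normal(size=3)
        fmap = rng.normal(size=(3, 2, 2))
        got = cosine_map(v, fmap)
        for i in range(2):
            for j in range(2):
                f = fmap[:, i, j]
                want = v @ f / (np.linalg.norm(v) * np.linalg.norm(f))
                assert got[i, j] == pytest.approx(want, rel=1e-6)


def test_prompt_embedding_identity_init_passes_features(rng):
    C = 5
    fmap = rng.normal(size=(C, 3, 3))
    conv = identity_fusion_conv(C)
    out = build_prompt_embedding(fmap, rng.normal(size=C), rng.normal(size=C), conv)
    np.testing.assert_array_equal(np.asarray(out.data), fmap)
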