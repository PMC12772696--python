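"""Attribution mechanisms against hand-computed and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from methconvt.interpret import (
    AttentionBundle,
    attention_analysis,
    control_centroid_background,
    gradcam_core,
    gradcam_pp,
    gradcam_tissue_profile,
    linear_importance,
    model_value_fn,
    row_entropy,
    shap_cohort_profile,
    shapley_exact,
    shapley_sampled,
)
from methconvt.model import MethConvTransformer, ModelSpec

RNG = np.random.default_rng(2024)


def small_model(seed=0, **kw):
    defaults = dict(
        P=64, conv_channels=(4, 8), conv_kernel=5, pool_sizes=(2, 2),
        n_layers=1, n_heads=2, d_cov=3, d_r=2, n_tissues=3, dropout=0.0,
    )
    defaults.update(kw)
    return MethConvTransformer(ModelSpec(**defaults), seed=seed)


# ---------------------------------------------------------------------------
# linear importance
# ---------------------------------------------------------------------------

def test_linear_importance_is_projection_passthrough():
    model = small_model(seed=1)
    signed, curve = linear_importance(model)
    np.testing.assert_array_equal(signed, model.params["proj_w"].data)
    np.testing.assert_array_equal(curve.values, np.abs(signed))
    assert (curve.values >= 0).all()
    # invariant to any downstream layers
    model.params["head_w"].data[:] = RNG.normal(size=model.params["head_w"].shape)
    signed2, _ = linear_importance(model)
    np.testing.assert_array_equal(signed, signed2)


# ---------------------------------------------------------------------------
# Grad-CAM++
# ---------------------------------------------------------------------------

def gradcam_oracle(a, g, eps):
    """Independent loop transcription of the alpha/weight/map formulas."""
    c, lp = a.shape
    m = np.zeros(lp)
    w = np.zeros(c)
    for k in range(c):
        third = sum(a[k, u] * g[k, u] ** 3 for u in range(lp))
        for t in range(lp):
            alpha = g[k, t] ** 2 / (2 * g[k, t] ** 2 + third + eps)
            w[k] += alpha * max(g[k, t], 0.0)
    for t in range(lp):
        m[t] = max(sum(w[k] * a[k, t] for k in range(c)), 0.0)
    return m


class TestGradCamCore:
    def test_single_unit_hand_value(self):
        m = gradcam_core(np.array([[1.0]]), np.array([[1.0]]), eps=1e-12)
        assert m[0] == pytest.approx(1.0 / 3.0)

    def test_nonpositive_gradients_annihilate(self):
        a = RNG.random((3, 5))
        g = -RNG.random((3, 5))
        np.testing.assert_array_equal(gradcam_core(a, g), np.zeros(5))

    def test_random_instances_match_loop_oracle(self):
        for _ in range(100):
            a = RNG.normal(size=(3, 5))
            g = RNG.normal(size=(3, 5))
            np.testing.assert_allclose(
                gradcam_core(a, g, eps=1e-8), gradcam_oracle(a, g, 1e-8), atol=1e-12
            )


class TestGradCamModel:
    def test_curve_shape_nonnegative_and_layer_names(self):
        model = small_model(seed=2)
        x = RNG.random(64)
        curve = gradcam_pp(model, x, np.zeros(2), [0], layer_choice="last")
        assert curve.values.shape == (64,)
        assert (curve.values >= 0).all()
        fine = gradcam_pp(model, x, np.zeros(2), [0], layer_choice="conv0")
        assert fine.values.shape == (64,)
        with pytest.raises(ValueError, match="unknown layer"):
            gradcam_pp(model, x, np.zeros(2), [0], layer_choice="conv9")
        with pytest.raises(ValueError, match="class_index"):
            gradcam_pp(model, x, np.zeros(2), [0], class_index=5)

    def test_invariant_to_constant_logit_shift(self):
        model = small_model(seed=3)
        x = RNG.random(64)
        before = gradcam_pp(model, x, np.zeros(2), [1]).values
        model.params["head_b"].data[1] += 7.0  # shifts the class logit only
        after = gradcam_pp(model, x, np.zeros(2), [1]).values
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_tissue_profile_singleton_and_symmetry(self):
        model = small_model(seed=4)
        x = RNG.random((2, 64))
        x[1] = x[0]  # identical samples in two tissues
        z = np.zeros((2, 2))
        per_tissue, overall, counts = gradcam_tissue_profile(model, x, z, [0, 1])
        np.testing.assert_allclose(per_tissue[0].values, per_tissue[1].values)
        np.testing.assert_allclose(overall.values, per_tissue[0].values)
        assert counts == {0: 1, 1: 1}
        # singleton tissue mean equals that sample's own map
        single = gradcam_pp(model, x[0], z[0], [0]).values
        np.testing.assert_allclose(per_tissue[0].values, single)


# ---------------------------------------------------------------------------
# Shapley
# ---------------------------------------------------------------------------

class TestShapleyExact:
    def test_linearity(self):
        c = RNG.normal(size=6)
        fn = lambda m: m @ c
        x = RNG.random(6)
        bg = RNG.random(6)
        phi = shapley_exact(fn, x, bg).phi
        np.testing.assert_allclose(phi, c * (x - bg), atol=1e-10)

    def test_null_player_and_dummy(self):
        fn = lambda m: m[:, 0] * 2.0 + m[:, 2] ** 2  # feature 1 ignored
        x = np.array([0.9, 0.5, 0.7])
        bg = np.array([0.1, 0.4, 0.2])
        phi = shapley_exact(fn, x, bg).phi
        assert phi[1] == pytest.approx(0.0, abs=1e-12)
        # a feature equal to its background value is also a null player
        x2 = x.copy()
        x2[2] = bg[2]
        phi2 = shapley_exact(fn, x2, bg).phi
        assert phi2[2] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_of_interchangeable_features(self):
        fn = lambda m: (m[:, 0] + m[:, 1]) ** 2  # features 0,1 interchangeable
        x = np.array([0.8, 0.8, 0.3])
        bg = np.array([0.2, 0.2, 0.1])
        phi = shapley_exact(fn, x, bg).phi
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_efficiency_and_permutation_oracle(self):
        f = 5
        w = RNG.normal(size=(f, f))
        fn = lambda m: np.einsum("ni,ij,nj->n", m, w, m) + np.sin(m).sum(axis=1)
        x = RNG.random(f)
        bg = RNG.random(f)
        phi = shapley_exact(fn, x, bg).phi
        assert phi.sum() == pytest.approx(
            float(fn(x[None])[0] - fn(bg[None])[0]), abs=1e-6
        )
        # brute-force permutation definition over all f! orderings
        oracle = np.zeros(f)
        for perm in itertools.permutations(range(f)):
            cur = bg.copy()
            prev = float(fn(cur[None])[0])
            for j in perm:
                cur[j] = x[j]
                val = float(fn(cur[None])[0])
                oracle[j] += val - prev
                prev = val
        oracle /= math.factorial(f)
        np.testing.assert_allclose(phi, oracle, atol=1e-10)

    def test_large_feature_set_directed_to_sampler(self):
        fn = lambda m: m.sum(axis=1)
        with pytest.raises(ValueError, match="shapley_sampled"):
            shapley_exact(fn, np.zeros(15), np.zeros(15))


class TestShapleySampled:
    def test_converges_to_exact_within_standard_error(self):
        f = 6
        w = RNG.normal(size=(f, f))
        fn = lambda m: np.tanh(m @ w[:, 0]) + (m @ w[:, 1]) ** 2
        x = RNG.random(f)
        bg = RNG.random(f)
        exact = shapley_exact(fn, x, bg).phi
        est = shapley_sampled(fn, x, bg, n_permutations=4000, seed=7)
        assert np.all(np.abs(est.phi - exact) < 4 * est.standard_error + 1e-12)

    def test_seeded_determinism(self):
        fn = lambda m: m.sum(axis=1) ** 2
        x, bg = RNG.random(5), RNG.random(5)
        a = shapley_sampled(fn, x, bg, n_permutations=50, seed=3)
        b = shapley_sampled(fn, x, bg, n_permutations=50, seed=3)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_constant_game_gives_zero(self):
        fn = lambda m: np.full(m.shape[0], 0.42)
        phi = shapley_sampled(fn, RNG.random(4), RNG.random(4),
                              n_permutations=20, seed=0).phi
        np.testing.assert_array_equal(phi, np.zeros(4))


class TestCohortShap:
    def test_model_value_fn_fixes_covariates(self):
        model = small_model(seed=5)
        x = RNG.random(64)
        fn = model_value_fn(model, np.array([0.5, 1.0]), [1], class_index=1)
        vals = fn(np.vstack([x, x]))
        assert vals.shape == (2,)
        assert vals[0] == vals[1]

    def test_singleton_cohort_mean_is_sample_phi(self):
        model = small_model(seed=6)
        x = RNG.random((1, 64))
        z = np.zeros((1, 2))
        bg = RNG.random(64)
        curve, per_sample = shap_cohort_profile(
            model, x, z, [0], bg, window_size=16, n_permutations=4, seed=0
        )
        np.testing.assert_allclose(curve.values, np.abs(per_sample[0]))
        assert per_sample.shape == (1, 64)

    def test_background_policy_picks_control_near_centroid(self):
        vals = np.array([[0.0, 0.0], [1.0, 1.0], [0.4, 0.4], [0.9, 0.9]])
        diag = np.array([0, 1, 0, 0])
        bg, bid = control_centroid_background(vals, diag, ["a", "b", "c", "d"])
        np.testing.assert_array_equal(bg, [0.4, 0.4])  # centroid ≈ (0.43, 0.43)
        assert bid == "c"
        with pytest.raises(ValueError, match="control"):
            control_centroid_background(vals, np.ones(4), None)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

class TestAttention:
    def test_uniform_attention_has_max_entropy(self):
        model = small_model(seed=7)
        model.params["block0_wq"].data[:] = 0.0
        model.params["block0_wk"].data[:] = 0.0
        bundle = attention_analysis(model, RNG.random(64), np.zeros(2), [0])
        L = model.spec.L
        np.testing.assert_allclose(bundle.row_entropies, np.log(L), atol=1e-10)

    def test_one_hot_rows_have_zero_entropy(self):
        eye = np.eye(8)
        np.testing.assert_array_equal(row_entropy(eye), np.zeros(8))

    def test_entropies_match_direct_summation(self):
        for _ in range(100):
            rows = RNG.dirichlet(np.ones(6), size=5)
            expected = np.array([-(r * np.log(r)).sum() for r in rows])
            np.testing.assert_allclose(row_entropy(rows), expected, atol=1e-12)

    def test_bundle_structure(self):
        model = small_model(seed=8)
        bundle = attention_analysis(model, RNG.random(64), np.zeros(2), [2])
        H, L = model.spec.n_heads, model.spec.L
        assert bundle.per_head.shape == (H, L, L)
        np.testing.assert_allclose(bundle.per_head.sum(axis=-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(
            bundle.averaged, bundle.per_head.mean(axis=0), atol=1e-12
        )
        # mean of stochastic matrices is stochastic
        np.testing.assert_allclose(bundle.averaged.sum(axis=-1), 1.0, atol=1e-6)
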