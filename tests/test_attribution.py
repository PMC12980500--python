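"""Attribution methods: closed forms, axioms, oracles, invariants."""

import numpy as np
import pytest

from conftest import FlatLinear, linear_model

import ecgxai.attribution as at
from ecgxai import nn
from ecgxai.exceptions import CapabilityError, ConfigurationError
from ecgxai.model import ScalarNet


@pytest.fixture(scope="module")
def w(rng):
    w = rng.normal(0, 1, (8, 16))
    w[3] = 0.0  # one silent lead: model constant in lead 3
    return w


@pytest.fixture(scope="module")
def x16(rng):
    return rng.normal(0, 1, (8, 16))


@pytest.fixture(scope="module")
def relu_toy():
    """Two-layer ReLU net with hand-set weights, for worked examples.

    score(x) = v . ReLU(W x_flat): implemented with a 1-sample-per-lead
    input treated through FlatLinear units is overkill; instead use a
    Conv1d(k=1) + ReLU + pool + head net small enough to reason about.
    """
    rng = np.random.default_rng(5)
    conv = nn.Conv1d(8, 4, 1, rng=rng)
    head = nn.Linear(4, 1, rng=rng)
    seq = nn.Sequential([conv, nn.ReLU(), nn.GlobalAvgPool(), head])
    return ScalarNet(seq)


class TestLinearClosedForms:
    def test_saliency_is_abs_weights_for_any_input(self, w, rng):
        model = linear_model(w)
        for _ in range(3):
            m = at.saliency(model, rng.normal(0, 1, (8, 16)))
            np.testing.assert_array_equal(m.values, np.abs(w))

    def test_silent_lead_row_is_zero(self, w, x16):
        m = at.saliency(linear_model(w), x16)
        assert np.all(m.values[3] == 0)

    def test_gradient_input_is_x_times_w_and_sums_to_score(self, w, x16):
        m = at.gradient_input(linear_model(w), x16)
        np.testing.assert_allclose(m.values, x16 * w, atol=1e-14)
        assert abs(m.values.sum() - linear_model(w).logits(x16)) < 1e-10

    def test_zero_input_gives_zero_gradient_input_map(self, w):
        m = at.gradient_input(linear_model(w), np.zeros((8, 16)))
        assert np.all(m.values == 0)

    @pytest.mark.parametrize("n_steps", [1, 4, 64])
    def test_ig_exact_for_linear_model_at_any_step_count(self, w, x16, n_steps):
        b = np.full_like(x16, 0.3)
        m = at.integrated_gradients(linear_model(w), x16, b, n_steps)
        np.testing.assert_allclose(m.values, (x16 - b) * w, atol=1e-12)

    def test_ig_zero_when_input_equals_baseline(self, w, x16):
        m = at.integrated_gradients(linear_model(w), x16, x16, 8)
        np.testing.assert_array_equal(m.values, 0 * x16)

    def test_deeplift_linear_equals_delta_times_w(self, w, x16):
        b = np.full_like(x16, -0.2)
        m = at.deeplift_rescale(linear_model(w), x16, b)
        np.testing.assert_allclose(m.values, (x16 - b) * w, atol=1e-12)

    def test_ig_rejects_bad_step_count(self, w, x16):
        with pytest.raises(ConfigurationError):
            at.integrated_gradients(linear_model(w), x16, None, 0)


class TestFiniteDifferenceOracle:
    def test_saliency_matches_finite_difference_on_relu_toy(self, relu_toy, rng):
        x = rng.normal(0, 1, (8, 12))
        m = at.saliency(relu_toy, x)
        gi = at.gradient_input(relu_toy, x)
        h = 1e-3
        for _ in range(20):
            i, j = rng.integers(0, 8), rng.integers(0, 12)
            xp, xm = x.copy(), x.copy()
            xp[i, j] += h
            xm[i, j] -= h
            fd = (relu_toy.logits(xp) - relu_toy.logits(xm)) / (2 * h)
            assert abs(m.values[i, j] - abs(fd)) < 1e-4
            assert abs(gi.values[i, j] - x[i, j] * fd) < 1e-4


class TestDeepLift:
    def test_summation_to_delta_on_residual_net(self, tiny_net, tiny_input):
        b = np.zeros_like(tiny_input)
        m = at.deeplift_rescale(tiny_net, tiny_input, b)
        delta = tiny_net.logits(tiny_input) - tiny_net.logits(b)
        assert abs(m.values.sum() - delta) < 1e-6

    def test_hand_tracked_rescale_on_single_relu_path(self):
        # score = w2 * ReLU(w1 * mean(x over leads/time)); choose x so the
        # unit is active at x and inactive at baseline 0
        rng = np.random.default_rng(0)
        conv = nn.Conv1d(8, 1, 1, rng=rng)
        conv.W[...] = 0.0
        conv.W[0, 1, 0] = 2.0           # listens to lead II only
        conv.b[...] = -1.0
        head = nn.Linear(1, 1, rng=rng)
        head.W[...] = 3.0
        head.b[...] = 0.0
        model = ScalarNet(nn.Sequential([conv, nn.ReLU(), nn.GlobalAvgPool(), head]))
        x = np.zeros((8, 4))
        x[1] = [1.0, 2.0, 0.25, 3.0]    # pre-ReLU: 2x-1 = [1, 3, -0.5, 5]
        b = np.zeros((8, 4))            # pre-ReLU: -1 everywhere -> ReLU 0
        m = at.deeplift_rescale(model, x, b)
        # multipliers: ReLU ratio = (ReLU(2x-1) - 0) / (2x - 1 - (-1)) = ReLU(2x-1)/(2x)
        pre = 2 * x[1] - 1
        ratio = np.maximum(pre, 0) / (2 * x[1])
        expected_lead2 = (x[1] - 0) * 2.0 * ratio * (1 / 4) * 3.0
        np.testing.assert_allclose(m.values[1], expected_lead2, atol=1e-12)
        assert np.all(m.values[[0, 2, 3, 4, 5, 6, 7]] == 0)

    def test_unsupported_layer_raises_capability_error(self, x16):
        class Weird(nn.Layer):
            def forward(self, x, train=False):
                return np.tanh(x).sum(axis=(1, 2))[:, None]

        model = ScalarNet(nn.Sequential([Weird()]))
        with pytest.raises(CapabilityError, match="Weird"):
            at.deeplift_rescale(model, x16, np.zeros_like(x16))


class TestShapley:
    def test_additive_model_recovers_per_segment_deltas_exactly(self, w, x16):
        # linear => additive across segments: phi_s = sum over segment of w*(x-b)
        model = linear_model(w)
        b = np.full_like(x16, 0.1)
        m = at.shapley_sampling(model, x16, b, n_segments=4, n_samples=1, seed=0)
        for s, (lo, hi) in enumerate(at.segment_bounds(16, 4)):
            expected = (w[:, lo:hi] * (x16 - b)[:, lo:hi]).sum()
            assert abs(m.values[0, lo] - expected) < 1e-10

    def test_efficiency_sums_to_score_delta(self, tiny_net, tiny_input):
        b = np.zeros_like(tiny_input)
        m = at.shapley_sampling(tiny_net, tiny_input, b, n_segments=4,
                                n_samples=8, seed=1)
        bounds = at.segment_bounds(64, 4)
        total = sum(m.values[0, lo] for lo, _ in bounds)
        delta = tiny_net.logits(tiny_input) - tiny_net.logits(b)
        assert abs(total - delta) < 1e-9

    def test_sampler_unbiased_against_exhaustive_oracle(self, tiny_net, tiny_input):
        b = np.zeros_like(tiny_input)
        exact = at.exact_shapley_segments(tiny_net, tiny_input, b, n_segments=3)
        runs = np.array([
            [at.shapley_sampling(tiny_net, tiny_input, b, 3, 40, seed=s)
             .values[0, lo] for lo, _ in at.segment_bounds(64, 3)]
            for s in range(10)])
        est = runs.mean(axis=0)
        se = runs.std(axis=0, ddof=1) / np.sqrt(len(runs))
        assert np.all(np.abs(est - exact) < 3 * se + 1e-12)

    def test_too_many_segments_rejected(self, tiny_net, tiny_input):
        with pytest.raises(ConfigurationError):
            at.shapley_sampling(tiny_net, tiny_input, None, n_segments=100,
                                n_samples=1, seed=0)


class TestGuidedBackprop:
    def test_equals_gradient_when_no_gates_fire(self):
        # all-positive weights and inputs: every ReLU input and gradient > 0
        rng = np.random.default_rng(2)
        conv = nn.Conv1d(8, 3, 1, rng=rng)
        conv.W[...] = np.abs(conv.W)
        conv.b[...] = 0.1
        head = nn.Linear(3, 1, rng=rng)
        head.W[...] = np.abs(head.W)
        model = ScalarNet(nn.Sequential([conv, nn.ReLU(), nn.GlobalAvgPool(), head]))
        x = np.abs(rng.normal(0, 1, (8, 6))) + 0.1
        gbp = at.guided_backprop(model, x)
        grad = model.input_gradient(x)
        np.testing.assert_allclose(gbp.values, grad, atol=1e-12)

    def test_dead_relu_gives_zero_map(self):
        rng = np.random.default_rng(3)
        conv = nn.Conv1d(8, 1, 1, rng=rng)
        conv.W[...] = 1.0
        conv.b[...] = -100.0          # unit never active
        head = nn.Linear(1, 1, rng=rng)
        model = ScalarNet(nn.Sequential([conv, nn.ReLU(), nn.GlobalAvgPool(), head]))
        m = at.guided_backprop(model, np.ones((8, 6)))
        assert np.all(m.values == 0)

    def test_negative_gradient_path_is_gated(self):
        # one active ReLU feeding a negative head weight: plain gradient is
        # negative, guided backprop must zero it
        rng = np.random.default_rng(4)
        conv = nn.Conv1d(8, 1, 1, rng=rng)
        conv.W[...] = 1.0
        conv.b[...] = 0.0
        head = nn.Linear(1, 1, rng=rng)
        head.W[...] = -2.0
        model = ScalarNet(nn.Sequential([conv, nn.ReLU(), nn.GlobalAvgPool(), head]))
        x = np.ones((8, 6))
        assert np.all(model.input_gradient(x) < 0)
        m = at.guided_backprop(model, x)
        assert np.all(m.values == 0)


class TestGradCAM:
    def test_nonnegative_and_lead_constant_over_random_inputs(self, tiny_net, rng):
        for _ in range(10):
            x = rng.normal(0, 1, (8, 64))
            m = at.gradcam(tiny_net, x)
            assert np.all(m.values >= 0)
            assert np.all(m.values == m.values[0][None, :])

    def test_nonpositive_channel_weights_clamp_to_zero(self, tiny_net, tiny_input):
        flipped = tiny_net.clone()
        flipped.head.W[...] = -np.abs(flipped.head.W)
        m = at.gradcam(flipped, tiny_input)
        assert np.all(m.values == 0)

    def test_missing_tap_layer_rejected(self, tiny_net, tiny_input):
        with pytest.raises(ConfigurationError):
            at.gradcam(tiny_net, tiny_input, tap_block=7)

    def test_guided_gradcam_combinations(self, tiny_net, tiny_input, rng):
        gbp = at.guided_backprop(tiny_net, tiny_input)
        zeros = at.AttributionMap(np.zeros((8, 64)), "gradcam")
        assert np.all(at.combine_guided_gradcam(gbp, zeros).values == 0)
        ones = at.AttributionMap(np.ones((8, 64)), "gradcam")
        np.testing.assert_array_equal(
            at.combine_guided_gradcam(gbp, ones).values, gbp.values)
        a, b = rng.normal(0, 1, (8, 64)), rng.normal(0, 1, (8, 64))
        np.testing.assert_array_equal(
            at.combine_guided_gradcam(a, b).values, a * b)
        with pytest.raises(ValueError):
            at.combine_guided_gradcam(np.ones((8, 4)), np.ones((8, 5)))


class TestSmoothGrad:
    def test_zero_noise_returns_base_map_exactly(self, tiny_net, tiny_input):
        m = at.smoothgrad(tiny_net, tiny_input, n_samples=7, noise_sd=0.0)
        base = at.saliency(tiny_net, tiny_input)
        np.testing.assert_array_equal(m.values, base.values)

    def test_single_sample_equals_base_on_the_perturbed_input(self, tiny_net, tiny_input):
        seed, noise_sd = 9, 0.05
        m = at.smoothgrad(tiny_net, tiny_input, n_samples=1, noise_sd=noise_sd,
                          seed=seed)
        scale = noise_sd * (tiny_input.max() - tiny_input.min())
        xp = tiny_input + np.random.default_rng(seed).normal(0, scale, tiny_input.shape)
        np.testing.assert_allclose(m.values, at.saliency(tiny_net, xp).values,
                                   atol=1e-12)

    def test_estimator_variance_scales_inversely_with_samples(self, tiny_net, tiny_input):
        def var_of_mean(n, reps=12):
            stack = np.stack([
                at.smoothgrad(tiny_net, tiny_input, n_samples=n, noise_sd=0.2,
                              seed=1000 + r).values for r in range(reps)])
            return stack.var(axis=0).mean()

        ratio = var_of_mean(4) / var_of_mean(16)
        assert 2.0 < ratio < 8.0      # ideal 4; wide band for 12-rep estimate


class TestShapVariants:
    def test_deepliftshap_single_baseline_equals_deeplift(self, tiny_net, tiny_input):
        b = np.random.default_rng(1).normal(0, 0.1, (8, 64))
        single = at.deepliftshap(tiny_net, tiny_input, b[None])
        plain = at.deeplift_rescale(tiny_net, tiny_input, b)
        np.testing.assert_allclose(single.values, plain.values, atol=1e-12)

    def test_deepliftshap_sums_to_mean_delta(self, tiny_net, tiny_input, rng):
        baselines = rng.normal(0, 0.2, (5, 8, 64))
        m = at.deepliftshap(tiny_net, tiny_input, baselines)
        deltas = [tiny_net.logits(tiny_input) - tiny_net.logits(b) for b in baselines]
        assert abs(m.values.sum() - np.mean(deltas)) < 1e-6

    def test_gradientshap_linear_matches_closed_form(self, w, x16, rng):
        model = linear_model(w)
        baselines = rng.normal(0, 0.5, (4, 8, 16))
        m = at.gradientshap(model, x16, baselines, n_samples=4000, seed=3)
        closed = (x16 - baselines.mean(axis=0)) * w
        # per-sample contribution is (x - b_i) * w: SE from baseline spread
        se = np.abs(w) * baselines.std(axis=0, ddof=1) / np.sqrt(4000)
        assert np.all(np.abs(m.values - closed) < 4 * se + 1e-9)

    def test_empty_baselines_rejected(self, tiny_net, tiny_input):
        with pytest.raises(ConfigurationError):
            at.gradientshap(tiny_net, tiny_input, np.empty((0, 8, 64)))


class TestDispatch:
    @pytest.fixture(scope="class")
    def light_cfg(self):
        return at.MethodConfig(ig_steps=8, sg_samples=4, shapley_segments=8,
                               shapley_samples=6, shap_baselines=2)

    @pytest.mark.parametrize("method", at.METHODS)
    def test_every_method_returns_finite_input_shaped_map(self, method, tiny_net,
                                                          rng, light_cfg):
        for _ in range(3):
            x = rng.normal(0, 1, (8, 64))
            m = at.compute_attribution(method, tiny_net, x, config=light_cfg)
            assert m.values.shape == (8, 64)
            assert np.all(np.isfinite(m.values))
            assert m.method_id == method
            if method == "gradcam":
                assert np.all(m.values >= 0)

    def test_unknown_method_rejected(self, tiny_net, tiny_input):
        with pytest.raises(ConfigurationError, match="lrp"):
            at.compute_attribution("lrp", tiny_net, tiny_input)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            at.MethodConfig(ig_steps=0)
        with pytest.raises(ConfigurationError):
            at.MethodConfig(sg_noise=-0.1)


class TestShapleyPerLead:
    def test_per_lead_players_recover_leadwise_deltas_for_additive_model(self, w, x16):
        model = linear_model(w)
        b = np.full_like(x16, 0.1)
        m = at.shapley_sampling(model, x16, b, n_segments=2, n_samples=1,
                                seed=0, per_lead=True)
        for lead in range(8):
            for lo, hi in at.segment_bounds(16, 2):
                expected = (w[lead, lo:hi] * (x16 - b)[lead, lo:hi]).sum()
                assert abs(m.values[lead, lo] - expected) < 1e-10

    def test_per_lead_and_joint_sum_to_same_delta(self, tiny_net, tiny_input):
        b = np.zeros_like(tiny_input)
        joint = at.shapley_sampling(tiny_net, tiny_input, b, 4, 2, seed=3)
        lead = at.shapley_sampling(tiny_net, tiny_input, b, 4, 2, seed=3,
                                   per_lead=True)
        delta = tiny_net.logits(tiny_input) - tiny_net.logits(b)
        bounds = at.segment_bounds(64, 4)
        joint_total = sum(joint.values[0, lo] for lo, _ in bounds)
        lead_total = sum(lead.values[l, lo] for l in range(8) for lo, _ in bounds)
        assert abs(joint_total - delta) < 1e-9
        assert abs(lead_total - delta) < 1e-9
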