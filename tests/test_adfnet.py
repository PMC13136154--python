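"""Network building blocks: CVFIM gating, fusion, alpha gate, weighted loss,
class weights, forward contracts and gradient wiring."""

import numpy as np
import pytest

from ccfocus import nn
from ccfocus.adfnet import (ADFNet, CVFIM, ClassWeights, FusionState,
                            NetworkConfig, compute_class_weights, fuse,
                            weighted_ce_loss)
from ccfocus.nn import Tensor


def zeroed_cvfim(channels=4):
    mod = CVFIM(np.random.default_rng(0), channels)
    for conv in (mod.phi_sag, mod.phi_cor):
        conv.weight.data[:] = 0
        conv.bias.data[:] = 0
    return mod


class TestCVFIM:
    def test_zero_phi_scales_features_by_exactly_1_5(self):
        mod = zeroed_cvfim()
        rng = np.random.default_rng(1)
        f_sag = Tensor(rng.normal(size=(2, 4, 5, 5)))
        f_cor = Tensor(rng.normal(size=(2, 4, 5, 5)))
        out_sag, out_cor = mod(f_sag, f_cor)
        assert np.array_equal(out_sag.data, 1.5 * f_sag.data)
        assert np.array_equal(out_cor.data, 1.5 * f_cor.data)

    def test_disabled_ablation_hook_matches_zero_phi(self):
        mod = CVFIM(np.random.default_rng(2), 4, disabled=True)
        f = Tensor(np.random.default_rng(3).normal(size=(1, 4, 3, 3)))
        g = Tensor(np.random.default_rng(4).normal(size=(1, 4, 3, 3)))
        out_f, out_g = mod(f, g)
        assert np.allclose(out_f.data, 1.5 * f.data)
        assert np.allclose(out_g.data, 1.5 * g.data)

    def test_gated_output_bounded_for_nonnegative_features(self):
        mod = CVFIM(np.random.default_rng(5), 4)
        f_sag = Tensor(np.abs(np.random.default_rng(6).normal(size=(2, 4, 6, 6))))
        f_cor = Tensor(np.random.default_rng(7).normal(size=(2, 4, 6, 6)))
        out_sag, _ = mod(f_sag, f_cor)
        assert np.all(out_sag.data >= f_sag.data - 1e-6)
        assert np.all(out_sag.data <= 2.0 * f_sag.data + 1e-6)

    def test_hand_computed_two_by_two_case(self):
        mod = zeroed_cvfim(channels=1)
        f_sag = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]]))
        f_cor = Tensor(np.zeros((1, 1, 2, 2)))
        out_sag, _ = mod(f_sag, f_cor)  # gate = sigmoid(0) = 0.5 everywhere
        assert np.allclose(out_sag.data, [[[[1.5, 3.0], [4.5, 6.0]]]])

    def test_shape_mismatch_rejected(self):
        mod = zeroed_cvfim()
        with pytest.raises(ValueError, match="mismatch"):
            mod(Tensor(np.zeros((1, 4, 5, 5))), Tensor(np.zeros((1, 4, 6, 6))))


class TestFuse:
    def test_alpha_one_returns_sagittal(self):
        v_sag = np.arange(8.0)
        v_cor = np.ones(8)
        assert np.array_equal(fuse(v_sag, v_cor, 1.0), v_sag)

    def test_alpha_zero_returns_axial(self):
        v_sag = np.arange(8.0)
        v_cor = np.ones(8)
        assert np.array_equal(fuse(v_sag, v_cor, 0.0), v_cor)

    def test_identical_vectors_are_fixed_point(self):
        v = np.random.default_rng(0).normal(size=6)
        for alpha in (0.0, 0.3, 0.67, 1.0):
            assert np.allclose(fuse(v, v, alpha), v)

    def test_output_between_inputs_elementwise(self):
        rng = np.random.default_rng(1)
        v_sag, v_cor = rng.normal(size=10), rng.normal(size=10)
        for alpha in np.linspace(0, 1, 7):
            out = fuse(v_sag, v_cor, float(alpha))
            assert np.all(out >= np.minimum(v_sag, v_cor) - 1e-12)
            assert np.all(out <= np.maximum(v_sag, v_cor) + 1e-12)

    def test_accepts_fusion_state_and_validates(self):
        v = np.ones(4)
        assert np.allclose(fuse(v, 2 * v, FusionState(0.5)), 1.5 * v)
        with pytest.raises(ValueError):
            FusionState(1.5)
        with pytest.raises(ValueError):
            fuse(np.ones(3), np.ones(4), 0.5)


class TestComputeAlpha:
    def test_zero_gate_gives_half(self):
        model = ADFNet(NetworkConfig(backbone="tiny", seed=0))
        model.gate.weight.data[:] = 0
        model.gate.bias.data[:] = 0
        v = Tensor(np.random.default_rng(2).normal(size=(3, 32)))
        w = Tensor(np.random.default_rng(3).normal(size=(3, 32)))
        alpha = model.compute_alpha(v, w)
        assert np.allclose(alpha.data, 0.5)

    def test_alpha_strictly_inside_unit_interval(self):
        model = ADFNet(NetworkConfig(backbone="tiny", seed=1))
        v = Tensor(np.random.default_rng(4).normal(size=(5, 32)) * 10)
        w = Tensor(np.random.default_rng(5).normal(size=(5, 32)) * 10)
        alpha = model.compute_alpha(v, w).data
        assert np.all((alpha > 0) & (alpha < 1))


class TestClassWeights:
    def test_paper_counts_give_8_64(self):
        w = compute_class_weights(311, 36)
        assert round(w.w_agenesis, 2) == 8.64
        assert w.w_normal == 1.0

    def test_balanced_counts(self):
        assert compute_class_weights(50, 50).w_agenesis == 1.0

    def test_four_to_one(self):
        assert compute_class_weights(100, 25).w_agenesis == 4.0

    def test_zero_agenesis_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            compute_class_weights(100, 0)


class TestWeightedCELoss:
    def test_confident_correct_prediction_is_zero(self):
        assert weighted_ce_loss([[1.0, 0.0]], [0],
                                ClassWeights(1.0, 8.64)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_normal_label_is_ln2(self):
        loss = weighted_ce_loss([[0.5, 0.5]], [0], ClassWeights(1.0, 1.0))
        assert loss == pytest.approx(np.log(2), rel=1e-12)

    def test_uniform_agenesis_scales_by_weight_before_normalization(self):
        w = ClassWeights(1.0, 8.64)
        loss = weighted_ce_loss([[0.5, 0.5]], [1], w)
        # normalized form divides by the weight sum; the raw weighted term is
        # w * ln 2
        assert loss * w.w_agenesis == pytest.approx(8.64 * np.log(2), rel=1e-12)

    def test_unit_weights_equal_plain_cross_entropy(self):
        rng = np.random.default_rng(6)
        logits = rng.normal(size=(16, 2))
        probs = nn.softmax(logits)
        labels = rng.integers(0, 2, 16)
        ours = weighted_ce_loss(probs, labels, ClassWeights(1.0, 1.0))
        plain = -np.mean(np.log(probs[np.arange(16), labels]))
        assert ours == pytest.approx(plain, abs=1e-12)

    def test_autograd_loss_matches_probability_form(self):
        rng = np.random.default_rng(7)
        logits = rng.normal(size=(8, 2))
        labels = rng.integers(0, 2, 8)
        w = ClassWeights(1.0, 4.0)
        fused = nn.weighted_softmax_ce(Tensor(logits), labels, w.as_array())
        direct = weighted_ce_loss(nn.softmax(logits), labels, w)
        assert float(fused.data) == pytest.approx(direct, rel=1e-5)


class TestForward:
    @pytest.fixture(scope="class")
    def model(self):
        return ADFNet(NetworkConfig(backbone="tiny", seed=3))

    @pytest.fixture(scope="class")
    def inputs(self):
        rng = np.random.default_rng(8)
        return rng.uniform(0, 255, (3, 32, 32)), rng.uniform(0, 255, (3, 32, 32))

    def test_eval_mode_is_deterministic(self, model, inputs):
        preds1 = model.predict(*inputs)
        preds2 = model.predict(*inputs)
        assert preds1 == preds2

    def test_probabilities_sum_to_one(self, inputs):
        for seed in range(3):
            model = ADFNet(NetworkConfig(backbone="tiny", seed=seed))
            for p in model.predict(*inputs):
                assert p.prob_normal + p.prob_agenesis == pytest.approx(1.0, abs=1e-6)
                assert 0 < p.alpha_used < 1

    def test_pixel_identical_inputs_give_identical_predictions(self, model):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 255, (1, 32, 32))
        y = rng.uniform(0, 255, (1, 32, 32))
        batch_sag = np.concatenate([x, x])
        batch_cor = np.concatenate([y, y])
        p = model.predict(batch_sag, batch_cor)
        assert p[0] == p[1]

    def test_wrong_input_shape_rejected(self, model):
        with pytest.raises(ValueError, match="expected"):
            model.forward(np.zeros((2, 3, 16, 16)), np.zeros((2, 3, 16, 16)))

    def test_pretrained_flag_raises_clear_error(self):
        with pytest.raises(NotImplementedError, match="weight"):
            ADFNet(NetworkConfig(backbone="tiny", pretrained=True))

    def test_cvfim_stage_validated(self):
        with pytest.raises(ValueError, match="cvfim_stage"):
            NetworkConfig(backbone="tiny", cvfim_stage=5)

    def test_gradients_reach_every_parameter_group(self, inputs):
        model = ADFNet(NetworkConfig(backbone="tiny", seed=4))
        model.train()
        logits = model.forward(*inputs, rng=np.random.default_rng(0))
        loss = nn.weighted_softmax_ce(logits, np.array([0, 1, 0]),
                                      np.array([1.0, 8.64]))
        loss.backward()
        dead = [name for name, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad != 0)]
        assert dead == []

    def test_backprop_matches_finite_differences(self, inputs):
        model = ADFNet(NetworkConfig(backbone="tiny", seed=5))
        model.eval()
        labels = np.array([0, 1, 0])
        w = np.array([1.0, 2.0])

        def loss_value():
            return float(nn.weighted_softmax_ce(
                model.forward(*inputs), labels, w).data)

        loss = nn.weighted_softmax_ce(model.forward(*inputs), labels, w)
        loss.backward()
        for param, idx in ((model.fc1.weight, (3, 7)),
                           (model.cvfim.phi_sag.weight, (1, 0, 0, 0)),
                           (model.stream_cor.stem.weight, (2, 0, 1, 1))):
            analytic = param.grad[idx]
            orig = param.data[idx]
            eps = 1e-3
            param.data[idx] = orig + eps
            up = loss_value()
            param.data[idx] = orig - eps
            down = loss_value()
            param.data[idx] = orig
            assert analytic == pytest.approx((up - down) / (2 * eps),
                                             rel=0.05, abs=1e-4)
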