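import numpy as np
import pytest

from spinalzfnet import model, nn
from spinalzfnet.autodiff import Tensor
from spinalzfnet.errors import ConfigurationError, SchemaError
from spinalzfnet.features import TOTAL_LENGTH, extract_record


class TestSpinalNet:
    def test_single_neuron_arithmetic(self):
        """w=1, q=2, b=0.5 → output 2.5 (the basic weighted-sum neuron)."""
        cfg = model.SpinalNetConfig(input_split=2, hidden_width=1, n_layers=1,
                                    out_dim=1, activation="linear")
        net = model.SpinalNet(in_dim=2, config=cfg)
        net.layers[0].weight.data[:] = [[1.0]]
        net.layers[0].bias.data[:] = 0.5
        net.projections[0].weight.data[:] = [[1.0]]
        net.projections[0].bias.data[:] = 0.0
        out = net(Tensor([[2.0, 0.0]]))
        assert out.data[0, 0] == pytest.approx(2.5)

    def test_all_zero_weights_give_zero(self):
        cfg = model.SpinalNetConfig(input_split=4, hidden_width=2, n_layers=4,
                                    out_dim=3, activation="linear")
        net = model.SpinalNet(in_dim=8, config=cfg)
        for p in net.parameters():
            p.data[:] = 0.0
        assert np.all(net(Tensor(np.random.default_rng(0).random((2, 8)))).data == 0.0)

    def test_linearity_under_weight_doubling(self, rng):
        """With linear activation and zero biases, doubling every weight of a
        single-layer spinal net doubles C1."""
        cfg = model.SpinalNetConfig(input_split=2, hidden_width=3, n_layers=1,
                                    out_dim=2, activation="linear")
        net = model.SpinalNet(in_dim=6, config=cfg)
        for p in net.parameters():
            if p.ndim == 1:
                p.data[:] = 0.0
        x = Tensor(rng.random((2, 6)))
        base = net(x).data.copy()
        for layer in net.layers:
            layer.weight.data *= 2.0  # double the neuron weights w_i only
        assert np.allclose(net(x).data, 2.0 * base)

    def test_each_layer_receives_segment_and_previous_output(self):
        cfg = model.SpinalNetConfig(input_split=4, hidden_width=5, n_layers=4)
        net = model.SpinalNet(in_dim=20, config=cfg)
        assert net.layers[0].weight.shape[0] == net.segment_length
        for layer in net.layers[1:]:
            assert layer.weight.shape[0] == net.segment_length + cfg.hidden_width

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError, match="input_split"):
            model.SpinalNetConfig(input_split=1)


class TestFusion:
    @pytest.fixture()
    def layer_and_inputs(self, rng):
        layer = model.FusionLayer(fusion_dim=8, rng=np.random.default_rng(3))
        features = Tensor(rng.random((4, TOTAL_LENGTH)))
        c1 = Tensor(rng.random((4, 8)))
        return layer, features, c1

    def test_forced_gate_one(self, layer_and_inputs):
        """U=1 ⇒ C2 = p + ½p1 exactly (the p2 and C1 terms vanish)."""
        layer, features, c1 = layer_and_inputs
        c2, state = layer(features, c1, u_override=1.0)
        assert np.allclose(c2.data, state.p + 0.5 * state.p1, atol=1e-12)

    def test_forced_gate_zero(self, layer_and_inputs):
        """U=0 ⇒ C2 = ⅙p2 + 1/12·C1 ((1−0)(2−0)/24 = 1/12)."""
        layer, features, c1 = layer_and_inputs
        c2, state = layer(features, c1, u_override=0.0)
        assert np.allclose(c2.data, state.p2 / 6.0 + state.C1 / 12.0, atol=1e-12)

    def test_random_fusion_matches_term_by_term_reevaluation(self, layer_and_inputs):
        layer, features, c1 = layer_and_inputs
        c2, s = layer(features, c1)
        expected = (s.U * s.p + 0.5 * s.U * s.p1 + (1 - s.U) * s.p2 / 6.0
                    + (1 - s.U) * (2 - s.U) * s.C1 / 24.0)
        assert np.allclose(c2.data, expected, atol=1e-12)

    def test_gate_stays_in_open_unit_interval(self, layer_and_inputs):
        layer, features, c1 = layer_and_inputs
        _, state = layer(features, c1)
        assert np.all(state.U > 0.0) and np.all(state.U < 1.0)


class TestZfnet:
    def test_output_is_four_logits_and_softmax_normalises(self, rng):
        net = model.ZFNet(in_dim=64, rng=np.random.default_rng(0))
        logits = net(Tensor(rng.random((3, 64))))
        assert logits.shape == (3, 4)
        proba = nn.softmax(logits.data)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_n_classes_fixed_at_four(self):
        with pytest.raises(ConfigurationError, match="n_classes"):
            model.ZfnetConfig(n_classes=3)

    def test_grid_too_small_for_poolings_rejected(self):
        with pytest.raises(ConfigurationError, match="grid"):
            model.ZFNet(model.ZfnetConfig(input_grid=4))


class TestAssembledClassifier:
    def test_prediction_deterministic_and_on_simplex(self, clean_samples):
        clf = model.SpinalZFNet(seed=0)
        sample = clean_samples[0]
        record = extract_record(sample.image, sample.kidney_mask)
        label_a, proba_a = model.spinalzfnet_predict(
            sample.image, sample.kidney_mask, clf, record=record)
        label_b, proba_b = model.spinalzfnet_predict(
            sample.image, sample.kidney_mask, clf, record=record)
        assert label_a == label_b
        assert np.array_equal(proba_a, proba_b)
        assert proba_a.min() >= 0.0 and proba_a.sum() == pytest.approx(1.0)
        assert label_a in clf.classes

    def test_schema_mismatch_names_the_problem(self):
        clf = model.SpinalZFNet(seed=0)
        with pytest.raises(SchemaError, match="schema"):
            clf.scale(np.zeros(100))

    def test_finite_difference_gradient_check_on_miniature(self, rng):
        """Backprop through spinal → fusion → head agrees with central
        finite differences on a miniature model to 1e-4 relative error."""
        spinal_cfg = model.SpinalNetConfig(input_split=2, hidden_width=2,
                                           n_layers=2, out_dim=3)
        spinal = model.SpinalNet(in_dim=4, config=spinal_cfg,
                                 rng=np.random.default_rng(0))
        fusion = model.FusionLayer(fusion_dim=3, rng=np.random.default_rng(1))
        head = nn.Linear(3, 4, rng=np.random.default_rng(2))
        x_img = Tensor(rng.random((2, 4)))
        x_feat = Tensor(rng.random((2, TOTAL_LENGTH)))
        labels = np.array([0, 2])

        def loss_value():
            c1 = spinal(x_img)
            c2, _ = fusion(x_feat, c1)
            return nn.cross_entropy(head(c2), labels)

        params = spinal.parameters() + fusion.parameters() + head.parameters()
        for p in params:
            p.zero_grad()
        loss_value().backward()
        eps = 1e-6
        checked = 0
        for p in params[:4] + params[-2:]:
            flat = p.data.reshape(-1)
            for i in range(min(3, flat.size)):
                original = flat[i]
                flat[i] = original + eps
                up = float(loss_value().data)
                flat[i] = original - eps
                down = float(loss_value().data)
                flat[i] = original
                numeric = (up - down) / (2 * eps)
                analytic = p.grad.reshape(-1)[i]
                scale = max(1.0, abs(numeric))
                assert abs(analytic - numeric) / scale < 1e-4
                checked += 1
        assert checked >= 10
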