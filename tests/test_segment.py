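import numpy as np
import pytest

from spinalzfnet import nn, phantom, segment
from spinalzfnet.autodiff import Tensor
from spinalzfnet.errors import ConfigurationError


@pytest.fixture(scope="module")
def small_net():
    return segment.build_enet(segment.EnetConfig.small(), seed=0)


@pytest.fixture(scope="module")
def trained_small():
    """A briefly trained desk-scale network on noise-free phantoms."""
    spec = phantom.PhantomSpec(image_size=64, n_per_class=5, seed=2,
                               noise_sd=0.0, impulse_frac=0.0)
    samples = phantom.generate(spec)
    net = segment.build_enet(segment.EnetConfig.small(), seed=2)
    net, trace = segment.train_segmenter(net, samples, epochs=25, seed=2, lr=5e-3)
    return net, trace, samples


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError, match="n_classes"):
            segment.EnetConfig(n_classes=1)
        with pytest.raises(ConfigurationError, match="stage"):
            segment.EnetConfig(stage_channels=(64, 128, 96))
        with pytest.raises(ConfigurationError, match="initial_channels"):
            segment.EnetConfig(initial_channels=1)


class TestStructure:
    def test_forward_shape_contract_default_config(self):
        net = segment.build_enet(seed=0)
        out = net(Tensor(np.zeros((1, 1, 64, 64))))
        assert out.shape == (1, 2, 64, 64)

    def test_projections_carry_no_bias(self, small_net):
        layers = small_net.projection_layers()
        assert layers and all(layer.bias is None for layer in layers)

    def test_fewer_parameters_than_plain_conv_baseline(self, small_net):
        """The bottleneck design must undercut an equal-depth stack of plain
        3×3 convolutions at the same widths."""
        cfg = small_net.config
        rng = np.random.default_rng(0)
        widths = ([cfg.initial_channels]
                  + [cfg.stage_channels[0]] * (1 + cfg.stage_repeats[0])
                  + [cfg.stage_channels[1]] * (1 + cfg.stage_repeats[1])
                  + [cfg.stage_channels[2]] * cfg.stage_repeats[2]
                  + [cfg.stage_channels[0]] * cfg.stage_repeats[3]
                  + [cfg.initial_channels] * cfg.stage_repeats[4])
        plain = nn.Sequential(*[
            nn.Conv2d(a, b, 3, padding=1, rng=rng)
            for a, b in zip([cfg.in_channels] + widths, widths + [cfg.n_classes])])
        assert small_net.n_parameters() < plain.n_parameters()

    def test_shape_preserved_for_any_multiple_of_eight(self, small_net):
        for size in (16, 24):
            out = small_net(Tensor(np.zeros((1, 1, size, size))))
            assert out.shape == (1, 2, size, size)

    def test_indivisible_input_rejected(self, small_net):
        with pytest.raises(ValueError, match="divisible"):
            small_net(Tensor(np.zeros((1, 1, 20, 20))))

    def test_upsampling_bottleneck_requires_pool_indices(self):
        rng = np.random.default_rng(0)
        block = segment.Bottleneck(8, 4, "up", 0.0, rng)
        with pytest.raises(ValueError, match="indices"):
            block(Tensor(np.zeros((1, 8, 8, 8))), indices=None)

    def test_unpooling_consumes_paired_encoder_indices(self):
        """The decoder unpooling must restore values at the positions the
        paired encoder pooling recorded (16×16 forward pass plumbing)."""
        rng = np.random.default_rng(1)
        down = segment.Bottleneck(4, 8, "down", 0.0, rng).eval()
        up = segment.Bottleneck(8, 4, "up", 0.0, rng).eval()
        x = Tensor(rng.random((1, 4, 16, 16)))
        pooled, idx = down(x)
        assert idx.shape == (1, 4, 8, 8)
        out = up(pooled, indices=idx)
        assert out.shape == (1, 4, 16, 16)


class TestTraining:
    def test_empty_dataset_rejected(self, small_net):
        with pytest.raises(ValueError, match="empty"):
            segment.train_segmenter(small_net, [], epochs=1, seed=0)

    def test_loss_decreases(self, trained_small):
        _, trace, _ = trained_small
        assert trace[-1] < trace[0]

    def test_training_is_deterministic(self):
        spec = phantom.PhantomSpec(image_size=64, n_per_class=1, seed=3,
                                   noise_sd=0.0, impulse_frac=0.0)
        samples = phantom.generate(spec)
        losses = []
        for _ in range(2):
            net = segment.build_enet(segment.EnetConfig.small(), seed=4)
            _, trace = segment.train_segmenter(net, samples, epochs=2, seed=4)
            losses.append(trace[-1])
        assert losses[0] == losses[1]

    def test_briefly_trained_network_reaches_good_iou(self, trained_small):
        net, _, samples = trained_small
        ious = [segment.iou(segment.segment_image(net, s.image)[0], s.kidney_mask)
                for s in samples]
        assert np.mean(ious) >= 0.8


class TestSegmentImage:
    def test_mask_binary_and_masked_image_zero_outside(self, trained_small):
        net, _, samples = trained_small
        mask, masked = segment.segment_image(net, samples[0].image)
        assert set(np.unique(mask.labels)) <= {0, 1}
        assert np.all(masked.pixels[mask.labels == 0] == 0.0)

    def test_resolution_mismatch_rejected(self, trained_small):
        net, _, _ = trained_small
        with pytest.raises(ValueError, match="resolution"):
            segment.segment_image(net, np.zeros((32, 32)))

    def test_iou_bounds(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.ones((4, 4), dtype=int)
        assert segment.iou(a, b) == 0.0
        assert segment.iou(b, b) == 1.0
        assert segment.iou(a, a) == 1.0  # empty-vs-empty convention
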