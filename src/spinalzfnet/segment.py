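"""ENet encoder–decoder for kidney-area segmentation.

The network follows the ENet design: a single initial block (strided
convolution concatenated with a max-pool of the input), three encoder stages
of bottleneck modules (stage 1 downsamples; stages 2 and 3 share structure
but stage 3 does not downsample), two decoder stages that replace max
pooling with max *unpooling* driven by the indices saved by the paired
encoder pooling, and one final full (transposed) convolution producing the C
class maps.  No projection carries a bias term; batch normalisation sits
between every convolution and its PReLU nonlinearity; downsampling
bottlenecks zero-pad the identity branch to match channel counts; the main
convolutions cycle through regular, dilated and asymmetric variants.  The
final upsampler is a learned transposed convolution (the initial block's
pooling has no indices to reuse).

Three downsamplings mean input dimensions must be divisible by 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigurationError
from .images import GrayImage, SegmentationMask
from .phantom import PhantomSample

# main-convolution variants cycled through within the deeper encoder stages
STAGE23_PATTERN = ("regular", "dilated2", "asymmetric5", "dilated4",
                   "regular", "dilated8", "asymmetric5", "dilated16")


@dataclass(frozen=True)
class EnetConfig:
    in_channels: int = 1
    n_classes: int = 2
    initial_channels: int = 16
    stage_channels: tuple[int, int, int] = (64, 128, 128)
    stage_repeats: tuple[int, int, int, int, int] = (4, 8, 8, 2, 1)
    dropout_p: tuple[float, float] = (0.01, 0.1)  # encoder stage 1, later stages

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.initial_channels <= self.in_channels:
            raise ConfigurationError(
                "initial_channels must exceed in_channels "
                f"({self.initial_channels} vs {self.in_channels})")
        if any(c <= 0 for c in self.stage_channels):
            raise ConfigurationError(f"stage_channels must be positive: {self.stage_channels}")
        if self.stage_channels[1] != self.stage_channels[2]:
            raise ConfigurationError(
                "stages 2 and 3 share structure; their widths must match "
                f"(got {self.stage_channels[1]} vs {self.stage_channels[2]})")
        if any(r < 1 for r in self.stage_repeats):
            raise ConfigurationError(f"stage_repeats must be >= 1: {self.stage_repeats}")

    @classmethod
    def small(cls) -> "EnetConfig":
        """Desk-scale variant for 64×64 phantom experiments."""
        return cls(initial_channels=8, stage_channels=(16, 32, 32),
                   stage_repeats=(1, 2, 2, 1, 1), dropout_p=(0.0, 0.0))


class InitialBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch - in_ch, 3, stride=2, padding=1,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)
        self.act = nn.PReLU(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        pooled, _ = ad.maxpool2d(x, 2)
        out = ad.concat([self.conv(x), pooled], axis=1)
        return self.act(self.bn(out))


class Bottleneck(nn.Module):
    """Residual bottleneck: 1×1 projection → main conv → 1×1 expansion.

    ``kind`` is one of ``regular``, ``dilated{d}``, ``asymmetric{k}``,
    ``down`` or ``up``.  Downsampling pools the identity branch (saving
    indices) and zero-pads its channels; upsampling projects the identity
    branch and max-unpools it with the indices from the paired encoder pool.
    """

    def __init__(self, in_ch: int, out_ch: int, kind: str, dropout: float, rng):
        super().__init__()
        self.kind = kind
        self.in_ch, self.out_ch = in_ch, out_ch
        internal = max(1, out_ch // 4)
        if kind == "down":
            self.proj = nn.Conv2d(in_ch, internal, 2, stride=2, bias=False, rng=rng)
        else:
            self.proj = nn.Conv2d(in_ch, internal, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(internal)
        self.act1 = nn.PReLU(internal)
        if kind.startswith("dilated"):
            d = int(kind[len("dilated"):])
            self.main = nn.Conv2d(internal, internal, 3, padding=d, dilation=d,
                                  bias=False, rng=rng)
        elif kind.startswith("asymmetric"):
            k = int(kind[len("asymmetric"):])
            self.main = nn.Sequential(
                nn.Conv2d(internal, internal, (k, 1), padding=(k // 2, 0),
                          bias=False, rng=rng),
                nn.Conv2d(internal, internal, (1, k), padding=(0, k // 2),
                          bias=False, rng=rng),
            )
        elif kind == "up":
            self.main = nn.ConvTranspose2d(internal, internal, 3, stride=2,
                                           padding=1, output_padding=1,
                                           bias=False, rng=rng)
        else:  # regular or down
            self.main = nn.Conv2d(internal, internal, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(internal)
        self.act2 = nn.PReLU(internal)
        self.expand = nn.Conv2d(internal, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.dropout = nn.Dropout2d(dropout, rng=rng)
        self.act_out = nn.PReLU(out_ch)
        if kind == "up":
            self.skip_proj = nn.Conv2d(in_ch, out_ch, 1, bias=False, rng=rng)
            self.skip_bn = nn.BatchNorm2d(out_ch)

    def projection_layers(self) -> list[nn.Conv2d]:
        layers = [self.proj, self.expand]
        if self.kind == "up":
            layers.append(self.skip_proj)
        return layers

    def forward(self, x: Tensor, indices: np.ndarray | None = None):
        out = self.act1(self.bn1(self.proj(x)))
        out = self.main(out)
        out = self.act2(self.bn2(out))
        out = self.dropout(self.bn3(self.expand(out)))
        saved = None
        if self.kind == "down":
            skip, saved = ad.maxpool2d(x, 2)
            if self.out_ch > self.in_ch:  # zero-pad the identity activations
                n, _, h, w = skip.shape
                pad = Tensor(np.zeros((n, self.out_ch - self.in_ch, h, w)))
                skip = ad.concat([skip, pad], axis=1)
        elif self.kind == "up":
            if indices is None:
                raise ValueError("upsampling bottleneck requires pooling indices")
            skip = self.skip_bn(self.skip_proj(x))
            skip = ad.max_unpool2d(skip, indices, 2)
        else:
            skip = x
        out = self.act_out(out + skip)
        return (out, saved) if self.kind == "down" else out


class ENet(nn.Module):
    def __init__(self, config: EnetConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.trained_resolution: tuple[int, int] | None = None
        rng = np.random.default_rng(seed)
        c0, (c1, c2, c3) = config.initial_channels, config.stage_channels
        r1, r2, r3, r4, r5 = config.stage_repeats
        p1, p2 = config.dropout_p
        self.initial = InitialBlock(config.in_channels, c0, rng)
        self.stage1_down = Bottleneck(c0, c1, "down", p1, rng)
        self.stage1 = [Bottleneck(c1, c1, "regular", p1, rng) for _ in range(r1)]
        self.stage2_down = Bottleneck(c1, c2, "down", p2, rng)
        self.stage2 = [Bottleneck(c2, c2, STAGE23_PATTERN[i % len(STAGE23_PATTERN)],
                                  p2, rng) for i in range(r2)]
        self.stage3 = [Bottleneck(c3, c3, STAGE23_PATTERN[i % len(STAGE23_PATTERN)],
                                  p2, rng) for i in range(r3)]
        self.stage4_up = Bottleneck(c3, c1, "up", p2, rng)
        self.stage4 = [Bottleneck(c1, c1, "regular", p2, rng) for _ in range(r4 - 1)]
        self.stage5_up = Bottleneck(c1, c0, "up", p2, rng)
        self.stage5 = [Bottleneck(c0, c0, "regular", p2, rng) for _ in range(r5 - 1)]
        # final full convolution: a learned transposed conv (no unpooling here)
        self.full_conv = nn.ConvTranspose2d(c0, config.n_classes, 3, stride=2,
                                            padding=1, output_padding=1, rng=rng)

    def projection_layers(self) -> list[nn.Conv2d]:
        layers = []
        for mod in [self.stage1_down, *self.stage1, self.stage2_down, *self.stage2,
                    *self.stage3, self.stage4_up, *self.stage4, self.stage5_up,
                    *self.stage5]:
            layers.extend(mod.projection_layers())
        return layers

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 8 or w % 8:
            raise ValueError(f"input dimensions must be divisible by 8, got {h}x{w}")
        out = self.initial(x)
        out, idx1 = self.stage1_down(out)
        for block in self.stage1:
            out = block(out)
        out, idx2 = self.stage2_down(out)
        for block in self.stage2:
            out = block(out)
        for block in self.stage3:
            out = block(out)
        out = self.stage4_up(out, indices=idx2)
        for block in self.stage4:
            out = block(out)
        out = self.stage5_up(out, indices=idx1)
        for block in self.stage5:
            out = block(out)
        return self.full_conv(out)


def build_enet(config: EnetConfig | None = None, seed: int = 0) -> ENet:
    return ENet(config or EnetConfig(), seed=seed)


def _pixel_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    n, c, h, w = logits.shape
    flat = logits.transpose(0, 2, 3, 1).reshape(n * h * w, c)
    return nn.cross_entropy(flat, labels.reshape(-1))


def train_segmenter(network: ENet, samples: list[PhantomSample], epochs: int = 15,
                    seed: int = 0, lr: float = 1e-3, batch_size: int = 8,
                    ) -> tuple[ENet, list[float]]:
    """Minimise per-pixel cross-entropy against the kidney masks.

    Deterministic given ``seed``; returns the network and the per-epoch mean
    loss trace.
    """
    if not samples:
        raise ValueError("train_segmenter requires a non-empty dataset")
    images = np.stack([s.image.pixels for s in samples])[:, None]
    labels = np.stack([s.kidney_mask.labels for s in samples])
    rng = np.random.default_rng(seed)
    optimizer = nn.Adam(network.parameters(), lr=lr)
    network.train(True)
    trace: list[float] = []
    n = len(samples)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            batch = order[start:start + batch_size]
            logits = network(Tensor(images[batch]))
            loss = _pixel_cross_entropy(logits, labels[batch])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    network.trained_resolution = images.shape[2:]
    network.train(False)
    return network, trace


def segment_image(network: ENet, image: GrayImage | np.ndarray,
                  ) -> tuple[SegmentationMask, GrayImage]:
    """Argmax class map and the background-zeroed masked image."""
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    if network.trained_resolution is not None and \
            pixels.shape != tuple(network.trained_resolution):
        raise ValueError(
            f"image shape {pixels.shape} does not match the training resolution "
            f"{tuple(network.trained_resolution)}")
    network.train(False)
    logits = network(Tensor(pixels[None, None]))
    labels = logits.data[0].argmax(axis=0)
    mask = SegmentationMask(labels, n_classes=network.config.n_classes)
    masked = GrayImage(pixels * (labels == 1))
    return mask, masked


def iou(predicted: SegmentationMask | np.ndarray,
        truth: SegmentationMask | np.ndarray) -> float:
    """Foreground intersection-over-union in [0, 1]."""
    p = predicted.foreground() if isinstance(predicted, SegmentationMask) \
        else np.asarray(predicted) > 0
    t = truth.foreground() if isinstance(truth, SegmentationMask) \
        else np.asarray(truth) > 0
    union = (p | t).sum()
    return float((p & t).sum() / union) if union else 1.0
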