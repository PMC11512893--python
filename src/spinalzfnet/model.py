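"""The hybrid SpinalZFNet classifier.

Three learned components classify a segmented kidney image into
normal / cyst / tumor / stone:

* **SpinalNet** — the flattened masked image is cut into segments fed
  sequentially to narrow hidden sub-layers; sub-layer *k* receives its input
  segment concatenated with sub-layer *k−1*'s output, and the per-layer
  output projections are summed into C1.
* **Fusion layer** — learnable weighted sums project the full handcrafted
  feature vector (p), its statistical block (p1) and its shape block (p2)
  to a common fusion width; a logistic gate U = σ(affine(p, p1, p2)) blends
  them with C1 as

  ``C2 = U·p + ½·U·p1 + ⅙·(1−U)·p2 + 1/24·(1−U)(2−U)·C1``

* **ZFNet head** — C2 is lifted to a single-channel grid and passed through
  five convolutions (response normalisation after the first two, max pooling
  after the first, second and fifth), flattened, and mapped by fully
  connected layers to the 4 class logits.

Feature blocks are z-scored with statistics frozen at fit time and then
balanced by block size (each z-score is divided by the square root of its
block's length), so the four named blocks contribute comparable aggregate
energy to the learned projections regardless of dimensionality — without
this, the 1323-dimension texture block out-weighs the 4-dimension
statistical block by two orders of magnitude purely by count.  The whole
stack is differentiable end to end through the autodiff engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .autodiff import Tensor, concat
from .errors import ConfigurationError, SchemaError
from .features import BLOCK_SLICES, TOTAL_LENGTH, FeatureRecord, extract_record
from .images import GrayImage, SegmentationMask
from .phantom import CLASSES

SPINAL_IMAGE_SIZE = 64  # masked image is resized to 64×64 for the spinal branch


# ---------------------------------------------------------------------------
# SpinalNet branch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpinalNetConfig:
    input_split: int = 8
    hidden_width: int = 32
    n_layers: int = 8
    out_dim: int = 64
    activation: str = "relu"  # or "linear"
    dropout_p: float = 0.0

    def __post_init__(self):
        if self.input_split < 2:
            raise ConfigurationError(f"input_split must be >= 2, got {self.input_split}")
        if self.hidden_width < 1:
            raise ConfigurationError(f"hidden_width must be >= 1, got {self.hidden_width}")
        if self.activation not in ("relu", "linear"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")


class SpinalNet(nn.Module):
    """Split-input spinal classifier branch producing C1."""

    def __init__(self, in_dim: int, config: SpinalNetConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config or SpinalNetConfig()
        rng = rng or np.random.default_rng(0)
        cfg = self.config
        self.segment_length = -(-in_dim // cfg.input_split)  # ceil; zero-padded
        self.in_dim = in_dim
        layers, projections = [], []
        for k in range(cfg.n_layers):
            extra = cfg.hidden_width if k > 0 else 0
            layers.append(nn.Linear(self.segment_length + extra, cfg.hidden_width,
                                    rng=rng))
            projections.append(nn.Linear(cfg.hidden_width, cfg.out_dim, rng=rng))
        self.layers = layers
        self.projections = projections
        self.dropout = nn.Dropout(cfg.dropout_p, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        n = x.shape[0]
        padded_len = self.segment_length * cfg.input_split
        if x.shape[1] < padded_len:
            pad = Tensor(np.zeros((n, padded_len - x.shape[1])))
            x = concat([x, pad], axis=1)
        c1 = None
        prev = None
        for k, (layer, proj) in enumerate(zip(self.layers, self.projections)):
            seg_idx = k % cfg.input_split
            segment = x[:, seg_idx * self.segment_length:(seg_idx + 1) * self.segment_length]
            inp = segment if prev is None else concat([segment, prev], axis=1)
            hidden = layer(inp)
            if cfg.activation == "relu":
                hidden = hidden.relu()
            hidden = self.dropout(hidden)
            prev = hidden
            out = proj(hidden)
            c1 = out if c1 is None else c1 + out
        return c1


def spinalnet_forward(x: np.ndarray, network: SpinalNet) -> np.ndarray:
    """Convenience inference wrapper: (N, in_dim) array → C1 array."""
    return network(Tensor(np.atleast_2d(x))).data


# ---------------------------------------------------------------------------
# fusion layer
# ---------------------------------------------------------------------------

@dataclass
class FusionState:
    """Intermediate quantities of the fusion: useful for inspection/tests."""

    p: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    U: np.ndarray
    C1: np.ndarray
    C2: np.ndarray


class FusionLayer(nn.Module):
    """Gate-weighted blend of feature projections with the SpinalNet output.

    The Taylor-like coefficients 1, ½, ⅙, 1/24 of the blend are fixed; the
    projections (the weight coefficients X) and the gate are learned.  The
    logistic gate keeps U in (0, 1) so every blend coefficient stays bounded.
    """

    def __init__(self, fusion_dim: int = 64, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fusion_dim = fusion_dim
        self.full_map = nn.Linear(TOTAL_LENGTH, fusion_dim, bias=False, rng=rng)
        self.stat_map = nn.Linear(BLOCK_SLICES["stat"].stop - BLOCK_SLICES["stat"].start,
                                  fusion_dim, bias=False, rng=rng)
        self.shape_map = nn.Linear(BLOCK_SLICES["shape"].stop - BLOCK_SLICES["shape"].start,
                                   fusion_dim, bias=False, rng=rng)
        self.gate = nn.Linear(3 * fusion_dim, 1, rng=rng)

    def forward(self, features: Tensor, c1: Tensor,
                u_override: float | None = None) -> tuple[Tensor, FusionState]:
        p = self.full_map(features)
        p1 = self.stat_map(features[:, BLOCK_SLICES["stat"]])
        p2 = self.shape_map(features[:, BLOCK_SLICES["shape"]])
        if u_override is None:
            u = self.gate(concat([p, p1, p2], axis=1)).sigmoid()
        else:
            u = Tensor(np.full((features.shape[0], 1), float(u_override)))
        one_minus = 1.0 - u
        c2 = u * p + 0.5 * (u * p1) + (1.0 / 6.0) * (one_minus * p2) \
            + (1.0 / 24.0) * (one_minus * (2.0 - u) * c1)
        state = FusionState(p=p.data, p1=p1.data, p2=p2.data, U=u.data,
                            C1=c1.data, C2=c2.data)
        return c2, state


def fusion_forward(record: FeatureRecord, c1: np.ndarray, layer: FusionLayer,
                   u_override: float | None = None) -> tuple[np.ndarray, FusionState]:
    """Run the fusion on a single feature record (inference convenience)."""
    features = Tensor(record.concatenated()[None])
    c2, state = layer(features, Tensor(np.atleast_2d(c1)), u_override=u_override)
    return c2.data, state


# ---------------------------------------------------------------------------
# ZFNet head
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZfnetConfig:
    input_grid: int = 8
    conv_channels: tuple[int, ...] = (16, 32, 32, 32, 32)
    kernel: int = 3
    pool_stride: int = 2
    fc_widths: tuple[int, ...] = (64, 32)
    n_classes: int = 4
    lrn_size: int = 5
    fc_dropout_p: float = 0.0

    def __post_init__(self):
        if self.n_classes != 4:
            raise ConfigurationError(f"n_classes must be 4, got {self.n_classes}")
        if len(self.conv_channels) != 5:
            raise ConfigurationError("ZFNet uses exactly 5 convolutional layers")
        if self.pool_stride < 2:
            raise ConfigurationError(f"pool_stride must be >= 2, got {self.pool_stride}")


class ZFNet(nn.Module):
    """Five-convolution head: LRN after conv1/conv2, pooling after conv1,
    conv2 and conv5, then the fully connected stack to 4 logits."""

    def __init__(self, config: ZfnetConfig | None = None, in_dim: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config or ZfnetConfig()
        rng = rng or np.random.default_rng(0)
        cfg = self.config
        grid = cfg.input_grid
        self.lift = nn.Linear(in_dim, grid * grid, rng=rng)
        k, pad = cfg.kernel, cfg.kernel // 2
        chans = (1,) + cfg.conv_channels
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], k, padding=pad, rng=rng)
                      for i in range(5)]
        self.lrn = nn.LocalResponseNorm(size=cfg.lrn_size)
        # spatial size after pools following conv1, conv2 and conv5
        final = grid // (cfg.pool_stride ** 3)
        if final < 1:
            raise ConfigurationError(
                f"input_grid {grid} too small for three poolings of stride "
                f"{cfg.pool_stride}")
        flat = cfg.conv_channels[-1] * final * final
        widths = (flat,) + cfg.fc_widths + (cfg.n_classes,)
        self.fcs = [nn.Linear(widths[i], widths[i + 1], rng=rng)
                    for i in range(len(widths) - 1)]
        self.fc_dropout = nn.Dropout(cfg.fc_dropout_p, rng=rng)

    def forward(self, c2: Tensor) -> Tensor:
        from . import autodiff as ad
        cfg = self.config
        n = c2.shape[0]
        x = self.lift(c2).reshape(n, 1, cfg.input_grid, cfg.input_grid)
        for i, conv in enumerate(self.convs):
            x = conv(x).relu()
            if i in (0, 1):          # response normalisation after conv1, conv2
                x = self.lrn(x)
            if i in (0, 1, 4):       # pooling after conv1, conv2 and conv5
                x, _ = ad.maxpool2d(x, cfg.pool_stride)
        x = x.reshape(n, -(-x.size // n))
        for j, fc in enumerate(self.fcs):
            x = fc(x)
            if j < len(self.fcs) - 1:
                x = self.fc_dropout(x.relu())
        return x


def zfnet_forward(c2: np.ndarray, network: ZFNet) -> np.ndarray:
    """Inference convenience: C2 array → class logits."""
    network.train(False)
    return network(Tensor(np.atleast_2d(c2))).data


# ---------------------------------------------------------------------------
# the assembled classifier
# ---------------------------------------------------------------------------

class SpinalZFNet(nn.Module):
    """SpinalNet branch + fusion layer + ZFNet head, trained end to end."""

    def __init__(self, spinal_config: SpinalNetConfig | None = None,
                 zfnet_config: ZfnetConfig | None = None,
                 fusion_dim: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spinal = SpinalNet(SPINAL_IMAGE_SIZE ** 2,
                                spinal_config or SpinalNetConfig(out_dim=fusion_dim),
                                rng=rng)
        if self.spinal.config.out_dim != fusion_dim:
            raise ConfigurationError("SpinalNet out_dim must equal fusion_dim")
        self.fusion = FusionLayer(fusion_dim, rng=rng)
        self.zfnet = ZFNet(zfnet_config, in_dim=fusion_dim, rng=rng)
        self.feature_mean = np.zeros(TOTAL_LENGTH)
        self.feature_std = np.ones(TOTAL_LENGTH)
        # block-balancing weights: 1/sqrt(block length) per named block
        balance = np.ones(TOTAL_LENGTH)
        for block_slice in BLOCK_SLICES.values():
            balance[block_slice] = 1.0 / np.sqrt(block_slice.stop - block_slice.start)
        self.feature_balance = balance
        self.classes = CLASSES

    # -- feature scaling ---------------------------------------------------
    def fit_scaler(self, features: np.ndarray) -> None:
        self.feature_mean = features.mean(axis=0)
        std = features.std(axis=0)
        self.feature_std = np.where(std > 1e-8, std, 1.0)

    def scale(self, features: np.ndarray) -> np.ndarray:
        if features.shape[-1] != TOTAL_LENGTH:
            raise SchemaError(
                f"feature vector length {features.shape[-1]} does not match the "
                f"trained schema ({TOTAL_LENGTH}); block layout {BLOCK_SLICES}")
        return (features - self.feature_mean) / self.feature_std * self.feature_balance

    # -- forward -----------------------------------------------------------
    def forward(self, images_flat: Tensor, features: Tensor) -> Tensor:
        c1 = self.spinal(images_flat)
        c2, _ = self.fusion(features, c1)
        return self.zfnet(c2)

    def predict_proba(self, images_flat: np.ndarray, features: np.ndarray) -> np.ndarray:
        self.train(False)
        logits = self.forward(Tensor(np.atleast_2d(images_flat)),
                              Tensor(self.scale(np.atleast_2d(features))))
        return nn.softmax(logits.data)


def masked_spinal_input(image: GrayImage | np.ndarray,
                        mask: SegmentationMask | np.ndarray) -> np.ndarray:
    """Background-zeroed image resized to the spinal branch resolution, flat."""
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    fg = mask.foreground() if isinstance(mask, SegmentationMask) else np.asarray(mask) > 0
    masked = pixels * fg
    if masked.shape != (SPINAL_IMAGE_SIZE, SPINAL_IMAGE_SIZE):
        masked = resize(masked, (SPINAL_IMAGE_SIZE, SPINAL_IMAGE_SIZE),
                        anti_aliasing=True, preserve_range=True)
    return masked.reshape(-1)


def spinalzfnet_predict(image, mask, model: SpinalZFNet,
                        record: FeatureRecord | None = None) -> tuple[str, np.ndarray]:
    """Classify one image/mask pair; returns (label, probabilities).

    Deterministic at inference: the model is switched to eval mode and no
    randomness is consumed.
    """
    record = record or extract_record(image, mask)
    proba = model.predict_proba(masked_spinal_input(image, mask)[None],
                                record.concatenated()[None])[0]
    return model.classes[int(proba.argmax())], proba


@dataclass
class ClassificationDataset:
    """Precomputed arrays for classifier training/evaluation."""

    images: np.ndarray    # (N, 4096) masked spinal-branch inputs
    features: np.ndarray  # (N, 1652) raw (unscaled) feature records
    labels: np.ndarray    # (N,) int class indices
    ids: np.ndarray       # (N,) stable sample identifiers

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, index) -> "ClassificationDataset":
        return ClassificationDataset(self.images[index], self.features[index],
                                     self.labels[index], self.ids[index])


def build_dataset(samples, masks=None) -> ClassificationDataset:
    """Extract spinal inputs + feature records from phantom samples.

    ``masks`` optionally overrides each sample's kidney mask (e.g. with ENet
    predictions); ids come from generation provenance where available.
    """
    images, features, labels, ids = [], [], [], []
    for i, sample in enumerate(samples):
        mask = masks[i] if masks is not None else sample.kidney_mask
        record = extract_record(sample.image, mask, label=sample.label)
        images.append(masked_spinal_input(sample.image, mask))
        features.append(record.concatenated())
        labels.append(CLASSES.index(sample.label))
        ids.append(sample.provenance.get("index", i))
    return ClassificationDataset(np.stack(images), np.stack(features),
                                 np.array(labels), np.array(ids))
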