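"""Geometric augmentation of segmented images: padding, rotation, translation.

Rotation angles are restricted to [1°, 359°]; exact multiples of 90° are
dispatched to pure pixel permutations so that intensity is conserved to the
last bit.  Vacated regions are filled with a "black or white" value, chosen
per draw when augmenting a whole dataset.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import GrayImage, SegmentationMask
from .phantom import PhantomSample


@dataclass(frozen=True)
class AugmentationSpec:
    """Parameter ranges for dataset-level augmentation draws."""

    pad_px: int = 0
    max_shift: int = 8
    angle_range: tuple[float, float] = (1.0, 359.0)
    seed: int = 0

    def __post_init__(self):
        if self.pad_px < 0:
            raise ValueError(f"pad_px must be >= 0, got {self.pad_px}")
        lo, hi = self.angle_range
        if not (1.0 <= lo <= hi <= 359.0):
            raise ValueError(f"angle_range must lie within [1, 359], got {self.angle_range}")


def _as_pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)


def pad(image, pad_px: int, fill: float = 0.0) -> GrayImage:
    """Add ``pad_px`` fill-valued pixels on every side."""
    if pad_px < 0:
        raise ValueError(f"pad_px must be >= 0, got {pad_px}")
    pixels = _as_pixels(image)
    return GrayImage(np.pad(pixels, pad_px, constant_values=fill))


def rotate(image, angle_deg: float, fill: float = 0.0, order: int = 1) -> GrayImage:
    """Rotate about the image centre; bilinear interpolation, same shape out.

    ``order=0`` gives nearest-neighbour resampling (for label masks).
    """
    if not (1.0 <= angle_deg <= 359.0):
        raise ValueError(f"angle_deg must lie in [1, 359], got {angle_deg}")
    pixels = _as_pixels(image)
    if angle_deg % 90 == 0:
        out = np.rot90(pixels, k=int(angle_deg // 90))
    else:
        out = ndimage.rotate(pixels, angle_deg, reshape=False, order=order,
                             mode="constant", cval=fill)
        out = np.clip(out, 0.0, 1.0)
    return GrayImage(out.copy())


def translate(image, shift: tuple[int, int], fill: float = 0.0) -> GrayImage:
    """Integer-pixel shift by ``(dx, dy)`` (columns right, rows down)."""
    pixels = _as_pixels(image)
    h, w = pixels.shape
    dx, dy = int(shift[0]), int(shift[1])
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"shift {shift} out of bounds for {h}x{w} image")
    out = np.full_like(pixels, fill)
    src_x = slice(max(0, -dx), min(w, w - dx))
    src_y = slice(max(0, -dy), min(h, h - dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    out[dst_y, dst_x] = pixels[src_y, src_x]
    return GrayImage(out)


def _transform_sample(sample: PhantomSample, angle: float, shift: tuple[int, int],
                      fill: float) -> PhantomSample:
    image = translate(rotate(sample.image, angle, fill=fill), shift, fill=fill)
    # masks follow the image geometry with nearest-neighbour resampling and
    # background fill, so labels stay binary
    kidney = translate(rotate(GrayImage(sample.kidney_mask.labels.astype(float)),
                              angle, fill=0.0, order=0), shift, fill=0.0)
    lesion = translate(rotate(GrayImage(sample.lesion_mask.labels.astype(float)),
                              angle, fill=0.0, order=0), shift, fill=0.0)
    prov = dict(sample.provenance)
    prov["augmented"] = {"angle": angle, "shift": shift, "fill": fill}
    return PhantomSample(
        image=image,
        kidney_mask=SegmentationMask((kidney.pixels > 0.5).astype(np.int64)),
        lesion_mask=SegmentationMask((lesion.pixels > 0.5).astype(np.int64)),
        label=sample.label,
        provenance=prov,
    )


def augment_dataset(samples: list[PhantomSample], multiplier: int, seed: int = 0,
                    spec: AugmentationSpec | None = None) -> list[PhantomSample]:
    """Expand ``samples`` to ``multiplier ×`` its size with random transforms.

    Each source sample contributes ``multiplier - 1`` copies, each rotated by
    a uniform angle in [1°, 359°] and translated by uniform integer shifts,
    with a Bernoulli(0.5) black-or-white fill.  Labels (and masks) are
    preserved under all transforms.
    """
    if multiplier < 1:
        raise ValueError(f"multiplier must be >= 1, got {multiplier}")
    spec = spec or AugmentationSpec(seed=seed)
    rng = np.random.default_rng(seed)
    out = list(samples)
    for sample in samples:
        for _ in range(multiplier - 1):
            angle = rng.uniform(*spec.angle_range)
            shift = (int(rng.integers(-spec.max_shift, spec.max_shift + 1)),
                     int(rng.integers(-spec.max_shift, spec.max_shift + 1)))
            fill = float(rng.integers(0, 2))  # black or white
            copy_sample = _transform_sample(sample, angle, shift, fill)
            # unique stable id so training can canonicalise sample order
            base = sample.provenance.get("index", 0)
            copy_sample.provenance["index"] = base * 10_000 + len(out) + 1
            out.append(copy_sample)
    return out
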