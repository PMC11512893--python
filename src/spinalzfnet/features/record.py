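"""Assembly of the per-image feature record J = [J1, J2] + H_shape + H_stat.

The record is a fixed-length vector with named blocks:

* ``surf`` (J1): up to ``SURF_BUDGET`` 64-element descriptors by response
  rank, zero-padded to 320 slots;
* ``texture`` (J2): the 1323-element WLD/DWT/HOG vector;
* ``shape``: 5 region descriptors of the segmentation mask;
* ``stat``: 4 masked-intensity statistics.

Total fixed length 320 + 1323 + 5 + 4 = 1652.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..images import GrayImage, SegmentationMask
from .shape_stats import shape_features, statistical_features
from .surf import describe_surf, detect_surf
from .texture import HOG_LENGTH, texture_features

SURF_BUDGET = 5                      # keypoints kept (by response rank)
SURF_BLOCK = SURF_BUDGET * 64        # 320
TEXTURE_BLOCK = 3 * HOG_LENGTH       # 1323
SHAPE_BLOCK = 5
STAT_BLOCK = 4
TOTAL_LENGTH = SURF_BLOCK + TEXTURE_BLOCK + SHAPE_BLOCK + STAT_BLOCK  # 1652

BLOCK_SLICES = {
    "surf": slice(0, SURF_BLOCK),
    "texture": slice(SURF_BLOCK, SURF_BLOCK + TEXTURE_BLOCK),
    "shape": slice(SURF_BLOCK + TEXTURE_BLOCK, SURF_BLOCK + TEXTURE_BLOCK + SHAPE_BLOCK),
    "stat": slice(SURF_BLOCK + TEXTURE_BLOCK + SHAPE_BLOCK, TOTAL_LENGTH),
}


@dataclass
class FeatureRecord:
    surf_block: np.ndarray
    texture_block: np.ndarray
    shape_block: np.ndarray
    stat_block: np.ndarray
    label: str | None = None

    def __post_init__(self):
        expected = {
            "surf_block": SURF_BLOCK, "texture_block": TEXTURE_BLOCK,
            "shape_block": SHAPE_BLOCK, "stat_block": STAT_BLOCK,
        }
        for name, length in expected.items():
            block = np.asarray(getattr(self, name), dtype=np.float64)
            if block.shape != (length,):
                raise ValueError(f"{name} must have length {length}, got {block.shape}")
            setattr(self, name, block)

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.surf_block, self.texture_block,
                               self.shape_block, self.stat_block])

    @property
    def offsets(self) -> dict[str, slice]:
        return dict(BLOCK_SLICES)


def extract_record(image: GrayImage | np.ndarray,
                   mask: SegmentationMask | np.ndarray,
                   label: str | None = None,
                   hessian_threshold: float = 1e-4) -> FeatureRecord:
    """Run all four feature extractors on an aligned image/mask pair."""
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    surf_block = np.zeros(SURF_BLOCK)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # border-skipped points just leave zeros
        points = detect_surf(pixels, hessian_threshold=hessian_threshold,
                             max_points=SURF_BUDGET)
        # replicate-padded sampling: desk-scale frames are small relative to
        # the canonical 20σ descriptor window
        descriptors = describe_surf(pixels, points, pad_border=True)
    for i, desc in enumerate(descriptors[:SURF_BUDGET]):
        surf_block[i * 64:(i + 1) * 64] = desc.values
    return FeatureRecord(
        surf_block=surf_block,
        texture_block=texture_features(pixels),
        shape_block=shape_features(mask).as_array(),
        stat_block=statistical_features(pixels, mask),
        label=label,
    )
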