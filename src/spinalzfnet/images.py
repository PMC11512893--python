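"""In-memory rasters: grayscale images and per-pixel label masks.

Intensities live in [0, 1] float throughout the pipeline; 8-/16-bit files are
rescaled on read and quantised on write (see :mod:`spinalzfnet.cli_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GrayImage:
    """A 2-D intensity raster with values in [0, 1]."""

    pixels: np.ndarray
    pixel_size: float = 1.0  # physical units per pixel; informational only

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("image intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SegmentationMask:
    """A 2-D integer label raster aligned to an image."""

    labels: np.ndarray
    n_classes: int = 2

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.dtype == bool:
            self.labels = self.labels.astype(np.int64)
        if self.labels.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {self.labels.shape}")
        if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
            raise ValueError(f"mask labels must lie in [0, {self.n_classes})")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def foreground(self) -> np.ndarray:
        """Boolean raster of non-background pixels."""
        return self.labels > 0

    def n_foreground(self) -> int:
        return int(self.foreground().sum())
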