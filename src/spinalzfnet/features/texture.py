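"""Texture branch: Haar DWT subbands → Weber local descriptor → HOG.

One analysis level of the orthonormal Haar wavelet splits the image into an
approximation (LL) and detail subbands; the LL, LH and HH channels are kept
for the texture chain (HL is computed — e.g. for the Parseval energy check —
but not fed forward).  Each retained subband is summarised by its Weber
differential-excitation map, arctan of the summed relative differences to
the 8-neighbourhood, which responds to local contrast the way Weber's law
predicts perception does.  A histogram-of-oriented-gradients descriptor over
the excitation map (64×64 window, 16×16-px cells at stride 8 → 7×7 grid,
9 unsigned orientation bins → 441 values per channel) yields the final
texture vector J2 of length 3 × 441 = 1323.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from skimage.transform import resize

from ..images import GrayImage

HOG_WINDOW = 64
HOG_CELL = 16
HOG_STRIDE = 8
HOG_BINS = 9
HOG_GRID = (HOG_WINDOW - HOG_CELL) // HOG_STRIDE + 1  # 7
HOG_LENGTH = HOG_GRID * HOG_GRID * HOG_BINS           # 441

WLD_EPS = 1e-3  # positivity shift before the Weber ratio


@dataclass
class SubbandSet:
    """One-level Haar subbands; ``hl`` is retained for energy accounting only."""

    ll: np.ndarray
    lh: np.ndarray
    hh: np.ndarray
    hl: np.ndarray
    mean_coeff: float

    @property
    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.ll, self.lh, self.hh

    def energy(self) -> float:
        """Total coefficient energy; equals the image energy (Parseval)."""
        return float(sum((b ** 2).sum() for b in (self.ll, self.lh, self.hl, self.hh)))


@dataclass
class WldMaps:
    excitation: np.ndarray  # arctan of summed relative differences, in (-π/2, π/2)
    orientation: np.ndarray
    magnitude: np.ndarray   # sqrt(Ax² + Ay²)
    ratio: np.ndarray       # Ay / Ax (0 where Ax = 0)


def dwt_decompose(image: GrayImage | np.ndarray) -> SubbandSet:
    """One-level orthonormal Haar analysis of a 2-D raster."""
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    if min(pixels.shape) < 2:
        raise ValueError(f"image too small for a DWT level: {pixels.shape}")
    ll, (lh, hl, hh) = pywt.dwt2(pixels, "haar")
    mean_coeff = float(np.mean(np.concatenate(
        [b.ravel() for b in (ll, lh, hl, hh)])))
    return SubbandSet(ll=ll, lh=lh, hh=hh, hl=hl, mean_coeff=mean_coeff)


def _neighbour_shifts(x: np.ndarray) -> list[np.ndarray]:
    """The 8-neighbourhood of every pixel, edges replicated."""
    padded = np.pad(x, 1, mode="edge")
    shifts = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            shifts.append(padded[1 + dy: 1 + dy + x.shape[0],
                                 1 + dx: 1 + dx + x.shape[1]])
    return shifts


def wld_maps(subband: np.ndarray) -> WldMaps:
    """Weber differential excitation and gradient maps of one subband.

    The subband is affinely shifted to [ε, 1+ε] first so the Weber ratio
    (difference over the centre value) is always defined.
    """
    x = np.asarray(subband, dtype=np.float64)
    lo, hi = x.min(), x.max()
    scale = hi - lo
    x = (x - lo) / scale + WLD_EPS if scale > 0 else np.full_like(x, WLD_EPS)
    if np.any(x <= 0):
        raise AssertionError("subband not strictly positive after shift")
    total = np.zeros_like(x)
    for neighbour in _neighbour_shifts(x):
        total += (neighbour - x) / x
    excitation = np.arctan(total)
    # horizontal/vertical gradients from the (-1, 0, 1) kernels, edge-replicated
    padded = np.pad(x, 1, mode="edge")
    ax = padded[1:-1, 2:] - padded[1:-1, :-2]
    ay = padded[2:, 1:-1] - padded[:-2, 1:-1]
    magnitude = np.sqrt(ax ** 2 + ay ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ax != 0, ay / np.where(ax != 0, ax, 1.0), 0.0)
    orientation = np.arctan(ratio)
    return WldMaps(excitation=excitation, orientation=orientation,
                   magnitude=magnitude, ratio=ratio)


def hog_extract(channel: np.ndarray) -> np.ndarray:
    """HOG over a 64×64 window: 7×7 overlapping cells × 9 unsigned bins = 441.

    Gradients come from central differences; each pixel votes its gradient
    magnitude into the two orientation bins bracketing its unsigned angle
    (linear interpolation).  Cell histograms are summed over 16×16 windows
    placed at stride 8, and the concatenated vector is L2-normalised.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.shape != (HOG_WINDOW, HOG_WINDOW):
        raise ValueError(
            f"HOG expects a {HOG_WINDOW}x{HOG_WINDOW} window, got {channel.shape}")
    padded = np.pad(channel, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    magnitude = np.sqrt(gx ** 2 + gy ** 2)
    angle = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    # per-pixel soft votes into the 9 bins (bin centres at 10°, 30°, ..., 170°? no:
    # bin b covers [20b, 20b+20); linear interpolation between bin centres 20b+10)
    votes = np.zeros((HOG_BINS, HOG_WINDOW, HOG_WINDOW))
    pos = angle / 20.0 - 0.5
    lower = np.floor(pos).astype(int)
    frac = pos - lower
    lower_bin = lower % HOG_BINS
    upper_bin = (lower + 1) % HOG_BINS
    idx = np.indices(angle.shape)
    votes[lower_bin, idx[0], idx[1]] += magnitude * (1 - frac)
    votes[upper_bin, idx[0], idx[1]] += magnitude * frac
    # box-sum each bin plane over 16×16 cells at stride 8 via an integral image
    out = np.zeros((HOG_GRID, HOG_GRID, HOG_BINS))
    for b in range(HOG_BINS):
        ii = np.zeros((HOG_WINDOW + 1, HOG_WINDOW + 1))
        ii[1:, 1:] = votes[b].cumsum(0).cumsum(1)
        for i in range(HOG_GRID):
            for j in range(HOG_GRID):
                y0, x0 = i * HOG_STRIDE, j * HOG_STRIDE
                out[i, j, b] = (ii[y0 + HOG_CELL, x0 + HOG_CELL] - ii[y0, x0 + HOG_CELL]
                                - ii[y0 + HOG_CELL, x0] + ii[y0, x0])
    flat = out.reshape(HOG_LENGTH)
    norm = np.linalg.norm(flat)
    return flat / norm if norm > 0 else flat


def texture_features(image: GrayImage | np.ndarray) -> np.ndarray:
    """The J2 texture vector: HOG of the WLD excitation of LL, LH and HH."""
    bands = dwt_decompose(image)
    parts = []
    for channel in bands.channels:
        excitation = wld_maps(channel).excitation
        if excitation.shape != (HOG_WINDOW, HOG_WINDOW):
            excitation = resize(excitation, (HOG_WINDOW, HOG_WINDOW),
                                anti_aliasing=False, preserve_range=True)
        parts.append(hog_extract(excitation))
    return np.concatenate(parts)
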