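"""Speeded-Up Robust Features: Hessian box-filter detector and descriptor.

The detector approximates the scale-normalised Hessian determinant with
integral-image box filters (sizes 9, 15, 21, 27 and 15, 27, 39, 51 over two
octaves), applies 3×3×3 non-maximum suppression in image/scale space,
refines each maximum by quadratic interpolation, and keeps the strongest
responses.  The descriptor assigns a dominant orientation from Haar-wavelet
responses in a 6σ disc (sliding 60° window) and summarises a 20σ oriented
square as a 4×4 grid of (Σdx, Σdy, Σ|dx|, Σ|dy|) sums, L2-normalised to a
64-vector — which makes it invariant to affine illumination scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..images import GrayImage

# filter sizes per octave; σ = 1.2 · L / 9
OCTAVE_SIZES = ((9, 15, 21, 27), (15, 27, 39, 51))
HESSIAN_WEIGHT = 0.81  # 0.9² balance weight on the mixed second derivative


@dataclass
class InterestPoint:
    x: float
    y: float
    scale: float
    response: float
    orientation: float = 0.0


@dataclass
class SurfDescriptor:
    point: InterestPoint
    values: np.ndarray  # 64 floats, unit norm

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (64,):
            raise ValueError("descriptor must have exactly 64 values")


def _integral(image: np.ndarray) -> np.ndarray:
    ii = np.zeros((image.shape[0] + 1, image.shape[1] + 1))
    ii[1:, 1:] = image.cumsum(0).cumsum(1)
    return ii


def _box_map(ii: np.ndarray, h: int, w: int, dy: int, dx: int,
             out_h: int, out_w: int, b: int) -> np.ndarray:
    """Sum of the h×w box whose top-left is offset (dy, dx) from each centre.

    Returns the map for centres in [b, H-b) × [b, W-b); callers embed it into
    a zero background.
    """
    y0 = b + dy
    x0 = b + dx
    return (ii[y0 + h: y0 + h + out_h, x0 + w: x0 + w + out_w]
            - ii[y0: y0 + out_h, x0 + w: x0 + w + out_w]
            - ii[y0 + h: y0 + h + out_h, x0: x0 + out_w]
            + ii[y0: y0 + out_h, x0: x0 + out_w])


def _det_hessian_map(ii: np.ndarray, size: int, shape: tuple[int, int]) -> np.ndarray:
    """Box-filter Hessian determinant, area-normalised, zero near borders."""
    height, width = shape
    l = size // 3
    b = size // 2
    out_h, out_w = height - 2 * b, width - 2 * b
    if out_h <= 0 or out_w <= 0:
        return np.zeros(shape)
    half_w = (2 * l - 1) // 2
    # the lobe l is odd for every filter size used, so the 3l-row filter is
    # symmetric about the centre: bands start at -(3l-1)/2, step l
    start = -((3 * l - 1) // 2)
    # Dyy: three stacked l-tall bands of width 2l-1, weights +1, -2, +1
    dyy = (_box_map(ii, l, 2 * l - 1, start, -half_w, out_h, out_w, b)
           - 2.0 * _box_map(ii, l, 2 * l - 1, start + l, -half_w, out_h, out_w, b)
           + _box_map(ii, l, 2 * l - 1, start + 2 * l, -half_w, out_h, out_w, b))
    dxx = (_box_map(ii, 2 * l - 1, l, -half_w, start, out_h, out_w, b)
           - 2.0 * _box_map(ii, 2 * l - 1, l, -half_w, start + l, out_h, out_w, b)
           + _box_map(ii, 2 * l - 1, l, -half_w, start + 2 * l, out_h, out_w, b))
    # Dxy: four l×l quadrant boxes offset 1 px from the centre axes
    dxy = (_box_map(ii, l, l, -l, 1, out_h, out_w, b)
           + _box_map(ii, l, l, 1, -l, out_h, out_w, b)
           - _box_map(ii, l, l, -l, -l, out_h, out_w, b)
           - _box_map(ii, l, l, 1, 1, out_h, out_w, b))
    norm = 1.0 / (size * size)
    det = (dxx * norm) * (dyy * norm) - HESSIAN_WEIGHT * (dxy * norm) ** 2
    full = np.zeros(shape)
    full[b: b + out_h, b: b + out_w] = det
    return full


def detect_surf(image: GrayImage | np.ndarray, hessian_threshold: float = 1e-4,
                max_points: int = 5) -> list[InterestPoint]:
    """Locate interest points as interpolated 3×3×3 maxima of the Hessian map."""
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    if min(pixels.shape) < 32:
        raise ValueError(f"image too small for SURF: {pixels.shape} (need >= 32)")
    ii = _integral(pixels)
    points: list[InterestPoint] = []
    for sizes in OCTAVE_SIZES:
        stack = np.stack([_det_hessian_map(ii, s, pixels.shape) for s in sizes])
        local_max = ndimage.maximum_filter(stack, size=3, mode="constant")
        cand = (stack == local_max) & (stack > hessian_threshold)
        cand[0] = cand[-1] = False  # only interior scales can be maxima
        for s, y, x in zip(*np.nonzero(cand)):
            # quadratic refinement of (x, y, scale) around the discrete maximum
            d = stack
            grad = 0.5 * np.array([d[s, y, x + 1] - d[s, y, x - 1],
                                   d[s, y + 1, x] - d[s, y - 1, x],
                                   d[s + 1, y, x] - d[s - 1, y, x]]) \
                if 0 < y < d.shape[1] - 1 and 0 < x < d.shape[2] - 1 else np.zeros(3)
            offset = np.zeros(3)
            if grad.any():
                hxx = d[s, y, x + 1] - 2 * d[s, y, x] + d[s, y, x - 1]
                hyy = d[s, y + 1, x] - 2 * d[s, y, x] + d[s, y - 1, x]
                hss = d[s + 1, y, x] - 2 * d[s, y, x] + d[s - 1, y, x]
                hess = np.diag([hxx if hxx else 1.0, hyy if hyy else 1.0,
                                hss if hss else 1.0])
                try:
                    offset = np.clip(-np.linalg.solve(hess, grad), -0.5, 0.5)
                except np.linalg.LinAlgError:
                    offset = np.zeros(3)
            size = sizes[s] + offset[2] * (sizes[s + 1] - sizes[s])
            points.append(InterestPoint(
                x=float(x + offset[0]), y=float(y + offset[1]),
                scale=1.2 * size / 9.0, response=float(d[s, y, x])))
    points.sort(key=lambda p: -p.response)
    # deduplicate across octaves (same structure found at shared filter sizes)
    kept: list[InterestPoint] = []
    for p in points:
        if all((p.x - q.x) ** 2 + (p.y - q.y) ** 2 > 4.0 or
               abs(p.scale - q.scale) > 0.3 for q in kept):
            kept.append(p)
        if len(kept) >= max_points:
            break
    return kept


def _haar(ii: np.ndarray, y: int, x: int, s: int) -> tuple[float, float]:
    """Haar responses of size 2s × 2s centred at (y, x); 0 if out of bounds."""
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    if y - s < 0 or x - s < 0 or y + s > h or x + s > w:
        return 0.0, 0.0

    def box(y0, x0, hh, ww):
        return ii[y0 + hh, x0 + ww] - ii[y0, x0 + ww] - ii[y0 + hh, x0] + ii[y0, x0]

    dx = box(y - s, x, 2 * s, s) - box(y - s, x - s, 2 * s, s)
    dy = box(y, x - s, s, 2 * s) - box(y - s, x - s, s, 2 * s)
    return dx, dy


def _dominant_orientation(ii: np.ndarray, point: InterestPoint) -> float:
    s = max(1, int(round(point.scale)))
    cx, cy = int(round(point.x)), int(round(point.y))
    responses = []
    for i in range(-6, 7):
        for j in range(-6, 7):
            if i * i + j * j > 36:
                continue
            dx, dy = _haar(ii, cy + j * s, cx + i * s, 2 * s)
            if dx == 0.0 and dy == 0.0:
                continue
            weight = np.exp(-(i * i + j * j) / (2 * 2.0 ** 2))
            responses.append((np.arctan2(dy, dx), weight * dx, weight * dy))
    if not responses:
        return 0.0
    angles = np.array([r[0] for r in responses])
    dxs = np.array([r[1] for r in responses])
    dys = np.array([r[2] for r in responses])
    best_angle, best_norm = 0.0, -1.0
    for w0 in np.arange(-np.pi, np.pi, 0.1):
        diff = (angles - w0) % (2 * np.pi)
        in_window = diff < np.pi / 3
        sx, sy = dxs[in_window].sum(), dys[in_window].sum()
        norm = sx * sx + sy * sy
        if norm > best_norm:
            best_norm, best_angle = norm, np.arctan2(sy, sx)
    return float(best_angle)


def describe_surf(image: GrayImage | np.ndarray,
                  points: list[InterestPoint],
                  pad_border: bool = False) -> list[SurfDescriptor]:
    """Build the 64-element oriented descriptor for each point.

    By default, points whose 20σ sampling window leaves the image are
    skipped with a warning rather than raising.  With ``pad_border=True``
    the image is edge-replicated so the window always fits — the intended
    mode for frames small relative to the descriptor footprint (e.g. 64 px
    phantoms, where the canonical window would otherwise reject nearly
    every point).
    """
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    offset = 0
    if pad_border and points:
        margin = int(max(np.ceil(20.0 * max(1.0, p.scale)) for p in points)) + 2
        pixels = np.pad(pixels, margin, mode="edge")
        points = [InterestPoint(x=p.x + margin, y=p.y + margin, scale=p.scale,
                                response=p.response, orientation=p.orientation)
                  for p in points]
        offset = margin
    ii = _integral(pixels)
    h, w = pixels.shape
    descriptors = []
    for point in points:
        s = max(1.0, point.scale)
        theta = _dominant_orientation(ii, point)
        point.orientation = theta
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        hs = max(1, int(round(s)))
        vec = np.zeros((4, 4, 4))
        ok = True
        for sub_i in range(4):
            for sub_j in range(4):
                for ii_s in range(5):
                    for jj_s in range(5):
                        # sample position in the oriented frame, units of σ
                        u = (sub_i - 2) * 5 + ii_s + 0.5
                        v = (sub_j - 2) * 5 + jj_s + 0.5
                        gx = point.x + s * (u * cos_t - v * sin_t)
                        gy = point.y + s * (u * sin_t + v * cos_t)
                        xi, yi = int(round(gx)), int(round(gy))
                        if not (hs <= xi < w - hs and hs <= yi < h - hs):
                            ok = False
                            break
                        dx, dy = _haar(ii, yi, xi, hs)
                        weight = np.exp(-(u * u + v * v) / (2 * 3.3 ** 2))
                        rdx = weight * (cos_t * dx + sin_t * dy)
                        rdy = weight * (-sin_t * dx + cos_t * dy)
                        vec[sub_i, sub_j] += (rdx, rdy, abs(rdx), abs(rdy))
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            warnings.warn(
                f"SURF point at ({point.x:.0f}, {point.y:.0f}) too close to the "
                "border for its window; skipped", stacklevel=2)
            continue
        flat = vec.reshape(64)
        norm = np.linalg.norm(flat)
        if norm > 0:
            flat = flat / norm
        if offset:
            point = InterestPoint(x=point.x - offset, y=point.y - offset,
                                  scale=point.scale, response=point.response,
                                  orientation=point.orientation)
        descriptors.append(SurfDescriptor(point=point, values=flat))
    return descriptors
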