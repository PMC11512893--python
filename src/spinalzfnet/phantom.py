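"""Synthetic kidney-CT phantom generator.

Real abdominal CT slices of the four diagnostic classes (normal, cyst, tumor,
stone) are emulated by a bright kidney-shaped ellipse on a dark background
with one class-specific lesion:

* **cyst** — a round, low-intensity (fluid-dark) inclusion;
* **stone** — a tiny near-saturated calcified speck (≤ 5 px);
* **tumor** — an irregular soft-tissue mass of intermediate intensity;
* **normal** — no lesion.

Mean lesion intensity on noise-free phantoms therefore orders
stone > parenchyma > tumor > cyst, which downstream texture/statistical
features can exploit.  Additive Gaussian noise models detector noise and
salt-and-pepper impulses give the median filter something to remove.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .images import GrayImage, SegmentationMask

CLASSES = ("normal", "cyst", "tumor", "stone")

# nominal intensities (fraction of full scale)
BACKGROUND = 0.1
PARENCHYMA = 0.6
CYST_INTENSITY = 0.22
TUMOR_INTENSITY = 0.42
STONE_INTENSITY = 0.97


@dataclass(frozen=True)
class PhantomSpec:
    """Generation conditions for a phantom dataset."""

    image_size: int = 128
    n_per_class: int = 10
    classes: tuple[str, ...] = CLASSES
    noise_sd: float = 0.03
    impulse_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ConfigurationError(f"image_size must be >= 64, got {self.image_size}")
        if self.n_per_class < 1:
            raise ConfigurationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if not (0.0 <= self.impulse_frac <= 0.2):
            raise ConfigurationError(
                f"impulse_frac must lie in [0, 0.2], got {self.impulse_frac}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        unknown = set(self.classes) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"classes contains unknown labels {sorted(unknown)}")


@dataclass
class PhantomSample:
    image: GrayImage
    kidney_mask: SegmentationMask
    lesion_mask: SegmentationMask
    label: str
    provenance: dict = field(default_factory=dict)

    @property
    def label_index(self) -> int:
        return CLASSES.index(self.label)


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float,
                  theta: float, radial_wobble: np.ndarray | None = None) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    r2 = (u / a) ** 2 + (v / b) ** 2
    if radial_wobble is None:
        return r2 <= 1.0
    # irregular boundary: modulate the unit radius sinusoidally in polar angle
    phi = np.arctan2(v / b, u / a)
    limit = 1.0 + sum(
        amp * np.sin(k * phi + psi) for k, (amp, psi) in enumerate(radial_wobble, start=2))
    return np.sqrt(r2) <= limit


def _draw_sample(label: str, spec: PhantomSpec, rng: np.random.Generator) -> PhantomSample:
    size = spec.image_size
    cx = size / 2 + rng.uniform(-0.05, 0.05) * size
    cy = size / 2 + rng.uniform(-0.05, 0.05) * size
    a = rng.uniform(0.28, 0.36) * size
    b = rng.uniform(0.18, 0.24) * size
    theta = rng.uniform(0, np.pi)
    kidney = _ellipse_mask(size, cx, cy, a, b, theta)

    img = np.full((size, size), BACKGROUND)
    img[kidney] = PARENCHYMA

    lesion = np.zeros((size, size), dtype=bool)
    prov = {"label": label, "center": (cx, cy), "axes": (a, b), "theta": theta}
    if label != "normal":
        # lesion center well inside the ellipse (<= 0.45 of each semi-axis)
        fu = rng.uniform(-0.45, 0.45)
        fv = rng.uniform(-0.45, 0.45)
        lx = cx + fu * a * np.cos(theta) - fv * b * np.sin(theta)
        ly = cy + fu * a * np.sin(theta) + fv * b * np.cos(theta)
        if label == "cyst":
            r = rng.uniform(0.08, 0.13) * size
            lesion = _ellipse_mask(size, lx, ly, r, r, 0.0)
            intensity = CYST_INTENSITY
        elif label == "tumor":
            r = rng.uniform(0.09, 0.14) * size
            wobble = [(rng.uniform(0.1, 0.25), rng.uniform(0, 2 * np.pi)) for _ in range(3)]
            lesion = _ellipse_mask(size, lx, ly, r, r * rng.uniform(0.7, 1.0),
                                   rng.uniform(0, np.pi), radial_wobble=wobble)
            intensity = TUMOR_INTENSITY
        else:  # stone: a <=5-px near-saturated speck (centre pixel + 4-neighbours)
            ix, iy = int(round(lx)), int(round(ly))
            for ddx, ddy in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
                px, py = ix + ddx, iy + ddy
                if 0 <= py < size and 0 <= px < size:
                    lesion[py, px] = True
            intensity = STONE_INTENSITY
        lesion &= kidney  # lesions never extend beyond the organ
        img[lesion] = intensity
        prov["lesion_center"] = (lx, ly)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    if spec.impulse_frac > 0:
        n_hits = int(round(spec.impulse_frac * img.size))
        flat = rng.choice(img.size, size=n_hits, replace=False)
        values = rng.integers(0, 2, size=n_hits).astype(float)  # salt or pepper
        img.reshape(-1)[flat] = values
    img = np.clip(img, 0.0, 1.0)

    return PhantomSample(
        image=GrayImage(img),
        kidney_mask=SegmentationMask(kidney.astype(np.int64)),
        lesion_mask=SegmentationMask(lesion.astype(np.int64)),
        label=label,
        provenance=prov,
    )


def generate(spec: PhantomSpec) -> list[PhantomSample]:
    """Generate ``n_per_class × len(classes)`` samples, deterministically in seed.

    Samples are ordered class-by-class in the order given by ``spec.classes``.
    """
    rng = np.random.default_rng(spec.seed)
    samples = []
    for label in spec.classes:
        for i in range(spec.n_per_class):
            sample = _draw_sample(label, spec, rng)
            sample.provenance["index"] = len(samples)
            samples.append(sample)
    return samples


def write_dataset(samples: list[PhantomSample], directory: str | Path) -> Path:
    """Write PNG images + masks and a ``filename,label,mask`` CSV manifest."""
    from .cli_io import write_image  # local import avoids a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "mask"])
        for i, sample in enumerate(samples):
            stem = f"{i:05d}_{sample.label}"
            img_name, mask_name = f"{stem}.png", f"{stem}_mask.png"
            write_image(directory / img_name, sample.image.pixels)
            write_image(directory / mask_name, sample.kidney_mask.labels.astype(float))
            write_image(directory / f"{stem}_lesion.png",
                        sample.lesion_mask.labels.astype(float))
            writer.writerow([img_name, sample.label, mask_name])
    return manifest
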