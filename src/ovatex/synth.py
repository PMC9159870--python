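"""Synthetic two-class ultrasound-like textures and noise injection.

The study images behind the pipeline (contrast-enhanced ultrasound of ovarian
masses) are not public, so this module produces labeled surrogate textures
that carry the statistical contrasts the feature extractors measure:

* class 0, "benign-like": a smooth random base field (Gaussian-blurred white
  noise) under multiplicative speckle — the granular, low-high-frequency
  texture of a homogeneous lesion;
* class 1, "malignant-like": the same field plus sparse bright spots and thin
  linear edge segments, mimicking the heterogeneous, vascularized internal
  architecture of malignant masses.  The additions give class 1 strictly
  higher high-frequency (spot/edge) energy in expectation.

Speckle is modeled multiplicatively, the standard assumption for ultrasound.
All images are float grids in [0, 1].  Generation is deterministic: image
``index`` under seed ``s`` draws its base field and speckle from an RNG keyed
on ``(s, index)`` and its malignant additions from a separate substream, so
an image does not depend on how many others are generated, and a class-1
image with zero spots and zero edges degenerates exactly to its class-0
counterpart.

``inject_noise`` corrupts an image with Gaussian, salt-and-pepper or speckle
noise for denoising experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SyntheticConfig",
    "LabeledImageSet",
    "generate_texture_image",
    "generate_dataset",
    "inject_noise",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults define the package's benchmark conditions.

    Parameters
    ----------
    n_per_class:
        Images per class (benchmark default 100, i.e. 200 total).
    image_size:
        (rows, cols); at least 16x16 so the largest LBP circle (r=3) and the
        7x7 texture-energy window fit.
    benign_smoothness:
        Gaussian blur sigma (pixels) of the base field; larger = smoother
        lesion background.
    malignant_spot_density:
        Fraction of pixels receiving a bright spot in class-1 images.
    malignant_edge_count:
        Number of thin bright line segments added to class-1 images.
    speckle_scale:
        Relative SD of the multiplicative speckle field.
    """

    n_per_class: int = 100
    image_size: tuple[int, int] = (128, 128)
    benign_smoothness: float = 3.0
    malignant_spot_density: float = 0.02
    malignant_edge_count: int = 6
    speckle_scale: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        rows, cols = self.image_size
        if rows < 16 or cols < 16:
            raise ValueError("image_size must be at least 16x16")
        if self.benign_smoothness <= 0:
            raise ValueError("benign_smoothness must be positive")
        if not 0 <= self.malignant_spot_density <= 1:
            raise ValueError("malignant_spot_density must lie in [0, 1]")
        if self.malignant_edge_count < 0:
            raise ValueError("malignant_edge_count must be nonnegative")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be positive")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


@dataclass(frozen=True)
class LabeledImageSet:
    images: list[np.ndarray]
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if len(self.images) != labels.size:
            raise ValueError("images and labels must have equal length")
        if labels.size and not np.isin(labels, [0, 1]).all():
            raise ValueError("labels must be 0 (benign-like) or 1 (malignant-like)")

    def __len__(self) -> int:
        return len(self.images)


def _draw_segment(img: np.ndarray, rng: np.random.Generator) -> None:
    """Add one thin bright line segment with random position/orientation."""
    rows, cols = img.shape
    length = rng.uniform(0.2, 0.5) * min(rows, cols)
    theta = rng.uniform(0, np.pi)
    r0 = rng.uniform(0, rows - 1)
    c0 = rng.uniform(0, cols - 1)
    n_pts = max(int(2 * length), 2)
    t = np.linspace(0, length, n_pts)
    rr = np.clip(np.round(r0 + t * np.sin(theta)).astype(int), 0, rows - 1)
    cc = np.clip(np.round(c0 + t * np.cos(theta)).astype(int), 0, cols - 1)
    img[rr, cc] += rng.uniform(0.4, 0.7)


def generate_texture_image(
    class_label: int, config: SyntheticConfig, index: int = 0
) -> np.ndarray:
    """One synthetic texture of the given class, deterministic in (config, index)."""
    if class_label not in (0, 1):
        raise ValueError(f"class_label must be 0 or 1, got {class_label!r}")
    if not 0 <= index < config.n_per_class:
        raise ValueError(f"index {index} out of range [0, {config.n_per_class})")
    rng = np.random.default_rng([config.seed, index])
    rows, cols = config.image_size

    base = ndimage.gaussian_filter(
        rng.standard_normal((rows, cols)), config.benign_smoothness, mode="reflect"
    )
    lo, hi = base.min(), base.max()
    span = hi - lo if hi > lo else 1.0
    img = 0.25 + 0.5 * (base - lo) / span  # smooth field in [0.25, 0.75]

    if class_label == 1:
        # separate substream so zero spots + zero edges collapses to class 0
        mrng = np.random.default_rng([config.seed, index, 1])
        if config.malignant_spot_density > 0:
            spots = mrng.random((rows, cols)) < config.malignant_spot_density
            img[spots] += mrng.uniform(0.3, 0.6, size=int(spots.sum()))
        for _ in range(config.malignant_edge_count):
            _draw_segment(img, mrng)

    img *= 1.0 + config.speckle_scale * rng.standard_normal((rows, cols))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(config: SyntheticConfig) -> LabeledImageSet:
    """2*n_per_class images: all benign-like first, then all malignant-like."""
    images = [
        generate_texture_image(cls, config, i)
        for cls in (0, 1)
        for i in range(config.n_per_class)
    ]
    labels = np.repeat([0, 1], config.n_per_class)
    return LabeledImageSet(images=images, labels=labels)


def inject_noise(image, kind: str, level: float, seed: int = 0) -> np.ndarray:
    """Corrupt an image with one of the supported noise models, clipping to [0,1].

    * ``gaussian`` — add N(0, level^2) to every pixel;
    * ``salt_pepper`` — set a fraction ``level`` of pixels to 0 or 1 with
      equal probability;
    * ``speckle`` — multiply by (1 + level * N(0,1)).
    """
    arr = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if level <= 0:
        raise ValueError("noise level must be positive")
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        noisy = arr + level * rng.standard_normal(arr.shape)
    elif kind == "salt_pepper":
        noisy = arr.copy()
        hit = rng.random(arr.shape) < level
        noisy[hit] = rng.choice([0.0, 1.0], size=int(hit.sum()))
    elif kind == "speckle":
        noisy = arr * (1.0 + level * rng.standard_normal(arr.shape))
    else:
        raise ValueError(f"unknown noise kind: {kind!r}")
    return np.clip(noisy, 0.0, 1.0)
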