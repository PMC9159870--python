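"""Laws' texture-energy features from the nine separable 3x3 masks.

The three 1-D kernels — level L3 = [1,2,1], border/edge B3 = [-1,0,1] and
dot/spot D3 = [-1,2,-1] — combine by outer product into nine 3x3 masks
(L3L3, L3B3, ..., D3D3).  All but L3L3 are zero-mean, so they suppress flat
regions and respond to edges, spots and their combinations.

Pipeline per mask: cross-correlate the image with the mask (symmetric
padding, same-shape output), divide pointwise by the L3L3 response to remove
local-contrast dependence ("balancing"), then aggregate with the texture
energy metric (TEM) — a 7x7 moving-window sum of absolute values.  The mean
of each TEM map over the eight zero-sum masks gives eight nonnegative,
contrast-invariant descriptors.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "MASK_NAMES",
    "build_masks",
    "filter_image",
    "balance",
    "tem",
    "laws_features",
]

_KERNELS_1D = {
    "L3": np.array([1, 2, 1]),
    "B3": np.array([-1, 0, 1]),
    "D3": np.array([-1, 2, -1]),
}

MASK_NAMES: tuple[str, ...] = (
    "L3L3", "L3B3", "L3D3",
    "B3L3", "B3B3", "B3D3",
    "D3L3", "D3B3", "D3D3",
)

TEM_WINDOW = 7
DEFAULT_EPSILON = 1e-8


def build_masks() -> dict[str, np.ndarray]:
    """The nine outer-product masks; mask XY = X^T (column) times Y (row)."""
    return {
        x + y: np.outer(_KERNELS_1D[x], _KERNELS_1D[y])
        for x in _KERNELS_1D
        for y in _KERNELS_1D
    }


def filter_image(image, mask) -> np.ndarray:
    """2-D cross-correlation with symmetric padding, same-shape output."""
    arr = np.asarray(image, dtype=float)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image {arr.shape} smaller than the 3x3 mask")
    # ndimage 'reflect' is half-sample symmetric extension
    return ndimage.correlate(arr, np.asarray(mask, dtype=float), mode="reflect")


def balance(tp, tp_l3l3, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Divide a filtered map by the L3L3 response, guarding small denominators.

    The divisor keeps the sign of the L3L3 response but its magnitude is
    floored at ``epsilon`` (zeros divide by +epsilon), so the output is always
    finite.
    """
    tp = np.asarray(tp, dtype=float)
    lum = np.asarray(tp_l3l3, dtype=float)
    if tp.shape != lum.shape:
        raise ValueError(f"shape mismatch: {tp.shape} vs {lum.shape}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    denom = np.where(lum >= 0, np.maximum(lum, epsilon), np.minimum(lum, -epsilon))
    return tp / denom


def tem(balanced) -> np.ndarray:
    """Texture energy metric: 7x7 moving-window sum of absolute values."""
    arr = np.asarray(balanced, dtype=float)
    if arr.shape[0] < TEM_WINDOW or arr.shape[1] < TEM_WINDOW:
        raise ValueError(f"image {arr.shape} smaller than the {TEM_WINDOW}x{TEM_WINDOW} TEM window")
    return ndimage.uniform_filter(np.abs(arr), size=TEM_WINDOW, mode="reflect") * TEM_WINDOW**2


def laws_features(image, epsilon: float = DEFAULT_EPSILON) -> dict[str, float]:
    """Eight texture-energy descriptors, one per zero-sum mask.

    Each descriptor is the mean of the TEM map of the balanced response;
    names are ``laws_{mask}``.  All values are nonnegative and invariant to
    multiplying the image by a positive constant (away from the epsilon
    floor).
    """
    masks = build_masks()
    lum = filter_image(image, masks["L3L3"])
    out: dict[str, float] = {}
    for name in MASK_NAMES:
        if name == "L3L3":
            continue
        balanced = balance(filter_image(image, masks[name]), lum, epsilon=epsilon)
        out[f"laws_{name}"] = float(tem(balanced).mean())
    return out
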