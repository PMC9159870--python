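"""2-D wavelet decomposition and wavelet-shrinkage denoising.

Ultrasound frames are degraded by additive noise (Gaussian, salt-and-pepper
"dots") on top of the multiplicative speckle inherent to the modality.  In the
wavelet domain that noise spreads thinly over all coefficients while image
structure concentrates in a few large ones, so soft-thresholding the detail
bands suppresses noise with little loss of structure.

The decomposition follows the classic separable scheme: each stage splits the
current approximation band B into a coarser approximation plus three detail
bands — J (horizontal detail, LH), U (vertical detail, HL) and F (diagonal
detail, HH) — and up to three stages are supported.  Band naming B/J/U/F is a
package convention mapping onto the standard LL/LH/HL/HH quartet.

The transform itself is delegated to PyWavelets with symmetric (half-sample)
boundary extension; this module owns the band bookkeeping, the threshold rule
and the denoising policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletDecomposition",
    "dwt2_level",
    "decompose3",
    "reconstruct",
    "denoise",
    "universal_threshold",
]

_MODE = "symmetric"


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


@dataclass
class WaveletDecomposition:
    """Multi-level 2-D DWT: final approximation plus per-level detail triples.

    ``details[ℓ-1]`` holds the level-ℓ triple ``(J_ℓ, U_ℓ, F_ℓ)`` =
    (horizontal, vertical, diagonal) detail, ℓ = 1 being the finest scale.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet_name: str
    original_shape: tuple[int, int]
    levels: int = field(init=False)

    def __post_init__(self) -> None:
        self.levels = len(self.details)
        if self.levels not in (1, 2, 3):
            raise ValueError("levels must be 1, 2 or 3")
        for triple in self.details:
            if len(triple) != 3:
                raise ValueError("each level needs a (J, U, F) detail triple")

    def band(self, name: str) -> np.ndarray:
        """Fetch a band by convention name, e.g. ``'F1'``, ``'J2'``, ``'B3'``."""
        kind, level = name[0].upper(), int(name[1:])
        if kind == "B":
            if level != self.levels:
                raise KeyError(f"only the final approximation B{self.levels} is stored")
            return self.approx
        idx = {"J": 0, "U": 1, "F": 2}[kind]
        return self.details[level - 1][idx]


def dwt2_level(image, wavelet: str = "haar"):
    """One separable 2-D DWT stage.

    Returns ``(approx, J, U, F)`` = (LL, LH, HL, HH) with symmetric boundary
    extension.  Requires at least a 2x2 image.
    """
    arr = _as_image(image)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"image {arr.shape} too small for a wavelet stage (need >= 2x2)")
    approx, (h, v, d) = pywt.dwt2(arr, wavelet, mode=_MODE)
    return approx, h, v, d


def decompose3(image, wavelet: str = "haar", levels: int = 3) -> WaveletDecomposition:
    """Recursive multi-stage decomposition of the approximation band.

    At ``levels=3`` this yields the ten bands B3 plus (J,U,F) at each of the
    three scales.  Raises if the image cannot support the requested depth,
    reporting the maximum feasible level.
    """
    arr = _as_image(image)
    if levels not in (1, 2, 3):
        raise ValueError("levels must be 1, 2 or 3")
    max_feasible = pywt.dwtn_max_level(arr.shape, wavelet)
    if levels > max_feasible:
        raise ValueError(
            f"image {arr.shape} supports at most {max_feasible} level(s) "
            f"with wavelet '{wavelet}', requested {levels}"
        )
    details = []
    approx = arr
    for _ in range(levels):
        approx, h, v, d = dwt2_level(approx, wavelet)
        details.append((h, v, d))
    return WaveletDecomposition(
        approx=approx,
        details=details,
        wavelet_name=wavelet,
        original_shape=arr.shape,
    )


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse transform back to ``original_shape``."""
    arr = decomp.approx
    for level in range(decomp.levels, 0, -1):
        h, v, d = decomp.details[level - 1]
        if arr.shape != h.shape:
            raise ValueError(
                f"approximation band {arr.shape} does not match level-{level} "
                f"detail bands {h.shape}"
            )
        arr = pywt.idwt2((arr, (h, v, d)), decomp.wavelet_name, mode=_MODE)
        # idwt2 may overshoot by one row/col when the finer band had odd size
        target = (
            decomp.original_shape
            if level == 1
            else decomp.details[level - 2][0].shape
        )
        arr = arr[: target[0], : target[1]]
    return arr


def universal_threshold(decomp: WaveletDecomposition) -> float:
    """VisuShrink threshold t = sigma_hat * sqrt(2 ln N).

    The noise scale is the median absolute deviation of the finest diagonal
    band: sigma_hat = median(|F1|) / 0.6745.  N is the pixel count of the
    original image.
    """
    f1 = decomp.details[0][2]
    sigma = float(np.median(np.abs(f1))) / 0.6745
    n = int(np.prod(decomp.original_shape))
    return sigma * float(np.sqrt(2.0 * np.log(n)))


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def denoise(
    image,
    wavelet: str = "haar",
    levels: int = 1,
    threshold_rule: str = "universal",
    manual_t: float = 0.0,
) -> np.ndarray:
    """Wavelet-shrinkage denoising: soft-threshold every detail band.

    Parameters
    ----------
    threshold_rule:
        ``'universal'`` uses the VisuShrink rule (MAD noise estimate from the
        finest diagonal band); ``'manual'`` applies ``manual_t`` directly.
        ``manual_t = 0`` is the identity up to transform round-trip error.

    The approximation band is never thresholded.
    """
    if threshold_rule not in ("universal", "manual"):
        raise ValueError(f"unknown threshold rule: {threshold_rule!r}")
    if threshold_rule == "manual" and manual_t < 0:
        raise ValueError("manual threshold must be nonnegative")
    decomp = decompose3(image, wavelet=wavelet, levels=levels)
    t = universal_threshold(decomp) if threshold_rule == "universal" else float(manual_t)
    shrunk = [tuple(_soft(b, t) for b in triple) for triple in decomp.details]
    return reconstruct(
        WaveletDecomposition(
            approx=decomp.approx,
            details=shrunk,
            wavelet_name=decomp.wavelet_name,
            original_shape=decomp.original_shape,
        )
    )
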