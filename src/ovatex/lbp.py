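"""Circular-neighborhood local binary patterns and multiscale descriptors.

A local binary pattern thresholds D points on a circle of radius r against the
center pixel, giving a D-bit string.  Two codings are provided:

* ``orig`` — the classic code Σ b_p 2^p, one of 2^D values;
* ``riu2`` — the rotation-invariant *uniform* coding: patterns with at most
  two circular 0/1 transitions keep their one-bit count (0..D) as the code,
  all remaining "non-uniform" patterns share the single code D+1.

The sign convention T(x) = 1 for x >= 0 (ties count as 1); because bilinear
interpolation can perturb an exact tie by floating-point rounding, a neighbor
within 1e-10 of the center counts as a tie.  Point p sits at
angle θ_p = 2πp/D measured counterclockwise from the +column axis, i.e. the
(row, col) offset is (−r·sinθ_p, r·cosθ_p); off-grid points are bilinearly
interpolated, and points that land within 1e-9 of a grid node are read
directly.  Because riu2 collapses all rotations of a pattern, its features do
not depend on this angular origin.

Texture descriptors are the energy Σ h_i² and entropy −Σ h_i log2 h_i of the
normalized code histogram, computed at several (D, r) scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LBPConfig",
    "LBPImage",
    "DEFAULT_SCALES",
    "sample_neighbors",
    "lbp_code_orig",
    "lbp_code_riu2",
    "uniformity",
    "lbp_image",
    "lbp_histogram",
    "lbp_features",
]

DEFAULT_SCALES: tuple[tuple[int, float], ...] = ((8, 1.0), (16, 2.0), (24, 3.0))

_GRID_SNAP = 1e-9
# interpolated neighbors within this of the center count as ties (bit = 1)
TIE_TOL = 1e-10


@dataclass(frozen=True)
class LBPConfig:
    D: int = 8
    r: float = 1.0
    mode: str = "riu2"

    def __post_init__(self) -> None:
        if not 4 <= self.D <= 24:
            raise ValueError("D must be in [4, 24]")
        if self.r < 1:
            raise ValueError("radius must be >= 1")
        if self.mode not in ("orig", "riu2"):
            raise ValueError(f"unknown LBP mode: {self.mode!r}")

    @property
    def valid_margin(self) -> int:
        return int(np.ceil(self.r))

    @property
    def n_bins(self) -> int:
        return 2**self.D if self.mode == "orig" else self.D + 2


@dataclass(frozen=True)
class LBPImage:
    codes: np.ndarray
    config: LBPConfig

    def __post_init__(self) -> None:
        hi = 2**self.config.D - 1 if self.config.mode == "orig" else self.config.D + 1
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > hi):
            raise ValueError("LBP codes out of range for mode")


def _circle_offsets(D: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    p = np.arange(D)
    theta = 2.0 * np.pi * p / D
    drow = -r * np.sin(theta)
    dcol = r * np.cos(theta)
    # snap near-integer offsets so axis-aligned samples are exact grid reads
    drow = np.where(np.abs(drow - np.round(drow)) < _GRID_SNAP, np.round(drow), drow)
    dcol = np.where(np.abs(dcol - np.round(dcol)) < _GRID_SNAP, np.round(dcol), dcol)
    return drow, dcol


def _bilinear(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear read at fractional (rows, cols); caller guarantees in-bounds."""
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    r1 = np.minimum(r0 + 1, image.shape[0] - 1)
    c1 = np.minimum(c0 + 1, image.shape[1] - 1)
    return (
        image[r0, c0] * (1 - fr) * (1 - fc)
        + image[r0, c1] * (1 - fr) * fc
        + image[r1, c0] * fr * (1 - fc)
        + image[r1, c1] * fr * fc
    )


def sample_neighbors(image, center: tuple[int, int], D: int, r: float) -> np.ndarray:
    """Gray values g_0..g_{D-1} on the circle of radius r around ``center``."""
    arr = np.asarray(image, dtype=float)
    row, col = center
    margin = int(np.ceil(r))
    if not (
        margin <= row < arr.shape[0] - margin and margin <= col < arr.shape[1] - margin
    ):
        raise ValueError(
            f"center {center} closer than ceil(r)={margin} to the border of {arr.shape}"
        )
    drow, dcol = _circle_offsets(D, r)
    return _bilinear(arr, row + drow, col + dcol)


def _threshold_bits(neighbors: np.ndarray, g_c: float) -> np.ndarray:
    return (np.asarray(neighbors, dtype=float) - g_c >= -TIE_TOL).astype(np.uint8)


def lbp_code_orig(neighbors, g_c: float, D: int) -> int:
    """Classic LBP code Σ_p T(g_p − g_c)·2^p, in [0, 2^D − 1]."""
    bits = _threshold_bits(neighbors, g_c)
    if bits.shape != (D,):
        raise ValueError(f"expected {D} neighbors, got {bits.shape}")
    return int(bits @ (1 << np.arange(D, dtype=np.int64)))


def uniformity(bits) -> int:
    """Number of 0/1 transitions when the bit string is traversed circularly."""
    b = np.asarray(bits, dtype=np.uint8)
    if b.size < 2:
        raise ValueError("need at least 2 bits")
    return int(np.count_nonzero(b != np.roll(b, -1)))


def lbp_code_riu2(neighbors, g_c: float, D: int) -> int:
    """Rotation-invariant uniform code: one-bit count if U <= 2, else D+1."""
    bits = _threshold_bits(neighbors, g_c)
    if bits.shape != (D,):
        raise ValueError(f"expected {D} neighbors, got {bits.shape}")
    if uniformity(bits) <= 2:
        return int(bits.sum())
    return D + 1


def lbp_image(image, config: LBPConfig) -> LBPImage:
    """Per-pixel LBP codes over the region where the full circle fits.

    Vectorized: for each circle point the whole image is sampled at once by
    bilinear interpolation of integer-shifted views.
    """
    arr = np.asarray(image, dtype=float)
    m = config.valid_margin
    out_shape = (arr.shape[0] - 2 * m, arr.shape[1] - 2 * m)
    if out_shape[0] < 1 or out_shape[1] < 1:
        raise ValueError(
            f"image {arr.shape} too small for radius {config.r} (margin {m})"
        )
    drow, dcol = _circle_offsets(config.D, config.r)
    centers = arr[m : m + out_shape[0], m : m + out_shape[1]]
    rows = np.arange(m, m + out_shape[0])[:, None]
    cols = np.arange(m, m + out_shape[1])[None, :]

    if config.mode == "orig":
        codes = np.zeros(out_shape, dtype=np.int64)
        for p in range(config.D):
            g_p = _bilinear(arr, rows + drow[p], cols + dcol[p])
            codes += ((g_p - centers) >= -TIE_TOL).astype(np.int64) << p
    else:
        ones = np.zeros(out_shape, dtype=np.int64)
        transitions = np.zeros(out_shape, dtype=np.int64)
        first = prev = None
        for p in range(config.D):
            g_p = _bilinear(arr, rows + drow[p], cols + dcol[p])
            bit = (g_p - centers) >= -TIE_TOL
            ones += bit
            if prev is None:
                first = bit
            else:
                transitions += bit != prev
            prev = bit
        transitions += prev != first  # close the circle
        codes = np.where(transitions <= 2, ones, config.D + 1)
    return LBPImage(codes=codes, config=config)


def lbp_histogram(lbp: LBPImage) -> np.ndarray:
    """Normalized code-frequency histogram (2^D bins for orig, D+2 for riu2)."""
    if lbp.codes.size == 0:
        raise ValueError("empty LBP code grid")
    counts = np.bincount(lbp.codes.ravel(), minlength=lbp.config.n_bins)
    return counts / counts.sum()


def _hist_energy_entropy(h: np.ndarray) -> tuple[float, float]:
    energy = float(np.sum(h**2))
    nz = h[h > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return energy, entropy


def lbp_features(image, scales=DEFAULT_SCALES) -> dict[str, float]:
    """Histogram energy and entropy of the riu2 code map at each (D, r) scale.

    Feature names follow ``lbp_energy_D{D}_r{r}`` / ``lbp_entropy_D{D}_r{r}``;
    radii are printed without a trailing ``.0``.
    """
    out: dict[str, float] = {}
    for D, r in scales:
        h = lbp_histogram(lbp_image(image, LBPConfig(D=D, r=r, mode="riu2")))
        energy, entropy = _hist_energy_entropy(h)
        rtag = f"{r:g}"
        out[f"lbp_energy_D{D}_r{rtag}"] = energy
        out[f"lbp_entropy_D{D}_r{rtag}"] = entropy
    return out
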