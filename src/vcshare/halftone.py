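"""Halftoning: error diffusion and block-wise limited gray-level halftoning.

Two halftoners are provided:

``error_diffusion``
    Classic Floyd–Steinberg error diffusion — the best-quality baseline,
    free to use any of the ``s_b + 1`` per-block gray levels.

``limited_halftone``
    A block-wise halftoner that restricts the number of black pixels in
    every non-overlapping block to a *candidate level set*.  Restricting
    the levels is what makes expansion-free share construction possible:
    the stacking constraint "max(cover levels) <= secret level <=
    min(block size, sum of cover levels)" can only be guaranteed for all
    blocks if the per-block darkness of the secret and of the covers is
    confined to compatible level sets (see :mod:`vcshare.efvcs`).

Each block's target level is the allowed level nearest to the block's
ideal darkness ``s_b * (1 - mean/255)``; ties break toward the darker
level, which is why a level-restricted reconstruction looks slightly
darker than an unrestricted halftone.  Within a block the black pixels
are placed uniformly at random — intra-block positions carry no tone
information and are re-arranged by the encryption step anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import as_binary, as_gray

__all__ = [
    "HalftoneConfig",
    "validate_levels",
    "error_diffusion",
    "pad_to_blocks",
    "block_means",
    "block_counts",
    "block_black_count",
    "nearest_levels",
    "placement",
    "limited_halftone",
]


def validate_levels(levels: Sequence[int], s_b: int) -> tuple[int, ...]:
    """Return ``levels`` as a strictly increasing tuple within [0, s_b]."""
    lv = tuple(int(x) for x in levels)
    if not lv:
        raise ValueError("level set must be nonempty")
    if any(b <= a for a, b in zip(lv, lv[1:])):
        raise ValueError(f"level set must be strictly increasing, got {lv}")
    if lv[0] < 0 or lv[-1] > s_b:
        raise ValueError(f"levels must lie in [0, {s_b}], got {lv}")
    return lv


@dataclass(frozen=True)
class HalftoneConfig:
    """Block shape and candidate black-pixel levels for limited halftoning."""

    block_shape: tuple[int, int] = (2, 2)
    levels: tuple[int, ...] = (3, 4)

    def __post_init__(self) -> None:
        bh, bw = self.block_shape
        if bh * bw < 2:
            raise ValueError("block must contain at least 2 pixels")
        object.__setattr__(self, "levels", validate_levels(self.levels, bh * bw))

    @property
    def s_b(self) -> int:
        """Pixels per block."""
        return self.block_shape[0] * self.block_shape[1]


def error_diffusion(img: np.ndarray) -> np.ndarray:
    """Floyd–Steinberg error diffusion, raster scan, threshold 128.

    Quantization error is pushed to the unprocessed neighbours with the
    standard 7/16, 3/16, 5/16, 1/16 weights.  Returns a binary image
    (0 = black, 1 = white) of the same shape.
    """
    work = as_gray(img).astype(np.float64)
    h, w = work.shape
    out = np.empty((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            old = work[r, c]
            bit = 1 if old >= 128 else 0
            out[r, c] = bit
            err = old - bit * 255.0
            if c + 1 < w:
                work[r, c + 1] += err * (7 / 16)
            if r + 1 < h:
                if c > 0:
                    work[r + 1, c - 1] += err * (3 / 16)
                work[r + 1, c] += err * (5 / 16)
                if c + 1 < w:
                    work[r + 1, c + 1] += err * (1 / 16)
    return out


def pad_to_blocks(
    img: np.ndarray, block_shape: tuple[int, int], fill: int = 255
) -> np.ndarray:
    """Pad bottom/right so both dimensions are block multiples.

    The default fill of 255 (white) keeps padded regions as light as the
    level set allows.  Returns the input unchanged when no padding is
    needed.
    """
    bh, bw = block_shape
    h, w = img.shape
    ph = (-h) % bh
    pw = (-w) % bw
    if ph == 0 and pw == 0:
        return img
    return np.pad(img, ((0, ph), (0, pw)), constant_values=fill)


def _block_view(img: np.ndarray, block_shape: tuple[int, int]) -> np.ndarray:
    bh, bw = block_shape
    h, w = img.shape
    if h % bh or w % bw:
        raise ValueError(f"image shape {img.shape} is not a multiple of {block_shape}")
    return img.reshape(h // bh, bh, w // bw, bw).swapaxes(1, 2)


def block_means(img: np.ndarray, block_shape: tuple[int, int]) -> np.ndarray:
    """Mean intensity of each non-overlapping block (row-major grid)."""
    return _block_view(as_gray(img), block_shape).mean(axis=(2, 3))


def block_counts(img: np.ndarray, block_shape: tuple[int, int]) -> np.ndarray:
    """Black-pixel count of each non-overlapping block of a binary image."""
    view = _block_view(as_binary(img), block_shape)
    bh, bw = block_shape
    return (bh * bw) - view.sum(axis=(2, 3), dtype=np.int64)


def block_black_count(block_mean: float, levels: Sequence[int], s_b: int) -> int:
    """Quantize one block's mean intensity onto the candidate level set.

    The ideal darkness of a block with mean intensity ``g`` is
    ``s_b * (1 - g/255)`` black pixels; the returned level is the
    nearest allowed level, ties broken toward the darker (larger) level.
    """
    lv = validate_levels(levels, s_b)
    if not 0 <= block_mean <= 255:
        raise ValueError(f"block mean must be in [0, 255], got {block_mean}")
    ideal = s_b * (1.0 - block_mean / 255.0)
    # scan dark-to-light so the first minimal distance is the darker level
    best = max(lv)
    best_d = abs(best - ideal)
    for level in sorted(lv, reverse=True)[1:]:
        d = abs(level - ideal)
        if d < best_d:
            best, best_d = level, d
    return best


def nearest_levels(means: np.ndarray, levels: Sequence[int], s_b: int) -> np.ndarray:
    """Vectorized :func:`block_black_count` over an array of block means."""
    lv = np.array(sorted(validate_levels(levels, s_b), reverse=True))
    ideal = s_b * (1.0 - np.asarray(means, dtype=np.float64) / 255.0)
    dist = np.abs(lv[None, :] - ideal.reshape(-1, 1))
    # argmin returns the first (darkest) level on ties
    return lv[np.argmin(dist, axis=1)].reshape(np.shape(means))


def placement(
    black_count: int, block_shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """A block bit pattern with exactly ``black_count`` black pixels,
    drawn uniformly from all C(s_b, black_count) arrangements."""
    bh, bw = block_shape
    s_b = bh * bw
    if not 0 <= black_count <= s_b:
        raise ValueError(f"black count must be in [0, {s_b}], got {black_count}")
    flat = np.ones(s_b, dtype=np.uint8)
    flat[rng.permutation(s_b)[:black_count]] = 0
    return flat.reshape(bh, bw)


def limited_halftone(
    img: np.ndarray,
    config: HalftoneConfig = HalftoneConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Block-wise halftone restricted to the configured level set.

    The image is padded with white to block-multiple dimensions; every
    block of the output has a black-pixel count drawn from
    ``config.levels``.  ``rng`` randomizes intra-block placement only;
    the per-block counts are deterministic functions of the input.
    """
    if rng is None:
        rng = np.random.default_rng()
    bh, bw = config.block_shape
    s_b = config.s_b
    padded = pad_to_blocks(as_gray(img), config.block_shape)
    targets = nearest_levels(block_means(padded, config.block_shape), config.levels, s_b)
    gh, gw = targets.shape
    # uniform placement for all blocks at once: rank the random keys
    keys = rng.random((gh * gw, s_b))
    ranks = np.argsort(keys, axis=1).argsort(axis=1)
    bits = (ranks >= targets.reshape(-1, 1)).astype(np.uint8)
    out = bits.reshape(gh, gw, bh, bw).swapaxes(1, 2).reshape(gh * bh, gw * bw)
    return out
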