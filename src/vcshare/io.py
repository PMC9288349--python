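"""Grayscale / bilevel image I/O and conversions.

Pixel conventions used throughout the package:

* A *gray image* is a 2-D ``uint8`` array with intensities in ``[0, 255]``
  (0 = black, 255 = white).
* A *binary image* is a 2-D ``uint8`` array over ``{0, 1}`` where
  **0 = black and 1 = white**.  Under this convention superimposing two
  shares (physically: stacking transparencies) is a pixelwise AND — a
  pixel is white only if it is white in every share.

Supported interchange formats are 8-bit grayscale PNG and raw (P5) PGM,
both lossless.  Color inputs are accepted and converted to luminance
(ITU-R 601 weights, as implemented by Pillow) with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "read_gray",
    "write_gray",
    "write_binary",
    "binarize",
    "binary_to_gray",
    "as_gray",
    "as_binary",
]

_SUPPORTED_SUFFIXES = {".png", ".pgm"}


def as_gray(img: np.ndarray) -> np.ndarray:
    """Validate ``img`` as a gray image and return it as ``uint8``.

    Raises ``ValueError`` if the array is not 2-D, is smaller than 2x2,
    or holds values outside ``[0, 255]``.
    """
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"gray image must be at least 2x2, got {arr.shape}")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"gray image must be integer-valued, got {arr.dtype}")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("gray image values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_binary(img: np.ndarray) -> np.ndarray:
    """Validate ``img`` as a binary image (values in {0, 1}, 0 = black)."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"binary image must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("binary image values must be 0 (black) or 1 (white)")
    return arr.astype(np.uint8)


def read_gray(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image (PNG or PGM) as a 2-D uint8 array.

    Multi-channel images are luminance-converted (ITU-R 601 weights)
    with a warning; bit depths other than 8 are rejected.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported format {path.suffix!r}; expected PNG or PGM")
    with Image.open(path) as im:
        if im.mode == "L":
            pass
        elif im.mode in ("RGB", "RGBA", "P", "LA"):
            warnings.warn(
                f"{path.name}: converting {im.mode} input to luminance (ITU-R 601)",
                stacklevel=2,
            )
            im = im.convert("L")
        else:
            raise ValueError(f"unsupported image mode {im.mode!r} (need 8-bit depth)")
        arr = np.asarray(im, dtype=np.uint8)
    return as_gray(arr)


def write_gray(img: np.ndarray, path: str | Path) -> None:
    """Write a gray image as 8-bit PNG or raw (P5) PGM, chosen by suffix."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported format {path.suffix!r}; expected PNG or PGM")
    Image.fromarray(as_gray(img), mode="L").save(path)


def binary_to_gray(img: np.ndarray) -> np.ndarray:
    """Map a binary image to display intensities: 0 -> 0, 1 -> 255."""
    return (as_binary(img) * np.uint8(255)).astype(np.uint8)


def write_binary(img: np.ndarray, path: str | Path) -> None:
    """Write a binary image as an 8-bit file (black -> 0, white -> 255)."""
    write_gray(binary_to_gray(img), path)


def binarize(img: np.ndarray, threshold: int = 128) -> np.ndarray:
    """Threshold a gray image: ``value < threshold`` -> 0 (black), else 1.

    The boundary value maps to white, so ``threshold=0`` yields an
    all-white image and ``threshold=256`` would yield all-black (but the
    threshold must lie in [0, 255]).
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return (as_gray(img) >= threshold).astype(np.uint8)
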