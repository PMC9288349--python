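"""Classic expanded (2,2) schemes: noise-share VCS and meaningful-cover EVCS.

Both schemes encrypt a binary secret pixel-by-pixel into m = 4 subpixels
per share, so shares are four times the secret's area.  A secret pixel
is encoded by choosing an n x m basis matrix for its (secret, cover)
combination and randomly permuting its columns; row i of the permuted
matrix becomes share i's 2x2 subpixel tile.

Plain (2,2)-VCS: every share tile has exactly 2 black subpixels, so a
single share is indistinguishable from noise.  Stacking (AND) gives 4
black subpixels where the secret is black and 2 where it is white.

(2,2)-EVCS with meaningful covers: a share tile has 3 black subpixels
where its cover is black and 2 where it is white — so each share shows
its cover — while the stack has 4 black subpixels where the secret is
black and 3 where it is white.  The canonical basis matrices for a black
secret on black/black covers and a white secret on black/black covers
are ``[[0,1,0,0],[1,0,0,0]]`` and ``[[0,1,0,0],[0,1,0,0]]`` (0 = black);
the remaining six combinations are found by exhaustive search over 4-bit
pattern pairs under the same row/stack count constraints and frozen at
import.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .io import as_binary
from .shares import ShareSet, stack

__all__ = [
    "BLACK",
    "WHITE",
    "all_patterns",
    "vcs_basis",
    "evcs_basis",
    "evcs_row_count",
    "evcs_stack_count",
    "permute_columns",
    "encrypt_vcs",
    "encrypt_evcs_expanded",
    "stack",
]

BLACK, WHITE = 0, 1
_M = 4  # subpixels per secret pixel
_TILE = (2, 2)  # subpixel layout of one row vector


def all_patterns(s_b: int, black_count: int) -> list[tuple[int, ...]]:
    """All length-``s_b`` bit patterns with exactly ``black_count`` zeros,
    in lexicographic order."""
    out = []
    for blacks in combinations(range(s_b), black_count):
        p = [1] * s_b
        for i in blacks:
            p[i] = 0
        out.append(tuple(p))
    return out


def evcs_row_count(cover_pixel: int) -> int:
    """Black subpixels in an EVCS share tile: 3 if the cover is black, else 2."""
    return 3 if cover_pixel == BLACK else 2


def evcs_stack_count(secret_pixel: int) -> int:
    """Black subpixels in a stacked EVCS tile: 4 if the secret is black, else 3."""
    return 4 if secret_pixel == BLACK else 3


def vcs_basis() -> tuple[np.ndarray, np.ndarray]:
    """Basis matrices (S0 for a white secret pixel, S1 for black).

    S0's rows are identical 2-black patterns (stack = 2 black); S1's
    rows are complementary 2-black patterns (stack = 4 black).
    """
    s0 = np.array([[0, 0, 1, 1], [0, 0, 1, 1]], dtype=np.uint8)
    s1 = np.array([[0, 0, 1, 1], [1, 1, 0, 0]], dtype=np.uint8)
    return s0, s1


def _search_evcs_basis(s: int, c1: int, c2: int) -> np.ndarray:
    t = evcs_stack_count(s)
    b1, b2 = evcs_row_count(c1), evcs_row_count(c2)
    for p1 in all_patterns(_M, b1):
        for p2 in all_patterns(_M, b2):
            if sum(a & b for a, b in zip(p1, p2)) == _M - t:
                return np.array([p1, p2], dtype=np.uint8)
    raise ValueError(f"no basis matrix exists for (s={s}, c1={c1}, c2={c2})")


# canonical matrices for the two black/black-cover cases; the rest are
# filled in by exhaustive search (all eight combinations are feasible)
_EVCS_BASIS: dict[tuple[int, int, int], np.ndarray] = {
    (BLACK, BLACK, BLACK): np.array([[0, 1, 0, 0], [1, 0, 0, 0]], dtype=np.uint8),
    (WHITE, BLACK, BLACK): np.array([[0, 1, 0, 0], [0, 1, 0, 0]], dtype=np.uint8),
}
for _s in (BLACK, WHITE):
    for _c1 in (BLACK, WHITE):
        for _c2 in (BLACK, WHITE):
            _EVCS_BASIS.setdefault((_s, _c1, _c2), _search_evcs_basis(_s, _c1, _c2))


def evcs_basis(s: int, c1: int, c2: int) -> np.ndarray:
    """The (2,2)-EVCS basis matrix for secret pixel ``s`` on cover pixels
    ``(c1, c2)`` (0 = black, 1 = white).  Returns a fresh 2x4 copy."""
    key = (int(s), int(c1), int(c2))
    if key not in _EVCS_BASIS:
        raise ValueError(f"pixel values must be 0 or 1, got {key}")
    return _EVCS_BASIS[key].copy()


def permute_columns(M: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random column permutation of ``M``."""
    M = np.asarray(M)
    return M[:, rng.permutation(M.shape[1])]


def _tiles_to_image(rows: np.ndarray, h: int, w: int) -> np.ndarray:
    """(h*w, 4) row vectors -> (2h, 2w) image of 2x2 tiles."""
    th, tw = _TILE
    return (
        rows.reshape(h, w, th, tw).swapaxes(1, 2).reshape(h * th, w * tw).astype(np.uint8)
    )


def _encrypt_expanded(
    secret: np.ndarray,
    basis_for_pixel: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Permute each pixel's basis matrix and lay rows out as 2x2 tiles.

    ``basis_for_pixel`` has shape (h*w, 2, 4): the basis matrix selected
    for every secret pixel in row-major order.
    """
    h, w = secret.shape
    n_px = h * w
    perms = np.argsort(rng.random((n_px, _M)), axis=1)
    permuted = np.take_along_axis(basis_for_pixel, perms[:, None, :], axis=2)
    return _tiles_to_image(permuted[:, 0, :], h, w), _tiles_to_image(permuted[:, 1, :], h, w)


def encrypt_vcs(secret: np.ndarray, rng: np.random.Generator) -> ShareSet:
    """Split a binary secret into two noise shares, each 2H x 2W."""
    secret = as_binary(secret)
    s0, s1 = vcs_basis()
    basis = np.where(secret.reshape(-1, 1, 1) == BLACK, s1, s0)
    sh1, sh2 = _encrypt_expanded(secret, basis, rng)
    return ShareSet(
        shares=[sh1, sh2],
        scheme="vcs",
        expansion=_M,
        block_shape=_TILE,
        secret_shape=secret.shape,
    )


def encrypt_evcs_expanded(
    secret: np.ndarray,
    cover1: np.ndarray,
    cover2: np.ndarray,
    rng: np.random.Generator,
) -> ShareSet:
    """Split a binary secret into two meaningful shares, each 2H x 2W.

    Share i's tile shows cover i's pixel (3-black tile = black cover
    pixel, 2-black = white); the stacked tiles show the secret (4-black
    = black, 3-black = white).
    """
    secret = as_binary(secret)
    cover1 = as_binary(cover1)
    cover2 = as_binary(cover2)
    if not (secret.shape == cover1.shape == cover2.shape):
        raise ValueError(
            f"secret and covers must share dimensions, got "
            f"{secret.shape}, {cover1.shape}, {cover2.shape}"
        )
    lut = np.empty((2, 2, 2, 2, _M), dtype=np.uint8)
    for (s, c1, c2), mat in _EVCS_BASIS.items():
        lut[s, c1, c2] = mat
    basis = lut[secret.ravel(), cover1.ravel(), cover2.ravel()]
    sh1, sh2 = _encrypt_expanded(secret, basis, rng)
    return ShareSet(
        shares=[sh1, sh2],
        scheme="evcs",
        expansion=_M,
        block_shape=_TILE,
        secret_shape=secret.shape,
    )
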