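"""Expansion-free extended visual cryptography (EF-EVCS).

Instead of expanding every secret pixel into m subpixels, the scheme
works on non-overlapping blocks of the images themselves: the secret
and both covers are first halftoned with black-pixel counts restricted
to candidate level sets (defaults: secret {3, 4}, covers {2, 3} on 2x2
blocks), and encryption then *rearranges* each cover block's pixels so
that the two share blocks AND together to exactly the secret block's
level.  The shares keep the covers' per-block tone — they look like the
cover images — and have the same pixel dimensions as the secret
(expansion factor 1).

Feasibility.  A stacked block's black count ranges over
``[max(b1, b2), min(s_b, b1 + b2)]`` when the share blocks carry b1 and
b2 black pixels: stacking can only darken, and it darkens most when the
white positions are disjoint.  A (secret_levels, cover_levels)
configuration is feasible when every combination of a secret level t
and cover levels b1, b2 satisfies ``max(b1, b2) <= t <= min(s_b,
b1 + b2)``.  With 2x2 blocks, secret {3,4} / cover {2,3} is the unique
two-level pair that is feasible and matches the classic EVCS subpixel
counts (cover tiles of 2 or 3 black, stacks of 3 or 4).  By contrast a
cover block holding 3 black pixels can never stack down to a 2-black
secret block, no matter how it is arranged — which is why unrestricted
halftoning breaks the scheme.

Security.  For every block the pattern pair is drawn uniformly from all
valid arrangements, so the pattern seen on a single share is uniform
over all C(s_b, b) patterns of its cover level b, independent of the
secret level; one share therefore leaks nothing beyond its own cover
(the posterior of the secret block's class stays at the 50% prior —
verified exactly in :mod:`vcshare.metrics`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np

from .halftone import (
    HalftoneConfig,
    block_counts,
    limited_halftone,
    pad_to_blocks,
    validate_levels,
)
from .io import as_gray
from .shares import ShareSet

__all__ = [
    "EfConfig",
    "check_feasible",
    "valid_pairs",
    "arrange_block",
    "encrypt_ef",
    "interpret_block",
    "reconstruct_gray",
]


@dataclass(frozen=True)
class EfConfig:
    """Block shape and the secret/cover candidate level sets.

    The defaults mirror the classic (2,2)-EVCS tile counts: secret
    blocks carry 3 or 4 black pixels (4 = black class, 3 = white),
    cover blocks 2 or 3 (3 = black class, 2 = white).
    """

    block_shape: tuple[int, int] = (2, 2)
    secret_levels: tuple[int, ...] = (3, 4)
    cover_levels: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        s_b = self.s_b
        if s_b < 2:
            raise ValueError("block must contain at least 2 pixels")
        object.__setattr__(self, "secret_levels", validate_levels(self.secret_levels, s_b))
        object.__setattr__(self, "cover_levels", validate_levels(self.cover_levels, s_b))

    @property
    def s_b(self) -> int:
        return self.block_shape[0] * self.block_shape[1]

    def validate_feasible(self) -> None:
        if not check_feasible(self.secret_levels, self.cover_levels, self.s_b):
            raise ValueError(
                f"infeasible configuration: secret levels {self.secret_levels} "
                f"cannot all be reached by stacking cover levels {self.cover_levels}"
            )


def check_feasible(
    secret_levels: tuple[int, ...] | list[int],
    cover_levels: tuple[int, ...] | list[int],
    s_b: int,
) -> bool:
    """True iff every (t, b1, b2) combination admits an arrangement,
    i.e. ``max(b1, b2) <= t <= min(s_b, b1 + b2)`` throughout."""
    secret_levels = validate_levels(secret_levels, s_b)
    cover_levels = validate_levels(cover_levels, s_b)
    return all(
        max(b1, b2) <= t <= min(s_b, b1 + b2)
        for t in secret_levels
        for b1 in cover_levels
        for b2 in cover_levels
    )


@lru_cache(maxsize=None)
def valid_pairs(
    t: int, b1: int, b2: int, s_b: int = 4
) -> tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]:
    """All pattern pairs (p1, p2) with black counts (b1, b2) whose AND
    has exactly ``t`` black pixels, in lexicographic order.

    Patterns are bit tuples of length ``s_b`` (0 = black).  Empty when
    the triple is infeasible.
    """
    from .classic import all_patterns  # local import avoids a cycle at load

    pairs = []
    for p1, p2 in product(all_patterns(s_b, b1), all_patterns(s_b, b2)):
        if s_b - sum(a & b for a, b in zip(p1, p2)) == t:
            pairs.append((p1, p2))
    return tuple(pairs)


def arrange_block(
    t: int, b1: int, b2: int, s_b: int, rng: np.random.Generator
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Draw (p1, p2) uniformly from all valid arrangements for the
    triple (t, b1, b2); raises ``ValueError`` when none exists."""
    pairs = valid_pairs(t, b1, b2, s_b)
    if not pairs:
        raise ValueError(
            f"no arrangement stacks cover levels ({b1}, {b2}) to secret level {t}"
        )
    return pairs[int(rng.integers(len(pairs)))]


def encrypt_ef(
    secret: np.ndarray,
    cover1: np.ndarray,
    cover2: np.ndarray,
    config: EfConfig = EfConfig(),
    rng: np.random.Generator | None = None,
) -> ShareSet:
    """Encrypt a gray secret into two cover-styled shares of the same size.

    The three gray images are halftoned independently onto their level
    sets before encryption ever sees them; encryption then only
    rearranges pixels inside each cover block.  Per block of the output:
    share i's black count equals cover i's halftone level, and the
    stacked count equals the secret's halftone level.
    """
    if rng is None:
        rng = np.random.default_rng()
    config.validate_feasible()
    secret = as_gray(secret)
    cover1 = as_gray(cover1)
    cover2 = as_gray(cover2)
    if not (secret.shape == cover1.shape == cover2.shape):
        raise ValueError(
            f"secret and covers must share dimensions, got "
            f"{secret.shape}, {cover1.shape}, {cover2.shape}"
        )
    bh, bw = config.block_shape
    s_b = config.s_b
    # independent halftoning; the gray originals are never consulted again
    ht_secret = limited_halftone(
        secret, HalftoneConfig(config.block_shape, config.secret_levels), rng
    )
    cover_cfg = HalftoneConfig(config.block_shape, config.cover_levels)
    ht_c1 = limited_halftone(cover1, cover_cfg, rng)
    ht_c2 = limited_halftone(cover2, cover_cfg, rng)

    t_grid = block_counts(ht_secret, config.block_shape)
    b1_grid = block_counts(ht_c1, config.block_shape)
    b2_grid = block_counts(ht_c2, config.block_shape)

    gh, gw = t_grid.shape
    share1 = np.empty((gh * bh, gw * bw), dtype=np.uint8)
    share2 = np.empty_like(share1)
    for i in range(gh):
        for j in range(gw):
            p1, p2 = arrange_block(
                int(t_grid[i, j]), int(b1_grid[i, j]), int(b2_grid[i, j]), s_b, rng
            )
            sl = np.s_[i * bh : (i + 1) * bh, j * bw : (j + 1) * bw]
            share1[sl] = np.reshape(p1, (bh, bw))
            share2[sl] = np.reshape(p2, (bh, bw))
    return ShareSet(
        shares=[share1, share2],
        scheme="ef-evcs",
        expansion=1,
        block_shape=config.block_shape,
        secret_shape=secret.shape,
        meta={
            "secret_levels": list(config.secret_levels),
            "cover_levels": list(config.cover_levels),
            "padded_shape": list(share1.shape),
        },
    )


_INTERPRET = {
    "recovered": {4: "black", 3: "white"},
    "cover": {3: "black", 2: "white"},
}


def interpret_block(black_count: int, context: str) -> str:
    """Classify a 2x2 block's black count as a black or white pixel.

    A 3-black block means *white* in a recovered (stacked) image but
    *black* on a cover share — the two contexts use shifted level pairs.
    """
    try:
        table = _INTERPRET[context]
    except KeyError:
        raise ValueError(f"context must be 'recovered' or 'cover', got {context!r}")
    try:
        return table[int(black_count)]
    except KeyError:
        raise ValueError(
            f"black count {black_count} is not a valid {context} level "
            f"(expected one of {sorted(table)})"
        )


def reconstruct_gray(stacked: np.ndarray, block_shape: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Render a stacked binary image as a blocky gray view.

    Each block becomes the constant gray value ``round(255 * (1 -
    black_count / s_b))``, replicated over the block — invertible back
    to the block counts, and the natural input for downstream viewing
    or recognition of recovered images.
    """
    bh, bw = block_shape
    s_b = bh * bw
    counts = block_counts(stacked, block_shape)
    grays = np.rint(255.0 * (1.0 - counts / s_b)).astype(np.uint8)
    return np.kron(grays, np.ones((bh, bw), dtype=np.uint8))
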