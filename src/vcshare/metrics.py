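"""Security and quality metrics for share sets.

The central security check is :func:`leakage_posterior`: by *exact*
enumeration (rational arithmetic, no sampling) of every encoding a
scheme can emit, it computes the posterior probability that the secret
pixel/block is black given the pattern observed on a single share.
For every shipped scheme this posterior equals the 0.5 prior for every
observable pattern — holding one share is exactly as informative as
holding nothing.

Quality is summarized by the pixel-expansion factor, the recovered
contrast alpha (difference in white-subpixel density between recovered
white and black regions, in units of the block size), and PSNR of the
blocky gray reconstruction against the halftoned secret.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations, product
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from skimage.metrics import peak_signal_noise_ratio

from . import classic
from .efvcs import valid_pairs
from .halftone import block_counts
from .io import as_binary, as_gray

__all__ = [
    "LeakageReport",
    "UniformityStratum",
    "expansion_factor",
    "posterior_from_distributions",
    "leakage_posterior",
    "share_uniformity",
    "contrast_alpha",
    "psnr",
]

Pattern = tuple[int, ...]


def _npixels(x) -> int:
    if isinstance(x, np.ndarray):
        return int(x.size)
    return int(np.prod(x))


def expansion_factor(secret, share) -> float:
    """Share pixel count divided by secret pixel count.

    Accepts images or shape tuples.  1.0 means expansion-free.
    """
    ns, nh = _npixels(secret), _npixels(share)
    if ns <= 0 or nh <= 0:
        raise ValueError("dimensions must be positive")
    return nh / ns


@dataclass
class LeakageReport:
    """Exact single-share posteriors P(secret = black | pattern)."""

    scheme: str
    share_index: int
    posteriors: dict[Pattern, Fraction]

    @property
    def max_deviation(self) -> Fraction:
        """Largest |posterior - 1/2| over all observable patterns."""
        half = Fraction(1, 2)
        return max(abs(p - half) for p in self.posteriors.values())


def posterior_from_distributions(
    dists: Mapping[str, Mapping[Pattern, Fraction]],
    priors: Mapping[str, Fraction] | None = None,
) -> dict[Pattern, dict[str, Fraction]]:
    """Bayes inversion of per-class pattern distributions.

    ``dists[cls][pattern]`` is P(pattern | cls).  Returns, for every
    pattern observable under at least one class, the posterior over
    classes (equal priors by default).  Exact rational arithmetic.
    """
    classes = list(dists)
    if priors is None:
        priors = {c: Fraction(1, len(classes)) for c in classes}
    patterns = {p for d in dists.values() for p in d}
    out: dict[Pattern, dict[str, Fraction]] = {}
    for p in sorted(patterns):
        joint = {c: priors[c] * dists[c].get(p, Fraction(0)) for c in classes}
        total = sum(joint.values())
        if total == 0:
            continue
        out[p] = {c: joint[c] / total for c in classes}
    return out


def _perm_marginal(matrix: np.ndarray, share_index: int) -> dict[Pattern, Fraction]:
    """Distribution of one share's pattern under uniform column permutation."""
    row = tuple(int(v) for v in matrix[share_index])
    counts: dict[Pattern, int] = {}
    n = 0
    for perm in permutations(range(len(row))):
        p = tuple(row[i] for i in perm)
        counts[p] = counts.get(p, 0) + 1
        n += 1
    return {p: Fraction(c, n) for p, c in counts.items()}


def _mix(
    parts: Sequence[tuple[Fraction, Mapping[Pattern, Fraction]]]
) -> dict[Pattern, Fraction]:
    out: dict[Pattern, Fraction] = {}
    for weight, dist in parts:
        for p, pr in dist.items():
            out[p] = out.get(p, Fraction(0)) + weight * pr
    return out


def _pair_marginal(
    t: int, b1: int, b2: int, s_b: int, share_index: int
) -> dict[Pattern, Fraction]:
    """Distribution of one share's block pattern under uniform sampling
    from all valid (p1, p2) arrangements for (t, b1, b2)."""
    pairs = valid_pairs(t, b1, b2, s_b)
    if not pairs:
        return {}
    counts: dict[Pattern, int] = {}
    for pair in pairs:
        p = pair[share_index]
        counts[p] = counts.get(p, 0) + 1
    return {p: Fraction(c, len(pairs)) for p, c in counts.items()}


def leakage_posterior(
    scheme: str,
    secret_levels: Sequence[int] = (3, 4),
    cover_levels: Sequence[int] = (2, 3),
    s_b: int = 4,
    share_index: int = 0,
) -> LeakageReport:
    """Exact single-share leakage for ``scheme`` in {vcs, evcs, ef-evcs}.

    For the classic schemes the encoding space is every column
    permutation of the basis matrices, with covers (where present)
    uniform; for EF-EVCS it is every valid pattern-pair arrangement
    with cover levels uniform.  The "black" class is a black secret
    pixel (classic) or the darkest secret level (EF-EVCS).
    """
    quarter = Fraction(1, 4)
    if scheme == "vcs":
        s0, s1 = classic.vcs_basis()
        dists = {
            "black": _perm_marginal(s1, share_index),
            "white": _perm_marginal(s0, share_index),
        }
    elif scheme == "evcs":
        dists = {}
        for cls, s in (("black", classic.BLACK), ("white", classic.WHITE)):
            parts = [
                (quarter, _perm_marginal(classic.evcs_basis(s, c1, c2), share_index))
                for c1, c2 in product((classic.BLACK, classic.WHITE), repeat=2)
            ]
            dists[cls] = _mix(parts)
    elif scheme == "ef-evcs":
        if len(secret_levels) != 2:
            raise ValueError("black/white leakage needs exactly two secret levels")
        lo, hi = sorted(secret_levels)
        w_cov = Fraction(1, len(cover_levels) ** 2)
        dists = {}
        for cls, t in (("black", hi), ("white", lo)):
            parts = [
                (w_cov, _pair_marginal(t, b1, b2, s_b, share_index))
                for b1, b2 in product(cover_levels, repeat=2)
            ]
            dists[cls] = _mix(parts)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    post = posterior_from_distributions(dists)
    return LeakageReport(
        scheme=scheme,
        share_index=share_index,
        posteriors={p: cp["black"] for p, cp in post.items()},
    )


@dataclass
class UniformityStratum:
    """Chi-square goodness of fit of share patterns within one cover level."""

    level: int
    statistic: float
    pvalue: float
    n_blocks: int


def share_uniformity(
    share: np.ndarray,
    cover_levels_map: np.ndarray,
    block_shape: tuple[int, int] = (2, 2),
) -> dict[int, UniformityStratum]:
    """Test pattern uniformity of a share within each cover-level stratum.

    ``cover_levels_map`` gives the expected black count of every block
    (the cover's halftone levels).  Within each stratum the observed
    frequencies of the C(s_b, b) possible patterns are tested against
    the uniform distribution (Pearson chi-square, dof = patterns - 1).
    Strata with fewer than 50 blocks trigger a warning.
    """
    share = as_binary(share)
    bh, bw = block_shape
    s_b = bh * bw
    counts = block_counts(share, block_shape)
    cover_levels_map = np.asarray(cover_levels_map)
    if counts.shape != cover_levels_map.shape:
        raise ValueError(
            f"cover level map shape {cover_levels_map.shape} does not match "
            f"the share's block grid {counts.shape}"
        )
    if not np.array_equal(counts, cover_levels_map):
        raise ValueError("share block counts are inconsistent with the cover levels")

    gh, gw = counts.shape
    blocks = share.reshape(gh, bh, gw, bw).swapaxes(1, 2).reshape(gh * gw, s_b)
    flat_levels = counts.ravel()
    results: dict[int, UniformityStratum] = {}
    for level in np.unique(flat_levels):
        level = int(level)
        pats = classic.all_patterns(s_b, level)
        index = {p: i for i, p in enumerate(pats)}
        sel = blocks[flat_levels == level]
        if len(sel) < 50:
            warnings.warn(
                f"stratum level={level} has only {len(sel)} blocks; "
                "the chi-square approximation may be poor",
                stacklevel=2,
            )
        obs = np.zeros(len(pats), dtype=np.int64)
        for row in sel:
            obs[index[tuple(int(v) for v in row)]] += 1
        if len(pats) < 2:
            # a single possible pattern is trivially uniform
            results[level] = UniformityStratum(level, 0.0, 1.0, len(sel))
            continue
        stat, pval = stats.chisquare(obs)
        results[level] = UniformityStratum(level, float(stat), float(pval), len(sel))
    return results


def contrast_alpha(
    recovered: np.ndarray,
    secret_classes: np.ndarray,
    block_shape: tuple[int, int] = (2, 2),
) -> float:
    """Recovered contrast alpha.

    ``secret_classes`` holds, per block of the recovered image, the
    secret's black/white class (0 = black, 1 = white).  Alpha is the
    mean number of white pixels per recovered block over secret-white
    blocks minus the same over secret-black blocks, divided by the
    block size; positive alpha means the secret is visually
    recognizable in the stack.
    """
    bh, bw = block_shape
    s_b = bh * bw
    whites = s_b - block_counts(recovered, block_shape)
    secret_classes = np.asarray(secret_classes)
    if whites.shape != secret_classes.shape:
        raise ValueError(
            f"class map shape {secret_classes.shape} does not match "
            f"the recovered block grid {whites.shape}"
        )
    white_mask = secret_classes == 1
    if white_mask.all() or (~white_mask).all():
        raise ValueError("contrast is undefined when only one secret class is present")
    return float(whites[white_mask].mean() - whites[~white_mask].mean()) / s_b


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB between two gray images.

    Identical images give ``math.inf``.
    """
    a, b = as_gray(a), as_gray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if np.array_equal(a, b):
        return math.inf
    return float(peak_signal_noise_ratio(a, b, data_range=255))
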