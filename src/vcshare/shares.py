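"""Share containers and Boolean stacking."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np

from .io import as_binary

__all__ = ["ShareSet", "stack"]


@dataclass
class ShareSet:
    """The n binary shares produced by one encryption, plus metadata.

    ``expansion`` is the subpixel count m per secret pixel (spatial
    area ratio share/secret); ``secret_shape`` records the original,
    pre-padding secret dimensions so viewers can crop back.
    """

    shares: list[np.ndarray]
    scheme: str
    expansion: int
    block_shape: tuple[int, int]
    secret_shape: tuple[int, int]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shares = [as_binary(s) for s in self.shares]
        if len(self.shares) < 2:
            raise ValueError("a share set needs at least 2 shares")
        shapes = {s.shape for s in self.shares}
        if len(shapes) != 1:
            raise ValueError(f"shares must have identical dimensions, got {shapes}")


def stack(shares: ShareSet | Sequence[np.ndarray] | Iterable[np.ndarray]) -> np.ndarray:
    """Superimpose shares: pixelwise AND (black wins) under 0 = black.

    Accepts a :class:`ShareSet` or any sequence of >= 2 equally sized
    binary images.
    """
    imgs = shares.shares if isinstance(shares, ShareSet) else [as_binary(s) for s in shares]
    if len(imgs) < 2:
        raise ValueError("stacking needs at least 2 shares")
    if len({im.shape for im in imgs}) != 1:
        raise ValueError("stacked shares must have identical dimensions")
    out = imgs[0]
    for im in imgs[1:]:
        out = out & im
    return out.astype(np.uint8)
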