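"""Synthetic gray-image fixtures and the batch share-split pipeline.

`make_fixture` generates deterministic test images — gradients,
checkerboards, text-like stroke patterns, and blob images whose dark
elliptical clusters on a bright background mimic the first-order
statistics of stained tissue micrographs (dark nuclei, light stroma).
They stand in for real image folders so the whole pipeline can be
exercised without any external dataset.

`degrade_dataset` applies the privacy workflow to a folder of images:
each secret is limited-halftoned, split into two meaningful shares,
the shares are stacked and the stack rendered as a blocky gray view.
Only the four derived artifacts are written — the original is never
copied into the output tree, mirroring a deployment where originals
are discarded after the shares are stored on separate servers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .efvcs import EfConfig, encrypt_ef, reconstruct_gray
from .halftone import HalftoneConfig, block_counts, limited_halftone, pad_to_blocks
from .io import read_gray, write_binary, write_gray
from .shares import stack

__all__ = ["FixtureSpec", "make_fixture", "DegradeRecord", "degrade_dataset"]

KINDS = ("gradient", "checkerboard", "text", "blobs")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic synthetic image."""

    kind: str = "blobs"
    shape: tuple[int, int] = (64, 64)
    seed: int = 0
    cell: int = 8  # checkerboard cell / text stroke pitch
    n_blobs: int = 12
    radius_range: tuple[int, int] = (3, 10)
    intensity_range: tuple[int, int] = (20, 90)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")


def make_fixture(spec: FixtureSpec) -> np.ndarray:
    """Deterministic synthetic gray image for ``spec`` (same spec+seed
    always yields the identical array)."""
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gradient":
        row = np.linspace(0, 255, w)
        img = np.tile(row, (h, 1))
    elif spec.kind == "checkerboard":
        rr, cc = np.indices((h, w))
        img = np.where(((rr // spec.cell) + (cc // spec.cell)) % 2 == 0, 0, 255)
    elif spec.kind == "text":
        # dark horizontal/vertical strokes on white, glyph-like density
        img = np.full((h, w), 235.0)
        n_strokes = max(4, (h * w) // (spec.cell * 32))
        for _ in range(n_strokes):
            r = int(rng.integers(0, h))
            c = int(rng.integers(0, w))
            length = int(rng.integers(spec.cell, 3 * spec.cell + 1))
            thick = int(rng.integers(1, 3))
            shade = float(rng.integers(0, 60))
            if rng.random() < 0.5:
                img[r : r + thick, c : c + length] = shade
            else:
                img[r : r + length, c : c + thick] = shade
    else:  # blobs
        img = np.full((h, w), 0.0)
        bg = 200 + 30 * rng.random((h, w))  # bright, lightly textured background
        img += bg
        rr, cc = np.indices((h, w))
        lo_r, hi_r = spec.radius_range
        lo_i, hi_i = spec.intensity_range
        for _ in range(spec.n_blobs):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            ry = int(rng.integers(lo_r, hi_r + 1))
            rx = int(rng.integers(lo_r, hi_r + 1))
            theta = rng.random() * np.pi
            dark = float(rng.integers(lo_i, hi_i + 1))
            dy, dx = rr - cy, cc - cx
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            inside = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
            img[inside] = dark
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class DegradeRecord:
    """Manifest entry for one processed image."""

    input: str
    seed: int
    share1: str
    share2: str
    recovered: str
    recovered_gray: str
    config: dict = field(default_factory=dict)


def _per_image_seed(master_seed: int, rel_path: str) -> int:
    """Stable per-image seed: adding files never perturbs existing ones."""
    digest = hashlib.sha256(f"{master_seed}:{rel_path}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _iter_images(in_dir: Path) -> Iterator[Path]:
    for p in sorted(in_dir.rglob("*")):
        if p.suffix.lower() in (".png", ".pgm") and p.is_file():
            yield p


def _default_covers(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Two fixed, visually distinct covers sized to the secret."""
    return (
        make_fixture(FixtureSpec(kind="blobs", shape=shape, seed=101)),
        make_fixture(FixtureSpec(kind="text", shape=shape, seed=202)),
    )


def degrade_dataset(
    in_dir: str | Path,
    out_dir: str | Path,
    config: EfConfig = EfConfig(),
    cover_policy: str = "fixed",
    seed: int = 0,
) -> list[DegradeRecord]:
    """Split every image in ``in_dir`` into shares and write the derived
    artifacts (share1, share2, recovered stack, recovered gray view).

    ``cover_policy``: ``"fixed"`` reuses the same two fixture covers for
    every image; ``"generated"`` draws fresh covers per image from its
    own seed.  The manifest (JSON lines, one record per image) is
    written to ``out_dir / "manifest.jsonl"``; unreadable images are
    skipped with a warning record-free, and the writer asserts that no
    output duplicates the original image.
    """
    import warnings

    if cover_policy not in ("fixed", "generated"):
        raise ValueError(f"cover_policy must be 'fixed' or 'generated', got {cover_policy!r}")
    config.validate_feasible()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[DegradeRecord] = []
    for path in _iter_images(in_dir):
        rel = path.relative_to(in_dir).as_posix()
        try:
            secret = read_gray(path)
        except (OSError, ValueError) as exc:
            warnings.warn(f"skipping unreadable image {rel}: {exc}", stacklevel=2)
            continue
        img_seed = _per_image_seed(seed, rel)
        rng = np.random.default_rng(img_seed)
        padded_shape = pad_to_blocks(secret, config.block_shape).shape
        if cover_policy == "fixed":
            c1, c2 = _default_covers(secret.shape)
        else:
            c1 = make_fixture(FixtureSpec(kind="blobs", shape=secret.shape, seed=img_seed ^ 1))
            c2 = make_fixture(FixtureSpec(kind="text", shape=secret.shape, seed=img_seed ^ 2))
        shares = encrypt_ef(secret, c1, c2, config, rng)
        recovered = stack(shares)
        gray_view = reconstruct_gray(recovered, config.block_shape)

        stem = Path(rel).with_suffix("")
        paths = {
            "share1": out_dir / f"{stem}_share1.png",
            "share2": out_dir / f"{stem}_share2.png",
            "recovered": out_dir / f"{stem}_recovered.png",
            "recovered_gray": out_dir / f"{stem}_recovered_gray.png",
        }
        for p in paths.values():
            p.parent.mkdir(parents=True, exist_ok=True)
        write_binary(shares.shares[0], paths["share1"])
        write_binary(shares.shares[1], paths["share2"])
        write_binary(recovered, paths["recovered"])
        write_gray(gray_view, paths["recovered_gray"])

        # originals are discarded, never re-stored: no output may equal them
        original_bytes = path.read_bytes()
        for p in paths.values():
            if p.read_bytes() == original_bytes:
                raise RuntimeError(f"output {p} duplicates the original image {rel}")

        records.append(
            DegradeRecord(
                input=rel,
                seed=img_seed,
                share1=str(paths["share1"].relative_to(out_dir)),
                share2=str(paths["share2"].relative_to(out_dir)),
                recovered=str(paths["recovered"].relative_to(out_dir)),
                recovered_gray=str(paths["recovered_gray"].relative_to(out_dir)),
                config={
                    "block_shape": list(config.block_shape),
                    "secret_levels": list(config.secret_levels),
                    "cover_levels": list(config.cover_levels),
                    "cover_policy": cover_policy,
                    "padded_shape": list(padded_shape),
                },
            )
        )
    manifest = out_dir / "manifest.jsonl"
    with manifest.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.__dict__) + "\n")
    return records
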