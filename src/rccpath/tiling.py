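"""Slide tiling and background filtering.

Slides are cut into fixed-size overlapping square patches on a regular grid
(default 512 px tiles with 50% overlap).  Patches dominated by near-white
background are discarded by a pixel-intensity threshold: a patch is
background when at least a given fraction of its pixels (default 50%) have a
mean-over-RGB intensity above a threshold (default 210).  An alternative
reading of the rule — mean intensity of the brightest 50% of pixels above
the threshold — is available via ``mode="brightest_mean"``.

Coordinates are 0-based with half-open pixel bounds ``[x, x + tile_size)``;
partial tiles at the right/bottom edges are dropped, not padded.  Patch
ordering is row-major, which fixes reproducible patch identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = ["TileGrid", "Patch", "tile_slide", "is_background", "filter_patches",
           "read_slide", "write_patches"]


@dataclass(frozen=True)
class TileGrid:
    tile_size: int = 512
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be at least 1 pixel")

    @property
    def stride(self) -> int:
        return int(round(self.tile_size * (1.0 - self.overlap_fraction)))

    def n_tiles(self, extent: int) -> int:
        """Number of full tiles along one axis of length ``extent``."""
        if extent < self.tile_size:
            return 0
        return (extent - self.tile_size) // self.stride + 1


@dataclass
class Patch:
    slide_id: str
    row: int
    col: int
    x: int  # left, inclusive
    y: int  # top, inclusive
    image: np.ndarray  # (tile, tile, 3) uint8
    label: str | None = None


def tile_slide(image: np.ndarray, grid: TileGrid, slide_id: str = "slide",
               label: str | None = None) -> list[Patch]:
    """Extract all full tiles of ``grid`` from an RGB image, row-major.

    Raises ``ValueError`` if the image is smaller than one tile in either
    dimension.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    h, w = image.shape[:2]
    t, s = grid.tile_size, grid.stride
    if h < t or w < t:
        raise ValueError(
            f"image {w}x{h} is smaller than one {t}x{t} tile"
        )
    patches = []
    for r in range(grid.n_tiles(h)):
        y = r * s
        for c in range(grid.n_tiles(w)):
            x = c * s
            patches.append(Patch(slide_id, r, c, x, y,
                                 image[y:y + t, x:x + t], label))
    return patches


def is_background(patch: Patch | np.ndarray, threshold: float = 210.0,
                  fraction: float = 0.5, mode: str = "fraction_above") -> bool:
    """Decide whether a patch is (near-white) background.

    ``fraction_above`` (default): background iff at least ``fraction`` of the
    pixels have mean-RGB intensity strictly above ``threshold``.
    ``brightest_mean``: background iff the mean intensity of the brightest
    ``fraction`` of pixels exceeds ``threshold``.
    """
    img = patch.image if isinstance(patch, Patch) else np.asarray(patch)
    intensity = img.astype(np.float64).mean(axis=2).ravel()
    if mode == "fraction_above":
        return float(np.mean(intensity > threshold)) >= fraction
    if mode == "brightest_mean":
        k = max(1, int(round(fraction * intensity.size)))
        brightest = np.partition(intensity, intensity.size - k)[-k:]
        return float(brightest.mean()) > threshold
    raise ValueError(f"unknown background mode {mode!r}")


def filter_patches(patches: list[Patch], threshold: float = 210.0,
                   fraction: float = 0.5,
                   mode: str = "fraction_above") -> tuple[list[Patch], int]:
    """Drop background patches, preserving order. Returns (kept, n_discarded)."""
    kept = [p for p in patches
            if not is_background(p, threshold, fraction, mode)]
    return kept, len(patches) - len(kept)


def read_slide(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG slide as an (H, W, 3) uint8 array."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    return np.ascontiguousarray(img[:, :, :3])


def write_patches(patches: list[Patch], out_dir: str | Path,
                  kept_flags: list[bool] | None = None) -> pd.DataFrame:
    """Write patches as ``<slide>_<row>_<col>.png`` plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    if kept_flags is None:
        kept_flags = [True] * len(patches)
    for p, kept in zip(patches, kept_flags):
        name = f"{p.slide_id}_{p.row}_{p.col}.png"
        if kept:
            iio.imwrite(out_dir / name, p.image)
        rows.append({"slide_id": p.slide_id, "row": p.row, "col": p.col,
                     "x": p.x, "y": p.y, "kept": kept, "file": name,
                     "label": p.label})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
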