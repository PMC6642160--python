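"""Tumor-probability heatmaps, slide scores and cleaned binary masks.

Per-patch tumor probabilities are spread back onto the slide: each heatmap
cell takes the mean probability of all patches covering it, and cells
covered by no kept patch are marked absent (NaN).  Heatmaps are built at a
configurable downsample factor (default 8) to bound memory on large slides;
a downsampled cell ``(r, c)`` is treated as covered by a patch when its
representative full-resolution pixel ``(r*ds, c*ds)`` falls inside the
patch footprint.  All masks and region areas downstream are computed at
that one scale, so morphometric ratios stay scale-consistent.

A slide-level score is the fraction of kept patches whose tumor probability
strictly exceeds 0.5.  High-probability masks use a strict 0.95 threshold;
cleanup labels 8-connected components and removes every component smaller
than one third of the largest ("main") region, suppressing speckle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as _cc_label

from .tiling import TileGrid

__all__ = ["ProbabilityHeatmap", "TumorMask", "build_heatmap", "slide_score",
           "high_prob_mask", "clean_mask"]


@dataclass
class ProbabilityHeatmap:
    values: np.ndarray          # (h, w) float, NaN where uncovered
    downsample: int
    slide_shape: tuple[int, int]

    @property
    def covered(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class TumorMask:
    mask: np.ndarray            # cleaned boolean mask
    components: pd.DataFrame    # component_id, area, retained
    main_region_id: int | None  # id of the largest component, None if empty
    labels: np.ndarray          # label image of retained components


def build_heatmap(manifest: pd.DataFrame, slide_shape: tuple[int, int],
                  grid: TileGrid, downsample: int = 8) -> ProbabilityHeatmap:
    """Average patch probabilities into a slide heatmap.

    ``manifest`` needs columns ``x, y, score`` (kept patches of one slide,
    scores in [0, 1]).  Raises on an empty manifest.
    """
    if len(manifest) == 0:
        raise ValueError("empty patch manifest")
    scores = manifest["score"].to_numpy(dtype=np.float64)
    if np.nanmin(scores) < 0 or np.nanmax(scores) > 1:
        raise ValueError("scores must lie in [0, 1]")
    H, W = slide_shape
    ds = int(downsample)
    hh, ww = (H + ds - 1) // ds, (W + ds - 1) // ds
    total = np.zeros((hh, ww))
    count = np.zeros((hh, ww), dtype=np.int64)
    t = grid.tile_size
    for x, y, s in zip(manifest["x"], manifest["y"], scores):
        # cells whose representative pixel r*ds lies in [y, y+t)
        r0 = (int(y) + ds - 1) // ds
        r1 = (int(y) + t - 1) // ds
        c0 = (int(x) + ds - 1) // ds
        c1 = (int(x) + t - 1) // ds
        total[r0:r1 + 1, c0:c1 + 1] += s
        count[r0:r1 + 1, c0:c1 + 1] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ProbabilityHeatmap(values, ds, (H, W))


def slide_score(scores, threshold: float = 0.5) -> float:
    """Fraction of patches scored strictly above ``threshold``.

    Serves as the slide-level score for slide-wise AUC.  NaN when there are
    no kept patches.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        return float("nan")
    return float(np.mean(scores > threshold))


def high_prob_mask(heatmap: ProbabilityHeatmap | np.ndarray,
                   threshold: float = 0.95) -> np.ndarray:
    """Boolean mask of cells with probability strictly above ``threshold``."""
    values = heatmap.values if isinstance(heatmap, ProbabilityHeatmap) else np.asarray(heatmap)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(values, nan=-1.0) > threshold


def clean_mask(mask: np.ndarray, min_fraction: float = 1.0 / 3.0) -> TumorMask:
    """Drop small components: keep those with area >= min_fraction * largest.

    Components use 8-connectivity.  An empty mask yields an empty, valid
    ``TumorMask``.  Idempotent: re-cleaning a cleaned mask changes nothing.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = _cc_label(mask, connectivity=2)
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    if ids.size == 0:
        return TumorMask(mask.copy(), pd.DataFrame(
            columns=["component_id", "area", "retained"]), None, labels)
    main_area = int(areas.max())
    main_id = int(ids[np.argmax(areas)])
    retained = areas >= min_fraction * main_area
    rows = pd.DataFrame({"component_id": ids, "area": areas,
                         "retained": retained})
    keep = np.isin(labels, ids[retained])
    cleaned = mask & keep
    out_labels = np.where(keep, labels, 0)
    return TumorMask(cleaned, rows, main_id, out_labels)
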