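"""From patch probabilities to a cleaned tumor mask and shape features.

Builds a probability heatmap by per-pixel averaging of overlapping patch
scores, applies the strict 0.95 threshold, removes regions smaller than one
third of the main region, and measures the surviving tumor regions.
"""

import numpy as np
import pandas as pd

from rccpath.heatmap import build_heatmap, clean_mask, high_prob_mask
from rccpath.morphometry import slide_tumor_features
from rccpath.tiling import TileGrid

# a 3x3 grid of half-overlapping 32px patches: the center of the slide is
# confidently tumor, one corner is an isolated speck
grid = TileGrid(32, 0.5)
rows = []
for x in range(0, 65, 16):
    for y in range(0, 65, 16):
        score = 0.99 if (16 <= x <= 48 and 16 <= y <= 48) else 0.10
        rows.append({"x": x, "y": y, "score": score})
rows[0]["score"] = 0.99  # isolated high-probability corner patch
manifest = pd.DataFrame(rows)

hm = build_heatmap(manifest, slide_shape=(96, 96), grid=grid, downsample=1)
mask = high_prob_mask(hm, threshold=0.95)
tm = clean_mask(mask, min_fraction=1 / 3)

print("components found:")
print(tm.components.to_string(index=False))
features = slide_tumor_features(tm)
print(f"total area {features['total_area']:.0f} px^2, "
      f"main region area {features['main_region_area']:.0f} px^2, "
      f"main region eccentricity {features['main_region_eccentricity']:.2f}")
# The corner speck is smaller than 1/3 of the main region, so the cleanup
# drops it; features are measured only on retained regions.
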