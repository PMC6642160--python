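"""Tile a synthetic slide and drop background patches.

Builds one slide with a near-white border and textured tissue, cuts it into
overlapping tiles and applies the intensity-threshold background filter.
"""

from rccpath.synthetic import SyntheticSlideSpec, generate_slide
from rccpath.tiling import TileGrid, filter_patches, tile_slide

spec = SyntheticSlideSpec(width=512, height=512, tumor_fraction=0.5, seed=0)
image, tumor_mask, label = generate_slide(spec)

grid = TileGrid(tile_size=64, overlap_fraction=0.5)
patches = tile_slide(image, grid, slide_id="demo")
kept, n_dropped = filter_patches(patches, threshold=210, fraction=0.5)

print(f"slide {image.shape[1]}x{image.shape[0]}, tile {grid.tile_size} "
      f"with stride {grid.stride}")
print(f"{len(patches)} grid positions, {len(kept)} tissue patches kept, "
      f"{n_dropped} background patches dropped")
# Kept patches are the ones with <50% of pixels brighter than intensity 210;
# they carry tissue texture and feed the classifier downstream.
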