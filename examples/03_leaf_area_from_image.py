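"""Measure leaf area from a detached-leaf photograph.

Renders the wet-lab layout (flattened leaves on white next to a
100 cm^2 black square), then runs the image pipeline: linear RGB
vegetation index -> Otsu threshold -> reference-square calibration.
"""

from weedphenom import (
    GA2018,
    generate_monocot,
    leaf_area_from_image,
    render_leaf_layout,
)

plant = generate_monocot(height_cm=22.0, n_leaves=5, seed=9)
layout = render_leaf_layout(plant, px_per_cm=20, square_area_cm2=100, seed=4)

area = leaf_area_from_image(layout.image, GA2018)
err = 100 * (area - plant.truth_leaf_area_cm2) / plant.truth_leaf_area_cm2
print(f"truth leaf area     {plant.truth_leaf_area_cm2:.2f} cm^2")
print(f"recovered from image {area:.2f} cm^2  ({err:+.2f}%)")
print(f"square pixels        {layout.square_px_count} "
      f"-> {layout.square_px_count / 100:.0f} px per cm^2")
# The residual error is rasterisation jitter at pixel boundaries; it
# shrinks with px_per_cm.
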