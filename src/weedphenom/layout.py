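"""Render detached-leaf layouts for image-based leaf-area ground truth.

The wet-lab procedure detaches all leaves, lays them flat on a white
sheet next to a black square of known area (100 cm^2), and photographs
the sheet from above.  Because both leaf surfaces used by the generators
are developable, flattening is exact: the rendered silhouette of each
leaf has precisely the leaf's one-sided area.  Rasterisation uses a
pixel-centre inclusion rule, which is unbiased, so silhouette pixel
counts track analytic areas to well under a percent at the default
20 px/cm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.draw import polygon as draw_polygon

from .errors import LayoutError, ParameterError
from .plants import PlantModel

__all__ = ["LeafLayout", "render_leaf_layout"]


@dataclass
class LeafLayout:
    """A rendered layout plus exact rasterisation metadata.

    ``plant_px_count`` is the exact number of pixels painted as leaf,
    and ``square_px_count`` the exact pixel count of the reference
    square — the quantities the imaging stage should recover.
    """

    image: np.ndarray
    px_per_cm: float
    square_px_count: int
    plant_px_count: int
    square_bbox: tuple  # (row0, col0, row1, col1), half-open


def render_leaf_layout(
    plant: Optional[PlantModel],
    px_per_cm: float = 20.0,
    square_area_cm2: float = 100.0,
    seed: int = 0,
    *,
    margin_cm: float = 1.0,
    canvas_px: Optional[tuple] = None,
) -> LeafLayout:
    """Render the flattened leaves of ``plant`` on white with a black
    reference square.

    Leaves are packed left-to-right in rows below the square with at
    least ``margin_cm`` of white between silhouettes, so silhouettes
    never touch.  The canvas is sized to fit unless ``canvas_px`` pins
    it, in which case an overflowing packing raises :class:`LayoutError`.
    ``plant = None`` (or a plant with no leaves) renders the square only.
    """
    if px_per_cm < 5:
        raise ParameterError("px_per_cm must be >= 5 for usable silhouettes")
    if square_area_cm2 <= 0:
        raise ParameterError("square_area_cm2 must be positive")
    rng = np.random.default_rng(seed)

    margin_px = int(round(margin_cm * px_per_cm))
    side_px = int(round(np.sqrt(square_area_cm2) * px_per_cm))

    outlines = []
    if plant is not None:
        for leaf in plant.leaves:
            o = leaf.outline2d * px_per_cm
            # random flips give the layout a hand-placed look; area unchanged
            if rng.random() < 0.5:
                o = o[:, ::-1]
            if rng.random() < 0.5:
                o = o * np.array([1.0, -1.0])
            o = o - o.min(axis=0)
            outlines.append(o)

    # row packing: square first, then leaves sorted tallest-first
    entries = []  # (width_px, height_px, outline or None)
    entries.append((side_px, side_px, None))
    for o in sorted(outlines, key=lambda o: -np.ptp(o[:, 1])):
        w = int(np.ceil(np.ptp(o[:, 0]))) + 1
        h = int(np.ceil(np.ptp(o[:, 1]))) + 1
        entries.append((w, h, o))

    max_row_w = (
        canvas_px[1] - 2 * margin_px
        if canvas_px is not None
        else max(int(60 * px_per_cm), max(e[0] for e in entries) + margin_px)
    )
    placements = []
    x, y, row_h = margin_px, margin_px, 0
    for w, h, o in entries:
        if w > max_row_w:
            raise LayoutError("a silhouette is wider than the canvas")
        if x + w > margin_px + max_row_w:
            x = margin_px
            y += row_h + margin_px
            row_h = 0
        placements.append((x, y, w, h, o))
        x += w + margin_px
        row_h = max(row_h, h)

    height_px = y + row_h + margin_px
    width_px = (
        canvas_px[1]
        if canvas_px is not None
        else max(p[0] + p[2] for p in placements) + margin_px
    )
    if canvas_px is not None:
        if height_px > canvas_px[0]:
            raise LayoutError(
                f"layout needs {height_px} rows, canvas has {canvas_px[0]}"
            )
        height_px = canvas_px[0]

    img = np.full((height_px, width_px, 3), 255, dtype=np.uint8)

    sq_x, sq_y = placements[0][0], placements[0][1]
    img[sq_y:sq_y + side_px, sq_x:sq_x + side_px] = 0
    square_px_count = side_px * side_px

    plant_px = 0
    for x0, y0, _, _, o in placements[1:]:
        rr, cc = draw_polygon(o[:, 1] + y0, o[:, 0] + x0, shape=img.shape[:2])
        plant_px += len(rr)
        img[rr, cc, 0] = rng.integers(30, 71, len(rr))
        img[rr, cc, 1] = rng.integers(120, 171, len(rr))
        img[rr, cc, 2] = rng.integers(30, 71, len(rr))

    return LeafLayout(
        image=img,
        px_per_cm=float(px_per_cm),
        square_px_count=int(square_px_count),
        plant_px_count=int(plant_px),
        square_bbox=(sq_y, sq_x, sq_y + side_px, sq_x + side_px),
    )
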