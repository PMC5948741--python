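"""Assemble single-plant field scenes as delivered by photogrammetry.

A scene holds the plant cloud embedded in its context: a ground patch at
z = 0, three graphic scale markers of known physical length (10 cm by
default) laid flat on the ground in a triangle around the plant, and
optionally adjacent weed plants outside an exclusion radius but sharing
the continuous ground, which is what prevents automatic plant isolation
in practice.  Exported scenes are "uncalibrated": every coordinate is
divided by ``scale_factor``, so the true centimetres-per-scene-unit is
``scale_factor`` and must be recovered from the markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .degrade import DegradationSpec, sample_point_cloud
from .errors import ParameterError
from .geometry import CM, UNCALIBRATED, PointCloud, ScaleMarker
from .plants import generate_dicot

__all__ = ["Scene", "build_scene", "LABEL_PLANT", "LABEL_GROUND",
           "LABEL_MARKER", "LABEL_NEIGHBOR"]

LABEL_PLANT = 0
LABEL_GROUND = 1
LABEL_MARKER = 2
LABEL_NEIGHBOR = 3


@dataclass
class Scene:
    """A plant cloud with ground, markers and optional neighbours.

    All payload coordinates are in scene units (cm / ``true_scale``).
    ``markers`` store the exact endpoints in scene units together with
    the true physical length, mirroring how the operator identifies the
    printed rules in the reconstruction software.
    """

    plant: PointCloud
    ground: PointCloud
    markers: List[ScaleMarker]
    neighbors: List[PointCloud] = field(default_factory=list)
    true_scale: float = 1.0

    def combined(self):
        """Merge all components into one cloud plus per-point source labels."""
        parts = [self.plant, self.ground] + self.neighbors
        labels = (
            [np.full(len(self.plant), LABEL_PLANT)]
            + [np.full(len(self.ground), LABEL_GROUND)]
            + [np.full(len(nb), LABEL_NEIGHBOR) for nb in self.neighbors]
        )
        pts = np.vstack([p.points for p in parts])
        cols = [
            p.colors if p.colors is not None
            else np.full((len(p), 3), 127, dtype=np.uint8)
            for p in parts
        ]
        cloud = PointCloud(pts, np.vstack(cols), unit_state=self.plant.unit_state)
        return cloud, np.concatenate(labels)


def _ground_patch(size_cm: float, density: float, rng,
                  marker_specs, marker_width_cm: float = 1.0):
    """Uniform random ground samples; points under a marker bar are
    coloured near-black so markers are visible in exports."""
    n = max(4, int(round(size_cm * size_cm * density)))
    xy = rng.uniform(-size_cm / 2.0, size_cm / 2.0, (n, 2))
    pts = np.column_stack([xy, np.zeros(n)])
    cols = np.empty((n, 3), dtype=np.uint8)
    cols[:, 0] = rng.integers(100, 140, n)
    cols[:, 1] = rng.integers(70, 100, n)
    cols[:, 2] = rng.integers(40, 70, n)
    for a, b in marker_specs:
        ab = b[:2] - a[:2]
        length = np.linalg.norm(ab)
        u = ab / length
        rel = xy - a[:2]
        t = rel @ u
        d = np.abs(rel @ np.array([-u[1], u[0]]))
        on_bar = (t >= 0) & (t <= length) & (d <= marker_width_cm / 2.0)
        cols[on_bar] = rng.integers(0, 30, (int(on_bar.sum()), 3))
    return PointCloud(pts, cols, unit_state=CM)


def build_scene(
    plant_cloud: PointCloud,
    marker_layout: Optional[list] = None,
    scale_factor: float = 1.0,
    n_neighbors: int = 0,
    seed: int = 0,
    *,
    marker_length_cm: float = 10.0,
    marker_radius_cm: float = 9.0,
    ground_size_cm: float = 24.0,
    ground_density: float = 40.0,
    exclusion_radius_cm: float = 8.0,
    neighbor_height_cm: float = 6.0,
) -> Scene:
    """Embed a plant cloud (cm, stem base at origin) into a scene.

    ``marker_layout`` optionally gives explicit endpoint pairs in cm;
    by default three markers of ``marker_length_cm`` are placed
    tangentially on the ground in a triangle of radius
    ``marker_radius_cm`` around the plant.  All coordinates are divided
    by ``scale_factor`` on output, producing an uncalibrated scene whose
    true cm-per-unit equals ``scale_factor``.

    Neighbour plants are small dicots whose stem bases sit on the same
    ground plane beyond ``exclusion_radius_cm``, so the ground connects
    them to the target plant with no gap.
    """
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be positive")
    rng = np.random.default_rng(seed)

    if marker_layout is None:
        marker_specs = []
        for k in range(3):
            ang = np.pi / 2.0 + k * 2.0 * np.pi / 3.0
            center = marker_radius_cm * np.array([np.cos(ang), np.sin(ang), 0.0])
            tangent = np.array([-np.sin(ang), np.cos(ang), 0.0])
            a = center - 0.5 * marker_length_cm * tangent
            b = center + 0.5 * marker_length_cm * tangent
            marker_specs.append((a, b))
    else:
        marker_specs = [
            (np.asarray(a, dtype=float), np.asarray(b, dtype=float))
            for a, b in marker_layout
        ]

    ground = _ground_patch(ground_size_cm, ground_density, rng, marker_specs)

    neighbors = []
    for k in range(n_neighbors):
        radius = rng.uniform(exclusion_radius_cm, 0.48 * ground_size_cm)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        offset = np.array([radius * np.cos(ang), radius * np.sin(ang), 0.0])
        nb_plant = generate_dicot(
            neighbor_height_cm * rng.uniform(0.7, 1.3),
            n_leaves=4,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        nb_cloud = sample_point_cloud(
            nb_plant,
            DegradationSpec(
                point_density=ground_density,
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
        )
        neighbors.append(
            PointCloud(nb_cloud.points + offset, nb_cloud.colors, unit_state=CM)
        )

    inv = 1.0 / scale_factor
    markers = [
        ScaleMarker(a * inv, b * inv, true_length_cm=marker_length_cm)
        for a, b in marker_specs
    ]
    return Scene(
        plant=plant_cloud.scaled(inv, unit_state=UNCALIBRATED),
        ground=ground.scaled(inv, unit_state=UNCALIBRATED),
        markers=markers,
        neighbors=[nb.scaled(inv, unit_state=UNCALIBRATED) for nb in neighbors],
        true_scale=float(scale_factor),
    )
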