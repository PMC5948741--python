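"""Extract plant height and leaf area from calibrated reconstructions.

Leaf area is the sum of mesh triangle areas — each triangle counted
once, so for an open single-sheet mesh the result is one-sided area.
Plant height follows the cylindrical stem convention: a cylinder of
configurable radius is erected along the ground normal through the stem
base, and height is the vertical extent of the cloud inside it, which
isolates the main stem from outlying leaves.

The stem is located as the densest vertical column of above-ground
points: the stem projects its entire height into a few square
centimetres of ground plan, so it dominates any leaf sheet locally.
By default the plant is assumed to stand on the fitted ground plane, so
height is measured from the plane itself; ``base_mode="lowest"``
instead subtracts the lowest in-cylinder point, for clouds whose base
is not at the ground (e.g. after aggressive cropping).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InputError, ParameterError
from .geometry import Plane, PointCloud, TriangleMesh

log = logging.getLogger(__name__)

__all__ = ["TraitRecord", "TraitConfig", "mesh_surface_area",
           "estimate_plant_height", "extract_traits"]


@dataclass
class TraitRecord:
    """Estimated traits for one plant, with full method provenance."""

    plant_id: str
    est_height_cm: float
    est_leaf_area_cm2: float
    method_flags: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "plant_id": self.plant_id,
            "est_height_cm": self.est_height_cm,
            "est_leaf_area_cm2": self.est_leaf_area_cm2,
            "method_flags": json.dumps(self.method_flags, sort_keys=True),
        }

    @classmethod
    def from_row(cls, row: dict) -> "TraitRecord":
        return cls(
            plant_id=str(row["plant_id"]),
            est_height_cm=float(row["est_height_cm"]),
            est_leaf_area_cm2=float(row["est_leaf_area_cm2"]),
            method_flags=json.loads(row["method_flags"]),
        )


@dataclass
class TraitConfig:
    """Parameters of trait extraction.

    ``subtract_area_cm2`` is removed from the mesh triangle sum before
    reporting leaf area (used with generator metadata to exclude the
    stem tube); ``two_sided_input`` halves the triangle sum for closed
    thin-solid meshes that represent each leaf by two coincident sheets.
    """

    stem_radius_cm: float = 1.0
    base_mode: str = "ground"
    height_method: str = "cylinder"
    subtract_area_cm2: float = 0.0
    two_sided_input: bool = False


def mesh_surface_area(mesh: Optional[TriangleMesh]) -> float:
    """Sum of triangle areas, cm^2.  Empty input yields 0 with a warning."""
    if mesh is None or mesh.n_faces == 0:
        log.warning("mesh_surface_area: empty mesh, returning 0")
        return 0.0
    return float(mesh.face_areas().sum())


def _stem_axis_uv(uv: np.ndarray, d: np.ndarray, cell_cm: float,
                  vote_min_height_cm: float) -> np.ndarray:
    """Ground-plan position of the densest vertical column.

    Votes come from clearly above-ground points (d > vote_min_height_cm)
    when any exist, so the uniformly dense ground patch does not outvote
    the stem; grid argmax is refined once by averaging the winning
    cell's points.  Ties go to the cell nearest the horizontal centroid.
    """
    above = d > vote_min_height_cm
    vote_uv = uv[above] if above.any() else uv
    ij = np.floor(vote_uv / cell_cm).astype(np.int64)
    ij -= ij.min(axis=0)
    key = ij[:, 0] * (ij[:, 1].max() + 1) + ij[:, 1]
    uniq, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
    best_count = counts.max()
    tied = np.flatnonzero(counts == best_count)
    if len(tied) > 1:
        centroid = vote_uv.mean(axis=0)
        cell_means = np.stack(
            [vote_uv[inv == t].mean(axis=0) for t in tied]
        )
        tied = tied[[int(np.argmin(np.linalg.norm(cell_means - centroid, axis=1)))]]
    members = inv == tied[0]
    return vote_uv[members].mean(axis=0)


def estimate_plant_height(
    cloud: PointCloud,
    ground: Plane,
    stem_radius_cm: float = 1.0,
    *,
    base_mode: str = "ground",
    method: str = "cylinder",
    cell_cm: float = 1.0,
    vote_min_height_cm: float = 0.5,
) -> float:
    """Plant height (cm) by the cylindrical stem convention.

    ``method="cylinder"`` measures the extent of points within
    ``stem_radius_cm`` of the vertical axis through the stem base;
    ``method="max_extent"`` uses every point and serves as a fallback
    for strongly tilted stems, where the vertical cylinder truncates
    the stem.  Degenerate clouds (a single point, or no vertical
    extent) yield 0.
    """
    if len(cloud) == 0:
        raise InputError("cannot estimate height of an empty cloud")
    if stem_radius_cm <= 0:
        raise ParameterError("stem_radius_cm must be positive")
    if base_mode not in ("ground", "lowest"):
        raise ParameterError(f"unknown base_mode {base_mode!r}")
    if len(cloud) == 1:
        return 0.0

    nrm = ground.normal
    e1 = np.cross(nrm, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(nrm, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(nrm, e1)
    uv = cloud.points @ np.column_stack([e1, e2])
    d = ground.signed_distance(cloud.points)

    if method == "max_extent":
        sel = np.ones(len(d), dtype=bool)
    elif method == "cylinder":
        axis = _stem_axis_uv(uv, d, cell_cm, vote_min_height_cm)
        sel = np.linalg.norm(uv - axis, axis=1) <= stem_radius_cm
        if not sel.any():
            return 0.0
    else:
        raise ParameterError(f"unknown height method {method!r}")

    d_sel = d[sel]
    if d_sel.max() - d_sel.min() < 1e-9:
        return 0.0
    base = d_sel.min() if base_mode == "lowest" else 0.0
    return float(max(d_sel.max() - base, 0.0))


def extract_traits(
    cloud: PointCloud,
    mesh: Optional[TriangleMesh],
    ground: Plane,
    config: Optional[TraitConfig] = None,
    plant_id: str = "plant",
) -> TraitRecord:
    """Bundle height and leaf-area estimation with full provenance."""
    config = config or TraitConfig()
    height = estimate_plant_height(
        cloud, ground, config.stem_radius_cm,
        base_mode=config.base_mode, method=config.height_method,
    )
    height_extent = estimate_plant_height(
        cloud, ground, config.stem_radius_cm,
        base_mode=config.base_mode, method="max_extent",
    )
    area = mesh_surface_area(mesh) if mesh is not None else 0.0
    if config.two_sided_input:
        area *= 0.5
    area = max(area - config.subtract_area_cm2, 0.0)
    flags = {
        "stem_radius_cm": config.stem_radius_cm,
        "base_mode": config.base_mode,
        "height_method": config.height_method,
        "height_max_extent_cm": height_extent,
        "subtract_area_cm2": config.subtract_area_cm2,
        "two_sided_input": config.two_sided_input,
        "n_points": len(cloud),
        "n_faces": 0 if mesh is None else mesh.n_faces,
        "ground_normal": [float(x) for x in ground.normal],
        "ground_offset": float(ground.offset),
    }
    return TraitRecord(
        plant_id=plant_id,
        est_height_cm=float(height),
        est_leaf_area_cm2=float(area),
        method_flags=flags,
    )
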