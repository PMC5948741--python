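"""Geometric containers shared across the pipeline.

Coordinate convention: right-handed, z-up. Calibrated data are in
centimetres with the ground plane near z = 0 and the plant stem base at
the origin. Uncalibrated data (as delivered by photogrammetry software)
are in arbitrary scene units until :func:`weedphenom.cloudproc.apply_scale`
converts them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "TriangleMesh",
    "PointCloud",
    "Plane",
    "ScaleMarker",
    "ScaleEstimate",
    "UNCALIBRATED",
    "CM",
]

UNCALIBRATED = "uncalibrated"
CM = "cm"


@dataclass
class TriangleMesh:
    """An indexed triangle mesh.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates.
    faces : (m, 3) int array
        Vertex indices of each triangle.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("mesh faces reference invalid vertex indices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Return the (m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "TriangleMesh":
        r = np.asarray(rotation, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64)
        return TriangleMesh(self.vertices @ r.T + t, self.faces.copy())

    def scaled(self, s: float) -> "TriangleMesh":
        return TriangleMesh(self.vertices * float(s), self.faces.copy())

    def concatenated(self, other: "TriangleMesh") -> "TriangleMesh":
        verts = np.vstack([self.vertices, other.vertices])
        faces = np.vstack([self.faces, other.faces + self.n_vertices])
        return TriangleMesh(verts, faces)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class PointCloud:
    """A point cloud with optional per-point 8-bit RGB colour.

    ``unit_state`` tracks whether coordinates are in scene units
    (``"uncalibrated"``) or centimetres (``"cm"``); metric filters refuse
    uncalibrated input.
    """

    points: np.ndarray
    colors: Optional[np.ndarray] = None
    unit_state: str = CM

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError("colors must have one RGB triple per point")
        if self.unit_state not in (UNCALIBRATED, CM):
            raise ValueError(f"unknown unit_state {self.unit_state!r}")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Return the sub-cloud at ``index`` (order preserved)."""
        cols = self.colors[index] if self.colors is not None else None
        return PointCloud(self.points[index], cols, self.unit_state)

    def scaled(self, s: float, unit_state: Optional[str] = None) -> "PointCloud":
        cols = None if self.colors is None else self.colors.copy()
        return PointCloud(self.points * float(s), cols,
                          unit_state if unit_state is not None else self.unit_state)


@dataclass
class Plane:
    """Plane ``normal . x = offset`` with a unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        n = np.linalg.norm(self.normal)
        if not np.isfinite(n) or n == 0:
            raise ValueError("plane normal must be a nonzero finite vector")
        self.normal = self.normal / n
        self.offset = float(self.offset)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.normal - self.offset


@dataclass
class ScaleMarker:
    """A graphic scale of known physical length laid on the ground."""

    endpoint_a: np.ndarray
    endpoint_b: np.ndarray
    true_length_cm: float = 10.0

    def __post_init__(self) -> None:
        self.endpoint_a = np.asarray(self.endpoint_a, dtype=np.float64).reshape(3)
        self.endpoint_b = np.asarray(self.endpoint_b, dtype=np.float64).reshape(3)
        if np.allclose(self.endpoint_a, self.endpoint_b):
            raise DegenerateInputError("marker endpoints coincide")
        if self.true_length_cm <= 0:
            raise ValueError("true marker length must be positive")

    @property
    def observed_length(self) -> float:
        return float(np.linalg.norm(self.endpoint_a - self.endpoint_b))


@dataclass
class ScaleEstimate:
    """Scene-unit to centimetre conversion estimated from scale markers.

    ``cm_per_unit`` is the unweighted mean of the per-marker ratios;
    ``residual_pct`` is the largest relative deviation of any single
    marker from that mean, in percent.
    """

    cm_per_unit: float
    per_marker_ratios: list = field(default_factory=list)
    residual_pct: float = 0.0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)
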