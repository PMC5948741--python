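"""File I/O: PLY/OBJ geometry, PNG images, CSV tables.

Meshes and clouds go through trimesh (ASCII or binary little-endian
PLY; OBJ for meshes).  Marker endpoints, ground-truth traits and
estimated traits are flat CSV tables read and written with pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import trimesh

from .geometry import UNCALIBRATED, PointCloud, ScaleMarker, TriangleMesh
from .traits import TraitRecord

__all__ = [
    "save_mesh", "load_mesh", "save_cloud", "load_cloud",
    "save_markers_csv", "load_markers_csv",
    "save_trait_records", "load_trait_records",
    "save_image", "load_image",
]

PathLike = Union[str, Path]


def save_mesh(mesh: TriangleMesh, path: PathLike) -> None:
    """Write a mesh as PLY (binary little-endian) or OBJ by extension."""
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(str(path))


def load_mesh(path: PathLike) -> TriangleMesh:
    tm = trimesh.load(str(path), process=False, force="mesh")
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def save_cloud(cloud: PointCloud, path: PathLike, encoding: str = "binary") -> None:
    """Write a point cloud as PLY with uchar RGB."""
    colors = cloud.colors
    if colors is None:
        colors = np.full((len(cloud), 3), 127, dtype=np.uint8)
    pc = trimesh.PointCloud(cloud.points, colors=colors)
    data = pc.export(file_type="ply", encoding=encoding)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def load_cloud(path: PathLike, unit_state: str = UNCALIBRATED) -> PointCloud:
    pc = trimesh.load(str(path), process=False)
    colors = None
    if getattr(pc, "colors", None) is not None and len(pc.colors):
        colors = np.asarray(pc.colors)[:, :3].astype(np.uint8)
    return PointCloud(np.asarray(pc.vertices), colors, unit_state=unit_state)


def save_markers_csv(markers: Iterable[ScaleMarker], path: PathLike) -> None:
    rows = []
    for i, m in enumerate(markers):
        rows.append({
            "marker_id": f"marker{i}",
            "ax": m.endpoint_a[0], "ay": m.endpoint_a[1], "az": m.endpoint_a[2],
            "bx": m.endpoint_b[0], "by": m.endpoint_b[1], "bz": m.endpoint_b[2],
            "true_length_cm": m.true_length_cm,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_markers_csv(path: PathLike) -> List[ScaleMarker]:
    df = pd.read_csv(path)
    return [
        ScaleMarker(
            [r.ax, r.ay, r.az], [r.bx, r.by, r.bz],
            true_length_cm=float(r.true_length_cm),
        )
        for r in df.itertuples()
    ]


def save_trait_records(records: Iterable[TraitRecord], path: PathLike) -> None:
    pd.DataFrame([r.to_row() for r in records]).to_csv(path, index=False)


def load_trait_records(path: PathLike) -> List[TraitRecord]:
    df = pd.read_csv(path)
    return [TraitRecord.from_row(row) for row in df.to_dict("records")]


def save_image(image: np.ndarray, path: PathLike) -> None:
    iio.imwrite(str(path), image)


def load_image(path: PathLike) -> np.ndarray:
    img = iio.imread(str(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    return np.asarray(img, dtype=np.uint8)
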