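"""Point-cloud cleaning and metric calibration.

These operations reproduce the manual mesh-processing workflow applied
to photogrammetric reconstructions of single plants: statistical removal
of isolated points, removal of points lying more than a fixed metric
distance (default 0.5 cm, closed interval — a point at exactly the
threshold survives) off the reconstructed surface, manual bounding-box
isolation of the target plant, robust ground-plane fitting, and
conversion from scene units to centimetres using printed scale markers
of known length.

The off-surface filter accepts either an explicit reference mesh or, when
none exists yet (the usual case for a raw dense cloud), measures each
point against a least-squares plane fitted to its k nearest neighbours.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, InputError, ParameterError, UnitError
from .geometry import (
    CM,
    UNCALIBRATED,
    Plane,
    PointCloud,
    ScaleEstimate,
    ScaleMarker,
    TriangleMesh,
)

log = logging.getLogger(__name__)

__all__ = [
    "remove_statistical_outliers",
    "grid_distance_filter",
    "crop_bounding_box",
    "fit_ground_plane",
    "calibrate_scale",
    "apply_scale",
    "scale_mesh",
    "point_mesh_distance",
]


def remove_statistical_outliers(
    cloud: PointCloud, k: int = 12, std_ratio: float = 2.0
) -> Tuple[PointCloud, np.ndarray]:
    """Drop points whose mean k-NN distance is anomalously large.

    A point is removed when its mean distance to its ``k`` nearest
    neighbours exceeds the global mean by more than ``std_ratio``
    standard deviations.  Survivor order is preserved.

    Returns the filtered cloud and the indices of removed points.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    n = len(cloud)
    if n <= k:
        raise InputError(f"cloud has {n} points, need more than k={k}")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + std_ratio * mean_d.std()
    keep = mean_d <= thresh
    removed = np.flatnonzero(~keep)
    return cloud.select(np.flatnonzero(keep)), removed


def _local_plane_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Distance of each point to the total-least-squares plane through
    its k nearest neighbours (the point itself excluded, so isolated
    points measure against the surface, not themselves)."""
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)
    nbrs = points[idx[:, 1:]]  # (n, k, 3)
    centred = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred)
    # smallest-eigenvector of each 3x3 covariance = local plane normal
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]
    rel = points - nbrs.mean(axis=1)
    return np.abs(np.einsum("ni,ni->n", rel, normals))


def grid_distance_filter(
    cloud: PointCloud,
    reference_surface: Optional[TriangleMesh] = None,
    max_dist_cm: float = 0.5,
    k: int = 12,
) -> Tuple[PointCloud, np.ndarray]:
    """Remove points farther than ``max_dist_cm`` from the surface.

    The threshold is metric, so the cloud must be calibrated.  Points at
    exactly ``max_dist_cm`` are kept.  With ``reference_surface`` given,
    distance is the unsigned point-to-mesh distance; otherwise each
    point is measured against the local plane of its ``k`` nearest
    neighbours.
    """
    if cloud.unit_state != CM:
        raise UnitError("grid filter threshold is metric; calibrate first")
    if max_dist_cm < 0:
        raise ParameterError("max_dist_cm must be nonnegative")
    if reference_surface is not None:
        if reference_surface.n_faces == 0:
            raise InputError("reference surface has no faces")
        d = point_mesh_distance(cloud.points, reference_surface)
    else:
        if len(cloud) <= k:
            raise InputError(f"cloud has {len(cloud)} points, need more than k={k}")
        d = _local_plane_distances(cloud.points, k)
    keep = d <= max_dist_cm
    removed = np.flatnonzero(~keep)
    return cloud.select(np.flatnonzero(keep)), removed


def crop_bounding_box(
    cloud: PointCloud, box_min: Sequence[float], box_max: Sequence[float]
) -> PointCloud:
    """Keep points inside the closed axis-aligned box."""
    lo = np.asarray(box_min, dtype=float).reshape(3)
    hi = np.asarray(box_max, dtype=float).reshape(3)
    if not np.all(lo < hi):
        raise ParameterError("box_min must be strictly below box_max")
    inside = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    if not inside.any():
        log.warning("crop_bounding_box removed every point")
    return cloud.select(np.flatnonzero(inside))


def fit_ground_plane(
    cloud: PointCloud,
    inlier_dist_cm: float = 0.3,
    n_trials: int = 300,
    seed: int = 0,
) -> Plane:
    """Robust consensus plane through the dominant planar structure.

    Random 3-point hypotheses are scored by inlier count at
    ``inlier_dist_cm``; the best hypothesis is refined by a
    total-least-squares fit on its inliers.  The normal is oriented so
    the majority of off-plane points (the plant) lie on the positive
    side; a ground patch therefore gets positive height upward.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise DegenerateInputError("plane fit needs at least 3 points")
    rng = np.random.default_rng(seed)
    tri = rng.integers(0, n, size=(n_trials, 3))
    a, b, c = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    normals = np.cross(b - a, c - a)
    norms = np.linalg.norm(normals, axis=1)
    valid = norms > 1e-12
    if not valid.any():
        raise DegenerateInputError("all sampled triples collinear")
    normals = normals[valid] / norms[valid][:, None]
    offsets = np.einsum("ij,ij->i", normals, a[valid])
    d = pts @ normals.T - offsets  # (n, trials)
    counts = (np.abs(d) <= inlier_dist_cm).sum(axis=0)
    best = int(np.argmax(counts))
    if counts[best] < 3:
        raise DegenerateInputError("no plane hypothesis found enough inliers")

    inliers = np.abs(d[:, best]) <= inlier_dist_cm
    sub = pts[inliers]
    centroid = sub.mean(axis=0)
    cov = (sub - centroid).T @ (sub - centroid)
    _, vecs = np.linalg.eigh(cov)
    normal = vecs[:, 0]
    offset = float(normal @ centroid)

    off = pts[~inliers]
    if len(off):
        if np.sum(off @ normal - offset > 0) < 0.5 * len(off):
            normal, offset = -normal, -offset
    elif normal[2] < 0:
        normal, offset = -normal, -offset
    return Plane(normal, offset)


MarkerLike = Union[ScaleMarker, Tuple]


def calibrate_scale(markers: Iterable[MarkerLike]) -> ScaleEstimate:
    """Estimate cm-per-scene-unit from observed scale markers.

    Each marker contributes the ratio of its true physical length to its
    observed endpoint separation; the estimate is the unweighted mean
    (all markers are printed at the same length, so weighting adds
    nothing).  ``residual_pct`` reports the worst single-marker relative
    deviation from the mean — the same consistency check the operator
    performs against the printed rules.
    """
    ms = []
    for m in markers:
        if isinstance(m, ScaleMarker):
            ms.append(m)
        else:
            a, b, *rest = m
            ms.append(ScaleMarker(a, b, rest[0] if rest else 10.0))
    if not ms:
        raise ParameterError("at least one marker is required")
    ratios = []
    for m in ms:
        sep = m.observed_length
        if sep <= 0 or not np.isfinite(sep):
            raise DegenerateInputError("marker endpoints coincide")
        ratios.append(m.true_length_cm / sep)
    ratios = np.asarray(ratios, dtype=float)
    mean = float(ratios.mean())
    residual = float(np.abs(ratios - mean).max() / mean * 100.0)
    return ScaleEstimate(
        cm_per_unit=mean,
        per_marker_ratios=[float(r) for r in ratios],
        residual_pct=residual,
    )


def apply_scale(cloud: PointCloud, estimate: ScaleEstimate) -> PointCloud:
    """Convert an uncalibrated cloud to centimetres."""
    if cloud.unit_state == CM:
        raise UnitError("cloud is already in cm; refusing to scale twice")
    return cloud.scaled(estimate.cm_per_unit, unit_state=CM)


def scale_mesh(mesh: TriangleMesh, estimate: ScaleEstimate) -> TriangleMesh:
    """Convert an uncalibrated mesh to centimetres."""
    return mesh.scaled(estimate.cm_per_unit)


def point_mesh_distance(
    points: np.ndarray, mesh: TriangleMesh, chunk: int = 256
) -> np.ndarray:
    """Exact unsigned distance from each point to the nearest triangle.

    Brute force over (point, triangle) pairs in chunks; intended for the
    moderate mesh sizes this pipeline handles.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    tri = mesh.triangles()
    out = np.empty(len(pts))
    for s in range(0, len(pts), chunk):
        p = pts[s:s + chunk]
        d2 = _point_triangle_sqdist(p[:, None, :], tri[None, :, 0],
                                    tri[None, :, 1], tri[None, :, 2])
        out[s:s + chunk] = np.sqrt(d2.min(axis=1))
    return out


def _point_triangle_sqdist(p, a, b, c):
    """Squared distance from points to triangles, fully broadcast.

    Closest-point classification into vertex / edge / face regions,
    following the standard barycentric region walk.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    shape = np.broadcast_shapes(p.shape, a.shape)
    closest = np.empty(shape)

    # face region
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = vb / denom
    w = vc / denom
    closest[...] = a + v[..., None] * ab + w[..., None] * ac

    # edge AC
    t_ac = np.clip(d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0, 1.0)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[..., None], a + t_ac[..., None] * ac, closest)

    # edge BC
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    t_bc = np.clip(num / np.where(den == 0, 1.0, den), 0.0, 1.0)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[..., None], b + t_bc[..., None] * (c - b), closest)

    # edge AB
    t_ab = np.clip(d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0, 1.0)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[..., None], a + t_ab[..., None] * ab, closest)

    # vertex regions override edges
    at_a = (d1 <= 0) & (d2 <= 0)
    at_b = (d3 >= 0) & (d4 <= d3)
    at_c = (d6 >= 0) & (d5 <= d6)
    closest = np.where(at_c[..., None], np.broadcast_to(c, shape), closest)
    closest = np.where(at_b[..., None], np.broadcast_to(b, shape), closest)
    closest = np.where(at_a[..., None], np.broadcast_to(a, shape), closest)

    diff = p - closest
    return np.einsum("...i,...i->...", diff, diff)
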