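"""Emulate reconstruction-like degradation of ideal plant geometry.

Multi-view photogrammetry does not return the true surface: it returns a
noisy, unevenly supported point cloud with ghost points near the surface
and missing detail at thin structures, most visibly at leaf tips.  This
module maps an ideal :class:`~weedphenom.plants.PlantModel` to such a
cloud (``sample_point_cloud``) or to a "reconstructed" mesh with the same
defects (``degrade_mesh``), with every defect seeded and quantified so
downstream estimates can be validated against exact truth.

Tip dropout removes surface support starting from each leaf's tip and
proceeding toward the base along the leaf axis.  The configured fraction
is the expected per-leaf fraction of one-sided area removed; the
per-leaf realisation is jittered (uniform on ``[0, 2f]`` at the default
jitter of 1) because end-detail loss in real reconstructions varies
strongly from leaf to leaf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np

from .errors import InputError, ParameterError
from .geometry import CM, PointCloud, TriangleMesh
from .plants import PlantModel

__all__ = ["DegradationSpec", "sample_point_cloud", "degrade_mesh"]


@dataclass
class DegradationSpec:
    """Parameters of the reconstruction-degradation model.

    Parameters
    ----------
    point_density : float
        Surface sampling density, points per cm^2 of one-sided area.
    noise_sigma_cm : float
        Isotropic Gaussian displacement applied to every sample.
    outlier_rate : float
        Fraction of samples replaced by ghost points displaced 2-10 cm
        off the surface in a random direction.
    tip_dropout_fraction : float
        Expected fraction of each leaf's area removed from the tip
        inward (0 disables).
    tip_dropout_jitter : float
        Relative spread of the per-leaf dropout fraction: each leaf
        removes ``f * (1 + jitter * U[-1, 1])`` of its area.
    seed : int
        Seed controlling sampling, noise, outliers and dropout draws.
    """

    point_density: float = 40.0
    noise_sigma_cm: float = 0.0
    outlier_rate: float = 0.0
    tip_dropout_fraction: float = 0.0
    tip_dropout_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.point_density <= 0:
            raise ParameterError("point_density must be positive")
        if self.noise_sigma_cm < 0:
            raise ParameterError("noise_sigma_cm must be nonnegative")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ParameterError("outlier_rate must be in [0, 1]")
        if not 0.0 <= self.tip_dropout_fraction <= 1.0:
            raise ParameterError("tip_dropout_fraction must be in [0, 1]")
        if not 0.0 <= self.tip_dropout_jitter <= 1.0:
            raise ParameterError("tip_dropout_jitter must be in [0, 1]")


def _dropout_face_mask(plant: PlantModel, fraction: float, jitter: float,
                       rng: np.random.Generator) -> Tuple[np.ndarray, List[float]]:
    """Boolean keep-mask over plant mesh faces after per-leaf tip dropout.

    Faces are removed in order of decreasing axial position until the
    drawn per-leaf area fraction is reached, so the removed region is the
    distal end of the leaf.
    """
    keep = np.ones(plant.mesh.n_faces, dtype=bool)
    face_areas = plant.mesh.face_areas()
    drawn: List[float] = []
    for leaf in plant.leaves:
        f_leaf = fraction * (1.0 + jitter * rng.uniform(-1.0, 1.0))
        f_leaf = float(np.clip(f_leaf, 0.0, 1.0))
        drawn.append(f_leaf)
        if f_leaf <= 0.0:
            continue
        lo, hi = leaf.face_range
        areas = face_areas[lo:hi]
        order = np.argsort(-leaf.face_axial, kind="stable")
        cum = np.cumsum(areas[order])
        target = f_leaf * areas.sum()
        n_drop = int(np.searchsorted(cum, target, side="left"))
        keep[lo + order[:n_drop]] = False
    return keep, drawn


def _sample_on_faces(mesh: TriangleMesh, face_idx: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    tri = mesh.triangles()[face_idx]
    r1 = rng.random(len(face_idx))
    r2 = rng.random(len(face_idx))
    flip = r1 + r2 > 1.0
    r1[flip] = 1.0 - r1[flip]
    r2[flip] = 1.0 - r2[flip]
    return (
        tri[:, 0]
        + r1[:, None] * (tri[:, 1] - tri[:, 0])
        + r2[:, None] * (tri[:, 2] - tri[:, 0])
    )


def _plant_colors(n: int, rng: np.random.Generator) -> np.ndarray:
    cols = np.empty((n, 3), dtype=np.uint8)
    cols[:, 0] = rng.integers(30, 71, n)
    cols[:, 1] = rng.integers(110, 171, n)
    cols[:, 2] = rng.integers(30, 71, n)
    return cols


def sample_point_cloud(
    plant: Union[PlantModel, TriangleMesh],
    spec: DegradationSpec,
    return_info: bool = False,
):
    """Sample a degraded surface point cloud from a plant (or bare mesh).

    Sampling is area-weighted over the mesh faces surviving tip dropout;
    each sample is then displaced by isotropic Gaussian noise, and a
    seeded subset of samples is replaced by off-surface ghost points
    (2-10 cm away, uniform).  Tip dropout requires leaf bookkeeping and
    is only available for :class:`PlantModel` input.

    The draw order (dropout -> face choice -> barycentric -> noise ->
    outliers -> colors) is fixed, so a given seed is reproducible.
    """
    if isinstance(plant, PlantModel):
        mesh = plant.mesh
        model: Optional[PlantModel] = plant
    else:
        mesh = plant
        model = None
    if mesh.n_faces == 0:
        raise InputError("cannot sample an empty mesh")
    if model is None and spec.tip_dropout_fraction > 0:
        raise ParameterError(
            "tip dropout requires a PlantModel with leaf bookkeeping"
        )

    rng = np.random.default_rng(spec.seed)
    if model is not None and spec.tip_dropout_fraction > 0:
        keep, _ = _dropout_face_mask(
            model, spec.tip_dropout_fraction, spec.tip_dropout_jitter, rng
        )
    else:
        keep = np.ones(mesh.n_faces, dtype=bool)

    areas = mesh.face_areas() * keep
    total = areas.sum()
    if total <= 0:
        raise InputError("no surface area left to sample")
    n = max(1, int(round(spec.point_density * total)))
    face_idx = rng.choice(mesh.n_faces, size=n, p=areas / total)
    pts = _sample_on_faces(mesh, face_idx, rng)

    if spec.noise_sigma_cm > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma_cm, pts.shape)

    outlier_idx = np.empty(0, dtype=np.int64)
    sources = np.empty((0, 3))
    if spec.outlier_rate > 0:
        n_out = int(round(spec.outlier_rate * n))
        if n_out:
            outlier_idx = np.sort(rng.choice(n, size=n_out, replace=False))
            sources = pts[outlier_idx].copy()
            direction = rng.normal(size=(n_out, 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            dist = rng.uniform(2.0, 10.0, n_out)
            pts[outlier_idx] = pts[outlier_idx] + direction * dist[:, None]

    cloud = PointCloud(pts, _plant_colors(n, rng), unit_state=CM)
    if return_info:
        info = {"outlier_indices": outlier_idx, "face_indices": face_idx,
                "outlier_sources": sources}
        return cloud, info
    return cloud


def _smooth_displacement(verts: np.ndarray, sigma: float,
                         rng: np.random.Generator, n_modes: int = 6,
                         wavelength_cm: Tuple[float, float] = (3.0, 8.0)):
    """Smooth random displacement field of RMS amplitude ``sigma``.

    Reconstruction error warps surfaces coherently over centimetres; it
    does not jitter vertices independently (which would crumple a finely
    tessellated mesh and inflate its area).  The field is a sum of a few
    random sinusoidal modes with wavelengths of a few cm.
    """
    disp = np.zeros_like(verts)
    amp = sigma * np.sqrt(2.0 / n_modes)
    for _ in range(n_modes):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        wavevec = rng.normal(size=3)
        wavevec /= np.linalg.norm(wavevec)
        wavevec *= 2.0 * np.pi / rng.uniform(*wavelength_cm)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        disp += amp * np.sin(verts @ wavevec + phase)[:, None] * direction
    return disp


def degrade_mesh(
    plant: PlantModel,
    spec: DegradationSpec,
) -> Tuple[TriangleMesh, dict]:
    """Return a "reconstructed" mesh: tip dropout plus a smooth warp.

    The warp amplitude is ``spec.noise_sigma_cm`` (RMS, cm).  The
    returned info dict reports the surviving leaf triangle-sum area,
    the stem triangle-sum area and the per-leaf dropout fractions drawn,
    so experiments can compare the estimator's output against both the
    ideal truth and the degraded support.
    """
    rng = np.random.default_rng(spec.seed)
    keep, drawn = _dropout_face_mask(
        plant, spec.tip_dropout_fraction, spec.tip_dropout_jitter, rng
    )
    verts = plant.mesh.vertices.copy()
    if spec.noise_sigma_cm > 0:
        verts = verts + _smooth_displacement(verts, spec.noise_sigma_cm, rng)
    faces = plant.mesh.faces[keep]
    # drop unreferenced vertices, preserving order
    used = np.unique(faces)
    remap = np.full(len(verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriangleMesh(verts[used], remap[faces])

    ideal_areas = plant.mesh.face_areas()
    lo, hi = plant.stem_face_range
    stem_keep = keep.copy()
    stem_keep[:] = False
    stem_keep[lo:hi] = keep[lo:hi]
    info = {
        "kept_leaf_area_ideal_cm2": float(
            ideal_areas[keep].sum() - ideal_areas[stem_keep].sum()
        ),
        "stem_area_cm2": float(ideal_areas[stem_keep].sum()),
        "per_leaf_dropout": drawn,
    }
    return out, info
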