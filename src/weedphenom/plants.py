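"""Parametric generators for single-weed morphotypes with exact trait truth.

Two architectural classes are modelled, matching the broad split between
the weeds this pipeline targets:

* **dicot** — broad ovate leaves on a straight vertical stem (cocklebur /
  thornapple habit);
* **monocot** — long, thin, arching strap leaves on a gently curved stem
  (johnsongrass habit).

Both generators are built so that the one-sided leaf area has a closed
form.  A dicot leaf is a planar ovate sheet folded along its midrib: the
fold is an isometry of each half, so the sheet's area equals the area of
the flat outline, which integrates to a Beta function.  A monocot leaf is
a ruled strip swept along a circular arc lying in a vertical plane, with
the rule direction a constant horizontal unit vector perpendicular to
that plane; the surface is developable and its area is exactly the
integral of the width profile along the arc.  Leaves are open single
sheets, so summing mesh triangle areas measures one-sided leaf area
directly.

Plant height ground truth is the stem base-to-tip length, which both
generators construct exactly from the ``height_cm`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.special import beta as beta_fn

from .errors import ParameterError
from .geometry import TriangleMesh

__all__ = ["LeafInfo", "PlantModel", "generate_dicot", "generate_monocot"]

# Ovate outline shape exponents: half-width ~ u^A (1-u)^B, widest at
# u = A/(A+B) ≈ 0.36 of the way from base to tip.
_OVATE_A = 1.0
_OVATE_B = 1.8
# Monocot width taper exponent: w(t) = w0 (1 - (t/L)^P).
_TAPER_P = 1.5


@dataclass
class LeafInfo:
    """Book-keeping for one generated leaf.

    ``face_range`` indexes the plant mesh; ``face_axial`` holds each
    face's normalised position along the leaf axis (0 = base, 1 = tip),
    used to strip tip detail when emulating reconstruction loss.
    ``outline2d`` is the flattened silhouette polygon (cm), whose area
    equals the leaf's one-sided area because both surfaces are
    developable.
    """

    area_cm2: float
    length_cm: float
    face_range: tuple
    face_axial: np.ndarray
    outline2d: np.ndarray


@dataclass
class PlantModel:
    """A synthetic plant mesh with exactly known traits."""

    morphotype: str
    mesh: TriangleMesh
    truth_height_cm: float
    truth_leaf_area_cm2: float
    per_leaf_areas_cm2: List[float]
    params: dict
    seed: int
    leaves: List[LeafInfo] = field(default_factory=list)
    stem_face_range: tuple = (0, 0)
    stem_area_cm2: float = 0.0

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


# ---------------------------------------------------------------------------
# ovate (dicot) leaf
# ---------------------------------------------------------------------------

def _ovate_peak(a: float = _OVATE_A, b: float = _OVATE_B) -> float:
    ustar = a / (a + b)
    return ustar**a * (1.0 - ustar) ** b


def _ovate_halfwidth(u: np.ndarray, width: float) -> np.ndarray:
    g = u**_OVATE_A * (1.0 - u) ** _OVATE_B
    return 0.5 * width * g / _ovate_peak()


def ovate_leaf_area(length_cm: float, width_cm: float) -> float:
    """Closed-form one-sided area of the ovate outline."""
    return (
        width_cm * length_cm * beta_fn(_OVATE_A + 1.0, _OVATE_B + 1.0) / _ovate_peak()
    )


def _dicot_leaf_mesh(length: float, width: float, fold_rad: float,
                     n_u: int, n_v: int):
    """Planar ovate sheet folded along the midrib, in leaf-local frame.

    Local frame: +x along the midrib from base to tip, base at origin.
    Returns (vertices, faces, vertex_axial, outline2d).
    """
    u_rows = np.linspace(0.0, 1.0, n_u + 1)[1:-1]
    hw = _ovate_halfwidth(u_rows, width)
    v = np.linspace(-1.0, 1.0, 2 * n_v + 1)

    n_rows = len(u_rows)
    xs = np.repeat(u_rows * length, len(v))
    ys = np.outer(hw, v).ravel()
    zs = np.abs(ys) * np.sin(fold_rad)
    ys = ys * np.cos(fold_rad)
    verts = np.column_stack([xs, ys, zs])
    axial = np.repeat(u_rows, len(v))

    base_idx = len(verts)
    tip_idx = base_idx + 1
    verts = np.vstack([verts, [0.0, 0.0, 0.0], [length, 0.0, 0.0]])
    axial = np.concatenate([axial, [0.0, 1.0]])

    faces = []
    ncol = len(v)
    for i in range(n_rows - 1):
        r0 = i * ncol
        r1 = (i + 1) * ncol
        for j in range(ncol - 1):
            faces.append([r0 + j, r0 + j + 1, r1 + j])
            faces.append([r0 + j + 1, r1 + j + 1, r1 + j])
    for j in range(ncol - 1):  # base fan
        faces.append([base_idx, j + 1, j])
    last = (n_rows - 1) * ncol
    for j in range(ncol - 1):  # tip fan
        faces.append([tip_idx, last + j, last + j + 1])

    # flattened outline: the unfolded flat sheet
    u_fine = np.linspace(0.0, 1.0, 201)
    hw_fine = _ovate_halfwidth(u_fine, width)
    top = np.column_stack([u_fine * length, hw_fine])
    bot = np.column_stack([u_fine[::-1] * length, -hw_fine[::-1]])
    outline = np.vstack([top, bot[1:-1]])
    return verts, np.asarray(faces, dtype=np.int64), axial, outline


# ---------------------------------------------------------------------------
# strap (monocot) leaf
# ---------------------------------------------------------------------------

def strap_leaf_area(length_cm: float, width_cm: float) -> float:
    """Closed-form one-sided area of the tapered strap."""
    return width_cm * length_cm * _TAPER_P / (_TAPER_P + 1.0)


def _strap_width(t: np.ndarray, length: float, width: float) -> np.ndarray:
    return width * (1.0 - (t / length) ** _TAPER_P)


def _strap_leaf_mesh(length: float, width: float, alpha0: float,
                     alpha_tip: float, h_dir: np.ndarray, rule_dir: np.ndarray,
                     n_t: int):
    """Ruled strap along a circular arc in the vertical plane spanned by
    ``h_dir`` and z, with cross rules along the constant horizontal
    ``rule_dir``.  ``alpha0``/``alpha_tip`` are the elevation angles of
    the midline at base and tip; t is arclength, so the one-sided area is
    exactly the integral of the width profile."""
    kappa = (alpha0 - alpha_tip) / length
    t = np.linspace(0.0, length, n_t + 1)
    alpha = alpha0 - kappa * t
    # closed-form arclength-parameterised circular arc
    horiz = (np.sin(alpha0) - np.sin(alpha)) / kappa
    vert = (np.cos(alpha) - np.cos(alpha0)) / (-kappa)
    mid = horiz[:, None] * h_dir[None, :] + vert[:, None] * np.array([0.0, 0.0, 1.0])
    w = _strap_width(t, length, width)

    stations = t[:-1]
    left = mid[:-1] - 0.5 * w[:-1, None] * rule_dir[None, :]
    right = mid[:-1] + 0.5 * w[:-1, None] * rule_dir[None, :]
    verts = np.empty((2 * len(stations) + 1, 3))
    verts[0::2][: len(stations)] = left
    verts[1::2][: len(stations)] = right
    apex = 2 * len(stations)
    verts[apex] = mid[-1]
    axial = np.empty(len(verts))
    axial[0::2][: len(stations)] = stations / length
    axial[1::2][: len(stations)] = stations / length
    axial[apex] = 1.0

    faces = []
    for j in range(len(stations) - 1):
        a, b = 2 * j, 2 * j + 1
        c, d = 2 * j + 2, 2 * j + 3
        faces.append([a, b, c])
        faces.append([b, d, c])
    faces.append([2 * len(stations) - 2, 2 * len(stations) - 1, apex])

    t_fine = np.linspace(0.0, length, 201)
    w_fine = _strap_width(t_fine, length, width)
    top = np.column_stack([t_fine, 0.5 * w_fine])
    bot = np.column_stack([t_fine[::-1], -0.5 * w_fine[::-1]])
    # tip (t = L) is degenerate, base edge is not: drop only the tip duplicate
    outline = np.vstack([top, bot[1:]])
    return verts, np.asarray(faces, dtype=np.int64), axial, outline


# ---------------------------------------------------------------------------
# stems
# ---------------------------------------------------------------------------

def _tube_mesh(centers: np.ndarray, tangents: np.ndarray, radius: float,
               n_seg: int):
    """Open tube (no caps) around a polyline with given unit tangents."""
    n_st = len(centers)
    # parallel-transport-ish frame: project a reference vector out of tangent
    ref = np.array([1.0, 0.0, 0.0])
    rings = np.empty((n_st, n_seg, 3))
    for i in range(n_st):
        tang = tangents[i]
        e1 = ref - np.dot(ref, tang) * tang
        nrm = np.linalg.norm(e1)
        if nrm < 1e-8:
            e1 = np.array([0.0, 1.0, 0.0]) - tang[1] * tang
            nrm = np.linalg.norm(e1)
        e1 = e1 / nrm
        e2 = np.cross(tang, e1)
        ang = 2.0 * np.pi * np.arange(n_seg) / n_seg
        rings[i] = (
            centers[i]
            + radius * np.cos(ang)[:, None] * e1
            + radius * np.sin(ang)[:, None] * e2
        )
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(n_st - 1):
        for j in range(n_seg):
            a = i * n_seg + j
            b = i * n_seg + (j + 1) % n_seg
            c = (i + 1) * n_seg + j
            d = (i + 1) * n_seg + (j + 1) % n_seg
            faces.append([a, b, c])
            faces.append([b, d, c])
    return verts, np.asarray(faces, dtype=np.int64)


def _straight_stem(height: float, radius: float, n_seg: int = 24):
    n_st = max(8, int(np.ceil(height)) + 1)
    z = np.linspace(0.0, height, n_st)
    centers = np.column_stack([np.zeros(n_st), np.zeros(n_st), z])
    tangents = np.tile([0.0, 0.0, 1.0], (n_st, 1))
    return _tube_mesh(centers, tangents, radius, n_seg), centers, tangents


def _curved_stem(height: float, radius: float, bend_rad: float,
                 bend_azimuth: float, n_seg: int = 24):
    """Stem of arclength ``height`` whose tangent tilts linearly from
    vertical to ``bend_rad`` at the tip, bending in the vertical plane at
    ``bend_azimuth``."""
    n_st = max(12, int(np.ceil(height)) + 1)
    s = np.linspace(0.0, height, n_st)
    h_dir = np.array([np.cos(bend_azimuth), np.sin(bend_azimuth), 0.0])
    if bend_rad < 1e-9:
        centers = s[:, None] * np.array([0.0, 0.0, 1.0])
        tangents = np.tile([0.0, 0.0, 1.0], (n_st, 1))
    else:
        kappa = bend_rad / height
        theta = kappa * s
        horiz = (1.0 - np.cos(theta)) / kappa
        vert = np.sin(theta) / kappa
        centers = horiz[:, None] * h_dir + vert[:, None] * np.array([0, 0, 1.0])
        tangents = (
            np.sin(theta)[:, None] * h_dir
            + np.cos(theta)[:, None] * np.array([0, 0, 1.0])
        )
    return _tube_mesh(centers, tangents, radius, n_seg), centers, tangents


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_dicot(
    height_cm: float,
    n_leaves: int = 6,
    leaf_scale: float = 0.75,
    seed: int = 0,
    *,
    stem_radius_cm: float = 0.2,
    width_ratio: float = 0.62,
    fold_deg: float = 15.0,
    n_u: int = 96,
    n_v: int = 8,
) -> PlantModel:
    """Generate a broad-leaved (dicot) weed.

    Parameters
    ----------
    height_cm
        Stem base-to-tip length; becomes ``truth_height_cm`` exactly.
    n_leaves
        Number of ovate leaves attached along the stem.
    leaf_scale
        Leaf length relative to plant height (before per-leaf variation).
    seed
        Seed for the per-leaf size/pose jitter; identical seeds and
        parameters give bit-identical meshes.

    Leaves attach between 30% and 72% of the stem and are tilted at most
    30 degrees above horizontal, so the stem tip remains the highest
    structure near the plant axis — the property the cylindrical height
    measurement relies on.
    """
    if height_cm <= 0:
        raise ParameterError("height_cm must be positive")
    if n_leaves < 1:
        raise ParameterError("n_leaves must be >= 1")
    if leaf_scale <= 0:
        raise ParameterError("leaf_scale must be positive")
    rng = np.random.default_rng(seed)

    (sv, sf), _, _ = _straight_stem(height_cm, stem_radius_cm)
    verts = [sv]
    faces = [sf]
    n_verts = len(sv)
    stem_faces = len(sf)

    fold = np.deg2rad(fold_deg)
    leaves: List[LeafInfo] = []
    areas: List[float] = []
    fracs = np.linspace(0.30, 0.72, n_leaves)
    azim0 = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(n_leaves):
        frac = fracs[i]
        # lower leaves are larger
        size = leaf_scale * height_cm * (
            0.55 + 0.25 * (1.0 - (frac - 0.30) / 0.42) + rng.uniform(-0.08, 0.08)
        )
        length = max(size, 0.2 * height_cm)
        width = width_ratio * length
        elev = np.deg2rad(rng.uniform(-8.0, 30.0))
        roll = np.deg2rad(rng.uniform(-10.0, 10.0))
        azim = azim0 + i * 2.39996 + rng.uniform(-0.2, 0.2)  # golden-angle phyllotaxis

        lv, lf, axial, outline = _dicot_leaf_mesh(length, width, fold, n_u, n_v)
        rot = _rot_z(azim) @ _rot_y(-elev) @ _rot_x(roll)
        attach = np.array(
            [stem_radius_cm * np.cos(azim), stem_radius_cm * np.sin(azim),
             frac * height_cm]
        )
        lv = lv @ rot.T + attach

        face_axial = axial[lf].mean(axis=1)
        f_start = stem_faces + sum(len(f) for f in faces[1:])
        leaves.append(
            LeafInfo(
                area_cm2=float(ovate_leaf_area(length, width)),
                length_cm=float(length),
                face_range=(f_start, f_start + len(lf)),
                face_axial=face_axial,
                outline2d=outline,
            )
        )
        areas.append(leaves[-1].area_cm2)
        faces.append(lf + n_verts)
        verts.append(lv)
        n_verts += len(lv)

    mesh = TriangleMesh(np.vstack(verts), np.vstack(faces))
    stem_area = float(mesh.face_areas()[:stem_faces].sum())
    return PlantModel(
        morphotype="dicot",
        mesh=mesh,
        truth_height_cm=float(height_cm),
        truth_leaf_area_cm2=float(np.sum(areas)),
        per_leaf_areas_cm2=[float(a) for a in areas],
        params=dict(
            height_cm=height_cm, n_leaves=n_leaves, leaf_scale=leaf_scale,
            stem_radius_cm=stem_radius_cm, width_ratio=width_ratio,
            fold_deg=fold_deg, n_u=n_u, n_v=n_v,
        ),
        seed=int(seed),
        leaves=leaves,
        stem_face_range=(0, stem_faces),
        stem_area_cm2=stem_area,
    )


def generate_monocot(
    height_cm: float,
    n_leaves: int = 5,
    leaf_length_ratio: float = 1.0,
    leaf_width_cm: Optional[float] = None,
    seed: int = 0,
    *,
    stem_radius_cm: float = 0.25,
    stem_bend_deg: float = 12.0,
    min_aspect: float = 10.0,
    n_t: int = 120,
) -> PlantModel:
    """Generate a grass-like (monocot) weed with arching strap leaves.

    ``height_cm`` is the stem arclength (base-to-tip along the possibly
    curved stem) and becomes ``truth_height_cm`` exactly.  Leaf length is
    ``leaf_length_ratio * height_cm`` scaled per leaf; ``leaf_width_cm``
    defaults to 5% of the nominal leaf length so the mandatory strap
    aspect ratio (length:width >= ``min_aspect``) holds.
    """
    if height_cm <= 0:
        raise ParameterError("height_cm must be positive")
    if n_leaves < 1:
        raise ParameterError("n_leaves must be >= 1")
    if leaf_length_ratio <= 0:
        raise ParameterError("leaf_length_ratio must be positive")
    rng = np.random.default_rng(seed)

    nominal_len = leaf_length_ratio * height_cm
    if leaf_width_cm is None:
        leaf_width_cm = 0.05 * nominal_len
    if leaf_width_cm <= 0:
        raise ParameterError("leaf_width_cm must be positive")

    bend_az = rng.uniform(0.0, 2.0 * np.pi)
    bend = np.deg2rad(stem_bend_deg)
    (sv, sf), centers, tangents = _curved_stem(
        height_cm, stem_radius_cm, bend, bend_az
    )
    verts = [sv]
    faces = [sf]
    n_verts = len(sv)
    stem_faces = len(sf)
    s_grid = np.linspace(0.0, height_cm, len(centers))

    leaves: List[LeafInfo] = []
    areas: List[float] = []
    fracs = np.linspace(0.15, 0.60, n_leaves)
    for i in range(n_leaves):
        length = nominal_len * rng.uniform(0.6, 1.0)
        if length / leaf_width_cm < min_aspect:
            raise ParameterError(
                f"strap aspect ratio {length / leaf_width_cm:.1f} below "
                f"required {min_aspect}:1; reduce leaf_width_cm"
            )
        # distichous-ish arrangement: alternate sides with jitter
        psi = bend_az + np.pi / 2.0 + (i % 2) * np.pi + rng.uniform(-0.35, 0.35)
        h_dir = np.array([np.cos(psi), np.sin(psi), 0.0])
        rule_dir = np.array([-np.sin(psi), np.cos(psi), 0.0])
        alpha0 = np.deg2rad(rng.uniform(55.0, 75.0))
        alpha_tip = np.deg2rad(rng.uniform(-70.0, -30.0))

        s_att = fracs[i] * height_cm
        j = int(np.searchsorted(s_grid, s_att))
        j = min(max(j, 0), len(centers) - 1)
        attach = centers[j] + stem_radius_cm * h_dir

        lv, lf, axial, outline = _strap_leaf_mesh(
            length, leaf_width_cm, alpha0, alpha_tip, h_dir, rule_dir, n_t
        )
        lv = lv + attach

        face_axial = axial[lf].mean(axis=1)
        f_start = stem_faces + sum(len(f) for f in faces[1:])
        leaves.append(
            LeafInfo(
                area_cm2=float(strap_leaf_area(length, leaf_width_cm)),
                length_cm=float(length),
                face_range=(f_start, f_start + len(lf)),
                face_axial=face_axial,
                outline2d=outline,
            )
        )
        areas.append(leaves[-1].area_cm2)
        faces.append(lf + n_verts)
        verts.append(lv)
        n_verts += len(lv)

    mesh = TriangleMesh(np.vstack(verts), np.vstack(faces))
    stem_area = float(mesh.face_areas()[:stem_faces].sum())
    return PlantModel(
        morphotype="monocot",
        mesh=mesh,
        truth_height_cm=float(height_cm),
        truth_leaf_area_cm2=float(np.sum(areas)),
        per_leaf_areas_cm2=[float(a) for a in areas],
        params=dict(
            height_cm=height_cm, n_leaves=n_leaves,
            leaf_length_ratio=leaf_length_ratio, leaf_width_cm=leaf_width_cm,
            stem_radius_cm=stem_radius_cm, stem_bend_deg=stem_bend_deg,
            n_t=n_t,
        ),
        seed=int(seed),
        leaves=leaves,
        stem_face_range=(0, stem_faces),
        stem_area_cm2=stem_area,
    )
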