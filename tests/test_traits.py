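"""Trait extraction: surface area and cylindrical plant height."""

import numpy as np
import pytest

from weedphenom import (
    DegradationSpec,
    Plane,
    PointCloud,
    TraitConfig,
    TriangleMesh,
    degrade_mesh,
    estimate_plant_height,
    extract_traits,
    generate_dicot,
    mesh_surface_area,
    sample_point_cloud,
)
from weedphenom.errors import InputError

GROUND = Plane([0.0, 0.0, 1.0], 0.0)


def random_rotation(rng):
    q = rng.normal(size=(3, 3))
    r, _ = np.linalg.qr(q)
    if np.linalg.det(r) < 0:
        r[:, 0] *= -1
    return r


def test_surface_area_elementary_shapes():
    tri = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
    assert mesh_surface_area(tri) == pytest.approx(0.5, abs=1e-15)
    square = TriangleMesh(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], [[0, 1, 2], [0, 2, 3]]
    )
    assert mesh_surface_area(square) == pytest.approx(1.0, abs=1e-15)


def test_surface_area_empty_mesh_is_zero():
    empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    assert mesh_surface_area(empty) == 0.0
    assert mesh_surface_area(None) == 0.0


def test_surface_area_matches_analytic_leaf(dicot):
    fa = dicot.mesh.face_areas()
    for leaf, analytic in zip(dicot.leaves, dicot.per_leaf_areas_cm2):
        lo, hi = leaf.face_range
        sub = TriangleMesh(dicot.mesh.vertices, dicot.mesh.faces[lo:hi])
        assert mesh_surface_area(sub) == pytest.approx(analytic, rel=1e-3)


def test_surface_area_rigid_invariance(dicot, rng):
    base = mesh_surface_area(dicot.mesh)
    for _ in range(3):
        moved = dicot.mesh.transformed(random_rotation(rng),
                                       rng.normal(size=3) * 10)
        assert mesh_surface_area(moved) == pytest.approx(base, rel=1e-9)


@pytest.mark.parametrize("s", [0.5, 2.0, 10.0])
def test_scaling_laws(dicot, s):
    """Area scales as s^2; height as s."""
    assert mesh_surface_area(dicot.mesh.scaled(s)) == pytest.approx(
        s**2 * mesh_surface_area(dicot.mesh), rel=1e-9
    )
    cloud = sample_point_cloud(dicot, DegradationSpec(point_density=40, seed=0))
    h1 = estimate_plant_height(cloud, GROUND)
    h2 = estimate_plant_height(cloud.scaled(s), GROUND,
                               stem_radius_cm=1.0 * s, cell_cm=1.0 * s,
                               vote_min_height_cm=0.5 * s)
    assert h2 == pytest.approx(s * h1, rel=1e-6)


def test_height_noiseless_dicot(clean_dicot_cloud, dicot):
    h = estimate_plant_height(clean_dicot_cloud, GROUND)
    assert h == pytest.approx(dicot.truth_height_cm, abs=0.05)


def test_height_single_point_is_zero():
    cloud = PointCloud([[0.3, 0.1, 5.0]])
    assert estimate_plant_height(cloud, GROUND) == 0.0


def test_height_empty_cloud_rejected():
    with pytest.raises(InputError):
        estimate_plant_height(PointCloud(np.zeros((0, 3))), GROUND)


def test_height_ignores_far_points(clean_dicot_cloud, dicot):
    """Points beyond the stem radius and below the top cannot change
    the cylinder height."""
    h0 = estimate_plant_height(clean_dicot_cloud, GROUND)
    extra = np.array([[5.0, 5.0, dicot.truth_height_cm - 2.0],
                      [-6.0, 2.0, 1.0]])
    aug = PointCloud(np.vstack([clean_dicot_cloud.points, extra]))
    assert estimate_plant_height(aug, GROUND) == pytest.approx(h0, abs=1e-12)


def test_height_tilted_stem_fallback():
    """A stem tilted 30 deg escapes the vertical cylinder; the
    max-extent fallback reports the projected height L*cos(30)."""
    length = 20.0
    t = np.linspace(0.0, length, 400)
    tilt = np.deg2rad(30.0)
    pts = np.column_stack([t * np.sin(tilt), np.zeros_like(t),
                           t * np.cos(tilt)])
    cloud = PointCloud(pts)
    h_cyl = estimate_plant_height(cloud, GROUND)
    h_ext = estimate_plant_height(cloud, GROUND, method="max_extent")
    expected = length * np.cos(tilt)
    assert h_ext == pytest.approx(expected, rel=1e-6)
    assert h_cyl < expected  # cylinder truncates the tilted stem


def test_height_base_mode_lowest():
    """A floating column is measured from its own lowest point."""
    z = np.linspace(3.0, 9.0, 200)
    cloud = PointCloud(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
    assert estimate_plant_height(cloud, GROUND, base_mode="lowest") == (
        pytest.approx(6.0, abs=1e-9)
    )
    assert estimate_plant_height(cloud, GROUND, base_mode="ground") == (
        pytest.approx(9.0, abs=1e-9)
    )


def test_extract_traits_noiseless_recovery(dicot, clean_dicot_cloud):
    record = extract_traits(
        clean_dicot_cloud, dicot.mesh, GROUND,
        TraitConfig(subtract_area_cm2=dicot.stem_area_cm2),
        plant_id="d0",
    )
    assert record.est_height_cm == pytest.approx(dicot.truth_height_cm, rel=0.01)
    assert record.est_leaf_area_cm2 == pytest.approx(
        dicot.truth_leaf_area_cm2, rel=0.01
    )


def test_extract_traits_without_mesh(clean_dicot_cloud):
    record = extract_traits(clean_dicot_cloud, None, GROUND)
    assert record.est_leaf_area_cm2 == 0.0
    assert record.est_height_cm > 0.0


def test_trait_record_roundtrip(tmp_path, dicot, clean_dicot_cloud):
    from weedphenom.io import load_trait_records, save_trait_records

    record = extract_traits(clean_dicot_cloud, dicot.mesh, GROUND,
                            plant_id="plant_7")
    path = tmp_path / "traits.csv"
    save_trait_records([record], path)
    back = load_trait_records(path)[0]
    assert back.plant_id == record.plant_id
    assert back.est_height_cm == record.est_height_cm
    assert back.est_leaf_area_cm2 == record.est_leaf_area_cm2
    assert back.method_flags == record.method_flags


def test_leaf_area_decreases_with_tip_dropout():
    """More tip dropout means less surviving mesh area, on average."""
    means = []
    for frac in (0.0, 0.05, 0.15):
        areas = []
        for seed in range(5):
            plant = generate_dicot(10.0, n_leaves=5, seed=seed)
            recon, info = degrade_mesh(
                plant, DegradationSpec(tip_dropout_fraction=frac, seed=seed)
            )
            areas.append(mesh_surface_area(recon) / plant.truth_leaf_area_cm2)
        means.append(np.mean(areas))
    assert means[0] > means[1] > means[2]
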