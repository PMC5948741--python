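"""Cloud filtering, ground fitting and scale calibration."""

import numpy as np
import pytest

from weedphenom import (
    PointCloud,
    ScaleMarker,
    apply_scale,
    build_scene,
    calibrate_scale,
    crop_bounding_box,
    fit_ground_plane,
    grid_distance_filter,
    remove_statistical_outliers,
)
from weedphenom.errors import (
    DegenerateInputError,
    InputError,
    ParameterError,
    UnitError,
)
from weedphenom.geometry import CM, UNCALIBRATED, TriangleMesh
from weedphenom.scene import LABEL_NEIGHBOR, LABEL_PLANT


def grid_cloud(n=10, spacing=1.0):
    x, y = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
    pts = np.column_stack([x.ravel(), y.ravel(), np.zeros(n * n)])
    return PointCloud(pts, unit_state=CM)


def brute_force_sor(points, k, std_ratio):
    """Independent O(n^2) statistical-outlier oracle."""
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    mean_k = np.sort(d, axis=1)[:, :k].mean(axis=1)
    thresh = mean_k.mean() + std_ratio * mean_k.std()
    return np.flatnonzero(mean_k > thresh)


def test_sor_removes_the_isolated_point():
    cloud = grid_cloud(10)
    pts = np.vstack([cloud.points, [[4.0, 4.0, 10.0]]])
    cloud = PointCloud(pts, unit_state=CM)
    kept, removed = remove_statistical_outliers(cloud, k=10, std_ratio=2.0)
    assert list(removed) == [100]
    assert len(kept) == 100
    assert np.array_equal(removed, brute_force_sor(pts, 10, 2.0))


def circle_cloud(n=60, radius=5.0):
    """Equally spaced ring: every point has identical k-NN distances."""
    ang = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                           np.zeros(n)])
    return PointCloud(pts, unit_state=CM)


def test_sor_keeps_equidistant_structure():
    """When all mean k-NN distances are equal nothing can exceed
    mean + 2 std, so the filter is the identity."""
    cloud = circle_cloud()
    kept, removed = remove_statistical_outliers(cloud, k=8, std_ratio=2.0)
    assert len(removed) == 0
    assert np.array_equal(kept.points, cloud.points)


def test_sor_matches_brute_force_on_random_cloud(rng):
    pts = rng.normal(size=(120, 3))
    cloud = PointCloud(pts, unit_state=CM)
    _, removed = remove_statistical_outliers(cloud, k=6, std_ratio=1.5)
    assert np.array_equal(removed, brute_force_sor(pts, 6, 1.5))


def test_sor_idempotent_on_structured_cloud():
    pts = np.vstack([circle_cloud().points, [[0.0, 0.0, 10.0]]])
    once, removed1 = remove_statistical_outliers(
        PointCloud(pts, unit_state=CM), 10, 2.0
    )
    assert list(removed1) == [60]
    twice, removed2 = remove_statistical_outliers(once, 10, 2.0)
    assert len(removed2) == 0
    assert np.array_equal(once.points, twice.points)


def test_sor_requires_more_points_than_k():
    cloud = grid_cloud(2)  # 4 points
    with pytest.raises(InputError):
        remove_statistical_outliers(cloud, k=4)


def flat_reference():
    v = np.array([[-5, -5, 0], [5, -5, 0], [5, 5, 0], [-5, 5, 0]], float)
    return TriangleMesh(v, [[0, 1, 2], [0, 2, 3]])


def test_grid_filter_closed_interval_semantics():
    """Points at 0.4 and exactly 0.5 cm survive; 0.6 cm is removed."""
    ref = flat_reference()
    cloud = PointCloud([[0, 0, 0.4], [1, 0, 0.5], [2, 0, 0.6]], unit_state=CM)
    kept, removed = grid_distance_filter(cloud, ref, max_dist_cm=0.5)
    assert np.array_equal(kept.points[:, 2], [0.4, 0.5])
    assert list(removed) == [2]


def test_grid_filter_identity_on_surface():
    ref = flat_reference()
    cloud = PointCloud([[x, y, 0.0] for x in range(3) for y in range(3)],
                       unit_state=CM)
    kept, removed = grid_distance_filter(cloud, ref, max_dist_cm=0.5)
    assert len(removed) == 0
    assert np.array_equal(kept.points, cloud.points)


def test_grid_filter_zero_threshold():
    ref = flat_reference()
    cloud = PointCloud([[0, 0, 0.0], [1, 0, 1e-3]], unit_state=CM)
    kept, _ = grid_distance_filter(cloud, ref, max_dist_cm=0.0)
    assert len(kept) == 1


def test_grid_filter_requires_cm():
    cloud = PointCloud([[0, 0, 0]] * 20, unit_state=UNCALIBRATED)
    with pytest.raises(UnitError):
        grid_distance_filter(cloud, flat_reference())


def test_grid_filter_local_plane_mode(rng):
    """Without a reference mesh, off-plane points are caught by the
    local neighbourhood plane."""
    cloud = grid_cloud(10)
    pts = np.vstack([cloud.points, [[4.5, 4.5, 2.0]]])
    kept, removed = grid_distance_filter(
        PointCloud(pts, unit_state=CM), max_dist_cm=0.5, k=8
    )
    assert list(removed) == [100]


def test_grid_filter_idempotent_with_reference():
    ref = flat_reference()
    pts = np.column_stack([
        np.linspace(-4, 4, 30), np.zeros(30),
        np.linspace(0, 1.0, 30),
    ])
    cloud = PointCloud(pts, unit_state=CM)
    once, _ = grid_distance_filter(cloud, ref, 0.5)
    twice, removed2 = grid_distance_filter(once, ref, 0.5)
    assert len(removed2) == 0
    assert np.array_equal(once.points, twice.points)


def test_crop_box(clean_dicot_cloud):
    lo = clean_dicot_cloud.points.min(axis=0) - 1
    hi = clean_dicot_cloud.points.max(axis=0) + 1
    assert len(crop_bounding_box(clean_dicot_cloud, lo, hi)) == len(
        clean_dicot_cloud
    )
    with pytest.raises(ParameterError):
        crop_bounding_box(clean_dicot_cloud, hi, lo)


def test_crop_removes_labeled_neighbors(clean_dicot_cloud):
    """Cropping to the plant's box removes the neighbour clusters, as
    verified against the generator's point labels."""
    scn = build_scene(clean_dicot_cloud, scale_factor=1.0, n_neighbors=2,
                      seed=5, exclusion_radius_cm=12.0, ground_size_cm=34.0)
    combined, labels = scn.combined()
    lo = clean_dicot_cloud.points.min(axis=0) - 0.5
    hi = clean_dicot_cloud.points.max(axis=0) + 0.5
    lo[2] = -0.5
    cropped = crop_bounding_box(combined, lo, hi)
    inside = np.all((combined.points >= lo) & (combined.points <= hi), axis=1)
    # all plant points kept; neighbour clusters (labelled) mostly outside
    assert inside[labels == LABEL_PLANT].all()
    assert inside[labels == LABEL_NEIGHBOR].mean() < 0.2
    for nb in scn.neighbors:
        centroid = nb.points.mean(axis=0)
        assert not np.all((centroid >= lo) & (centroid <= hi))
    assert len(cropped) == inside.sum()


def test_ground_plane_exact_on_clean_patch(rng):
    xy = rng.uniform(-5, 5, (300, 2))
    cloud = PointCloud(np.column_stack([xy, np.zeros(300)]), unit_state=CM)
    plane = fit_ground_plane(cloud, seed=0)
    assert abs(plane.normal[2]) > 1 - 1e-9
    assert abs(plane.offset) < 1e-9


def test_ground_plane_noisy_patch_within_one_degree(rng):
    xy = rng.uniform(-5, 5, (500, 2))
    z = rng.normal(0, 0.05, 500)
    cloud = PointCloud(np.column_stack([xy, z]), unit_state=CM)
    plane = fit_ground_plane(cloud, inlier_dist_cm=0.3, seed=1)
    # total-least-squares oracle on the full patch
    pts = cloud.points - cloud.points.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    oracle = vt[2]
    cos = abs(np.dot(plane.normal, oracle))
    assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0


def test_ground_plane_three_exact_points():
    cloud = PointCloud([[0, 0, 0], [1, 0, 0], [0, 1, 1]], unit_state=CM)
    plane = fit_ground_plane(cloud, seed=0)
    d = plane.signed_distance(cloud.points)
    assert np.abs(d).max() < 1e-9


def test_ground_plane_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        fit_ground_plane(PointCloud([[0, 0, 0], [1, 1, 1]], unit_state=CM))
    collinear = PointCloud(
        np.outer(np.arange(10.0), [1.0, 1.0, 0.0]), unit_state=CM
    )
    with pytest.raises(DegenerateInputError):
        fit_ground_plane(collinear, seed=0)


def test_calibrate_single_marker():
    est = calibrate_scale([ScaleMarker([0, 0, 0], [5, 0, 0], 10.0)])
    assert est.cm_per_unit == pytest.approx(2.0, abs=1e-15)
    assert est.residual_pct == 0.0


def test_calibrate_three_markers_mean_and_residual():
    markers = [
        ([0, 0, 0], [10 / 1.9, 0, 0], 10.0),
        ([0, 0, 0], [5.0, 0, 0], 10.0),
        ([0, 0, 0], [10 / 2.1, 0, 0], 10.0),
    ]
    est = calibrate_scale(markers)
    assert est.cm_per_unit == pytest.approx(2.0, rel=1e-12)
    assert est.residual_pct == pytest.approx(5.0, rel=1e-9)


def test_marker_default_length_is_10cm():
    m = ScaleMarker([0, 0, 0], [1, 0, 0])
    assert m.true_length_cm == 10.0


def test_calibrate_degenerate_marker():
    with pytest.raises(DegenerateInputError):
        ScaleMarker([1, 1, 1], [1, 1, 1])
        # construction itself fails; calibrate on tuples likewise:
    with pytest.raises((DegenerateInputError, ValueError)):
        calibrate_scale([([1, 1, 1], [1, 1, 1], 10.0)])


def test_apply_scale_and_roundtrip(clean_dicot_cloud):
    scn = build_scene(clean_dicot_cloud, scale_factor=2.0, seed=1)
    est = calibrate_scale(scn.markers)
    calibrated = apply_scale(scn.plant, est)
    assert calibrated.unit_state == CM
    assert np.abs(calibrated.points - clean_dicot_cloud.points).max() < 1e-9
    with pytest.raises(UnitError):
        apply_scale(calibrated, est)


@pytest.mark.parametrize("true_scale", [0.1, 1.0, 2.0, 37.5, 100.0])
def test_calibration_exact_over_scale_range(clean_dicot_cloud, true_scale):
    """Noiseless scenes recover any true scale to 1e-12 relative."""
    scn = build_scene(clean_dicot_cloud, scale_factor=true_scale, seed=2)
    est = calibrate_scale(scn.markers)
    assert est.cm_per_unit == pytest.approx(true_scale, rel=1e-12)
    assert est.residual_pct < 1e-10
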