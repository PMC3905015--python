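import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pixelccs import (
    FixtureSpec,
    RasterConfig,
    RasterTooLargeError,
    SphereCloud,
    circle_union_area,
    fixture_cloud,
    make_rotation_grid,
    pixels_per_angstrom,
    predict_ccs,
    project_silhouette,
    stride_corrected_count,
    sweep_stride,
    sweep_theta,
)
from pixelccs.projection import rotation_matrix


def sphere_cloud(centers, radius=3.0):
    centers = np.asarray(centers, float).reshape(-1, 3)
    return SphereCloud(centers, np.full(len(centers), radius), "test", 0.0)


# --- rotation grid ---------------------------------------------------------

@pytest.mark.parametrize("theta,n_orient,theta_eff", [
    (180.0, 1, 180.0),
    (90.0, 4, 90.0),
    (30.0, 36, 30.0),
    (1.0, 32400, 1.0),
    (29.0, 36, 30.0),      # snaps to the nearest admissible angle
    (40.5, 25, 36.0),      # tie between 45 and 36 resolved to the smaller
])
def test_rotation_grid_counts(theta, n_orient, theta_eff):
    grid = make_rotation_grid(theta)
    assert grid.n_orientations == n_orient
    assert grid.theta_effective == theta_eff
    n = round(180.0 / grid.theta_effective)
    assert 180.0 / grid.theta_effective == pytest.approx(n)
    assert grid.n_orientations == n * n
    assert grid.orientations[0] == (0.0, 0.0)


@pytest.mark.parametrize("theta", [0.0, -5.0, 181.0])
def test_rotation_grid_rejects_bad_theta(theta):
    with pytest.raises(ValueError):
        make_rotation_grid(theta)


# --- pixel bookkeeping -----------------------------------------------------

@pytest.mark.parametrize("count,stride,expected", [
    (2307, 5, 57675),
    (578, 10, 57800),
    (42, 1, 42),
])
def test_stride_corrected_count(count, stride, expected):
    assert stride_corrected_count(count, stride) == expected


def test_pixels_per_angstrom():
    assert pixels_per_angstrom(1000, 100) == 10.0
    assert pixels_per_angstrom(500, 100) == 5.0
    # the inverse is a pixel size that reproduces the window width
    px = 1.0 / pixels_per_angstrom(1000, 100)
    assert 1000 * px == pytest.approx(100)
    with pytest.raises(ValueError):
        pixels_per_angstrom(0, 100)
    with pytest.raises(ValueError):
        pixels_per_angstrom(100, -1)


# --- single-orientation silhouette areas -----------------------------------

def test_single_sphere_is_a_disk(fine_raster):
    cloud = sphere_cloud([[0, 0, 0]])
    area = project_silhouette(cloud, (17.0, 42.0), fine_raster)
    assert area == pytest.approx(math.pi * 9.0, rel=0.01)


def test_spheres_coincident_along_viewing_axis(fine_raster):
    cloud = sphere_cloud([[0, 0, 0], [0, 0, 10]])
    area = project_silhouette(cloud, (0.0, 0.0), fine_raster)
    assert area == pytest.approx(math.pi * 9.0, rel=0.01)


def test_disjoint_disks_add(fine_raster):
    cloud = sphere_cloud([[0, 0, 0], [10, 0, 0]])
    area = project_silhouette(cloud, (0.0, 0.0), fine_raster)
    assert area == pytest.approx(2 * math.pi * 9.0, rel=0.01)


def test_overlapping_disks_match_lens_formula(fine_raster):
    cloud = sphere_cloud([[0, 0, 0], [3.0, 0, 0]])
    area = project_silhouette(cloud, (0.0, 0.0), fine_raster)
    truth = circle_union_area([[0, 0], [3.0, 0]], [3.0, 3.0])
    assert truth.method == "closed_form"
    assert area == pytest.approx(truth.area, rel=0.01)


def test_translation_invariance():
    raster = RasterConfig(pixel_size=0.1, stride=2)
    cloud = sphere_cloud([[0, 0, 0], [2, 1, -1], [-3, 2, 4]])
    moved = cloud.translated([123.4, -56.7, 89.0])
    for orientation in [(0, 0), (30, 60), (45, 135)]:
        a = project_silhouette(cloud, orientation, raster)
        b = project_silhouette(moved, orientation, raster)
        assert a == b  # raster anchors on the bounding box, so bit-identical


def test_area_bounds_single_orientation(random_cloud, fine_raster):
    """max single disk <= silhouette <= sum of disks, per orientation."""
    area = project_silhouette(random_cloud, (25.0, 70.0), fine_raster)
    disk_areas = math.pi * random_cloud.radii ** 2
    assert disk_areas.max() * 0.99 <= area <= disk_areas.sum() * 1.01


def test_adding_a_sphere_never_shrinks_area(fine_raster):
    base = sphere_cloud([[0, 0, 0], [4, 1, 0]])
    bigger = sphere_cloud([[0, 0, 0], [4, 1, 0], [2, -3, 1]])
    for orientation in [(0, 0), (60, 30)]:
        assert project_silhouette(bigger, orientation, fine_raster) >= \
            project_silhouette(base, orientation, fine_raster)


def test_raster_budget_enforced():
    cloud = sphere_cloud([[0, 0, 0], [500, 0, 0]])
    with pytest.raises(RasterTooLargeError, match="pixel_size"):
        project_silhouette(cloud, (0, 0),
                           RasterConfig(pixel_size=0.01, stride=1,
                                        max_pixels=10_000))


@pytest.mark.parametrize("bad", [
    {"pixel_size": 0.0},
    {"stride": 0},
    {"padding": -1.0},
])
def test_raster_config_validation(bad):
    with pytest.raises(ValueError):
        RasterConfig(**bad)


# --- rotationally averaged CCS ---------------------------------------------

def test_sphere_ccs_is_rotation_invariant(fine_raster):
    result = predict_ccs(sphere_cloud([[5, -2, 7]]), 30.0, fine_raster)
    assert result.grid.n_orientations == 36
    assert np.all(result.areas == result.areas[0])
    assert result.ccs == pytest.approx(math.pi * 9.0, rel=0.01)


def test_rod_ccs_between_extreme_orientations(fine_raster):
    rod = fixture_cloud(FixtureSpec(kind="collinear_rod", count=3, spacing=3.0))
    result = predict_ccs(rod, 30.0, fine_raster)
    assert result.areas.min() < result.ccs < result.areas.max()
    assert result.ccs == pytest.approx(result.areas.mean())


def test_theta_180_is_single_face_on_area(helix_cloud, fine_raster):
    result = predict_ccs(helix_cloud, 180.0, fine_raster)
    assert result.grid.n_orientations == 1
    face_on = project_silhouette(helix_cloud.centered(), (0.0, 0.0), fine_raster)
    assert result.ccs == face_on


def test_ccs_monotone_in_probe_radius():
    spec = FixtureSpec(kind="random_cloud", count=20, seed=5, extent=8)
    raster = RasterConfig(pixel_size=0.1, stride=1)
    ccs = [predict_ccs(fixture_cloud(spec, probe_radius=p), 90.0, raster).ccs
           for p in (0.0, 0.7, 1.4, 2.0)]
    assert all(a <= b for a, b in zip(ccs, ccs[1:]))


def test_stride_converges_with_pixel_size(helix_cloud):
    """Strided area approaches the stride-1 area as the raster refines."""
    orientation = (30.0, 60.0)
    devs = []
    for px in (0.4, 0.1, 0.025):
        a1 = project_silhouette(helix_cloud, orientation,
                                RasterConfig(pixel_size=px, stride=1))
        a5 = project_silhouette(helix_cloud, orientation,
                                RasterConfig(pixel_size=px, stride=5))
        devs.append(abs(a5 - a1) / a1)
    assert devs[-1] < devs[0]
    assert devs[-1] < 0.01


# --- parameter sweeps -------------------------------------------------------

def test_sweep_stride_single_value_matches_predict(helix_cloud):
    raster = RasterConfig(pixel_size=0.2, stride=1)
    sweep = sweep_stride(helix_cloud, 90.0, [1], raster)
    assert sweep.ccs[0] == predict_ccs(helix_cloud, 90.0, raster).ccs
    assert sweep.values == [1.0]


def test_sweep_stride_values_increasing_and_timed(random_cloud):
    raster = RasterConfig(pixel_size=0.05, stride=1)
    sweep = sweep_stride(random_cloud, 90.0, [40, 3, 10], raster)
    assert sweep.values == [3.0, 10.0, 40.0]
    assert all(t > 0 for t in sweep.elapsed_s)
    assert len(sweep.ccs) == 3


def test_sweep_theta_sphere_invariant(fine_raster):
    cloud = sphere_cloud([[0, 0, 0]])
    sweep = sweep_theta(cloud, [180.0, 90.0, 30.0], fine_raster)
    # identical per-orientation areas; the mean varies only in the last ulp
    np.testing.assert_allclose(sweep.ccs, sweep.ccs[0], rtol=1e-12)


def test_sweep_rejects_empty_inputs(helix_cloud):
    with pytest.raises(ValueError):
        sweep_stride(helix_cloud, 30.0, [])
    with pytest.raises(ValueError):
        sweep_theta(helix_cloud, [])


# --- property: rasterizer vs analytic union on small disk sets --------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(-8, 8), st.floats(-8, 8),
                          st.floats(1.0, 4.0)),
                min_size=1, max_size=3))
def test_raster_matches_circle_union_within_discretization_bound(disks):
    centers = np.array([[x, y, 0.0] for x, y, _ in disks])
    radii = np.array([r for _, _, r in disks])
    cloud = SphereCloud(centers, radii, "prop", 0.0)
    raster = RasterConfig(pixel_size=0.05, stride=2)
    measured = project_silhouette(cloud, (0.0, 0.0), raster)
    truth = circle_union_area(centers[:, :2], radii).area
    perimeter = 2 * math.pi * radii.sum()
    bound = perimeter * raster.stride * raster.pixel_size
    assert abs(measured - truth) <= bound


def test_rotation_matrix_is_orthonormal():
    rot = rotation_matrix(33.0, 71.0)
    np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-12)
    assert np.linalg.det(rot) == pytest.approx(1.0)
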