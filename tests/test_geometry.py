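"""Polygon primitives: chaining, orientation, symmetry, resampling, rays."""

import numpy as np
import pytest

import stematlas as sa
from stematlas.geometry import (ChainError, DegeneratePolygonError,
                                GeometryError, Polygon, PointPattern,
                                _min_dist_to_edges)

from conftest import SUITE_SEED


def brute_min_dist(point, poly: Polygon) -> float:
    """Independent point-to-boundary distance: loop over every edge."""
    best = np.inf
    n = poly.n_vertices
    for i in range(n):
        a, b = poly.xy[i], poly.xy[(i + 1) % n]
        d = b - a
        t = np.clip(np.dot(point - a, d) / np.dot(d, d), 0, 1)
        best = min(best, float(np.hypot(*(point - (a + t * d)))))
    return best


def circle_polygon(r, n=720):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([r * np.cos(t), r * np.sin(t)]))


# --------------------------------------------------------------------------
# chaining
# --------------------------------------------------------------------------

def test_chain_hollow_square_visits_all_boundary_pixels():
    mask = np.zeros((5, 5), bool)
    mask[1:4, 1:4] = True
    mask[2, 2] = False
    poly = sa.chain_contour_pixels(mask)
    assert poly.n_vertices == 8
    # every boundary pixel appears exactly once
    pix = {(x, y) for x, y in poly.xy}
    assert len(pix) == 8


def test_chain_circle_matches_boundary_pixel_count():
    rr, cc = np.mgrid[0:121, 0:121]
    disk = (rr - 60) ** 2 + (cc - 60) ** 2 <= 50 ** 2
    from scipy import ndimage as ndi
    inner = ndi.binary_erosion(disk)
    boundary = disk & ~inner
    n_boundary = int(boundary.sum())  # independent boundary-pixel scan
    poly = sa.chain_contour_pixels(boundary)
    assert abs(poly.n_vertices - n_boundary) <= 0.05 * n_boundary


def test_chain_two_loops_reports_component_count():
    mask = np.zeros((9, 9), bool)
    mask[1:4, 1:4] = True
    mask[1:4, 5:8] = True
    mask[2, 2] = mask[2, 6] = False
    with pytest.raises(ChainError, match="2"):
        sa.chain_contour_pixels(mask)


# --------------------------------------------------------------------------
# orientation and centring
# --------------------------------------------------------------------------

def test_orient_ccw_identity_flip_and_idempotence():
    ccw = Polygon([[0, 0], [1, 0], [1, 1], [0, 1]])
    assert np.array_equal(sa.orient_ccw(ccw).xy, ccw.xy)
    cw = Polygon([[0, 0], [0, 1], [1, 1], [1, 0]])
    fixed = sa.orient_ccw(cw)
    assert fixed.signed_area == pytest.approx(1.0)
    assert np.array_equal(sa.orient_ccw(fixed).xy, fixed.xy)
    assert set(map(tuple, fixed.xy)) == set(map(tuple, cw.xy))


def test_orient_ccw_degenerate_raises():
    with pytest.raises(DegeneratePolygonError):
        sa.orient_ccw(Polygon([[0, 0], [1, 1], [2, 2]]))


def test_centre_polygon_square_idempotent_and_lshape_oracle():
    sq = Polygon([[1, 1], [3, 1], [3, 3], [1, 3]])
    centred, c = sa.centre_polygon(sq)
    assert c == pytest.approx((2.0, 2.0))
    again, c2 = sa.centre_polygon(centred)
    assert c2 == pytest.approx((0.0, 0.0), abs=1e-12)

    # L-shape centroid against an independent decomposition into rectangles:
    # [0,2]x[0,1] (area 2, centre (1,.5)) + [0,1]x[1,2] (area 1, centre (.5,1.5))
    ell = Polygon([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]])
    expected = (np.array([1.0, 0.5]) * 2 + np.array([0.5, 1.5]) * 1) / 3
    _, got = sa.centre_polygon(ell)
    assert got == pytest.approx(tuple(expected), abs=1e-12)


# --------------------------------------------------------------------------
# asymmetry
# --------------------------------------------------------------------------

def test_asymmetry_zero_on_self_and_brute_force_oracle(rng):
    sq = Polygon([[0, 0], [1, 0], [1, 1], [0, 1]])
    assert sa.polygon_asymmetry(sq, sq) == 0.0
    moved = sa.translate_polygon(sq, 0.0, 0.1)
    expected = sum(brute_min_dist(v, sq) for v in moved.xy)
    assert sa.polygon_asymmetry(moved, sq) == pytest.approx(expected, rel=1e-12)

    # random polygon pair against brute force
    a = sa.synth_contour(2.0, 1.2, 0.1, 0.05, seed=rng, n_v=40)
    b = sa.synth_contour(1.8, 1.1, 0.05, 0.05, seed=rng, n_v=35)
    expected = sum(brute_min_dist(v, b) for v in a.xy)
    assert sa.polygon_asymmetry(a, b) == pytest.approx(expected, rel=1e-10)


def test_asymmetry_outside_vertex_distance_to_circle():
    circ = circle_polygon(1.0)
    tri = Polygon([[2, 0], [2.001, 0.001], [2.001, -0.001]])
    d = _min_dist_to_edges(np.array([[2.0, 0.0]]), circ)[0]
    assert d == pytest.approx(1.0, abs=1e-3)
    assert sa.polygon_asymmetry(tri, circ) == pytest.approx(3.0, abs=0.01)


# --------------------------------------------------------------------------
# symmetry axis and alignment
# --------------------------------------------------------------------------

def test_symmetry_axis_vertical_ellipse_is_fixed_point():
    ell = sa.synth_contour(2.0, elongation=1.5, n_v=360)
    ang = sa.find_symmetry_axis(ell)
    assert min(abs(ang) % np.pi, np.pi - abs(ang) % np.pi) < 0.01


def test_symmetry_axis_restores_rotated_ellipse():
    ell = sa.synth_contour(2.0, elongation=1.5, n_v=360)
    rot = sa.rotate_polygon(ell, np.deg2rad(30))
    ang = sa.find_symmetry_axis(rot)
    # total orientation error of the restored axis, mod pi
    err = (np.deg2rad(30) + ang) % np.pi
    err = min(err, np.pi - err)
    assert np.degrees(err) < 0.5


def test_symmetry_axis_circle_any_angle_accepted():
    circ = circle_polygon(1.0, 360)
    ang = sa.find_symmetry_axis(circ)
    aligned = sa.rotate_polygon(circ, ang)
    assert sa.polygon_asymmetry(sa.flip_x(aligned), aligned) < 1e-6 * circ.perimeter


def test_align_upwards_egg_invariant_and_recovery():
    egg = sa.synth_contour(2.0, elongation=1.3, asym=0.2, n_v=360)
    up = sa.align_upwards(egg)
    # already symmetric and pointing up: aligned copy equals a vertex roll
    assert sa.polygon_asymmetry(up, egg) < 1e-6 * egg.perimeter
    # rotated by 90 degrees: restored
    rot = sa.rotate_polygon(egg, np.deg2rad(90))
    restored = sa.align_upwards(rot)
    assert sa.polygon_asymmetry(restored, egg) < 1e-3 * egg.perimeter
    # vertex 1 is the top vertex
    assert restored.xy[0, 1] == pytest.approx(restored.xy[:, 1].max())


def test_align_upwards_square_beats_grid_alternatives():
    sq = sa.rotate_polygon(Polygon([[-1, -1], [1, -1], [1, 1], [-1, 1]]),
                           np.deg2rad(17))
    aligned = sa.align_upwards(sq)
    best = sa.polygon_asymmetry(sa.flip_x(aligned), aligned)
    grid = np.deg2rad(np.arange(0, 180, 0.1))
    alts = [sa.polygon_asymmetry(sa.flip_x(sa.rotate_polygon(sq, g)),
                                 sa.rotate_polygon(sq, g)) for g in grid[::10]]
    assert best <= min(alts) + 1e-9


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def test_resample_circle_uniform_spacing():
    poly = circle_polygon(1.0, 1000)
    res = sa.resample_polygon(poly, 200)
    r = np.hypot(*res.xy.T)
    assert np.abs(r - 1).max() < 1e-4
    seg = np.hypot(*np.diff(np.vstack([res.xy, res.xy[:1]]), axis=0).T)
    assert seg.max() / seg.min() < 1.01
    assert res.n_vertices == 200


def test_resample_identity_on_equilateral_loop():
    sq = Polygon([[0, 0], [1, 0], [1, 1], [0, 1]])
    res = sa.resample_polygon(sq, 4)
    assert np.abs(res.xy - sq.xy).max() < 1e-9


def test_resample_square_to_eight_hits_corners_and_midpoints():
    sq = Polygon([[0, 0], [1, 0], [1, 1], [0, 1]])
    res = sa.resample_polygon(sq, 8)
    expected = np.array([[0, 0], [0.5, 0], [1, 0], [1, 0.5],
                         [1, 1], [0.5, 1], [0, 1], [0, 0.5]], float)
    assert np.abs(res.xy - expected).max() < 1e-12


def test_resample_too_few_vertices_raises():
    with pytest.raises(GeometryError):
        sa.resample_polygon(circle_polygon(1.0), 2)


def test_resample_hausdorff_bounded_by_longest_edge(rng):
    poly = sa.synth_contour(2.0, 1.2, 0.1, 0.1, seed=rng, n_v=100)
    res = sa.resample_polygon(poly, 37)
    import shapely
    h = shapely.hausdorff_distance(poly.to_shapely().exterior,
                                   res.to_shapely().exterior, densify=0.05)
    longest = np.hypot(*np.diff(np.vstack([poly.xy, poly.xy[:1]]), axis=0).T).max()
    # resampled vertices lie on the loop; deviation is at most one edge length
    assert h <= longest + 1e-9


# --------------------------------------------------------------------------
# Douglas-Peucker
# --------------------------------------------------------------------------

def test_dp_collinear_side_collapses():
    side = np.column_stack([np.linspace(0, 1, 100), np.zeros(100)])
    poly = Polygon(np.vstack([side, [[1, 1], [0, 1]]]))
    simp = sa.simplify_dp(poly, 0.01)
    assert simp.n_vertices == 4


def test_dp_square_with_edge_points_keeps_corners():
    corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    pts = []
    for i in range(4):
        a, b = corners[i], corners[(i + 1) % 4]
        for t in np.linspace(0, 1, 11)[:-1]:
            pts.append(a + (b - a) * t)
    simp = sa.simplify_dp(Polygon(pts), 0.01)
    assert simp.n_vertices == 4
    assert set(map(tuple, simp.xy)) == set(map(tuple, corners))


@pytest.mark.parametrize("seed", range(6))
def test_dp_deviation_bound_and_subset_property(seed):
    rng = np.random.default_rng(SUITE_SEED + seed)
    poly = sa.synth_contour(rng.uniform(1, 4), rng.uniform(1, 1.5),
                            rng.uniform(0, 0.2), rng.uniform(0, 0.3),
                            seed=rng, n_v=150)
    tol = rng.uniform(0.02, 0.3)
    simp = sa.simplify_dp(poly, tol)
    assert simp.n_vertices <= poly.n_vertices
    in_set = {tuple(v) for v in poly.xy}
    assert all(tuple(v) in in_set for v in simp.xy)
    worst = max(brute_min_dist(v, simp) for v in poly.xy)
    assert worst <= tol + 1e-12


# --------------------------------------------------------------------------
# rays
# --------------------------------------------------------------------------

def test_ray_distance_circle_and_rectangle():
    circ = circle_polygon(2.0, 2000)
    for th in np.linspace(0, 2 * np.pi, 17):
        assert sa.ray_intersection_distance(circ, th) == pytest.approx(2.0, abs=1e-3)
    rect = Polygon([[-1, -2], [1, -2], [1, 2], [-1, 2]])
    assert sa.ray_intersection_distance(rect, 0.0) == pytest.approx(1.0)
    assert sa.ray_intersection_distance(rect, np.pi / 2) == pytest.approx(2.0)


def test_ray_distance_star_polygon_matches_bruteforce(rng):
    t = np.linspace(0, 2 * np.pi, 10, endpoint=False)
    r = np.where(np.arange(10) % 2 == 0, 2.0, 0.8)
    star = Polygon(np.column_stack([r * np.cos(t), r * np.sin(t)]))
    thetas = rng.uniform(0, 2 * np.pi, 50)

    def brute(theta):
        u = np.array([np.cos(theta), np.sin(theta)])
        best = np.inf
        for i in range(star.n_vertices):
            a = star.xy[i]
            b = star.xy[(i + 1) % star.n_vertices]
            d = b - a
            den = u[0] * d[1] - u[1] * d[0]
            if abs(den) < 1e-14:
                continue
            s = (a[0] * d[1] - a[1] * d[0]) / den
            tt = (a[0] * u[1] - a[1] * u[0]) / den
            if s > 1e-9 and -1e-9 <= tt <= 1 + 1e-9:
                best = min(best, s)
        return best

    got = sa.ray_distances(star, thetas)
    expected = np.array([brute(th) for th in thetas])
    assert np.abs(got - expected).max() < 1e-9


def test_ray_origin_outside_raises():
    sq = Polygon([[1, 1], [2, 1], [2, 2], [1, 2]])
    with pytest.raises(GeometryError):
        sa.ray_intersection_distance(sq, 0.3)


# --------------------------------------------------------------------------
# point pattern container
# --------------------------------------------------------------------------

def test_point_pattern_rejects_far_outside_points():
    win = Polygon([[0, 0], [1, 0], [1, 1], [0, 1]])
    PointPattern(np.array([[0.5, 0.5], [1.0, 1.0]]), win)  # boundary ok
    with pytest.raises(GeometryError):
        PointPattern(np.array([[2.0, 2.0]]), win)
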