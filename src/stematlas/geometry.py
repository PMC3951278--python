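"""Polygon primitives for stem-contour analysis.

Contours of stem cross-sections are handled as closed polygons in a
mathematical frame: x to the right, y up, units of millimetres, vertices
ordered counter-clockwise and (after centring) referenced to the area
centroid.  Angles are radians, counter-clockwise from the +x axis.

The operations here — pixel chaining, orientation, centring, bilateral
symmetry-axis alignment, arc-length resampling, Douglas-Peucker
simplification and ray/boundary intersection — are the geometric substrate
shared by contour extraction, shape modelling and spatial normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.morphology import thin as _homotopic_thin
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar


class GeometryError(ValueError):
    """Invalid geometric input."""


class DegeneratePolygonError(GeometryError):
    """Polygon with (near-)zero area or too few vertices."""


class ChainError(GeometryError):
    """Pixel curve cannot be chained into a single closed loop."""


# --------------------------------------------------------------------------
# Core containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Polygon:
    """Closed polygon: ordered vertex loop, last vertex connects to first.

    ``xy`` is an (n, 2) float array in mm.  The loop is stored open (the
    first vertex is not repeated at the end).
    """

    xy: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        arr = np.asarray(self.xy, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise GeometryError(f"polygon vertices must be (n, 2), got {arr.shape}")
        # drop exactly repeated consecutive vertices (incl. closing repeat)
        keep = np.any(arr != np.roll(arr, 1, axis=0), axis=1)
        if keep.any():
            arr = arr[keep]
        if len(arr) < 3:
            raise DegeneratePolygonError(f"polygon needs >=3 distinct vertices, got {len(arr)}")
        object.__setattr__(self, "xy", arr)

    @property
    def n_vertices(self) -> int:
        return len(self.xy)

    @property
    def signed_area(self) -> float:
        x, y = self.xy[:, 0], self.xy[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def is_ccw(self) -> bool:
        return self.signed_area > 0

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid (centre of gravity of the enclosed region)."""
        x, y = self.xy[:, 0], self.xy[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = 0.5 * np.sum(cross)
        if abs(a) < 1e-300:
            raise DegeneratePolygonError("zero-area polygon has no area centroid")
        cx = np.sum((x + xn) * cross) / (6.0 * a)
        cy = np.sum((y + yn) * cross) / (6.0 * a)
        return np.array([cx, cy])

    @property
    def perimeter(self) -> float:
        return float(np.sum(np.hypot(*(np.roll(self.xy, -1, axis=0) - self.xy).T)))

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) vertex arrays of the n closing edges."""
        return self.xy, np.roll(self.xy, -1, axis=0)

    def to_shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.xy)

    def contains_point(self, x: float, y: float) -> bool:
        return bool(shapely.contains_xy(self.to_shapely(), x, y))


@dataclass(frozen=True)
class PointPattern:
    """Planar point pattern with its observation window polygon."""

    points: np.ndarray
    window: Polygon
    tolerance: float = 1e-6

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if len(pts):
            poly = self.window.to_shapely()
            inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
            if not inside.all():
                bad = pts[~inside]
                d = shapely.distance(poly.exterior,
                                     shapely.points(bad[:, 0], bad[:, 1]))
                onb = shapely.contains_xy(poly.buffer(self.tolerance),
                                          bad[:, 0], bad[:, 1])
                if not (onb | (d <= self.tolerance)).all():
                    worst = float(np.max(d))
                    raise GeometryError(
                        f"{int(np.sum(~inside))} point(s) outside window "
                        f"(max distance {worst:.3g} mm)")

    @property
    def n(self) -> int:
        return len(self.points)


# --------------------------------------------------------------------------
# Rigid transforms
# --------------------------------------------------------------------------

def rotate_points(xy: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return np.asarray(xy, float) @ rot.T


def rotate_polygon(p: Polygon, angle: float) -> Polygon:
    return Polygon(rotate_points(p.xy, angle), meta=dict(p.meta))


def translate_polygon(p: Polygon, dx: float, dy: float) -> Polygon:
    return Polygon(p.xy + np.array([dx, dy]), meta=dict(p.meta))


def flip_x(p: Polygon) -> Polygon:
    """Mirror about the y-axis (x -> -x)."""
    out = p.xy.copy()
    out[:, 0] = -out[:, 0]
    return Polygon(out, meta=dict(p.meta))


# --------------------------------------------------------------------------
# Pixel chaining
# --------------------------------------------------------------------------

# neighbour scan order: 4-connected first (E, N, W, S), then diagonals —
# otherwise a diagonal shortcut at a corner can strand part of the loop
_NEIGHBOURS = [(0, 1), (-1, 0), (0, -1), (1, 0),
               (-1, 1), (-1, -1), (1, -1), (1, 1)]


def chain_contour_pixels(mask: np.ndarray) -> Polygon:
    """Chain the pixels of a closed 1-px-wide curve into an ordered polygon.

    The mask is first reduced to unit width by homotopic thinning, then
    traversed pixel by pixel: starting from an initial pixel, the first
    unprocessed 8-neighbour is repeatedly taken until the loop closes.
    Coordinates are returned in pixel units with ``x = col`` and
    ``y = n_rows - 1 - row`` (image scan order converted to y-up).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ChainError("empty mask: 0 components")
    # a unit-width curve contains no solid 2x2 block; thinning an already
    # thin ring could erode its corner pixels, so thin only when needed
    solid2x2 = ndi.minimum_filter(mask, size=2, mode="constant").any()
    curve = _homotopic_thin(mask) if solid2x2 else mask
    # prune stray spur pixels (single-neighbour ends left by rasterisation)
    for _ in range(8):
        nb = ndi.convolve(curve.astype(np.uint8), np.ones((3, 3), np.uint8),
                          mode="constant") - curve
        spurs = curve & (nb <= 1)
        if not spurs.any():
            break
        curve = curve & ~spurs
    n_comp = ndi.label(curve, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise ChainError(f"expected a single closed curve, found {n_comp} components")

    rows, cols = np.nonzero(curve)
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))

    visited = np.zeros_like(curve, dtype=bool)
    path = [start]
    visited[start] = True
    cur = start
    h, w = curve.shape
    while True:
        nxt = None
        for dr, dc in _NEIGHBOURS:
            r, c = cur[0] + dr, cur[1] + dc
            if 0 <= r < h and 0 <= c < w and curve[r, c] and not visited[r, c]:
                nxt = (r, c)
                break
        if nxt is None:
            break
        path.append(nxt)
        visited[nxt] = True
        cur = nxt

    n_pix = int(curve.sum())
    if len(path) != n_pix:
        raise ChainError(
            f"open or branching curve: chained {len(path)} of {n_pix} pixels")
    if max(abs(path[-1][0] - start[0]), abs(path[-1][1] - start[1])) > 1:
        raise ChainError("curve does not close: last pixel not adjacent to first")

    arr = np.array(path, dtype=float)
    xy = np.column_stack([arr[:, 1], (h - 1) - arr[:, 0]])
    return Polygon(xy)


# --------------------------------------------------------------------------
# Orientation / centring
# --------------------------------------------------------------------------

def orient_ccw(p: Polygon) -> Polygon:
    """Return the polygon in counter-clockwise order (signed area > 0)."""
    a = p.signed_area
    scale = max(p.perimeter, 1.0)
    if abs(a) < 1e-12 * scale**2:
        raise DegeneratePolygonError("degenerate polygon: zero signed area")
    if a > 0:
        return p
    # reverse traversal, keeping the first vertex first
    return Polygon(np.vstack([p.xy[:1], p.xy[:0:-1]]), meta=dict(p.meta))


def centre_polygon(p: Polygon) -> tuple[Polygon, tuple[float, float]]:
    """Translate the area centroid to the origin; return (polygon, centroid)."""
    c = p.centroid
    return Polygon(p.xy - c, meta=dict(p.meta)), (float(c[0]), float(c[1]))


# --------------------------------------------------------------------------
# Asymmetry objective and symmetry-axis search
# --------------------------------------------------------------------------

def _min_dist_to_edges(points: np.ndarray, fixed: Polygon) -> np.ndarray:
    """Min Euclidean distance from each point to the boundary of `fixed`.

    Vectorised point-to-segment distance over all vertex/edge pairs;
    ``points`` may be (..., V, 2).
    """
    a, b = fixed.edges                       # (E, 2)
    d = b - a                                # (E, 2)
    dd = np.einsum("ej,ej->e", d, d)
    dd = np.where(dd == 0, 1.0, dd)
    pa = points[..., None, :] - a            # (..., V, E, 2)
    t = np.clip(np.einsum("...ej,ej->...e", pa, d) / dd, 0.0, 1.0)
    proj = pa - t[..., None] * d
    dist2 = np.einsum("...ej,...ej->...e", proj, proj)
    return np.sqrt(dist2.min(axis=-1))


def polygon_asymmetry(moving: Polygon | np.ndarray, fixed: Polygon) -> float:
    """Sum over vertices of `moving` of the minimal distance to `fixed`'s boundary."""
    pts = moving.xy if isinstance(moving, Polygon) else np.asarray(moving, float)
    return float(_min_dist_to_edges(pts, fixed).sum())


def _asymmetry_profile(vertices: np.ndarray, angles: np.ndarray,
                       fixed: Polygon, chunk: int = 24) -> np.ndarray:
    """Asymmetry objective for many candidate rotations of one vertex set."""
    c, s = np.cos(angles), np.sin(angles)
    rots = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], -2)  # (A,2,2)
    rots = rots.astype(np.float32)
    verts = np.asarray(vertices, np.float32)
    a, b = fixed.edges
    a32 = a.astype(np.float32)
    d32 = (b - a).astype(np.float32)
    dd = np.einsum("ej,ej->e", d32, d32)
    dd = np.where(dd == 0, np.float32(1), dd)
    out = np.empty(len(angles))
    for i in range(0, len(angles), chunk):
        sl = slice(i, i + chunk)
        rotated = np.einsum("aij,vj->avi", rots[sl], verts)       # (A,V,2)
        pa = rotated[:, :, None, :] - a32                          # (A,V,E,2)
        t = np.clip(np.einsum("avej,ej->ave", pa, d32) / dd, 0.0, 1.0)
        proj = pa - t[..., None] * d32
        dist2 = np.einsum("avej,avej->ave", proj, proj)
        out[sl] = np.sqrt(dist2.min(axis=-1)).sum(axis=-1)
    return out


def _subsample_loop(xy: np.ndarray, max_pts: int) -> np.ndarray:
    if len(xy) <= max_pts:
        return xy
    idx = np.linspace(0, len(xy), max_pts, endpoint=False).astype(int)
    return xy[idx]


def _scan_and_refine(vertices: np.ndarray, fixed: Polygon,
                     coarse_step_deg: float = 1.0,
                     scan_max_pts: int = 128) -> float:
    """Coarse angular scan then golden-section refinement of the asymmetry.

    The coarse scan runs on subsampled loops (the objective is smooth at the
    contour scale); the bracketed refinement uses the exact objective.
    """
    step = np.deg2rad(coarse_step_deg)
    grid = np.arange(0.0, 2 * np.pi, step)
    fixed_scan = (fixed if fixed.n_vertices <= scan_max_pts
                  else Polygon(_subsample_loop(fixed.xy, scan_max_pts)))
    prof = _asymmetry_profile(_subsample_loop(vertices, scan_max_pts),
                              grid, fixed_scan)
    best = grid[int(np.argmin(prof))]
    res = minimize_scalar(
        lambda a: polygon_asymmetry(rotate_points(vertices, a), fixed),
        bounds=(best - 2 * step, best + 2 * step), method="bounded",
        options={"xatol": 1e-6})
    return float(res.x)


def find_symmetry_axis(p: Polygon) -> float:
    """Rotation (radians) that brings the bilateral symmetry axis vertical.

    The polygon is mirrored about the y-axis; the rotation phi* of the
    mirrored copy that best matches the original (minimal vertex-to-boundary
    asymmetry, coarse 1-degree scan then bounded golden-section/parabolic
    refinement) identifies the symmetry axis: the composite map is the
    reflection about the line at angle pi/2 + phi*/2, so the axis sits at
    that angle and rotating p by -phi*/2 brings it vertical.
    """
    flipped = flip_x(p)
    phi = _scan_and_refine(flipped.xy, p)
    return -phi / 2.0


def _roll_to_top(p: Polygon) -> Polygon:
    """Roll vertex order so vertex 1 is the top vertex (max y, then min x)."""
    i = np.lexsort((p.xy[:, 0], -p.xy[:, 1]))[0]
    return Polygon(np.roll(p.xy, -i, axis=0), meta=dict(p.meta))


def align_upwards(p: Polygon) -> Polygon:
    """Rotate a centred polygon so its symmetry axis is vertical, pointing up.

    The up/down ambiguity of the half-angle is resolved by requiring the
    vertex farthest from the centroid to have positive y; the vertex list is
    then rolled so the top vertex comes first.
    """
    ang = find_symmetry_axis(p)
    q = rotate_polygon(p, ang)
    far = q.xy[np.argmax(np.einsum("ij,ij->i", q.xy, q.xy))]
    if far[1] < 0:
        q = rotate_polygon(q, np.pi)
    return _roll_to_top(q)


# --------------------------------------------------------------------------
# Resampling and simplification
# --------------------------------------------------------------------------

def resample_polygon(p: Polygon, n_v: int) -> Polygon:
    """Resample the closed loop to exactly `n_v` vertices.

    Vertices are placed at equal arc-length spacing along the loop, starting
    from (and preserving) the current first vertex; orientation is kept.
    """
    if n_v < 3:
        raise GeometryError(f"cannot resample to {n_v} < 3 vertices")
    closed = np.vstack([p.xy, p.xy[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise DegeneratePolygonError("zero-perimeter polygon")
    target = np.arange(n_v) * (total / n_v)
    x = np.interp(target, cum, closed[:, 0])
    y = np.interp(target, cum, closed[:, 1])
    return Polygon(np.column_stack([x, y]), meta=dict(p.meta))


def _dp_chain(xy: np.ndarray, i: int, j: int, tol: float, keep: np.ndarray) -> None:
    """Mark Douglas-Peucker survivors on the open chain xy[i..j] (anchors kept)."""
    if j <= i + 1:
        return
    a, b = xy[i], xy[j]
    d = b - a
    nn = np.hypot(*d)
    pts = xy[i + 1:j]
    if nn == 0:
        dist = np.hypot(*(pts - a).T)
    else:
        u = d / nn
        dist = np.abs(u[0] * (pts[:, 1] - a[1]) - u[1] * (pts[:, 0] - a[0]))
    k = int(np.argmax(dist))
    if dist[k] > tol:
        keep[i + 1 + k] = True
        _dp_chain(xy, i, i + 1 + k, tol, keep)
        _dp_chain(xy, i + 1 + k, j, tol, keep)


def simplify_dp(p: Polygon, tol: float) -> Polygon:
    """Douglas-Peucker simplification of the closed loop at tolerance `tol` (mm).

    The loop is split at the first vertex and at the vertex farthest from it;
    each half-chain is simplified recursively (recursive subdivision at the
    farthest vertex until every original vertex lies within `tol` of the
    simplified curve).  Output vertices are a subset of the input vertices.
    """
    if tol <= 0:
        raise GeometryError("tolerance must be > 0")
    xy = p.xy
    n = len(xy)
    far = int(np.argmax(np.hypot(*(xy - xy[0]).T)))
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[far] = True
    # two open chains: 0..far and far..0 (wrapping)
    _dp_chain(xy, 0, far, tol, keep)
    wrapped = np.vstack([xy[far:], xy[:1]])
    keep_w = np.zeros(len(wrapped), dtype=bool)
    keep_w[0] = keep_w[-1] = True
    _dp_chain(wrapped, 0, len(wrapped) - 1, tol, keep_w)
    keep[far:] |= keep_w[:-1]
    idx = np.nonzero(keep)[0]
    while len(idx) < 3:  # flat loop: retain the vertex farthest off the anchor line
        rest = np.setdiff1d(np.arange(n), idx)
        a, b = xy[idx[0]], xy[idx[-1]]
        d = b - a
        nn = np.hypot(*d)
        dist = (np.abs(np.cross(d / nn, xy[rest] - a)) if nn > 0
                else np.hypot(*(xy[rest] - a).T))
        idx = np.sort(np.append(idx, rest[int(np.argmax(dist))]))
    return Polygon(xy[idx], meta=dict(p.meta))


# --------------------------------------------------------------------------
# Ray / boundary intersection
# --------------------------------------------------------------------------

def ray_distances(p: Polygon, thetas: np.ndarray,
                  warn_multiple: bool = True) -> np.ndarray:
    """Distance from the origin to p's boundary along rays at angles `thetas`.

    The origin must lie strictly inside the polygon.  Contours are assumed
    star-shaped with respect to the origin; should a ray cross the boundary
    more than once the nearest intersection is returned (with a warning).
    """
    if not p.contains_point(0.0, 0.0):
        raise GeometryError("origin is not strictly inside the polygon")
    thetas = np.atleast_1d(np.asarray(thetas, float))
    u = np.column_stack([np.cos(thetas), np.sin(thetas)])      # (T, 2)
    a, b = p.edges                                             # (E, 2)
    d = b - a
    denom = u[:, None, 0] * d[None, :, 1] - u[:, None, 1] * d[None, :, 0]  # (T, E)
    cross_ad = a[:, 0] * d[:, 1] - a[:, 1] * d[:, 0]           # (E,)
    cross_au = a[None, :, 0] * u[:, None, 1] - a[None, :, 1] * u[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = cross_ad[None, :] / denom
        t = cross_au / denom
    eps = 1e-9
    valid = (np.abs(denom) > 1e-300) & (s > eps) & (t >= -eps) & (t < 1 - eps)
    s_val = np.where(valid, s, np.inf)
    rho = s_val.min(axis=1)
    if not np.isfinite(rho).all():
        # fall back to an inclusive parameter range for rays through vertices
        valid2 = (np.abs(denom) > 1e-300) & (s > eps) & (t >= -1e-6) & (t <= 1 + 1e-6)
        s_val = np.where(valid2, s, np.inf)
        rho = s_val.min(axis=1)
        if not np.isfinite(rho).all():
            raise GeometryError("ray found no boundary intersection")
    if warn_multiple:
        n_hits = np.sum(s_val < np.inf, axis=1)
        # collapse duplicate hits at shared vertices before counting
        if np.any(n_hits > 1):
            many = 0
            for row in s_val[n_hits > 1]:
                hits = np.sort(row[np.isfinite(row)])
                if np.any(np.diff(hits) > 1e-6 * max(hits[0], 1e-12)):
                    many += 1
            if many:
                warnings.warn(
                    f"{many} ray(s) crossed the boundary more than once; "
                    "nearest intersection used (contour not star-shaped?)",
                    stacklevel=2)
    return rho


def ray_intersection_distance(p: Polygon, theta: float) -> float:
    """Distance from the origin to the boundary along the ray at angle theta."""
    return float(ray_distances(p, np.array([theta]))[0])
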