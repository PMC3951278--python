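"""Spatial normalisation of bundle patterns and kernel intensity mapping.

Each slice's point pattern is projected into the reference-contour space in
two steps: a rigid rotation matching the observed slice contour to the
model contour of that slice (genotype + slab + stem prediction), and a
polar transform that keeps the angular position of every point while
rescaling its radius by the ratio of the reference-contour to the
slice-model-contour boundary distances along the point's ray:

    theta'(x) = theta(x),    rho'(x) = rho(x) * rho_ref(theta) / rho_slice(theta)

Normalised patterns live in a common raster grid over the reference
contour, where per-slice kernel intensity maps (isotropic Gaussian kernel
with edge correction) can be averaged point-wise, globally or per level of
an experimental factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter

from .geometry import (GeometryError, PointPattern, Polygon,
                       _scan_and_refine, ray_distances, rotate_points,
                       rotate_polygon)


# --------------------------------------------------------------------------
# Rigid + polar normalisation
# --------------------------------------------------------------------------

def rigid_align(slice_contour: Polygon, pattern: PointPattern,
                model_contour: Polygon) -> tuple[PointPattern, float]:
    """Rotation minimising the slice-contour / model-contour difference.

    Both contours must be centred.  The optimal angle (coarse 1-degree scan
    of the vertex-to-boundary asymmetry plus golden-section refinement) is
    applied to the slice contour and to the points.
    """
    angle = _scan_and_refine(slice_contour.xy, model_contour)
    angle = float((angle + np.pi) % (2 * np.pi) - np.pi)  # wrap to (-pi, pi]
    new_window = rotate_polygon(slice_contour, angle)
    new_points = rotate_points(pattern.points, angle)
    return PointPattern(new_points, new_window), float(angle)


def polar_normalise(pattern: PointPattern, slice_model: Polygon,
                    reference: Polygon,
                    outside_tolerance: float = 0.01) -> PointPattern:
    """Project a pattern from the slice-model contour onto the reference.

    Angles are preserved; radii are scaled by rho_ref(theta)/rho_slice(theta)
    evaluated by exact ray-boundary intersection.  The same map is applied
    to the pattern's own window polygon.  Points marginally outside the
    slice model (observed-contour vs model mismatch) are tolerated up to
    ``outside_tolerance`` of the pattern and clamped to the boundary.
    """
    pts = pattern.points

    def mapped(xy: np.ndarray, clamp: bool) -> np.ndarray:
        if len(xy) == 0:
            return xy.copy()
        theta = np.arctan2(xy[:, 1], xy[:, 0])
        rho = np.hypot(xy[:, 0], xy[:, 1])
        rho_slice = ray_distances(slice_model, theta)
        rho_ref = ray_distances(reference, theta)
        if clamp:
            out = rho > rho_slice * (1 + 1e-9)
            if np.mean(out) > outside_tolerance:
                raise GeometryError(
                    f"{np.sum(out)} of {len(xy)} points fall outside the "
                    "slice model contour (> tolerated fraction)")
            if out.any():
                warnings.warn(f"{int(np.sum(out))} point(s) outside the slice "
                              "model clamped to its boundary", stacklevel=3)
                rho = np.minimum(rho, rho_slice)
        new_rho = np.where(rho > 0, rho * rho_ref / rho_slice, 0.0)
        return np.column_stack([new_rho * np.cos(theta), new_rho * np.sin(theta)])

    new_pts = mapped(pts, clamp=True)
    new_window = Polygon(mapped(pattern.window.xy, clamp=False),
                         meta=dict(pattern.window.meta))
    # the radial map preserves containment ray-wise; between the vertices of a
    # sparse window the mapped chords can cut slightly inside, so the window
    # tolerance is loosened to the chord-sag scale
    return PointPattern(new_pts, new_window, tolerance=1e-3)


# --------------------------------------------------------------------------
# Kernel intensity estimation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Raster over the reference space: pixel centres at origin + (i+1/2)*step."""

    x0: float
    y0: float
    dx: float
    dy: float
    nx: int
    ny: int

    @classmethod
    def from_polygon(cls, p: Polygon, n: int = 128, pad: float = 0.05) -> "GridSpec":
        xmin, ymin = p.xy.min(axis=0)
        xmax, ymax = p.xy.max(axis=0)
        w, h = xmax - xmin, ymax - ymin
        x0, y0 = xmin - pad * w, ymin - pad * h
        return cls(x0=float(x0), y0=float(y0),
                   dx=float(w * (1 + 2 * pad) / n), dy=float(h * (1 + 2 * pad) / n),
                   nx=n, ny=n)

    @property
    def x_centres(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centres(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.dy

    @property
    def pixel_area(self) -> float:
        return self.dx * self.dy


@dataclass(frozen=True)
class IntensityGrid:
    """Estimated intensity raster (points/mm^2) with a validity mask.

    Row index follows y (row 0 at the bottom of the frame).
    """

    values: np.ndarray
    mask: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        v = np.asarray(self.values, float)
        m = np.asarray(self.mask, bool)
        if v.shape != (self.grid.ny, self.grid.nx) or m.shape != v.shape:
            raise ValueError("values/mask shape does not match grid spec")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)

    def integral(self) -> float:
        """Integral of the intensity over the valid window (expected count)."""
        return float(self.values[self.mask].sum() * self.grid.pixel_area)


def default_bandwidth(window: Polygon) -> float:
    """Rule-of-thumb Gaussian sigma: min bounding-box side / 8 (mm)."""
    w, h = window.xy.max(axis=0) - window.xy.min(axis=0)
    return float(min(w, h)) / 8.0


def window_mask(window: Polygon, grid: GridSpec) -> np.ndarray:
    xs, ys = np.meshgrid(grid.x_centres, grid.y_centres)
    return shapely.contains_xy(window.to_shapely(), xs.ravel(), ys.ravel()) \
        .reshape(grid.ny, grid.nx)


def kde_intensity(pattern: PointPattern, grid: GridSpec, sigma: float | None = None,
                  correction: str = "uniform") -> IntensityGrid:
    """Gaussian kernel intensity estimate of a point pattern on a grid.

    lambda(u) = sum_i k_sigma(u - x_i) / e, with edge correction
    ``uniform``:  e(u)   = integral of k_sigma(u - .) over the window;
    ``per_point``: e(x_i) = same integral at the data point, which makes the
    estimate conserve mass exactly (integral over the window = n points).
    """
    if correction not in ("uniform", "per_point"):
        raise ValueError(f"unknown edge correction {correction!r}")
    if sigma is None:
        sigma = default_bandwidth(pattern.window)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    mask = window_mask(pattern.window, grid)
    if pattern.n == 0:
        return IntensityGrid(np.zeros((grid.ny, grid.nx)), mask, grid)

    xs, ys = grid.x_centres, grid.y_centres
    px, py = pattern.points[:, 0], pattern.points[:, 1]
    norm = 1.0 / (np.sqrt(2 * np.pi) * sigma)
    gx = norm * np.exp(-0.5 * ((xs[None, :] - px[:, None]) / sigma) ** 2)  # (n, nx)
    gy = norm * np.exp(-0.5 * ((ys[None, :] - py[:, None]) / sigma) ** 2)  # (n, ny)

    if correction == "per_point":
        mf = mask.astype(float)
        e_i = grid.pixel_area * np.einsum("iy,yx,ix->i", gy, mf, gx)
        e_i = np.maximum(e_i, 1e-12)
        raw = np.einsum("i,iy,ix->yx", 1.0 / e_i, gy, gx)
        values = np.where(mask, raw, 0.0)
    else:
        raw = np.einsum("iy,ix->yx", gy, gx)
        e_u = gaussian_filter(mask.astype(float), sigma=(sigma / grid.dy, sigma / grid.dx),
                              mode="constant", truncate=8.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(mask & (e_u > 1e-6), raw / np.maximum(e_u, 1e-12), 0.0)
    return IntensityGrid(values, mask, grid)


# --------------------------------------------------------------------------
# Group-wise averaging
# --------------------------------------------------------------------------

def average_maps(maps: list[IntensityGrid],
                 min_coverage: float = 0.5) -> IntensityGrid:
    """Point-wise mean of intensity maps sharing one grid spec.

    Each pixel averages the maps whose mask covers it; the output mask
    keeps pixels covered by at least ``min_coverage`` of the maps.
    """
    if not maps:
        raise ValueError("no maps to average")
    spec = maps[0].grid
    for m in maps[1:]:
        if m.grid != spec:
            raise ValueError("grid-spec mismatch between maps")
    vals = np.stack([m.values for m in maps])
    masks = np.stack([m.mask for m in maps])
    count = masks.sum(axis=0)
    total = np.where(masks, vals, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    out_mask = count >= min_coverage * len(maps)
    return IntensityGrid(np.where(out_mask, mean, 0.0), out_mask, spec)


def factor_average(maps: list[IntensityGrid], labels: list, level,
                   min_coverage: float = 0.5) -> IntensityGrid:
    """Average of the maps whose label equals ``level``."""
    if len(maps) != len(labels):
        raise ValueError("maps and labels differ in length")
    sel = [m for m, lab in zip(maps, labels) if lab == level]
    if not sel:
        raise KeyError(f"no map with label {level!r}")
    return average_maps(sel, min_coverage=min_coverage)
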