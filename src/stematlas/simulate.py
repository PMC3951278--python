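"""Synthetic study generator: contours, bundle patterns and rendered images.

No raw imagery of the original study is deposited, so every pipeline stage
is exercised on synthetic data with known ground truth.  The generator
emulates the study design: two genotypes (wild type and a larger mutant),
seven stems per genotype, an internode cut into slabs A..H giving seven
cutting positions ('ab'..'gh') observed on two slab faces each.

Contours are bilaterally symmetric egg-like curves (ellipse with a
y-dependent width modulation plus smooth symmetric radial noise) carrying
multiplicative genotype, cutting-position and per-stem size effects, and
are emitted at random rotations/translations so that the alignment stages
have real work to do.  Bundle patterns are inhomogeneous-Poisson or
hard-core (Matern II) point processes with a peripheral-enriched intensity
profile: bundles are more numerous towards the periphery of a section,
with a low-intensity collar at the very edge where the bark was removed.
Rendered section images combine Voronoi parenchyma cells (50-150 um),
bright cell walls on a dark field, and bundles drawn as ~300 um dark
clusters with thick bright rims.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from skimage.draw import polygon2mask
from scipy import ndimage as ndi

from .geometry import PointPattern, Polygon, rotate_points
from .shape_model import DEFAULT_CUTS


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------------------
# Parametric contours
# --------------------------------------------------------------------------

def synth_contour(size: float, elongation: float = 1.0, asym: float = 0.0,
                  noise_sd: float = 0.0, seed=None, n_v: int = 400) -> Polygon:
    """Bilaterally symmetric egg-like contour, centred, CCW, `n_v` vertices.

    ``size`` is the x half-width (mm); the y half-height is
    ``size * elongation``; ``asym`` narrows the top (egg shape) while
    preserving mirror symmetry about the y-axis; ``noise_sd`` adds smooth
    periodic radial noise (mm), generated symmetrically.  With
    ``asym = 0, elongation = 1, noise_sd = 0`` the result is a circle of
    radius ``size``.
    """
    if size <= 0:
        raise ValueError("size must be > 0")
    rng = _rng(seed)
    t = np.arange(n_v) * (2 * np.pi / n_v)
    x = size * np.cos(t)
    y = size * elongation * np.sin(t)
    if asym:
        x = x * (1.0 - asym * y / (size * elongation))
    if noise_sd > 0:
        ks = np.arange(1, 7)
        coefs = rng.standard_normal(len(ks)) * (noise_sd / size) / ks
        psi = np.arctan2(x, y)  # angle from the +y axis: mirror-even basis
        f = 1.0 + np.cos(np.outer(psi, ks)) @ coefs
        x, y = x * f, y * f
    poly = Polygon(np.column_stack([x, y]))
    c = poly.centroid
    return Polygon(poly.xy - c)


@dataclass(frozen=True)
class StemDesign:
    """Design of a synthetic contour study mirroring the original sampling."""

    genotypes: tuple = ("WT", "M")
    size_mult: tuple = (0.95, 1.05)      # mutant sections larger than wild type
    stems_per_genotype: int = 7
    cuts: tuple = DEFAULT_CUTS
    faces: tuple = (1, 2)
    base_size_mm: float = 8.0            # ~16 mm internode diameter
    cut_size: tuple | None = None        # per-cut size factor (default 0.97..1.03)
    cut_elongation: tuple | None = None  # per-cut elongation (default 1.25..1.10)
    asym: float = 0.1
    stem_sd: float = 0.03                # relative SD of the per-stem size effect
    noise_sd_mm: float = 0.05
    max_shift_mm: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.stem_sd < 0 or self.noise_sd_mm < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.stems_per_genotype < 1 or len(self.genotypes) < 1 or len(self.cuts) < 1:
            raise ValueError("counts must be >= 1")

    def resolved_cut_size(self) -> np.ndarray:
        if self.cut_size is not None:
            return np.asarray(self.cut_size, float)
        return np.linspace(0.97, 1.03, len(self.cuts))

    def resolved_cut_elongation(self) -> np.ndarray:
        if self.cut_elongation is not None:
            return np.asarray(self.cut_elongation, float)
        return np.linspace(1.25, 1.10, len(self.cuts))


def synth_contour_dataset(design: StemDesign) -> tuple[list, dict]:
    """Contours with factor labels for every genotype/stem/cut/face cell.

    Each contour is emitted at a random rotation and translation (alignment
    must undo them).  Returns ``(rows, truth)`` where ``rows`` is a list of
    ``(Polygon, factors-dict)`` and ``truth`` records every generating
    parameter (per-stem size effects, per-row rotations, sizes).
    """
    rng = _rng(design.seed)
    cut_size = design.resolved_cut_size()
    cut_elong = design.resolved_cut_elongation()
    stem_eff = {(g, f"S{s + 1}"): (rng.standard_normal() * design.stem_sd)
                for g in design.genotypes
                for s in range(design.stems_per_genotype)}
    rows, row_truth = [], []
    for gi, g in enumerate(design.genotypes):
        for s in range(design.stems_per_genotype):
            stem = f"S{s + 1}"
            for ci, cu in enumerate(design.cuts):
                for face in design.faces:
                    size = (design.base_size_mm * design.size_mult[gi]
                            * cut_size[ci] * (1.0 + stem_eff[(g, stem)]))
                    poly = synth_contour(size, float(cut_elong[ci]), design.asym,
                                         design.noise_sd_mm, seed=rng)
                    rot = float(rng.uniform(0, 2 * np.pi))
                    shift = rng.uniform(-design.max_shift_mm, design.max_shift_mm, 2)
                    placed = Polygon(rotate_points(poly.xy, rot) + shift)
                    fac = {"genotype": g, "stem": stem, "cut": cu, "face": face}
                    rows.append((placed, fac))
                    row_truth.append({**fac, "size": size, "rotation": rot,
                                      "shift": shift.tolist()})
    truth = {"stem_effects": {f"{k[0]}/{k[1]}": v for k, v in stem_eff.items()},
             "genotype_mult": dict(zip(design.genotypes, design.size_mult)),
             "cut_size": cut_size.tolist(),
             "cut_elongation": cut_elong.tolist(),
             "rows": row_truth}
    return rows, truth


def synth_effect_table(noise_sd: float = 0.0, seed=None, n_v: int = 200,
                       genotypes: tuple = ("WT", "M"),
                       stems_per_genotype: int = 7,
                       cuts: tuple = DEFAULT_CUTS, faces: tuple = (1, 2),
                       base_size_mm: float = 8.0,
                       genotype_scale: float = 0.05,
                       cut_scale: float = 0.03, elong_scale: float = 0.25,
                       stem_sd: float = 0.03):
    """Coordinate table generated additively from the per-coordinate model.

    Unlike :func:`synth_contour_dataset` (multiplicative shape effects plus
    random placement, for exercising the full alignment pipeline), this
    builds XY(i, j) = mu(j) + alpha_G(j) + beta_C(j) + s_S(G)(j) + noise
    exactly, with sum-to-zero effect vectors spanning a size mode and an
    elongation mode, so least-squares recovery can be checked to machine
    precision at zero noise.  Returns ``(ContourTable, effects)`` where
    ``effects`` maps 'mu', 'alpha', 'beta', 'stem' to the true vectors.
    """
    from .shape_model import ContourTable
    import pandas as pd

    rng = _rng(seed)
    mu_poly = synth_contour(base_size_mm, 1.15, 0.1, 0.0, n_v=n_v)
    mu = np.concatenate([mu_poly.xy[:, 0], mu_poly.xy[:, 1]])
    size_mode = mu.copy()                       # scaling the whole contour
    elong_poly = synth_contour(base_size_mm, 1.35, 0.1, 0.0, n_v=n_v)
    elong_mode = (np.concatenate([elong_poly.xy[:, 0], elong_poly.xy[:, 1]])
                  - mu)                          # pure elongation direction

    n_g, n_c = len(genotypes), len(cuts)
    g_coef = genotype_scale * (np.arange(n_g) - (n_g - 1) / 2) * 2 / max(n_g - 1, 1)
    alpha = {g: g_coef[i] * size_mode for i, g in enumerate(genotypes)}
    a_c = cut_scale * np.linspace(-1, 1, n_c)
    b_c = elong_scale * np.linspace(1, -1, n_c)
    beta = {cu: a_c[i] * size_mode + b_c[i] * elong_mode
            for i, cu in enumerate(cuts)}
    stem_eff = {}
    for g in genotypes:
        coefs = rng.standard_normal(stems_per_genotype) * stem_sd
        coefs -= coefs.mean()
        for sidx in range(stems_per_genotype):
            stem_eff[(g, f"S{sidx + 1}")] = coefs[sidx] * size_mode

    rows, facs = [], []
    for g in genotypes:
        for sidx in range(stems_per_genotype):
            stem = f"S{sidx + 1}"
            for cu in cuts:
                for face in faces:
                    vec = mu + alpha[g] + beta[cu] + stem_eff[(g, stem)]
                    if noise_sd > 0:
                        vec = vec + rng.standard_normal(2 * n_v) * noise_sd
                    rows.append(vec)
                    facs.append({"genotype": g, "stem": stem, "cut": cu,
                                 "face": face})
    table = ContourTable(np.stack(rows), pd.DataFrame(facs), n_v)
    effects = {"mu": mu, "alpha": alpha, "beta": beta, "stem": stem_eff}
    return table, effects


# --------------------------------------------------------------------------
# Point processes
# --------------------------------------------------------------------------

def _uniform_in_window(n: int, window: Polygon, rng: np.random.Generator) -> np.ndarray:
    """n iid uniform points in the window (rejection from the bounding box)."""
    poly = window.to_shapely()
    xmin, ymin = window.xy.min(axis=0)
    xmax, ymax = window.xy.max(axis=0)
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 16)
        cand = np.column_stack([rng.uniform(xmin, xmax, m),
                                rng.uniform(ymin, ymax, m)])
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def sample_inhom_poisson(lambda_fn, window: Polygon, seed=None,
                         lam_max: float | None = None) -> PointPattern:
    """Inhomogeneous Poisson pattern by thinning a homogeneous one.

    ``lambda_fn(x, y)`` must be vectorised and bounded on the window; the
    bound is estimated on a grid unless ``lam_max`` is given.  The total
    count is Poisson with mean the integral of lambda over the window.
    """
    rng = _rng(seed)
    poly = window.to_shapely()
    if lam_max is not None and lam_max <= 0:
        raise ValueError("lam_max must be > 0")
    if lam_max is None:
        xmin, ymin = window.xy.min(axis=0)
        xmax, ymax = window.xy.max(axis=0)
        gx, gy = np.meshgrid(np.linspace(xmin, xmax, 64), np.linspace(ymin, ymax, 64))
        vals = np.asarray(lambda_fn(gx.ravel(), gy.ravel()), float)
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
        vals = np.concatenate([vals[inside],
                               np.asarray(lambda_fn(window.xy[:, 0], window.xy[:, 1]),
                                          float)])
        if np.any(vals < 0):
            raise ValueError("lambda_fn takes negative values on the window")
        peak = float(vals.max(initial=0.0))
        if peak == 0:
            return PointPattern(np.empty((0, 2)), window)
        lam_max = 1.2 * peak
    n = rng.poisson(lam_max * poly.area)
    pts = _uniform_in_window(n, window, rng)
    lam = np.asarray(lambda_fn(pts[:, 0], pts[:, 1]), float)
    keep = rng.uniform(0, 1, n) < lam / lam_max
    return PointPattern(pts[keep], window)


def sample_hardcore(lam: float, r_min: float, window: Polygon,
                    seed=None) -> PointPattern:
    """Matern II hard-core pattern: dependent thinning of a Poisson(lam).

    Every proposal carries a uniform birth mark; a point is retained only
    if no other proposal within ``r_min`` has a smaller mark, so retained
    points are pairwise at least ``r_min`` apart.  With ``r_min = 0`` the
    pattern reduces to homogeneous Poisson.
    """
    if lam < 0 or r_min < 0:
        raise ValueError("lam and r_min must be >= 0")
    rng = _rng(seed)
    if r_min > 0 and lam * np.pi * r_min**2 > 2:
        warnings.warn("hard-core packing near-infeasible: "
                      "most proposals will be thinned", stacklevel=2)
    poly = window.to_shapely()
    n = rng.poisson(lam * poly.area)
    pts = _uniform_in_window(n, window, rng)
    if r_min == 0 or n < 2:
        return PointPattern(pts, window)
    marks = rng.uniform(0, 1, n)
    tree = cKDTree(pts)
    keep = np.ones(n, dtype=bool)
    for i, j in tree.query_pairs(r_min):
        if marks[i] < marks[j]:
            keep[j] = False
        else:
            keep[i] = False
    return PointPattern(pts[keep], window)


def peripheral_intensity(lam0: float, gradient: float = 1.0, radius: float = 8.0,
                         collar_width: float = 0.8, collar_level: float = 0.5):
    """Radial intensity profile with peripheral enrichment and a bark collar.

    lambda(r) = lam0 * (1 + gradient * (r/radius)^2), tapered linearly down
    to ``collar_level`` of its value within ``collar_width`` of ``radius``.
    Models bundles being more numerous towards the periphery, with reduced
    observed intensity at the very edge where the bark was removed.
    """

    def f(x, y):
        r = np.hypot(np.asarray(x, float), np.asarray(y, float))
        base = lam0 * (1.0 + gradient * (r / radius) ** 2)
        ramp = 1.0 - (1.0 - collar_level) * np.clip(
            (r - (radius - collar_width)) / collar_width, 0.0, 1.0)
        return base * ramp

    return f


# --------------------------------------------------------------------------
# Scene truth and rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of one rendered section: contour, bundles, intensity."""

    contour: Polygon
    bundles: np.ndarray          # (n, 2) mm, centred frame
    lambda_fn: object = None     # callable intensity descriptor, optional

    def __post_init__(self):
        b = np.asarray(self.bundles, float).reshape(-1, 2)
        object.__setattr__(self, "bundles", b)
        if len(b):
            ok = shapely.contains_xy(self.contour.to_shapely(), b[:, 0], b[:, 1])
            if not ok.all():
                raise ValueError(f"{int(np.sum(~ok))} bundle(s) outside the contour")


def make_scene(seed=None, size: float = 3.2, elongation: float = 1.12,
               asym: float = 0.08, noise_sd: float = 0.03,
               n_bundles: int = 120, r_min: float = 0.35,
               margin: float = 0.35) -> SceneTruth:
    """Scaled-down section scene with exactly ``n_bundles`` planted bundles.

    Bundle sites are drawn by sequential inhibition (dart throwing) from
    the peripheral-enriched intensity profile, at least ``r_min`` mm apart
    and ``margin`` mm inside the contour.
    """
    rng = _rng(seed)
    contour = synth_contour(size, elongation, asym, noise_sd, seed=rng)
    inner = shapely.buffer(contour.to_shapely(), -margin)
    inner_poly = Polygon(np.asarray(inner.exterior.coords)[:-1])
    lam = peripheral_intensity(1.0, gradient=1.0, radius=size * elongation,
                               collar_width=margin, collar_level=0.5)
    placed: list = []
    tries = 0
    while len(placed) < n_bundles and tries < 200 * n_bundles:
        cand = _uniform_in_window(1, inner_poly, rng)[0]
        tries += 1
        if rng.uniform() > lam(cand[0], cand[1]) / lam(size, 0.0):
            continue
        if placed and np.min(np.hypot(*(np.asarray(placed) - cand).T)) < r_min:
            continue
        placed.append(cand)
    if len(placed) < n_bundles:
        warnings.warn(f"placed only {len(placed)} of {n_bundles} bundles",
                      stacklevel=2)
    return SceneTruth(contour, np.asarray(placed), lam)


def _to_px(xy_mm: np.ndarray, origin: np.ndarray, n_rows: int,
           resolution: float) -> np.ndarray:
    """mm (centred frame, y up) -> fractional (row, col) pixel coordinates."""
    rel = (np.asarray(xy_mm) - origin) / resolution
    return np.column_stack([(n_rows - 1) - rel[:, 1], rel[:, 0]])


def render_section_image(truth: SceneTruth, resolution: float = 0.005,
                         seed=None) -> np.ndarray:
    """Render a grey-level macroscopy-like image of a section scene.

    Dark-field convention: background dark, cell walls bright, cell lumens
    intermediate; bundles are ~300 um dark clusters ringed by thick bright
    walls.  Parenchyma is a Voronoi tessellation of hard-core cell seeds
    (cells 50-150 um across).
    """
    if not 0.002 <= resolution <= 0.01:
        raise ValueError("resolution must be in [0.002, 0.01] mm/px")
    rng = _rng(seed)
    bg, lumen, wall, bundle_fill = 20.0, 100.0, 220.0, 25.0

    xy = truth.contour.xy
    margin = 0.3
    origin = xy.min(axis=0) - margin
    extent = xy.max(axis=0) - xy.min(axis=0) + 2 * margin
    n_cols = int(np.ceil(extent[0] / resolution))
    n_rows = int(np.ceil(extent[1] / resolution))
    img = np.full((n_rows, n_cols), bg)

    inside = polygon2mask((n_rows, n_cols),
                          _to_px(truth.contour.xy, origin, n_rows, resolution))
    img[inside] = lumen

    # Voronoi parenchyma walls from hard-core cell seeds (~100 um cells)
    seeds = sample_hardcore(150.0, 0.055, truth.contour, seed=rng).points
    if len(seeds) >= 3:
        seed_px = _to_px(seeds, origin, n_rows, resolution)
        rr, cc = np.nonzero(inside)
        _, lab = cKDTree(seed_px).query(np.column_stack([rr, cc]), k=1)
        label_img = np.full(img.shape, -1, dtype=np.int32)
        label_img[rr, cc] = lab
        diff = np.zeros_like(inside)
        diff[:, :-1] |= (label_img[:, :-1] != label_img[:, 1:])
        diff[:-1, :] |= (label_img[:-1, :] != label_img[1:, :])
        img[diff & inside] = wall

    # outer boundary wall (2 px thick)
    ring = inside & ~ndi.binary_erosion(inside, iterations=2)
    img[ring] = wall

    # bundles: dark disk with a thick bright rim
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    for b in truth.bundles:
        r_mm = rng.uniform(0.12, 0.18)
        bpx = _to_px(b[None, :], origin, n_rows, resolution)[0]
        r_px = r_mm / resolution
        d2 = (yy - bpx[0]) ** 2 + (xx - bpx[1]) ** 2
        img[d2 <= (r_px + 3) ** 2] = wall
        img[d2 <= r_px ** 2] = bundle_fill

    img = img + rng.normal(0.0, 5.0, img.shape)
    out = np.clip(img, 0, 255).astype(np.uint8)
    return out


def render_slab_scan(contours: list[Polygon], resolution: float = 0.0353,
                     seed=None, pad_mm: float = 4.0) -> np.ndarray:
    """RGB flat-scan image of several slabs laid out in a row.

    Slabs are bright (HSV value ~0.8) on a dark scanner background
    (value ~0.1), matching the bimodal value histogram the threshold at
    0.5 relies on.
    """
    rng = _rng(seed)
    widths = [float(np.ptp(p.xy[:, 0])) for p in contours]
    heights = [float(np.ptp(p.xy[:, 1])) for p in contours]
    total_w = sum(widths) + pad_mm * (len(contours) + 1)
    total_h = max(heights) + 2 * pad_mm
    n_cols = int(np.ceil(total_w / resolution))
    n_rows = int(np.ceil(total_h / resolution))
    fg = np.array([204, 184, 152], float)   # value 204/255 = 0.8
    bgv = np.array([26, 24, 22], float)     # value ~0.1
    img = np.ones((n_rows, n_cols, 3)) * bgv
    x_cursor = pad_mm
    for p, w in zip(contours, widths):
        shift = np.array([x_cursor - p.xy[:, 0].min(),
                          total_h / 2 - (p.xy[:, 1].min() + p.xy[:, 1].max()) / 2])
        mask = polygon2mask((n_rows, n_cols),
                            _to_px(p.xy + shift, np.zeros(2), n_rows, resolution))
        img[mask] = fg
        x_cursor += w + pad_mm
    img = img + rng.normal(0, 2.0, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)
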