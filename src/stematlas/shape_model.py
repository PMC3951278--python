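"""Statistical analysis and modelling of aligned stem contours.

Aligned, resampled contours (n_v = 200 vertices, n_c = 400 coordinates)
form a data table XY(i, j), one row per slab face.  Three analyses are
provided:

* PCA of the coordinate table (covariance-based: all columns are mm), used
  to visualise contour variability and reconstruct synthetic extreme
  contours along each mode;
* ANOVA of the first principal-component scores under the full model
  ``SC = mu + alpha_G + beta_C + (alpha beta)_GC + s_S(G) + eps``,
  with the genotype effect tested against the stem-within-genotype stratum
  (the stem is the biological replicate) and the remaining effects against
  the residual;
* a simplified per-coordinate linear model ``XY(.,j) = mu(j) + alpha_G(j)
  + beta_C(j) + s_S(G)(j) + eps`` fitted by least squares under sum-to-zero
  constraints, whose intercepts reconstruct the reference (average) contour
  and whose coefficients predict genotype / cutting-position / stem
  contours and 3D stem models.

Sum-to-zero coding is essential: it makes mu(j) the grand-average contour,
which is the atlas space used for spatial normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Polygon

FACTOR_COLUMNS = ("genotype", "stem", "cut", "face")

#: cutting positions between consecutive slabs A..H
DEFAULT_CUTS = ("ab", "bc", "cd", "de", "ef", "fg", "gh")


class DesignError(ValueError):
    """Experimental design cannot support the requested fit or test."""


# --------------------------------------------------------------------------
# Contour table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContourTable:
    """Coordinate table XY(i, j) with per-row factor labels.

    ``coords`` is (n_rows, 2*n_v): columns x1..x_nv then y1..y_nv, in mm.
    """

    coords: np.ndarray
    factors: pd.DataFrame
    n_v: int

    def __post_init__(self):
        c = np.asarray(self.coords, float)
        if c.shape[1] != 2 * self.n_v:
            raise ValueError(f"expected {2 * self.n_v} columns, got {c.shape[1]}")
        if len(self.factors) != len(c):
            raise ValueError("factor table and coordinate table row counts differ")
        if np.isnan(c).any():
            raise ValueError("coordinate table contains missing values")
        object.__setattr__(self, "coords", c)

    @property
    def n_rows(self) -> int:
        return len(self.coords)

    def row_polygon(self, i: int) -> Polygon:
        return coords_to_polygon(self.coords[i], self.n_v)


def coords_to_polygon(vec: np.ndarray, n_v: int) -> Polygon:
    vec = np.asarray(vec, float)
    return Polygon(np.column_stack([vec[:n_v], vec[n_v:2 * n_v]]))


def polygon_to_coords(p: Polygon) -> np.ndarray:
    return np.concatenate([p.xy[:, 0], p.xy[:, 1]])


def build_contour_table(polygons: list[Polygon],
                        factors: pd.DataFrame | list[dict]) -> ContourTable:
    """Assemble aligned polygons and factor labels into a contour table.

    All polygons must share the same vertex count (vertices are assumed to
    be in direct correspondence across rows).
    """
    fac = pd.DataFrame(factors).reset_index(drop=True)
    counts = {i: p.n_vertices for i, p in enumerate(polygons)}
    n_v = counts[0]
    bad = [i for i, c in counts.items() if c != n_v]
    if bad:
        raise ValueError(f"vertex-count mismatch for rows {bad}: "
                         f"expected {n_v} vertices")
    coords = np.stack([polygon_to_coords(p) for p in polygons])
    return ContourTable(coords, fac, n_v)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAModel:
    mean: np.ndarray          # (n_c,)
    loadings: np.ndarray      # (n_c, k), orthonormal columns
    scores: np.ndarray        # (n, k), zero column means
    inertia: np.ndarray       # (k,) variance fractions, sums to 1
    n_v: int


def fit_pca(table: ContourTable) -> PCAModel:
    """Covariance PCA of the coordinate table (no scaling: shared mm units)."""
    X = table.coords
    if len(X) < 2:
        raise DesignError("PCA needs at least 2 contours")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 1e-12:
        raise DesignError("rank-0 data: all contours identical")
    k = int(np.sum(s > 1e-12 * s[0]))
    var = s[:k] ** 2
    return PCAModel(mean=mean, loadings=vt[:k].T, scores=u[:, :k] * s[:k],
                    inertia=var / var.sum(), n_v=table.n_v)


def synthetic_extreme_contour(pca: PCAModel, component: int, score: float) -> Polygon:
    """Contour reconstructed as mean + score x loading of one component."""
    if not 0 <= component < pca.loadings.shape[1]:
        raise IndexError(f"component {component} out of range "
                         f"(model has {pca.loadings.shape[1]})")
    vec = pca.mean + score * pca.loadings[:, component]
    return coords_to_polygon(vec, pca.n_v)


# --------------------------------------------------------------------------
# ANOVA of PC scores
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTable:
    """F statistics and p-values per component and effect."""

    table: pd.DataFrame   # index PC1.., columns (effect, {'F','p'})


_EFFECTS = ("genotype", "cut", "genotype:cut", "stem")


def _check_factors(factors: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("genotype", "stem", "cut") if c not in factors.columns]
    if missing:
        raise DesignError(f"factor table lacks columns {missing}")
    return factors


def anova_pc_scores(pca: PCAModel, factors: pd.DataFrame,
                    n_components: int = 5) -> AnovaTable:
    """Nested mixed-model ANOVA of the first principal-component scores.

    For each component, sums of squares of the balanced design are used:
    genotype is tested against the stem-within-genotype mean square, while
    cutting position, the genotype x cut interaction and the stem effect
    are tested against the residual.
    """
    factors = _check_factors(factors)
    n_components = min(n_components, pca.scores.shape[1])
    g = factors["genotype"].astype(str).to_numpy()
    s = factors["stem"].astype(str).to_numpy()
    c = factors["cut"].astype(str).to_numpy()
    glev, clev = np.unique(g), np.unique(c)
    if len(glev) < 2 or len(clev) < 2:
        raise DesignError("need >=2 levels of genotype and cut")
    for gl in glev:
        if len(np.unique(s[g == gl])) < 2:
            raise DesignError(
                f"genotype {gl!r} has a single stem: genotype test undefined")
    gs = np.char.add(np.char.add(g, "/"), s)
    gc = np.char.add(np.char.add(g, "/"), c)
    n = len(g)
    n_stems = len(np.unique(gs))

    df_g = len(glev) - 1
    df_s = n_stems - len(glev)
    df_c = len(clev) - 1
    df_gc = df_g * df_c
    df_e = n - 1 - df_g - df_s - df_c - df_gc
    if df_e <= 0:
        raise DesignError("no residual degrees of freedom")

    rows = {}
    for j in range(n_components):
        y = pca.scores[:, j]
        if np.ptp(y) <= 1e-12 * max(1.0, np.abs(y).max()):
            raise DesignError(f"component {j + 1} scores have zero variance")
        grand = y.mean()
        ymap = pd.Series(y)
        mg = ymap.groupby(pd.Series(g)).transform("mean").to_numpy()
        mc = ymap.groupby(pd.Series(c)).transform("mean").to_numpy()
        mgc = ymap.groupby(pd.Series(gc)).transform("mean").to_numpy()
        mgs = ymap.groupby(pd.Series(gs)).transform("mean").to_numpy()
        ss_g = float(np.sum((mg - grand) ** 2))
        ss_c = float(np.sum((mc - grand) ** 2))
        ss_gc = float(np.sum((mgc - mg - mc + grand) ** 2))
        ss_s = float(np.sum((mgs - mg) ** 2))
        ss_t = float(np.sum((y - grand) ** 2))
        ss_e = max(ss_t - ss_g - ss_c - ss_gc - ss_s, 0.0)
        ms = {"genotype": ss_g / df_g, "cut": ss_c / df_c,
              "genotype:cut": ss_gc / df_gc, "stem": ss_s / df_s}
        ms_e = ss_e / df_e
        res = {}
        for eff, dfn in (("genotype", df_g), ("cut", df_c),
                         ("genotype:cut", df_gc), ("stem", df_s)):
            denom, dfd = ((ms["stem"], df_s) if eff == "genotype" else (ms_e, df_e))
            f = ms[eff] / denom if denom > 0 else np.inf
            res[(eff, "F")] = f
            res[(eff, "p")] = float(stats.f.sf(f, dfn, dfd))
        rows[f"PC{j + 1}"] = res
    tab = pd.DataFrame(rows).T
    tab.columns = pd.MultiIndex.from_tuples(tab.columns)
    return AnovaTable(tab[[ (e, k) for e in _EFFECTS for k in ("F", "p") ]])


# --------------------------------------------------------------------------
# Per-coordinate linear contour model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContourLinearModel:
    """Sum-to-zero linear model of contour coordinates.

    For each coordinate j: XY(i, j) = mu(j) + alpha_G(j) + beta_C(j)
    + s_S(G)(j) + eps(i, j), with sum_G alpha_G = 0, sum_C beta_C = 0 and
    sum_S s_S(G) = 0 within each genotype.
    """

    mu: np.ndarray
    alpha: dict            # genotype -> (n_c,)
    beta: dict             # cut -> (n_c,)
    stem_effects: dict     # (genotype, stem) -> (n_c,)
    residuals: np.ndarray  # (n, n_c)
    n_v: int
    cuts: tuple = field(default=DEFAULT_CUTS)


def fit_contour_model(table: ContourTable) -> ContourLinearModel:
    """Least-squares fit of the per-coordinate genotype + cut + stem model."""
    fac = _check_factors(table.factors)
    g = fac["genotype"].astype(str).to_numpy()
    c = fac["cut"].astype(str).to_numpy()
    s = fac["stem"].astype(str).to_numpy()
    glev = list(dict.fromkeys(g))
    clev = list(dict.fromkeys(c))
    empty = [(gl, sl, cl)
             for gl in glev
             for sl in np.unique(s[g == gl])
             for cl in clev
             if not np.any((g == gl) & (s == sl) & (c == cl))]
    if empty:
        raise DesignError(f"empty design cell(s) {empty[:5]}: effects inestimable")

    n = len(g)
    cols = [np.ones(n)]
    names = [("mu", None)]
    for gl in glev[:-1]:
        cols.append((g == gl).astype(float) - (g == glev[-1]).astype(float))
        names.append(("alpha", gl))
    for cl in clev[:-1]:
        cols.append((c == cl).astype(float) - (c == clev[-1]).astype(float))
        names.append(("beta", cl))
    stems_by_g = {gl: list(dict.fromkeys(s[g == gl])) for gl in glev}
    for gl in glev:
        slev = stems_by_g[gl]
        for sl in slev[:-1]:
            col = np.zeros(n)
            col[(g == gl) & (s == sl)] = 1.0
            col[(g == gl) & (s == slev[-1])] = -1.0
            cols.append(col)
            names.append(("stem", (gl, sl)))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, table.coords, rcond=None)
    fitted = X @ coef
    resid = table.coords - fitted

    def pick(kind):
        return {nm[1]: coef[i] for i, nm in enumerate(names) if nm[0] == kind}

    mu = coef[0]
    alpha = pick("alpha")
    alpha[glev[-1]] = -sum(alpha.values()) if alpha else np.zeros_like(mu)
    beta = pick("beta")
    beta[clev[-1]] = -sum(beta.values()) if beta else np.zeros_like(mu)
    stem_eff = {}
    for gl in glev:
        slev = stems_by_g[gl]
        acc = np.zeros_like(mu)
        for i, nm in enumerate(names):
            if nm[0] == "stem" and nm[1][0] == gl:
                stem_eff[(gl, nm[1][1])] = coef[i]
                acc = acc + coef[i]
        stem_eff[(gl, slev[-1])] = -acc
    cuts_in_order = tuple(cl for cl in DEFAULT_CUTS if cl in clev) or tuple(sorted(clev))
    return ContourLinearModel(mu=mu, alpha=alpha, beta=beta,
                              stem_effects=stem_eff, residuals=resid,
                              n_v=table.n_v, cuts=cuts_in_order)


def reference_contour(m: ContourLinearModel) -> Polygon:
    """Reference (average) contour reconstructed from the intercepts mu(j)."""
    return coords_to_polygon(m.mu, m.n_v)


def slab_cuts(slab: str, cuts: tuple) -> list[str]:
    """Cutting positions adjacent to a slab (slab 'D' -> cuts 'cd' and 'de').

    End slabs bounded by a single named cut use that one cut.
    """
    letter = slab.strip().lower()
    if len(letter) != 1:
        raise ValueError(f"slab label must be a single letter, got {slab!r}")
    adj = [cu for cu in cuts if letter in cu]
    if not adj:
        raise KeyError(f"no cutting position adjacent to slab {slab!r}")
    return adj


def predict_contour(m: ContourLinearModel, genotype: str | None = None,
                    slab: str | None = None, stem: str | None = None,
                    cut: str | None = None) -> Polygon:
    """Model contour for a genotype / slab (or cut) / stem combination.

    The slab effect is the mean of the cut-position effects on either side
    of the slab.  With no effect requested this is the reference contour.
    """
    vec = m.mu.copy()
    if genotype is not None:
        if genotype not in m.alpha:
            raise KeyError(f"unknown genotype {genotype!r}")
        vec = vec + m.alpha[genotype]
    if slab is not None and cut is not None:
        raise ValueError("give either slab or cut, not both")
    if cut is not None:
        if cut not in m.beta:
            raise KeyError(f"unknown cutting position {cut!r}")
        vec = vec + m.beta[cut]
    elif slab is not None:
        adj = slab_cuts(slab, tuple(m.beta.keys()) if not m.cuts else m.cuts)
        missing = [a for a in adj if a not in m.beta]
        if missing:
            raise KeyError(f"cut(s) {missing} not in model")
        vec = vec + np.mean([m.beta[a] for a in adj], axis=0)
    if stem is not None:
        if genotype is None:
            raise ValueError("stem effect requires the genotype")
        key = (genotype, str(stem))
        if key not in m.stem_effects:
            raise KeyError(f"unknown stem {key}")
        vec = vec + m.stem_effects[key]
    return coords_to_polygon(vec, m.n_v)


@dataclass(frozen=True)
class StemModel3D:
    """Stack of predicted contours, one per cutting position (z = index)."""

    layers: list  # of (z, Polygon)
    genotype: str | None


def build_stem_3d(m: ContourLinearModel, genotype: str | None = None) -> StemModel3D:
    """Predicted contour at every cutting position, stacked top to bottom."""
    layers = [(z, predict_contour(m, genotype=genotype, cut=cu))
              for z, cu in enumerate(m.cuts)]
    return StemModel3D(layers=layers, genotype=genotype)
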