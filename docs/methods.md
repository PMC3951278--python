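# Methods

This note records the models, parameter choices and numerical decisions
behind `stematlas`, and what the synthetic-data tests do and do not show.

## Coordinate conventions

All geometry lives in a mathematical frame: x to the right, y up, units of
millimetres, angles in radians counter-clockwise from the +x axis. Image
pixels are converted on load as `x = col * resolution`,
`y = (n_rows − 1 − row) * resolution`, so "top vertex" and "pointing
upwards" mean maximal y. Polygons are stored as open loops (the first
vertex is not repeated), oriented counter-clockwise (signed area > 0), and
centred contours have their **area** centroid (shoelace moments, not the
vertex mean) at the origin.

## Contour extraction

Slab scans: the HSV value channel `V = max(R,G,B)/255` is thresholded at
0.5 (the histogram of this kind of imagery is bimodal around 0.1 for the
background and 0.8 for tissue); components below 1000 px are treated as
dust; holes are filled so the outer boundary is unique. Boundary pixels
(foreground 4-adjacent to background, the image border counting as
background) are reduced to unit width by homotopic thinning *only when a
solid 2×2 block is present* — thinning an already unit-wide ring would
erode its corner pixels. The chain walk takes the first unprocessed
neighbour with 4-connected neighbours scanned before diagonals; a
diagonal-first order can cut a corner and strand part of the loop. The
walk must visit every curve pixel and close 8-adjacently, otherwise a
`ChainError` reports the component count or the break.

Slice (macroscopy) images: a cell-detecting watershed runs on the image
smoothed with a Gaussian of σ = 2 px, seeded at regional minima of depth
≥ 10 grey levels (cell lumens; the depth floor suppresses noise minima)
plus one marker along the image border from which the background floods.
Basins reached from the border are background; the union of cell basins is
hole-filled, closed with a radius-30 px disk (sequence-decomposed
footprint: ~13× faster, differs from the exact disk on ~0.01 % of pixels,
well below the later 100 µm simplification), and reduced to its largest
component. The contour is chained, scaled to mm, Douglas–Peucker
simplified at 100 µm and re-centred. The marker policy (σ = 2, depth 10,
border marker) is an implementation choice; only the watershed + hole-fill
+ closing chain itself is fixed by the method.

## Symmetry alignment

The bilateral symmetry axis of a centred polygon is found by mirroring it
about the y-axis and rotating the mirrored copy to minimise the asymmetry
objective: the sum over the rotating polygon's vertices of the minimal
Euclidean distance to the fixed polygon's *boundary* (vertex-to-edge, not
vertex-to-vertex). The composite map `rotation(φ) ∘ mirror` is the
reflection about the line at angle π/2 + φ/2, so the axis of symmetry sits
at that angle and the rotation that brings it vertical is **−φ*/2**. The
objective can be multimodal, so a coarse 1° scan over [0, 2π) brackets the
minimum before bounded golden-section/parabolic refinement; the coarse
scan runs on loops subsampled to ≤ 128 vertices in float32 (the objective
is smooth at the contour scale), while the refinement uses the exact
objective. The φ*/2 ↔ φ*/2 + π ambiguity is resolved by requiring the
vertex farthest from the centroid to have positive y; the top vertex
(maximal y, ties broken by minimal x) becomes vertex 1. Resampling places
exactly n_v vertices at equal arc length starting from vertex 1 — arc
length rather than index subsampling, which is equivalent on near-uniform
pixel chains and robust on uneven ones.

## Shape model

The contour table *XY*(i, j) holds n_c = 2 × 200 coordinates per aligned
contour, vertices assumed in direct correspondence. PCA is computed on the
covariance (all columns share mm units; no scaling) via SVD of the centred
table. The ANOVA of the first five PC scores uses the balanced-design sum
of squares of the nested layout — genotype, cutting position, their
interaction, and stem nested in genotype — with genotype tested against
the stem-within-genotype mean square (the stem is the biological
replicate) and everything else against the residual. For the balanced
design this is exact; unbalanced designs are warned about rather than
silently mis-tested. A Monte-Carlo null simulation in the test suite
verifies the 5 % size of the fixed-effect tests.

The per-coordinate linear model drops the interaction and is fitted by
least squares with **sum-to-zero coding**, which is what makes the
intercepts μ(j) the reference (grand-average) contour. The stem term is
estimated as a fixed nested effect under sum-to-zero constraints —
per-stem contours must be reconstructable from coefficients, which a pure
variance component would not provide — while the ANOVA stratum above
honours its random-effect role. Slab effects (slabs are bounded by two
cutting positions) are the mean of the adjacent cut coefficient vectors;
an end slab bounded by a single named cut uses that one cut. Missing
design cells make nested effects inestimable and raise an error naming
the cell.

## Bundle detection

The alternate sequential filter applies opening-then-closing with exact
discrete disks of radius 1..10 px (reflective border padding). This erases
parenchyma cell walls (3–8 px) while ~300 µm bundles (≥ 24 px radius at
5 µm/px) persist as deep dark basins. Extended minima are computed
properly as the **regional minima of the h-minima transform** (greyscale
reconstruction by erosion of image + h over image, then regional minima):
the common shortcut of thresholding the reconstruction residue at h marks
only the pixels at each pit's exact minimum value, which fragments noisy
pit floors and misses bundle centres. Depth thresholds are 30 grey levels
for large bundles and 20 for small ones; shallow-threshold components that
touch a deep-threshold region are dropped in favour of the deep region.
Touching bundles are separated by a watershed on the complement of the
Euclidean distance map, seeded at h-maxima of depth 2 px (plateau and
rasterisation ripples merged). Detections are kept only if ≥ 90 % of their
pixels lie inside the slice contour, which removes the background basin;
centroids are translated by the slice-contour centroid. An `invert` flag
covers imagery where bundles are locally bright instead of dark.

## Spatial normalisation and intensity

Rigid alignment reuses the asymmetry scan (1° coarse + refinement) between
the observed slice contour and the slice's model contour. The polar
transform keeps θ(x) and scales ρ(x) by ρ_ref(θ)/ρ_slice(θ), both
evaluated by exact ray–segment intersection rather than an angular lookup
table (no interpolation error; contours are assumed star-shaped about the
centroid — multiple crossings trigger a warning and the nearest is used).
Points marginally outside the slice model (observed vs modelled contour
mismatch, e.g. bark removal) are tolerated up to 1 % of the pattern and
clamped radially to the boundary; more than that is an error. Mapped
window vertices land exactly on the reference boundary; between vertices
of a sparse (simplified) window the mapped chords can deviate at the
chord-sag scale, so the pattern container uses a 1 µm tolerance for dense
windows and 1 mm for the mapped window check.

Kernel intensity uses an isotropic Gaussian, bandwidth σ = (shorter side
of the window bounding box)/8 by default — a documented stand-in for a
"size of the bounding frame" rule of thumb, exposed as a parameter. Two
edge corrections are provided: `uniform` divides λ̂(u) by
e(u) = ∫_W k_σ(u−v) dv (the default), and `per_point` divides each kernel
by e(x_i) evaluated as the kernel's discrete sum over masked grid pixels,
which makes the discrete integral of the map equal the point count
*exactly* (the mass identity the tests assert at 0.5 %). Maps share a
128×128 grid over the reference bounding box expanded by 5 %; point-wise
averages keep pixels covered by at least half the maps.

## Synthetic data

The generator mirrors the study conditions: 2 genotypes × 7 stems × 7
cutting positions ('ab'..'gh', slabs A–H) × 2 slab faces = 196 contours;
base half-width 8 mm (≈ 16 mm internode diameter), genotype size
multipliers 0.95/1.05 (the mutant larger), per-cut size factors
0.97..1.03 and elongations 1.25..1.10, per-stem size SD 3 %, contour noise
0.05 mm, and random placement (rotation + translation) that the alignment
stages must undo. Contours are ellipses with a y-dependent width
modulation (egg shape) plus low-order mirror-symmetric radial Fourier
noise — the simplest family exhibiting a size mode and a round-vs-elongated
mode. A second generator builds the coordinate table *additively* from
sum-to-zero effect vectors so least-squares recovery can be checked to
machine precision.

Bundle intensity defaults to λ(r) = 1.33·(1 + (r/8 mm)²) points/mm² with a
linear roll-off to 50 % in the outer 0.8 mm (bark collar) — about 400
bundles per full-size section, enriched twofold at the periphery. Rendered
sections are scaled down (3.2 mm half-width at 5 µm/px, 120 planted
bundles at least 0.35 mm apart) so that the morphological chain runs in
seconds rather than minutes; cells are a Voronoi tessellation of hard-core
seeds (50–150 µm cells), walls bright on a dark field, bundles dark disks
(0.12–0.18 mm radius) with thick bright rims, plus Gaussian noise (SD 5
grey levels).

What passing these tests shows: the geometry, statistics and estimation
machinery are correct, and the imaging chain recovers planted structure
under realistic scale relationships. What they do not show: robustness to
real tissue variability — stitching seams, uneven illumination, collapsed
or doubled bundles, bark remnants — none of which the renderer emulates.

## Atlas-recovery experiment

For the recovery check, slices are distorted copies of the reference and
their patterns are simulated from the pulled-back intensity
λ(T(x))·k(θ)², where T is the slice→reference polar map and k its radial
scale (the Jacobian of the transform in polar coordinates), so the
normalised patterns are exactly Poisson with intensity λ in reference
space and the measured error isolates the estimation chain. The interior
mean absolute relative error (pixels more than 2σ inside the boundary) is
~9 %, dominated by kernel smoothing bias (≈ σ²∇²λ/2λ ≈ 11 % at the
centre for the default bandwidth). The 1/K variance-decay check uses a
homogeneous intensity on the reference window, where the kernel estimate
is unbiased in the interior and the mean-squared error is pure variance;
with the peripheral surface the smoothing bias (independent of K) would
mask the decay. Ratios are asserted within a factor of two of the ideal
4× and 16×, reflecting the Monte-Carlo noise of a handful of groups of
spatially correlated maps.

## Known limitations

- Contours must be star-shaped about their centroid for the polar
  transform; strongly lobed sections would need thin-plate or spline maps.
- The ANOVA assumes a balanced (or near-balanced) design.
- The bandwidth rule is a fixed fraction of the frame; no data-driven
  bandwidth selection is provided.
- Mosaic stitching of macroscopy tiles is out of scope; inputs are single
  images.
- The h = 30/20 depth thresholds are in grey levels of the filtered image
  and assume dark bundles on a brighter field (use `invert` otherwise).
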