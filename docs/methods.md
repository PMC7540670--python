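# Methods

## Model and procedure

The pipeline treats an expert range map as a binary spatial process
y(s) and an SDM as a continuous occupancy-probability surface
p(s) = 1 − exp(−λ̄), with λ̄ the integrated intensity of an
inhomogeneous Poisson point process (IPP). Both are compared through
the Bernoulli log-loss l(y, p) = −2[y log p + (1 − y) log(1 − p)], a
proper scoring rule: its expectation under the true occupancy
probability is minimized by predicting that probability, so neither
map style can game the metric by hedging. The deviance
∫_S l(y(s), p(s)) ds is evaluated by quadrature on a lon/lat grid
(default 10 arc minutes) and normalized by the deviance of the null map
covering all of S, giving the expert score 1 − D_expert/D_null.
Partitioning S into the map's inside and outside splits D_expert into a
commission and an omission term; divided by D_null these are the
"scaled inside" and "scaled outside" components and satisfy
score = 1 − (scaled_inside + scaled_outside) exactly.

Assumptions: occupancy in disjoint cells is conditionally independent
Bernoulli with p from the IPP; the surface is treated as a fixed arbiter
(its estimation error is not propagated into the score); maps and
surface share one grid.

## Geodesy

All areas and perimeters are computed on the WGS84 authalic sphere
(R = 6371.0072 km), the sphere with the same surface area as the WGS84
ellipsoid. Polygon edges are straight in lon/lat degree space and are
densified to ≤ 0.05° segments before integration; area uses the
spherical Green's-theorem line integral R²∮ sin φ dλ and length the
great-circle (haversine) sum. Using one sphere for both measures keeps
the isoperimetric identity behind the Polsby–Popper index consistent
(a small geodesic circle scores 1.0 to within 10⁻⁶). Regional areas
agree with fully ellipsoidal values to ~0.5% at mid-latitudes (the
1°×1° equatorial square: 12 363.7 km² spherical vs 12 308.8 km²
ellipsoidal), far below the variation the shape metrics respond to.
Antimeridian-crossing polygons are rejected with an error: the intended
domain (continental study areas) never produces them.

## Grid and quadrature

The grid is graticule-aligned (origin snapped to multiples of the
resolution), cells are half-open [W, E) × [S, N), and a cell belongs to
the study area iff its center does; the same center rule rasterizes
maps, so a map equal to the study area reproduces the null map exactly
and scores exactly 0. Quadrature weights are the exact spherical areas
of graticule cells, R²Δλ(sin φ_N − sin φ_S). The expert score and both
scaled components are invariant to any uniform rescaling of the
weights, so the weighted/unweighted choice only affects absolute
deviances (on an equal-area grid the two coincide). λ̄ per cell uses the
midpoint rule, λ(center)·area.

Each score reports a *discretization bound*: the summed
a_j·|l(1,p_j) − l(0,p_j)| over boundary cells (masked cells whose
rasterized y differs from a rook neighbour), divided by D_null. This
bounds the score change attainable by re-assigning boundary cells, and
the 10′-vs-5′ convergence check holds within the sum of the two grids'
bounds on smooth surfaces.

Probabilities are clamped to [ε, 1 − ε], ε = 10⁻¹⁰, to keep the loss
finite at p ∈ {0, 1}; clamp counts are recorded on the surface. A
surface clamped at the upper bound everywhere makes the null deviance
vanish and is rejected as degenerate.

## Geometry and study areas

Invalid polygons (routine in digitized shapefiles) are repaired with
the structural make-valid algorithm, dropping collapsed parts; a
polygon whose hole equals its shell therefore becomes empty and errors.
Holes subtract area and add perimeter; multipolygon metrics are
computed on the whole (parts summed). The alpha hull uses the Delaunay
circumradius criterion with the disk radius in decimal degrees
(default α = 8°, the convention of the R alphahull package) — a planar
construction in degree space, adequate at the continental scales it
serves. Fewer than three non-collinear points fall back to a buffered
convex hull (buffer α/10) with a warning. The study area is
convex_hull(alpha_hull(points) ∪ map_a ∪ map_b) ∩ land.

## IPP fitting

The log-linear IPP log-likelihood Σᵢ log λ(sᵢ) − Σⱼ λ(cⱼ)aⱼ uses the
scoring grid's cells as quadrature nodes (Berman–Turner style), with
each point taking its cell's covariate values. Covariates are
standardized to zero mean/unit variance inside the mask; optimization
is BFGS with the analytic gradient (gradient tolerance 10⁻⁸, max 500
iterations; the objective is concave, so this is a deterministic
global fit). Standard errors come from the analytic observed
information, transformed to the natural covariate scale. With an
intercept, the score equation forces the fitted total intensity to
equal the observed count — verified to 1% on every fixture. The scoring
module accepts any externally supplied λ̄ surface, so SDMs of other
families (e.g. boosted trees) can be plugged in unchanged.

## Multimodel inference

All 2^p − 1 non-empty main-effects subsets (guarded at p = 16) are fit
by OLS with an intercept; the intercept-only model is excluded from the
candidate set (three predictors therefore yield seven models). AICc
uses k = coefficients + 1 for the residual variance:
AICc = n log(RSS/n) + 2k + 2k(k+1)/(n−k−1). Akaike weights are
exp(−Δ/2) normalized over the set; predictor importance is the summed
weight of models containing the predictor, with importance ≥ 0.8
deemed important and those predictors refit as one linear model
(adjusted R² reported raw and truncated at 0, since near-null fits can
produce small negative values). Categorical predictors are dummy-coded
against a first-level reference and enter or leave a model as one
block. Rank-deficient designs are dropped with a warning and weights
renormalized. Moran's I uses row-standardized rook contiguity on the
study grid (queen optional); with row standardization the checkerboard
attains exactly −1 and the permutation-null mean is −1/(n−1).

## Synthetic scenarios

The generator emulates a habitat-specialist species in a 10°×10°
mid-latitude region: 4–7 Gaussian suitability kernels (amplitude
0.005–0.015 points/km², length scale 0.6–1.2°) over a 10⁻⁵/km²
background, giving per-cell occupancy peaks near 0.9 against a ~0.003
background at 10 arc minutes and a few thousand occurrence points per
pattern. Points are drawn cell-multinomially with uniform within-cell
jitter from one integer seed. Two map styles are derived from the same
surface: *tight* (threshold p ≥ 0.5, no smoothing) emulating maps
restricted to confirmed breeding areas, and *generous* (threshold 0.05,
convex hull, 0.5° dilation) emulating maps that include every reached
area. What the generator does **not** emulate: observer sampling bias,
spatially autocorrelated covariate error, true map digitization noise,
or trait-score dependence — so passing tests demonstrate the metric's
mathematical behaviour and the direction of the style contrast, not
empirical magnitudes for real atlases.

## Problem sizes and numerical choices

Tests and the acceptance script run at the scale the statistics
require rather than continental scale: scoring grids of ≤ 3 600 cells
(10° regions at 10′), IPP recovery at n ≈ 500 points × 50 replicates on
a 30′ grid, and 20 seeded scenarios for the style contrast. Ties on
cell boundaries are resolved by the half-open cell convention;
degenerate inputs (empty maps, zero perimeter, constant fields,
off-mask points) raise errors listed per function.

## Known limitations

- Spherical (authalic) rather than fully ellipsoidal measures; ~0.5%
  regional area error at most, identical across compared maps.
- The alpha hull is planar in degree space; at high latitudes its disk
  criterion becomes anisotropic in kilometres.
- No propagation of SDM uncertainty into the expert score.
- Binary cell membership by center containment; no fractional-coverage
  rasterization is offered, since the score's definition takes one
  binary y per cell and the discretization bound already quantifies the
  boundary-cell effect.
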