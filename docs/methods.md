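# Methods

## The measurement model

A leaf-strip cross-section is treated as an open planar curve observed at
n roughly equally spaced points (default n = 35, i.e. 17 per half-strip
plus a shared midrib point; the digitiser enforces equal path spacing, so
the integer index t = 0, …, n−1 is an adequate curve parameter and no
chord-length reparameterisation is applied). Coordinates are in mm, y-up,
with the adaxial (upper) leaf surface toward +y and the chain ordered
left-to-right; under that convention positive signed curvature means the
section curls toward the adaxial side (involute), negative toward the
abaxial side (revolute).

Both observation vectors are smoothed by one linear smoother,
x_s = Sx and y_s = Sy, with S = (I + λK)⁻¹ the hat matrix of the natural
cubic smoothing spline with a knot at every index (K is the Reinsch
roughness matrix DᵀW⁻¹D). Because the identical S acts on both coordinates,
every derived geometric quantity is invariant under rotation and
translation of the digitised points, and covariant under scaling (length
scales by a, curvature by 1/a). Smoothing strength is specified by
trace(S) — the effective degrees of freedom — which runs from 2
(straight-line fit) to n (interpolation). The penalty λ matching a
requested trace is solved by bisection on log λ using the eigenvalues of K
(tolerance 0.01 on the trace, 200-iteration budget; the map is strictly
monotone, so the search always converges). The default trace of 10 gives
light smoothing that captures the overall transverse shape of a 35-point
strip without chasing digitisation noise; it is a user parameter, not
automatically selected.

Curvature is evaluated from the exact derivatives of the fitted splines on
a regular grid over [0, n−1] (spacing dt = 0.25 by default; the choice is
immaterial well below 1 % for smooth strips). Strip length is the
composite-trapezoid integral of the speed ṡ over the full grid.

## Boundary handling of the curvature average

The per-strip statistic is the arithmetic mean of signed κ over the
evaluation grid. Smoothing splines are biased at open ends: the roughness
penalty flattens the fit in a boundary layer of width ~λ^(1/4) index units,
and the natural end conditions force the second derivative — hence κ — to
zero exactly at the extremities. On a clean semicircle at trace 10 the
full-grid mean is ~10 % below the true curvature; the effect is a property
of the estimator, not of the data (it reproduces to four decimals in an
independent smoothing-spline implementation). `strip_measures` therefore
excludes a fixed fraction (default 0.10) of the index range at each end
from the curvature average — roughly the boundary-layer width at the
default trace — which brings the error on constant-curvature oracles to
about +1 % across radii 0.5–5 mm while leaving the average independent of
dt (the trim is defined on the t-axis, not in grid points). The length
integral always uses the whole grid: the strip does not get shorter because
its ends are harder to differentiate. Setting `boundary_trim_frac=0`
restores the untrimmed mean. An arc-length-weighted mean is available as an
option; with near-equal point spacing it differs negligibly from the plain
mean.

## Convex-hull index

The hull is computed on the raw digitised points (smoothing does not move
the hull appreciably, while it does change the length estimate, so the
ratio deliberately mixes raw hull and spline length). The midrib landmark,
when present, is excluded from the hull input; interpreting the exclusion
as dropping the single landmark point is the only version expressible in
the coordinate data model — excluding midrib *protrusion pixels* would
require segmentation the inputs do not carry. The maximum diameter is the
all-pairs maximum over hull vertices (vertex counts are tiny; a rotating-
calipers implementation is kept as a cross-check). The index is the
natural logarithm of length/diameter — the log base is a convention; all
reported magnitudes here use ln. Collinear (flat) sections have no 2-D
hull; the diameter then falls back to the maximum pairwise point distance,
giving an index of exactly 0 for a straight strip.

## Image digitisation

Binarisation uses Otsu's threshold by default (the acquisition protocol
overexposes the strip, so the section is the bright foreground); a fixed
threshold is available for reproducibility. Only the largest connected
component is kept, which also removes specks (dust in the PEG solution).
Thinning produces the skeleton; the returned midline is the longest
endpoint-to-endpoint geodesic on the skeleton pixel graph (Euclidean step
weights), which prunes side spurs. Skeletons containing cycles longer than
a tolerance (16 px) are rejected — a strip rolled tightly enough to
self-touch cannot be reduced to a simple path, and silently cutting the
loop would fabricate geometry. The chain gets a 5-px moving-average
sub-pixel refinement (thinning leaves ±half-pixel jitter; the window is
negligible against the 4×-thickness minimum curvature radius the digitiser
is rated for), then n points are sampled at equal path spacing, scaled to
mm and flipped y-up.

Orientation: the chain is ordered so x increases end-to-end; when the end-
to-end x-span is below 5 % of the section's extent (a C-shaped section),
the chain starts at the lower endpoint instead, which keeps the adaxial
sign convention. For sections rolled past a full turn the traversal sign is
genuinely unrecoverable from geometry alone — the operator must supply
orientation metadata; the generator sidesteps this by emitting coordinates
in construction order.

## PEG calibration

The default concentration → potential map is the quadratic
Π = −11.517c² − 1.0508c − 0.0342 (MPa; c in g PEG 3350 per g water;
valid on [0, 0.55] g/g at 20 °C; no temperature model). Above 0.45 g/g
evaluation warns: solution viscosity can mechanically impede rolling.
The seven standard treatment potentials (−0.06 … −2.82 MPa) are stored as
a named constant; they are measured values that differ slightly from the
polynomial at the matching concentrations, and neither is substituted for
the other. Refitting from a psychrometer table is ordinary least squares
with at least degree + 2 distinct concentrations required, residual
diagnostics attached, and monotonicity enforced on the result.

## Synthetic data

`make_shape` builds strips by unit-speed construction from a prescribed
curvature profile (θ = ∫κ, x = ∫cos θ, y = ∫sin θ; quadrature step
length/10⁴) and samples them at equal arc length, so curvature, length,
chord and hull of every strip are analytically known — these are the
oracles the measurement modules are tested against. Digitisation error is
isotropic Gaussian noise on the coordinates (default SD 0.02 mm, roughly
the positional uncertainty of clicking a skeleton point at the microscope).

`simulate_experiment` emulates the genotype-contrast design: each strip is
a two-half arc whose mean curvature follows the genotype's piecewise-linear
response to osmotic potential, anchored at the reported group contrasts
(low rollers −0.137 → +0.022 mm⁻¹, high rollers +0.120 → +0.452 mm⁻¹
between −0.06 and −2.82 MPa), with one half scaled up and the other down by
the asymmetry factor (default 0.1; one leaf side rolls more than the
other), between-strip curvature spread (SD 0.05 mm⁻¹, i.e. a realistic
~10–40 % CV within a treatment cell), osmotic shrinkage of strip length
(1 %/MPa low group, 3 %/MPa high group, on a 15 mm full-turgor width), and
the digitisation noise above. Randomness flows from one integer seed
through spawned child streams, so experiments are exactly reproducible and
sub-streams independent.

What the generator does **not** emulate: real lamina thickness variation,
midrib protrusion geometry, lighting/segmentation artefacts in real
micro-photographs, serial correlation of manual clicking, or hysteresis of
rolling. Passing tests therefore demonstrate correctness of the geometry
pipeline and the statistical machinery under the stated noise model, not
robustness to every imaging pathology of real wheat sections.

## Statistical analysis

Per-strip records feed a group × potential summary (cell mean, SE = sd/√n
reported as missing for singleton cells) and a fixed-effects two-way ANOVA
with interaction (statsmodels OLS, type-II sums of squares; identical for
the balanced designs the generator emits). Mixed models with nested random
effects (leaf side within replicate within cultivar) are deliberately out
of scope: the package's validation surface is geometric recovery, and the
fixed-effects ANOVA reproduces the headline significance structure (strong
group, potential and group × potential effects) on the anchored
simulations. A log-|response| variance-stabilising transform is available
(off by default) because spread grows with dehydration. A response with no
variation yields F = NaN with a warning rather than a fabricated zero.

## Problem sizes

Default validation sizes: 35-point strips; rasterised oracles at radius
100 px and stroke thickness 5 px; the anchored recovery experiment uses
2 groups × 3 potentials × 25 replicates; the invariance suite uses 100
random strips; the hull oracle 1000 random point sets; ANOVA calibration
200 record-level datasets. These sizes give stable estimates (cell-mean
SEs ~0.01 mm⁻¹) while keeping the whole suite fast.

## Known limitations

- Mean curvature of near-closed or multi-turn sections depends on a
  traversal orientation that geometry alone cannot fix (see digitisation).
- The boundary trim is calibrated for light smoothing (trace ≈ 8–14 on
  n ≈ 35); very low traces widen the boundary layer beyond the default
  trim and will re-introduce attenuation.
- The hull index is orientation-blind: it cannot distinguish involute from
  revolute rolling (use the signed mean curvature for that), and it dips
  during the revolute → flat → involute transition.
- One section per image; overlapping or touching strips are rejected, not
  separated.
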