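# Methods

## The estimator

The input is a triangulated aortic surface and an ordered coronary
centerline in a shared millimetre frame. The pipeline has four stages.

**Signed vertex distance.** Each centerline point is assigned the
Euclidean distance to the closest surface *vertex* (not the closest
point on a triangle), found with a k-d tree whose results are, by
construction, identical to an exhaustive vertex scan (the tree proposes
a slightly inflated candidate ball; the winner is chosen with the same
squared-distance arithmetic as a brute-force scan, smallest index on
exact ties). The vertex convention biases distances upward by at most
about half an edge length (≈ 0.2 mm at the intended 0.4 mm edge), second
order in edge length for points near a smooth surface patch. Points
inside the surface get a negative sign. For watertight surfaces
(every edge shared by exactly two faces) the interior test is ray
parity, accelerated by binning triangles on a 2-D grid in the plane
perpendicular to a fixed ray direction; rays that graze an edge, vertex
or coplanar triangle are retried along alternative fixed directions,
with the generalized winding number as the final fallback, so the result
is deterministic and robust. Open surfaces (clipped segmentations) are
accepted: the sign then comes from the dot product of the offset with
the angle-weighted pseudo-normal at the nearest vertex, and a warning is
recorded; a degenerate pseudo-normal falls back to a positive sign.

**Ostium origin.** Arc length is measured by cumulative chord length.
The origin `s = 0` is placed at the ostium: the first inside-to-outside
sign change of the signed distance, located by linear interpolation
between the bracketing samples. Only the first few centerline points are
expected to be inside (the centerline starts proximal to the ostium). If
no point is inside, the origin stays at the first point with a warning;
a centerline that never exits raises an error. A `first-point` origin
mode reproduces the alternative convention of measuring from the start
of the centerline.

**Resampling and differentiation.** Samples proximal to the ostium
(`s < 0`) are discarded. The retained distance samples are linearly
interpolated onto a uniform grid (default spacing 0.001 mm); grid points
proximal to the first retained sample are filled by linear extrapolation
of the first retained segment, which continues the intramural slope
rather than inserting an artificial plateau (a clamped fill creates a
zero-derivative lead-in of roughly the wall-offset length that biases
the subsequent fit by up to +0.4 mm). The derivative is computed by
central differences on the grid (one-sided at the two endpoints), with
no additional smoothing — the piecewise fit is the de-facto smoother.

**Two-piece fit.** A continuous two-piece linear model
`y = a + b·x (x < k)`, `y = a + b·k + c·(x − k) (x ≥ k)` is fit to the
derivative over the first 20 mm of arc by least squares, with the
transition `k ≥ 0` reported as the IM length. For fixed `k` the model is
linear in `(a, b, c)` with basis `[1, min(x, k), max(x − k, 0)]`; the
normal-equation entries are assembled from prefix sums of
`1, x, x², y, xy` split at `k`, so each candidate costs O(1) after an
O(n) precomputation. The search scans a coarse grid (0.05 mm) over
`[0, k_max]` and refines the minimizer by golden section (tolerance
1e-4 mm). The search is deterministic and needs no initial guess; SSE
ties are broken toward the smallest `k` (the shorter, more conservative
IM length), and the refined `k` is only accepted when it strictly lowers
the SSE so the tie-break survives flat SSE profiles. `k_max` defaults to
the end of the available profile rather than the fit window; with a
globally scanned profile, however, a transition beyond the window can
never strictly beat `k = 0` (both reduce to a single line on the window
data), so — unlike a local optimizer, which can converge to such values —
this implementation does not produce transitions past the window.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `window_mm` | 20 | arc span of the derivative used by the fit |
| `spacing_mm` | 0.001 | resampling grid step |
| `k_max_mm` | profile end | upper bound of the transition search |
| `coarse_step_mm` | 0.05 | coarse transition-search step |
| `refine_tol_mm` | 1e-4 | golden-section interval tolerance |

A profile shorter than the window truncates the window with a warning.
Fewer than 10 samples in the window, or a degenerate design, is an
error.

## Phantom design

The phantom provides geometry with an analytically known answer: a
watertight capped cylinder (radius 12 mm, height 40 mm) triangulated at
a target edge length (0.4 mm; wall rings with alternating half-step
azimuthal offset, caps as concentric rings with radius-proportional
point counts, stitched by an angle-ordered zipper — all edges fall
within [0.5, 2] × the target), and a planar centerline in the x–z
half-plane advancing by a fixed design arc step (0.4 mm), with the axial
step chosen so each chord has the designed length
(`dz = sqrt(max(ds² − dr², 0))`).

The designed signed-distance profile, as a function of arc from the
ostium, is:

* depth `−d0` (default 1 mm) inside the lumen during the proximal inset;
* a single radial wall-crossing chord from `−d0` to `+d0` (the crossing
  is steeper than the sampling step, so it appears as one long chord and
  the zero crossing — the ostium — lies exactly `d0` along it);
* the intramural regime at wall offset `d0` with small distance slope
  `b` (default 0.05), ending at the designed exit;
* a curved departure: the distance *slope* rises linearly from `b`
  toward the asymptotic slope `c` (default 1.0, i.e. finally leaving
  perpendicular to the wall) over a departure scale defaulting to a
  quarter of the aortic circumference (π/2 · R ≈ 18.8 mm).

Two aspects of this design are deliberate. First, the ground truth is
bookkept geometrically: the recorded ostium is the zero crossing and the
recorded exit is the distance-slope transition, with the intramural
regime length set to `im_length_mm − d0` so that *exit − ostium* equals
the designed IM length exactly — matching the surgical definition
(ostium to exit along the vessel). Second, the departure must be a
curve, not a kink: distance to a fixed surface is 1-Lipschitz along any
path, so a sustained distance slope above 1 is geometrically impossible,
and an abrupt constant-slope departure would make the derivative a step
function. A continuous two-piece linear model does not place its knee at
a step (the global SSE minimizer lands millimetres away, because the
second piece must start at the first piece's endpoint); a vessel that
curves away produces a linearly rising derivative, which is exactly the
fitted model and is also what real departing vessels produce. With this
design the estimator recovers designed IM lengths of 3–12 mm to within
0.21 mm at the 0.4 mm study resolution.

Optional Gaussian jitter (with a mandatory seed) is applied to the
points before arc length is computed; the recorded truth remains the
noiseless design.

### What the phantom does and does not emulate

It reproduces the *geometric* structure the estimator consumes —
interior start, wall crossing, wall-parallel intramural course, gradual
departure — at the study's mesh and centerline resolution. It does not
emulate anatomy (no sinuses, no curved aortic axis, no elliptical
intramural lumen), image noise, segmentation smoothing artifacts, or
operator variability in centerline placement. Passing recovery tests
therefore demonstrates correctness of the geometry/fit pipeline at
realistic resolution, not clinical accuracy; the cohort statistics
module carries the clinical-agreement evidence.

### Noise sensitivity

White point jitter is a harsh error model: at 0.4 mm spacing, 0.1 mm
jitter inflates cumulative chord length by ≈ 17 % (‖Δ + η‖ exceeds ‖Δ‖
in expectation) and gives the raw derivative a sample noise of ≈ ±0.35,
comparable to the full signal range — under those conditions the
estimate degrades to errors of several millimetres. At 0.02 mm jitter
the mean recovery error over 20 replicates stays within ±0.5 mm. Real
centerline error is smooth and operator-driven rather than white, so
these figures bracket rather than predict practical robustness; the
method applies no smoothing, by design.

## Cohort statistics

The packaged table carries 58 surgical AAOCA patients (49 right, 9 left)
with verbatim radiologic, computational and surgical IM-length strings.
Parsing conventions: a plain number maps to itself; a range `A–B`
(en-dash or hyphen) to its midpoint; any cell containing "short"
(case-insensitive) to 0 mm. Raw strings are retained alongside parsed
values. A table whose per-anomaly counts differ from 58/49/9 triggers an
integrity warning but is still analysed.

Agreement is summarised by RMSE against the surgical measurement, the
mean signed error with its sample (n−1) standard deviation, and the
two-sided Wilcoxon signed-rank test comparing the computational and
radiologic estimates. The Wilcoxon implementation drops zero
differences and mid-ranks ties; exact mode computes the distribution of
the positive rank sum over all 2^n sign assignments via a dynamic
program over doubled ranks (identical to exhaustive enumeration,
including tied ranks) and is used for n ≤ 25; above that the normal
approximation with tie and continuity corrections is used. On the
packaged table the left cohort gives the exact p = 0.0977 (= 2·25/512)
and the right cohort the approximate p = 0.862.

One reporting note: the left-cohort computational error SD computes to
3.7485 mm from the parsed table, which rounds to 3.7 rather than the
conventionally cited 3.8; the n−1 denominator is retained (the n
denominator gives 3.35, much farther), and the JSON report always
carries full precision.

## Numerical choices and degenerate inputs

* Zero-area faces are dropped at mesh validation; meshes need ≥ 4
  vertices and ≥ 4 non-degenerate faces.
* Duplicate consecutive centerline points are dropped with a warning;
  fewer than two distinct points is an error.
* Results serialize to JSON at full float precision; an undefined second
  slope is stored as null.
* The coarse-grid SSE comparison uses a 1e-9 relative tie tolerance so
  that flat SSE profiles (e.g. a constant derivative) deterministically
  return `k = 0` instead of a noise-selected interior point.
* Prefix-sum normal equations lose ≈ 1e-13 absolute precision to
  cancellation at n ≈ 2·10⁴ samples; irrelevant at the 1e-4 mm search
  tolerance but visible if SSE is compared to zero.

## Known limitations

* The estimator is undefined in principle when the intramural and
  departing distance slopes coincide (nothing to detect); the fit then
  collapses to a small `k`.
* Recovery error at fixed resolution is dominated by mesh-vertex
  quantization noise interacting with a shallow SSE profile in `k`
  (ΔSSE of a few percent over Δk ≈ 0.25 mm), so the error fluctuates
  with mesh phase rather than decreasing monotonically: across the
  resolution sequence 0.4 → 0.2 → 0.1 mm the maximum recovery error
  over designed lengths 3–12 mm measures 0.20 → 0.24 → 0.013 mm. The
  error envelope converges, but a single halving step can move against
  the trend.
* The 20 mm window and the global profile search mean transitions
  beyond the window are never reported; estimates larger than the
  window require enlarging `window_mm`.
* Sign assignment for open meshes relies on pseudo-normals and can be
  wrong near boundary edges of heavily clipped surfaces.
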