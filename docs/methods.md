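# Methods

This document describes the model behind `vesseltrack`, the meaning of each
configuration parameter, the scope of the synthetic phantom generator, the
numerical choices made in the implementation, and known limitations.

## Overview

`vesseltrack` segments blood vessels in grey-scale fundus images by *tracking*:
instead of classifying every pixel, it finds a sparse set of seed points on the
vessels and then follows each vessel iteratively, estimating the two edge
points of the cross-section at every step with a Bayesian maximum a posteriori
(MAP) decision. The output is a vessel tree — ordered sequences of edge-point
pairs with topology (parent/child links at bifurcations and crossings) — from
which a binary segmentation mask is rasterized.

The pipeline has four stages:

1. **Seed selection** — grey-level minima on a sparse grid, validated by a
   bank of oriented matched filters against a locally adaptive threshold.
2. **Direction estimation** — a Sobel gradient field; the dominant local
   gradient orientation gives the vessel direction (vessels are locally
   parallel to their edges, so the dominant *gradient* direction is normal to
   the vessel axis).
3. **Iterative MAP tracking** — at each step the tracker extrapolates the
   vessel center, collects an intensity profile on a search window across the
   vessel, and picks the most probable edge configuration under a Bayesian
   model of the cross-section.
4. **Branch handling** — a gradient-symmetry test predicts upcoming
   bifurcations/crossings; when it fires, the search window switches from a
   line to a semicircle and the MAP decision is taken over normal,
   bifurcation and crossing configurations jointly.

## Conventions

Points are `(row, col)` with the origin at the top-left pixel center; angles
are radians, measured counter-clockwise from the +col axis; the unit vector of
angle θ is `(sin θ, cos θ)`. Images are float arrays in [0, 255]; vessels are
*darker* than the background (fundus green-channel convention).

## Seed selection

Grid lines are placed every `grid_spacing` (default 30) pixels in both
directions. Along each line, strict local minima of the grey profile are
candidate seeds (plateaus count once, at their center); candidates closer than
3 px are merged, keeping the darkest. Candidates outside the field of view
(FOV) are discarded. The FOV mask is loaded from a file when given, otherwise
estimated by thresholding and keeping the largest connected component; if
neither works the full frame is used.

Each candidate is validated with a bank of 12 matched filters, 15° apart. Each
kernel is a rotated Gaussian band: constant along the vessel axis over a length
of `kernel_length` (default 9) px, Gaussian across it with spread
`profile_sigma` (default 2) px, and demeaned so it has zero response on
constant regions. Kernels are built by evaluating the rotated continuous band
on the pixel grid (no resampling of the 0° kernel). The candidate's response is
the maximum over orientations of the correlation with the *inverted* image
(vessels are dark, the filter is a ridge detector). The response must exceed a
locally adaptive threshold `μ + alpha·σ` (default `alpha` = 1.2), where μ and σ
are the mean and standard deviation of the inverted image in a
`seed_window`×`seed_window` (default 61) box around the candidate, clipped to
the frame. Validated seeds carry the best filter orientation as their initial
direction.

When the clipped kernel footprint at the image border loses pixels it no longer
sums to zero, which would leak the DC grey level into the response; the clipped
band is therefore demeaned again before correlating.

## Gradient and direction estimation

The gradient field is the 3×3 Sobel operator (reflective border handling),
optionally after Gaussian pre-smoothing with `gradient_sigma` (default 1.0 in
the tracker; the bare field used in examples has no smoothing). Each pixel
carries a modulus `G` and an angle `φ = atan2(g_row, g_col)`.

The dominant gradient orientation at a point maximizes the sum of squared
projections `Σ G_i² cos²(φ_i − θ)` over a `neighborhood`×`neighborhood`
(default 5) window. This is a quadratic form in the unit vector of θ, so the
maximizer has the closed form `θ* = ½·atan2(Σ G_i² sin 2φ_i, Σ G_i² cos 2φ_i)`.
The vessel direction is the dominant gradient orientation rotated a quarter
turn, with the sign chosen to continue the current tracking direction (never
more than 90° away from the reference).

## Cross-section model and MAP edge detection

At tracking step k the tracker knows the previous center `O`, direction `D`,
and diameter `d`. It extrapolates a new center `O_s = O + s·D'` (step length
`s`, default 3 px; `D'` is the direction re-estimated at `O`), and collects a
**search window**: a segment of length `max(2d, min_window_length)` through
`O_s`, perpendicular to the vessel, sampled every `candidate_spacing` (default
0.5) px with nearest-pixel grey lookup. The samples form an intensity profile
with candidate edge points at every sample.

A **configuration** assigns candidate indices to vessel cross-sections:

- *normal* — one chord (2 indices),
- *bifurcation* — two chords (4 indices),
- *crossing* — three chords (6 indices, the middle one belonging to the
  vessel being followed).

Given a configuration, the modeled profile is piecewise: background level
`I_b` outside all chords; inside a chord from edge `a` to edge `b`, an
inverted-Gaussian dip

    x(l) = (I_c − I_b) · exp(−l² / 2σ_χ²) + I_b,    σ_χ = |b − a| / 4,

where `l` is the signed distance from the chord midpoint along the chord.
Overlapping chords take the darker (minimum) value. The likelihood of the
observed profile is an independent Gaussian per sample: spread `σ_v` inside
chords, `σ_b` outside.

Local statistics are estimated from moving regions around the current
cross-section: `I_c` and `σ_v` from an oriented strip along the vessel axis
inside the vessel (half-width `max(0.5, d/8)`); `I_b` and `σ_b` as the median
and 1.4826·MAD (median absolute deviation) of two square regions (side
`max(3, round(d))`) placed `d/2 + region_margin` (default 2) px outside the two
edges. The median/MAD pair is consistent with the mean/std for Gaussian
background but robust to contamination by a second vessel near junctions. All
σ values are floored at `sigma_floor` (default 0.5) so noise-free images stay
well-posed.

For normal configurations on linear windows, a **Gibbs smoothness prior**
penalizes deviation of the new edge points from straight-line extrapolations of
the recent edge history:

    log prior = −log Z − λ(t₁² + t₂²),    Z = `gibbs_z` (1), λ = `gibbs_lambda` (0.01),

where `t₁`, `t₂` are the distances of the two candidate edge points from
total-least-squares lines fitted through the last few steps' edge points.
Branch configurations get a flat prior.

The MAP decision maximizes log likelihood + log prior over all feasible
configurations. Feasibility pruning: chord length in
`[min_chord, max_chord_factor · d_prev]` (default factor 1.5), at least
`min_gap` (default 2) samples of background between consecutive chords, and
for crossings the middle chord's midpoint within the previous diameter of the
window axis. Ties are broken by simplicity (normal < bifurcation < crossing),
then by lexicographic index order.

The MAP search is exact but not brute-force: all per-interval likelihood gains
are computed in one vectorized batch, and the best bifurcation/crossing is
found by prefix/suffix maxima over positive-gain intervals, which reproduces
the exhaustive optimum (including tie-breaks) at O(pairs) cost.

## Branch prediction and semicircle windows

Near a bifurcation the two vessel edges stop being parallel. At each step the
gradient direction is estimated at the two points halfway between the center
and each edge point (the gradient-magnitude peak of a Gaussian edge, the
best-signal location); if the two directions, folded to [0°, 90°], differ by
at least `t_angle_deg` (default 5°), a branch is predicted. The tracker then
replaces the linear window by a **semicircle** of radius
`semicircle_radius_factor · d` (default 1.5) centered on the current center and
opening in the tracking direction, and runs the MAP decision with bifurcation
and crossing configurations enabled. A bifurcation ends the current segment
and queues both daughter chords for later tracking (widest first); a crossing
queues the two outer chords and continues through the middle one.

## Tracking loop and stopping

From each seed the tracker runs in both directions (initial window length
`L0`, default 10 px). Tracking stops when: the diameter collapses below 1 px;
the local contrast `|I_c − I_b|` drops below `kappa_contrast · σ_b`; the
window leaves the image; no feasible configuration exists; the step lands on
an already-visited pixel (collision, checked after a short grace period so a
vessel does not collide with itself); or `max_iterations` (default 2000) is
reached. Visited pixels are recorded by filling the quadrilateral spanned by
consecutive edge pairs; the final mask is the union of these quadrilaterals
over all segments.

Determinism: the pipeline contains no random choices (the `rng_seed` config
value is reserved for future stochastic variants); identical inputs and
configuration produce byte-identical outputs.

## Phantom generator

The phantom module renders synthetic vessel images with exact ground truth
for validation. A vessel is a polyline with a (possibly linearly varying)
width; its image is the same inverted-Gaussian cross-section used by the
tracker's model, cut off at `|l| ≤ w/2`, with vessel level `I_c` = 100 and
background `I_b` = 160 (contrast 60) by default. Distances to the centerline
are computed against a dense polyline sampling (0.25 px step) via a k-d tree;
where vessels overlap the darker value wins. Independent Gaussian noise is
added per region (`sigma_v` on the vessel mask, `sigma_b` elsewhere, both
default 5), then clipped to [0, 255].

Ground truth contains the binary vessel mask (distance ≤ w/2), the dense
centerline samples with per-sample width, tangent angle and vessel id, and
junction locations. Layout factories provide the study conditions: a straight
vessel at a given angle, a Y-junction (trunk width 8, branches 6 and 5), a
crossing (widths 8 and 6 at 70° relative angle), parallel vessels, and a 512²
benchmark tree (trunk 12, two branches 8 and 5, plus a thin crossing vessel of
width 3). These defaults are the evaluation conditions of the test suite; they
are not tuned to the tracker.

The generator's scope is deliberately narrow: piecewise-linear centerlines,
symmetric Gaussian cross-sections, constant per-vessel contrast, stationary
Gaussian noise. It validates the tracking machinery, not the realism of
fundus imagery (no central light reflex, no background texture, no optic disc
or lesions).

## Numerical choices

- Candidate spacing on search windows is 0.5 px (configurable): integer
  spacing quantizes recoverable chords and dominates the width error for thin
  vessels.
- `I_c` is estimated from the interior strip rather than the single center
  pixel: the strip mean has ~√n lower variance, which stabilizes the dip
  amplitude of the model under noise.
- The MAP search uses exact vectorized scoring with dominance pruning
  (positive-gain intervals only), verified against exhaustive enumeration.
- Gradient estimates used by the tracker apply Gaussian pre-smoothing
  (σ = 1.0) before Sobel: isotropic smoothing is orientation-unbiased and
  damps per-pixel angle noise.
- Total-least-squares edge lines come from the smallest eigenvector of the
  2×2 scatter matrix of the recent edge points (closed form, no iteration).

## Limitations

- The cross-section model assumes a single Gaussian dip; central light
  reflexes (bright core inside the vessel) are not modeled and can split a
  wide vessel into two thin ones.
- Width estimates carry the model's chord-to-width convention (chord between
  MAP edge points); very thin vessels (< 2 px) fall below the feasibility
  floor and are not tracked.
- Branch prediction relies on local gradient symmetry and can miss shallow
  branch angles (< `t_angle_deg`), in which case a bifurcation is passed
  through as if normal.
- Crossing handling assumes the crossing vessel is roughly straight through
  the junction; X-junctions at very shallow relative angles may be read as
  two bifurcations.
- Seed validation assumes vessels darker than background; images with
  inverted polarity must be negated first.
- The tracker is sequential and single-scale; tortuous vessels with curvature
  radii near the step length can be cut short.
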