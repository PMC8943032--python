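# Methods

This note documents the geometric model, its parameters and numerical
choices, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the construction was genuinely
open.

## Coordinate system and wall representation

All geometry lives in the consensus cochlear coordinate system: the
modiolar axis is z, the x-axis (A-axis) runs through the round-window
center, and the insertion angle θ is measured in degrees from the round
window, increasing from base to apex.  Lengths are mm, angles degrees;
internal trigonometry is in radians and the degree/radian boundary is
the API surface.

Each cochlear wall (lateral and modiolar) is a sampled curve: in-plane
radius r(θ) and height z(θ) on a strictly increasing θ grid.  The
packaged mean templates sample every 22.5° from 0° to 990° and use a
plateau-exponential radius law

    r(θ) = c + a · exp(−(θ/τ)^q),

a smooth, monotonically tightening spiral.  Per wall, the linear
coefficients (c, a) are solved so that the curve's A and B dimensions —
A = r(0°) + r(180°), B = r(90°) + r(270°) — equal the corrosion-cast
population means (lateral 9.24/6.80 mm, modiolar 5.46/3.17 mm).  The
remaining shape parameters are frozen in `scripts/make_templates.py`
(modiolar τ = 101°, lateral τ = 160°, q = 1 for both): they were
calibrated once so that the mean-anatomy insertion model reproduces the
three published clinical EID/IA electrode anchors (see below), which is
the only shape information available for the modiolar wall at this
level of description.  The template height rises as
`4.2 mm · (θ/990°)^1.4`, a typical overall cochlear spiral rise; height
contributes little to insertion depth (the path is nearly planar per
turn) but is carried through all arc lengths.

**Individualization.**  A cochlea with measures (A, B) is obtained by
anisotropic in-plane scaling of the template: x by A/A_ref, y by
B/B_ref.  The scaled curve is re-parametrized by its own polar angle
(scaling changes point angles), under which its measured A/B equal the
requested values exactly.  The lateral wall's height profile is then
projected onto the modiolar wall (the lateral template's height
characteristics are the better constrained), by monotone-cubic
interpolation over θ.  Interpolation of r and z is shape-preserving
monotone cubic (PCHIP) throughout, chosen over splines to avoid
overshoot creating non-physical radius oscillation.

## Insertion trajectory

A perimodiolar array advanced with a straightener is modelled as a
composite planar-tangency path at a constant offset `d_off` from the
modiolar wall:

1. **Offset path**: the modiolar wall displaced by `d_off` along its
   in-plane outward normal (toward the lateral wall); where a normal
   offset would break monotone winding the displacement falls back to
   radial.  Heights come from the projected lateral profile.
2. **Entry point**: the intersection of the A-axis with the lateral
   wall on the round-window side.
3. **Straight segment**: from the entry point to the first tangency of
   the sight-line with the offset path, restricted to θ ∈ (0°, 90°).
   Its planar length is `l_str`, the tangency angle `IA_str`; both are
   solved on a 0.25°-resampled polyline with linear refinement of the
   tangency condition cross(q − E, dq) = 0.  If the offset path already
   curves away from the sight-line at its basal start (very large
   offsets in small cochleae), the start point is the release point and
   l_str degenerates accordingly.
4. **l_crit**: the distance from the entry point along the same ray to
   its first re-intersection with the basal lateral wall — how deep a
   still-straight array can go before touching the outer wall.
5. **EID(IA)**: the cumulative 3D arc length (chord sums on the
   resampled grid) along the composite path, a strictly monotone map
   inverted by linear interpolation; while the tip is on the straight
   segment its polar angle runs from 0 to IA_str, so the map covers the
   whole insertion.  Insertion depth is a physical electrode length,
   hence 3D.

Tangency and l_crit are solved in the plane-of-rotation projection
(heights attached afterwards): the tangential-release construction is a
planar one, and no 3D tangency construction is defined at this level of
description.

Where the offset path would cross the lateral wall (apically, for large
`d_off`), construction either fails with the offending angle or, where
the caller requests it, truncates there and flags the trajectory; the
transition quantities are basal and unaffected by apical truncation.

**Offset tuning.**  `tune_doff` scans d_off ∈ [0, 1.5] mm in 0.1 mm
steps (optionally ternary-refined to 0.01 mm) for the offset whose
EID at a clinical anchor insertion angle best matches the published
insertion depth; ties resolve to the smaller offset.  The three
packaged electrode specifications carry the published anchors:
Contour Advance 16.6 mm @ 348° (d_off 0.8 mm), Mid-Scala 19.2 mm @ 398°
(1.0 mm), Slim Modiolar 15.4 mm @ 406° (0.3 mm).  On the packaged mean
anatomy the model reproduces these depths within 0.8% and inverts each
anchor to its published offset exactly on the 0.1 mm grid.

## Curvature and tip fold-over

`r_pre(IA)` is the local radius of curvature of the planar curved
segment, estimated as the circumradius of three consecutive points on a
1° grid (no smoothing by default; the straight segment reports an
unbounded radius).  The 1°-polyline estimator carries sub-micrometre
jitter; tests treat "decreasing" as decreasing up to that jitter.

`r_fold(IA)` is the critical tip radius for fold-over: the radius of a
planar arc whose one end stands on the modiolar wall at angle IA with
its tangent perpendicular to the local wall tangent ("standing up"),
while its other end merges tangentially into the path running `d_LW`
inside the lateral wall.  Because the arc end is perpendicular to the
wall, the arc centre lies along the local wall tangent at distance r;
r is solved by a bracketing root search (bisection bracket scan plus
Brent refinement, xtol 1e-6 mm) on the tangency residual
min‖C(r) − path‖ − r.  The path contact is searched within ±45° of IA
(adjustable): in planar projection consecutive turns overlap, so an
unwindowed minimum would jump windings.  Angles where no radius solves
the construction are reported as NaN, not raised.  On concentric-circle
phantoms the solver matches the closed form
r = (ρ_p² − ρ_m²)/(2ρ_p) to 0.1%.

`d_LW` (the array's minimal clearance from the lateral wall in the
fold construction) is not pinned by any published value; the default is
0.4 mm, a typical apical array radius, and it is configurable and
recorded in every report.

The profile spans IA = 90°–720° in 1° steps.  Summary quantities:
`basal_max_r_fold` (max over IA ≤ 270°, the radius a basally released
tip must exceed), the **risk angle** (first IA > 270° where r_pre drops
to that basal maximum — an array pre-curved for that position could
fold over if released in the base) and the **crossover angle** (first
IA with r_pre < r_fold).  On the mean anatomy the basal maximum is
≈1.2 mm and the 0.3 mm-offset design shows a risk angle near 350°,
within clinically used insertion angles, while the 0.8/1.0 mm designs
show none — the qualitative pattern that motivates designing arrays
for > 0.3 mm modiolar clearance.

## Statistics

Two-tailed tests at α = 5% throughout, no multiple-testing correction
(reports annotate the number of tests).  The rank-sum comparison uses
exact enumeration for small tie-free samples (n ≤ 20) and the
tie-corrected normal approximation otherwise; distribution shape is
compared with the two-sample Kolmogorov–Smirnov test, applied to
mean-normalized values when lateral and modiolar spreads are compared.
Shared variance is Pearson's r squared, reported in percent.  Where
only mean ± SD and n are available (literature electrode validation),
a pooled-variance two-sample t with df = n₁ + n₂ − 2 is computed from
the summary statistics — the classic hand calculation, deliberately not
Welch's.

## Synthetic cohorts

The generator draws (A_lat, B_lat, A_mod, B_mod) from a multivariate
normal — the minimal distributional assumption given that only means,
SDs and correlations are published — truncated at ±4 SD per coordinate
and at the physical orderings A_lat > A_mod, B_lat > B_mod (violating
draws are rejected and redrawn; the acceptance step shifts means by
well under 0.5% of an SD at the packaged calibrations).  Packaged
profiles:

| profile   | means (mm)             | SDs (mm)              | lat–mod r |
|-----------|------------------------|-----------------------|-----------|
| corrosion | 9.24, 6.80, 5.46, 3.17 | 0.42, 0.36, 0.32, 0.32 | 0.70 |
| clinical  | 9.18, 6.99, 4.66, 2.82 | 0.40, 0.31, 0.34, 0.26 | 0.37 |
| microct   | 9.60, 7.14, 5.04, 2.91 | 0.31, 0.34, 0.31, 0.32 | 0.70 |

The correlation matrix is completed from two pinned values — the
lateral–modiolar correlation per axis (table above) and the cross-axis
correlation corr(A_lat, B_lat) = 0.8, reflecting the strong shared-size
coupling of the A and B dimensions — with the remaining entries filled
by the product (shared-factor) structure and the matrix projected to
the nearest positive-definite correlation if needed.  The
lateral–modiolar value is published per method, not per axis; one
shared value is used for both axes.  The µCT correlation is not
published numerically; the corrosion value is used as both are
high-precision cadaveric methods.

Segment tables are generated by inverting the summation formulas:
A₁ + A₇ is a Beta(4,4)-distributed split of A_lat − A_mod, and A₂…A₆ a
symmetric Dirichlet(4) composition of A_mod (likewise for B), so the
derived measures of the output reproduce the input to machine
precision and r₀ automatically lies between A₁ and A_lat.  The clinical
noise profile subtracts the soft-tissue offsets (0.80 mm on A_mod,
0.35 mm on B_mod — the differences between the corrosion and clinical
printed means, attributed to soft tissue that casts include and CT
excludes) and adds 0.1 mm Gaussian measurement noise to every measure.

**What the generator does not emulate:** the segment-level covariance
structure within a cochlea (segments are a random composition, not
anatomically modelled), the cast-specific missing-value pattern beyond
a missing-at-random option, side asymmetries, and any non-Gaussian
shape of the real population.  Tests passing on synthetic cohorts
therefore validate the pipeline's computations and calibration logic,
not anatomical claims about real populations.

All randomness flows from a single integer seed through one generator
stream; outputs record the seed, and re-running a manifest reproduces
byte-identical CSVs.

## Problem sizes and tolerances

Trajectories are built on 0.25°-resampled polylines (closed-form circle
phantoms agree to 0.1% at this resolution); curvature profiles use the
1° grid they are defined on.  Cohort-level checks run at the study size
n = 108, with 100–500 replicate seeds for calibration means and n =
20–40 cohorts for geometry band checks; the full default test suite
completes in well under a minute on one CPU.  Degenerate inputs
(entry point on the offset path, path touching the wall, anatomies
shorter than a requested angle) return the documented degenerate values
or flagged truncations rather than failing.

## Known limitations

* Both walls share one template family; true lateral-wall regression
  models and µCT-averaged modiolar templates would differ in detail.
  Templates are versioned data files and can be swapped without code
  changes.
* The fold-over construction is planar; near the apex the real 3D
  height change adds curvature demands the model understates.
* `r_fold` depends on the unpublished clearance d_LW; absolute values
  should be read relative to the configurable default, though the
  angular shape of the profile is robust to it.
* The model predicts geometric risk conditions, not clinical fold-over
  incidence rates.
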