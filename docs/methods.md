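# Methods

This note records the models, parameter choices and numerical decisions
behind `spinescan`, and what the synthetic-data tests do and do not
demonstrate.

## Coordinate conventions

All geometry is in millimetres in a RAS frame: x toward the patient's
right, y anterior, z superior.  Transverse contours live in (x, y) and are
ordered counter-clockwise viewed from superior; the coronal projection of
the spine is x(z).  With these axes the sign rule of the offset correction
holds literally: a vertebral body rotated toward the patient's right
produces x_off > 0.

## Slicing

Meshes are cut by exact triangle/plane intersection at each level; raw
point clouds use a slab of configurable half-width (default 2 mm)
projected onto the plane.  Unstructured slice points are ordered by an
angular sort around the centroid, repaired by a greedy nearest-neighbour
chain when the result self-intersects (non-star-shaped slices), and
resampled uniformly in arc length (default 512 points).  A gap between
consecutive ordered points larger than `max_gap` (default 15 mm) raises a
fragmented-contour error — the situation where arms or a waist band
intersect the slab, which the interactive workflow would handle by
masking; declarative box masks (`MaskRegion`) serve that purpose here.
Ten to fifteen regularly spaced levels over the central 80 % of the torso
height are the default plan; severe curves warrant more.

## Dip detection

The spinous process shows as an indentation toward anterior on the
posterior arc.  The detector scans the posterior window (default 40 % of
arc length, centred on the −y azimuth from the centroid; anterior
indentations such as the umbilicus are thereby excluded) for local maxima
of y, takes the deepest, and measures its depth against a local polynomial
baseline fitted to the arch with the indentation excluded (quartic when
enough support points exist — the posterior arch of a torso is
flat-bottomed, and a quadratic extrapolates it poorly).  The dip centre is
refined as the centroid of the top half of the baseline-subtracted
indentation: the plain 3-point parabola is noise-limited, while a
full-extent centroid is biased when the indentation sits on a slanted part
of the arch.  Depth below `depth_threshold` (default 1 mm) gives
confidence `none`; above twice the threshold, `clear`.  On noisy scans the
pipeline first applies a circular moving average to the contour (default
9 points ≈ 16 mm of arc) and to the profile (7 points); both windows are
small relative to realistic dip widths (~35 mm).

## Reflection axis and asymmetry

The mid-sagittal axis is parameterized by its angle from the anterior
direction and its lateral offset at the dip's y-level.  The fit minimizes
the trimmed mean squared nearest-point distance between the mirrored
healthy half and the pathological half; the trimming quantile (default
0.70) operationalizes matching only where the pathological side is not, or
little, distorted.  Multi-start Nelder-Mead over a ±10° × ±15 mm grid
around the initial axis; optima with |angle| ≥ 45° are rejected.  The
halves are split once with the initial axis and held fixed during the
optimization; the trimmed objective absorbs the resulting boundary
effects.

Two axis modes exist because they serve different purposes:

* `vertical` (pipeline default): the angle is fixed at 0 and only the
  offset is fitted — the analogue of translating a vertical crosshair,
  which is how the interactive workflow the package automates is actually
  operated.  The sector partition then uses a vertical lateral separation
  line.
* `free`: angle and offset both fitted.  Useful when the patient was not
  upright in the scanner frame.  Caveat, observed on synthetic rib-hump
  contours: a freely tilting axis partially "symmetrizes away" the hump
  (a 15° vertebral rotation draws a ~3° axis tilt), which collapses the
  sector imbalance that the offset correction needs.  When the scan frame
  is trustworthy, `vertical` is the better default.

The asymmetry of a slice is the area enclosed between the reflected
healthy half and the pathological half, computed as the sum of absolute
quadrilateral strip areas after resampling both halves to matching
arc-length fractions (200 points).

## Offset correction

Sector membership is decided in the axis-aligned frame with origin at the
dip; the anterior-posterior separation line sits at the distance d
anterior of the dip (default 50 mm, configurable; the distance between
vertebral body and back skin is treated as constant within a subject,
which the normalized δ-profiles support).  Each sector's polygon is the
contour points in its quadrant plus the crossline intersection points and
the crossline centre; its area is the shoelace area of the convex hull.
Points exactly on a separation line tie-break toward the +x / anterior
sector.  R_ω is measured on the side the raw imbalance points to.  The
published rendering of the offset formula is typographically ambiguous;
the default grouping scales the *sum* of both normalized imbalances by
R_ω (this makes x_off vanish for symmetric contours and bounds |x_off| by
2 R_ω), and `grouping="second-term"` provides the alternative reading for
sensitivity analysis.

## Trajectory, fit and severity

The coronal fit is linear least squares in a scaled domain (the
general nonlinear least-squares formulation reduces to this for a
polynomial model), converted back to plain powers of z; degrees 1–7.
Included-angle knots are the curve endpoints plus the real roots of x''
inside the data range — endpoints are included so that C-type (degree-2)
fits, which have no inflexion, still yield one total-curvature angle.
Lateral deviation is the maximal perpendicular distance of the fitted
curve from its endpoint chord; class boundaries are mild ≤ 10 mm,
strong ≥ 20 mm.  Cobb bands (no scoliosis < 10°, mild ≤ 20°, moderate
≤ 40°, severe > 40°) are provided as a classification helper; band edges
go to the lower band.

## Curve matching

Curves are sampled at n points (default 50) uniform in normalized level;
correspondence is point-to-point at equal normalized level — trajectories
share the physical level axis, and nearest-point correspondence would
allow degenerate slides.  The transform (translation + rotation about the
sample at normalized level 0.5) is found by bounded least squares with
multi-start at α ∈ {−30°, 0°, +30°}; |α| is bounded just inside 45° so an
upside-down match is impossible.  The optimality value is the mean squared
residual distance (mm²) after alignment.  One consequence of the level
correspondence: matching an exactly rotated copy of a curve leaves a small
reparametrization residual (≈5 mm² for a 20° rotation of a 400 mm curve)
even though the transform itself is recovered to ≪0.5°.

## Vertebral rotation and δ-profile

Q is the foot of the posterior perpendicular from the vertebral body P at
distance PS, so the triangle QPR has its right angle at Q and
α = atan(QR/PS), signed by the lateral direction of the dip shift (for
PS = 58.9 mm, a 25 mm shift gives α ≈ 23°).  The vertebral-body-to-skin
distances δ_i are normalized per subject as (δ_i − δ̄)/δ̄ (mean exactly
zero), with levels mapped affinely to [0, 1] between the iliac crest and
the vertebra prominens.

## Synthetic torso

Cross-sections are superellipses (exponent 2.5, half-widths 150 × 110 mm
with a smooth waist narrowing, height 450 mm) carrying:

* a Gaussian posterior dip (depth 6 mm, width 18 mm) that follows the
  spinous-process line;
* a per-level vertebral rotation profile proportional to the spine's
  lateral deflection, which (a) shifts the vertebral body away from the
  dip by QR = d_skin·tan(rot) with d_skin = 50 mm, and (b) adds a
  posterior rib-hump bump on the rotation side with a contralateral
  anterior flattening of equal amplitude — changing the contour asymmetry
  without moving the dip much, the mechanism that motivates the offset
  correction;
* the hump gain is 26 mm per unit sin(rotation), chosen once so the
  forward model is self-consistent: the sector-area offset evaluated on a
  clean rotated contour approximately equals the embedded dip shift QR at
  the default d.

Meshes are stacked rings (64 × 128 by default) triangulated and capped,
with Gaussian vertex noise (default σ = 0.5 mm, the resolution scale of
RGB-D surface fusion) drawn from a seeded generator — output is
bit-identical for identical spec and seed.  Presets `straight`, `c-mild`,
`c-moderate`, `c-strong`, `s-curve` span the severity regimes (apex
amplitudes 0/12/25/55/18 mm, peak rotations 0/6/12/22/10°).

What the generator does *not* emulate: breast or scapular geometry and
the occlusions under heavy breasts, arms entering the slab, posture sway
between repeat scans beyond i.i.d. vertex noise, level-dependent
vertebral-body depth, and non-superelliptic (e.g. barrel-chested) section
shapes.  Passing the synthetic recovery tests therefore shows the
pipeline is correct and noise-stable under the stated geometry, not that
it is clinically validated.

## Problem sizes and runtime choices

Default analyses use 15 slice levels, 512-point contours and 64 × 128-ring
meshes (~8 k vertices); the repeat-scan and cohort suites use 3 and
3 × 10 torsos respectively.  These sizes keep the whole test suite around
a minute while leaving all recovery margins comfortably resolved (the
noise-limited trajectory SD is ~1 mm against acceptance margins of
3–5 mm).

## Known limitations

* The offset correction amplifies dip-position error (a lateral dip error
  e produces an opposing x_off ≈ −2.4 e under the default geometry), so
  contour smoothing before dip detection matters; the defaults reflect
  that.
* The free-angle axis fit is unreliable precisely on strongly rotated
  contours (see above); severity estimates for strong scoliosis are
  generally less accurate, consistent with the behaviour the method shows
  on clinical severe cases.
* Severity classes at exactly 10/20 mm and Cobb 20/40° follow the printed
  ≤ / ≥ conventions; the moderate deviation class is the open interval
  (10, 20) mm.
* Whether R_ω multiplies both imbalance terms or only the posterior one
  is genuinely ambiguous in the source rendering; both variants are
  implemented and the choice is echoed in every report.
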