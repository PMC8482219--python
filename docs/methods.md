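# Methods

This note documents the models, conventions and numerical choices behind
`gazekit`, in the order data flows through the package.

## World and camera conventions

All positions are in millimetres in a world frame anchored at the
bottom-center of the screen: x to the viewer's right, y up, z from the
screen toward the user.  The screen is the plane z = 0 with targets in
x ∈ [−200, 200], y ∈ [50, 350] mm (a 400×300 mm display).  The default eye
sits at O_e = (0, 200, 550), i.e. 550 mm in front of the screen center.

The eye-camera is an ideal pinhole that looks at the eyeball center (its
optical axis joins the camera center and O_e), with world-up as the up
hint, focal length 35 mm, principal point at the image origin, and image
coordinates in millimetres on the virtual sensor.  Intrinsics are
deliberately arbitrary: every gaze mapping in the package is fitted from
image coordinates, so any non-degenerate focal length or pixel scale is
absorbed by calibration — a property the test suite asserts.

## The schematic eye

A two-sphere Gullstrand–Le Grand-style model.  Along the optical axis from
the eyeball center O_e: the corneal center of curvature O_c at 5.3 mm, the
pupil center P_c at 9.2 mm; corneal radius 7.8 mm, eyeball radius 12 mm,
aqueous refractive index 1.336, angle kappa (6°, 2°).  The radii and axial
distances are documented schematic-eye values; they are not all printed for
the original simulation framework this package's study protocol mirrors, so
all of them are user-overridable in the `EyeModel` config block and every
default is recorded in output metadata.  Oculomotor limits are 35° left and
right, 25° up, 30° down; fixations beyond them raise an error naming the
offending axis.

**Gaze kinematics.**  To fixate a target the visual axis, anchored at the
corneal center (the model's nodal point; configurable to O_e), must pass
through the target.  The visual axis is the optical axis rotated by kappa —
by the vertical angle about the eye's horizontal axis, then the horizontal
angle about its vertical axis, in that (documented, otherwise arbitrary)
order.  Because O_c itself moves with the orientation, the optical axis is
solved by a fixed-point iteration (rotate the current visual axis onto the
required direction; converges to 1e−14 in a handful of steps).

**Pupil observation.**  With refraction enabled (the default) the camera
sees the virtual pupil image: the ray from the camera refracts into the
corneal sphere (Snell's law, air → 1.336) and must pass through the true
pupil center.  Snell coplanarity confines the refraction point to the plane
through camera, O_c and P_c, so the solve is one angle on the corneal
circle, found by bracketed bisection to ≲1e−12 mm — well below the 1e−9 mm
tolerance the pipeline assumes.  Glints are specular reflections of the
four screen-corner LEDs (the classic spherical-mirror problem), solved the
same way; a reflection with no bracket (invisible cap) is recorded missing.

**What the simulator does not model:** photorealistic eye images, eyelids
and blinks, pupil dilation, head movement (chin-rest protocol, fixed head),
sensor noise (optional seeded Gaussian jitter exists for fixture
generation).  Simulated sessions are therefore noise-free and deterministic:
passing tests show geometric correctness of the pipeline, not robustness to
detection noise in real images.

## Gaze mappings

`fit_poly2` solves the per-axis second-order polynomial
(x², y², xy, x, y, 1 design) by QR-based least squares, unregularized —
9 calibration points against 6 coefficients per axis are well-conditioned
on calibration grids, and rank-deficiency raises a singular-fit error.
`fit_homography` is the direct linear transform with isotropic (Hartley)
pre-normalization of both point sets; the matrix is stored with unit
Frobenius norm (bottom-right entry 1 only for display, to avoid dividing by
a possibly tiny entry).  Higher-order polynomial mappings are deliberately
absent: they overfit nine points and push the epipole to infinity.

## Eye-camera location compensation

The nine calibration targets, linearly rescaled from the screen's target
range to [−1, +1]² (corners to corners — this keeps the normalized plane
affine to the screen for the targets; the interior mapping is otherwise a
free choice), form the ideal grid.  Regressing the calibration eye features
onto that grid with the second-order polynomial yields T_en; applying it to
every feature moves the session into the normalized plane Π_n regardless of
where the camera actually was.  The epipole of (normalized features ↔
targets) lands near the screen center, the signature of a virtually aligned
camera.

For recorded data, quad-glint normalization runs first: the homography
sending the four enumerated corneal reflections to the unit square [0, 1]²
(any fixed square works — the next stage is fitted afterwards) is applied
to the pupil center, removing head-translation effects.  Glint order is
taken from the input enumeration and never re-sorted.  Records with missing
or degenerate glints are flagged invalid, not zero-filled.

## Eye-feature undistortion

After compensation the normalized grid still bends like a barrel-distorted
image, because the pupil center travels on a spherical cap, not a plane.
The correction uses the standard calibrated-camera model with
r² = x_n² + y_n²:

    rho   = (1 + k1 r² + k2 r⁴ + k3 r⁶) / (1 + k4 r² + k5 r⁴ + k6 r⁶)
    tau_x = 2 p1 x_n y_n + p2 (r² + 2 x_n²)
    tau_y = p1 (r² + 2 y_n²) + 2 p2 x_n y_n
    phi   = (s1 r² + s2 r⁴,  s3 r² + s4 r⁴)
    p_n*  = p_n · rho + tau + phi     (componentwise)

The correction maps *observed* normalized features toward the ideal grid
(the corrected feature is what feeds the final gaze mapping), and the
coefficients minimize the squared distance of the corrected calibration
features to the ideal grid — Levenberg–Marquardt, zero initialization,
deterministic, tolerances 1e−14, at most 500 iterations; non-convergence
returns the best iterate flagged rather than raising.  The default free set
is {k1, k2, p1, p2, s1…s4}: 8 parameters against the 18 equations of a 3×3
grid.  The rational radial tail k3…k6 is not identifiable from nine points
and stays zero unless explicitly unlocked.  On aligned-camera sessions the
fitted k1 is negative (barrel), the fit visibly straightens grid lines and
roughly halves the calibration residual; the curvature reduction is real
but modest under the default eye constants (the barrel term is mild,
k1 ≈ −0.07), so the package asserts the direction of the effect rather
than a large fixed factor.

## Epipolar diagnostics

The fundamental matrix between eye plane and screen is estimated with the
Hartley-normalized 8-point algorithm and rank-2 enforcement by truncated
SVD, convention dst^T F src = 0 with src the eye plane.  Because a
calibration grid is nearly homographic (almost coplanar correspondences),
the design matrix's two smallest singular values are reported as a
degeneracy ratio; near-1 values mean the epipole is unconstrained.  It is
exactly the non-homographic part of the geometry — refraction and the
non-planar pupil locus — that localizes the epipole, and for a kappa-free
eye the recovered epipole matches the generating camera's screen-plane
(x, y) to numerical precision.  With a nonzero angle kappa the epipole is
displaced by the kappa offset projected to the screen (about 58 mm
horizontally for 6°): kappa acts as a translation of the normalized space,
and the epipole diagnostic reports the virtual camera of the *visual*-axis
frame.

## Evaluation

Angular errors use the right-angled-triangle convention: an on-screen
offset d at viewing distance D subtends atan(d/D).  Simulated data use the
eye-to-screen distance (550 mm); recorded data use the study geometry
(0.27675 mm pixel pitch, 450 mm).  Signed per-axis errors feed the Gaussian
analysis; absolute errors feed reliability summaries.  The Gaussian fit is
the maximum-likelihood one (sample mean, population standard deviation);
the high-accuracy statistic is the fitted density's mass inside
(−0.5°, +0.5°), computed from the Gaussian CDF.  A zero-variance sample is
treated as a point mass.  A two-component EM mixture (deterministic
quantile initialization) exists for explicitly requested multi-peak fits.

Sweep-level band masses are computed from running sufficient statistics
(n, Σx, Σx²) per error axis — exactly equal to fitting the pooled sample,
without storing 4 million values per method.  Errors are embedded in the
screen plane as 3-vectors; the z component of a screen-plane estimate is
identically zero, which is why the z-axis band mass is exactly 1 for every
method.

KDE fixation reduction picks the observed sample point with the highest
product-Gaussian kernel density (Silverman bandwidth; the bandwidth
optimization of the original analysis is unspecified, so the deterministic
rule is the default), restricted to observed points so the representative
is always a real sample.  Outlier filtering is two-stage: trials with mean
gaze offset above 5° are dropped whole, then individual estimations whose
error magnitude deviates from the pooled mean by more than 3σ (the 99.7th
percentile rule).  The rule operates on magnitudes; on a unit-normal signed
error sample it removes ≈0.9% (the folded-normal tail), slightly more than
the 0.3% of a signed-error variant.

## Study protocol sizes

The full simulated protocol is a 21×21×21 camera grid (9261 positions)
× 441 targets = 4,084,101 gaze estimates per pipeline; it runs in a few
minutes on one CPU because eye poses are solved once per target set and the
refraction solve is vectorized over camera chunks.  Single-axis sweeps fix
the other two coordinates at the aligned values (x = 0, y = 200, z = 0).
Fixture sessions mirror the user-study protocol: a 7×5 target grid, 150
samples per target (5250 rows per trial), 3×3 calibration subset, seeded
jitter, written in the annotated-CSV schema with screen/image coordinates
in pixels (origin top-left).

## Known limitations

* The compensation cannot make two camera depths agree exactly: the pupil
  locus is a spherical cap, so projections from different depths differ by
  more than a scale factor.  The residual after normalization is ~3e−4 in
  normalized units — negligible for gaze accuracy, but not zero.
* Absolute error levels depend on the schematic-eye constants (corneal
  radius, pupil depth); with different published constant sets the
  traditional homography's worst-case error shifts by a few tenths of a
  degree while the ordering of the six pipelines is stable.
* The undistortion model corrects radially symmetric and mildly tangential
  bending; keystone-like cubic terms from very large camera angles are
  outside its span and survive correction.
* Real-image feature extraction (pupil ellipse fitting, glint detection) is
  out of scope; recorded sessions enter as annotated CSV.
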