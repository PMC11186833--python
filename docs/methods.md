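# Methods

`pearlring` reconstructs the microscopic surface of a near-spherical object
(a cultured pearl) from a ring of optical-microscope images, and ships a
simulator of the acquisition device so that every stage can be validated
against ground truth.  This note documents the models, the defaults and the
design choices.

## Acquisition model

The physical device keeps camera and objective fixed and rolls the pearl
under them: a silicone plate on a translation stage drags the sphere, and a
Teflon support converts the commanded translation into rotation.  Two
properties of that mechanism matter for reconstruction and are part of the
motion model:

* **Friction loss.** Only a fraction `efficiency` of the commanded
  translation becomes rolled arc.  Default 25.13/32 ≈ 0.785: one full ring
  of an 8 mm sphere (circumference ≈ 25 mm) takes roughly 32 mm of
  commanded travel.
* **Sliding noise.** The realized arc per step is perturbed
  (`arc_noise_sd`, default 0.05 mm — chosen so the simulated
  consecutive-frame overlap scatters by ≈ ±5.8 % around its 68 % mean),
  and the sphere slips sideways, perpendicular to travel, as a random walk
  (`lateral_sd`, default 0.004 mm per step).

Equivalently, a virtual camera orbits the sphere on an equatorial ring.
Conventions: sphere center at the origin, ring in the plane `z = 0`,
longitude counterclockwise from `+x`, boresight radially inward, up-vector
`+z`.  Lateral slip displaces the camera along `+z`.

## Optics and rendering

The camera is an ideal pinhole with focal length `f` (mm) and pixel pitch
`p` (µm); distortion and principal-point offsets are out of scope.  The
working distance is tied to the magnification by the pinhole relation
`wd = f / m`, which makes the on-object pixel footprint at the tangent
point exactly `p / m` — the same constant used to convert measured pixel
shifts to on-object arcs.  The renderer intersects each pixel ray with the
(slightly ellipsoidal) sphere, samples an equirectangular texture
bilinearly, and applies depth-dependent defocus: surface points whose depth
differs from the focus depth by more than `dof_half_width` (default
0.01 mm) are blurred with a uniform disk of radius `blur_scale × defocus`
(default 150 px/mm).  A disk PSF is cheap, monotone in defocus and
sufficient to order focus scores, which is all the focus pipeline needs.

**Field of view.**  The default study configuration uses 256 × 256 px
frames at an effective magnification of 1.0 (footprint 3.45 µm, on-object
FOV 0.88 mm), sized so that ~93 frames at 68 % overlap close one ring of an
8.3 mm sphere.  The effective on-object FOV of the physical instrument
after cropping is a free configuration value — the nominal 50× sensor FOV
is not compatible with ~90 frames per ring, so the simulator treats frame
count, sensor size and magnification as study parameters rather than
deriving one from another.

## Surface texture

The generator draws three feature classes, at their physical sizes, over a
smoothed speckle background on a longitude-seamless equirectangular canvas:

| class  | physical size        | rendering                          |
|--------|----------------------|------------------------------------|
| stain  | 0.02–0.2 mm          | Gaussian blobs, ± contrast         |
| front  | 0.005–0.01 mm        | short fine segments (growth fronts)|
| stripe | 0.05 mm–full ring    | thin bands along the longitude     |

Densities (2 /mm², 150 /mm², 0.25 /mm²) were set once so that a 0.88 mm
frame contains a realistic mix of a few stains, many fronts and occasional
stripes, giving SIFT a few hundred keypoints per frame.  What the synthetic
data does **not** emulate: specular reflections and illumination gradients
(available but off by default — the physical lighting problems are
hardware, not algorithmic), sensor noise, and the gemological appearance of
nacre.  Passing tests therefore demonstrate the geometry/consistency of the
pipeline, not robustness to adverse lighting.

## Focus pipeline

Sharpness is the squared-gradient (GRAS) measure: the sum of squared
horizontal first differences, optionally thresholded (`|d| > t`, default
t = 0).  Autofocus picks the stack frame with maximal score (ties toward
the lowest index).  Focus stacking selects, per pixel, the frame with the
largest windowed squared-gradient (window 9 px), after smoothing the
per-frame sharpness maps with a Gaussian (σ = 4 px) so seams follow a
smooth decision map.  This is the standard open equivalent of commercial
stacking tools; the altered effective perspective it introduces is absorbed
by the focal-length calibration below.

## Matching and pose bootstrap

Consecutive composites (plus the ring-closure pair, last→first) are matched
with SIFT keypoints and Lowe's ratio test (ratio 0.75, cross-checked; the
detector skips the 2× upsampling octave for speed — the frames have texture
to spare).  The inter-frame motion is modeled as a pure translation: an
exhaustive translation-only consensus (inlier tolerance 2 px) partitions
the matches into valid/invalid and reports the median inlier displacement.
Fewer than four surviving pairs flags the pair for **pinned
correspondences** — user-supplied point pairs in a CSV, the open
replacement for manually added alignment markers when overlap drops too
low.

Each shift's along-travel component is converted to an on-object arc
(`arc = px · p/m`, sign flipped because features flow against the travel
direction) and to a rotation angle via the spherical assumption
(`angle = arc / R`).  The sphere radius comes from ring closure: the arcs
of one full ring, including the closing pair, sum to the circumference.
The vertical shift components accumulate into per-frame slip estimates.
This closed-form bootstrap replaces the render-a-reference-sphere-and-align
loop; the rendered round trip is retained as a cross-validation path
(`render_reference_dataset`) and reproduces the bootstrapped angles within
0.2° at the study step size.

## Sphere-constrained refinement

The bootstrap is first-order (tangential) and carries a ≈0.2 % scale bias
at 4° steps (larger at coarser steps).  Refinement removes it: free
parameters are per-frame longitude and lateral slip (frame 0 fixed as
gauge), the global radius and optionally the global focal length.  Each
inlier correspondence is back-projected from its frame onto the sphere and
reprojected into the partner frame; the RMS reprojection error is minimized
by damped Gauss–Newton (Levenberg–Marquardt) with forward-difference
Jacobians, up to 40 sampled correspondences per pair.  Steps that do not
reduce the objective are rejected and the damping increased, so the
recorded residual sequence is monotone non-increasing; convergence is
declared when an accepted step improves the RMS by less than `tol_px`
(default 1e-3 px), with at most 100 iterations (30 in the default
pipeline).  The fixed, known working distance anchors the scale, so radius
and focal length are jointly identifiable.  On the study conditions the
refined solution recovers the diameter to ≈0.03 % and per-frame angles to
≈0.02°.

## Alignment quality and focal-length calibration

Focus stacking changes the effective perspective, so the focal length used
in reconstruction must be calibrated.  Alignment quality is scored as

    E_tot = ε/λ₁ + E_vertical/λ₂ + E_horizontal/λ₃

* **ε** — ellipticity of the ellipse fitted to the camera ring in the
  vertical (top-down) view; it penalizes alignments that are not
  ring-shaped.
* **E_vertical, E_horizontal** — the start-to-end gap of the ring in the
  rasterized vertical and horizontal orthographic views (px).  For masks,
  `ring_gap` skeletonizes the view and measures the distance between the
  endpoints of the largest open contour (0 if closed).  For camera rings
  the gap is taken directly between the ordered start and end positions in
  view pixels: the two definitions agree on open rings, and the
  position-based one remains informative when a wrong focal guess makes
  the cumulative rotation overshoot 360° and the rasterized contour closes
  on itself.
* **λ₁–λ₃** — per-term maxima over the calibration grid, so each criterion
  is equally weighted in [0, 1].  The maxima are floored at the view's
  measurement resolution (0.01 ellipticity, 1 px) so a term that is zero or
  pure noise across the whole grid cannot dominate the sum.  Because the λ
  are grid-relative, absolute E_tot values are comparable only within one
  calibration run.

Calibration re-runs the pose bootstrap at each grid focal length with that
value held fixed; the assumed on-object scale follows the pinhole relation
through the fixed working distance (`m̂ = f̂ / wd`), so a wrong focal guess
scales every arc by `f_true/f̂` and the walk-around ring (consecutive
shifts plus the closure shift) misses its own starting point by a
proportional gap.  The sphere radius is held at its nominal prior during
the scan — with a free radius the scale gauge would partially re-close the
ring and flatten the minimum.  Measured shifts do not depend on the focal
guess, so they are computed once and reused across the grid.  A grid point
whose bootstrap fails is assigned the worst observed terms and flagged in
the table.  On data rendered at 5.75 mm, a 4.0–7.0 mm grid at 0.25 mm
steps returns 5.75 mm.

## Meshing, texturing, coverage

The reconstruction is delivered on a UV sphere at the recovered radius
(default resolution 64 × 128 segments; area within 0.05 % of 4πR²).  Each
composite is back-projected onto the sphere (exact horizon visibility test
`P̂ · c > R`) and blended into an equirectangular texture with a cosine
feather that decays from the image center, suppressing seams in the ~68 %
overlap regions.  Faces whose centroid no image sees stay uncovered;
coverage is the covered-area fraction, which for one ring is the spherical
zone of the frame height: `h/(2R)` ≈ 11 % per ring at the default FOV.
Physical scale is anchored by the ring width, which equals the on-object
image height.  With exact poses and a defocus-free acquisition the textured
band reproduces the source texture with MAE ≤ 5 gray levels; defocus
residues in stacked composites add to that error, which is one reason the
texture is delivered alongside the geometry rather than fused into it.

## Validation arithmetic

Diameter accuracy is reported as `100·(1 − |rec − meas|/meas)` **truncated**
(not rounded) at one decimal — the truncation is deliberate: it reproduces
the reporting convention of the reference tables (e.g. a computed 99.76 %
is reported as 99.7).  Ellipticity is `(d_max − d_min)/d_max`, reported to
three decimals.  Reconstructed diameters come from the ellipse fitted to
the camera ring minus twice the working distance; since the refinement uses
a single global radius, reconstructed rings are nearly circular and their
ellipticity underestimates the sphere's true equatorial ellipticity — the
direct ellipse-fit value is therefore carried in the report as a separate
field and no accuracy target is attached to it.

## Problem sizes and numerical choices

The default study conditions (93 frames, 256 px frames, 3-depth z-stacks,
4096-texel textures) run the full pipeline in ~1.5 min on one CPU; unit
tests use a reduced 1 mm sphere (23 frames per ring) for full-ring
properties and the full-size geometry for step-size-sensitive checks.
Degenerate inputs are errors, not silent fallbacks: empty stacks, shape
mismatches, non-positive radii, <5-point or collinear ellipse fits, rays
that miss the sphere entirely (rays inside a frame that individually miss
are clamped to the nearest sphere point so refinement stays defined).
Ties in autofocus go to the lowest stack index; ties in the focal grid
argmin to the first (lowest) grid value.

## Known limitations

* Pure-translation consensus assumes small per-frame rotations; at coarse
  steps (≳15°/frame) the bootstrap bias grows and refinement carries the
  full burden.
* A single global radius cannot represent a visibly ellipsoidal object;
  the local-radius arc conversion in the simulator is first-order.
* Texturing blends in image space with no exposure compensation.
* The calibration identifies the focal length only up to the grid
  resolution, and its E_tot values are not comparable across runs.
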