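# Methods

This note records the model behind `thermocover`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic benchmark does and does not establish about clinical
data.

## Physical model

A fractional CO₂ laser head applies a square array of microbeams; each
application ("pulse") heats a square skin patch. The skin behaves as a
first-order inertia system: after a pulse at t = 0 the surface
temperature follows T(t) = T₀ + ΔT·(1 − e^(−t/τ)) with baseline
T₀ ≈ 33 °C and steady-state elevation ΔT ≈ 2.5 °C reached within a few
seconds. The elevated footprints persist for upwards of twenty minutes,
so a frame acquired between 10 s and a few minutes after the last pulse
shows every footprint at effectively full, stable contrast. The analysis
window check (`check_analysis_window`, default closed interval
[10 s, 180 s]) encodes exactly this: earlier frames are still rising
toward steady state, later frames are increasingly blurred by
thermoregulation.

Because the beam fluence is bell-shaped, footprint centres run hotter
than edges. The generator models this as a linear radial falloff in
Chebyshev distance (default 30% from centre to edge) plus a soft
penumbra: a linear ramp of total width `taper_px` (default 1 px)
*centred on the nominal footprint boundary*, following the optics
convention that a spot edge is the half-intensity point of its penumbra.
Centring the ramp is what makes threshold-based footprint measurement
unbiased: any cut near half the edge intensity crosses the ramp at the
nominal boundary.

Overlapping pulses combine by maximum by default (`compose="max"`):
tissue temperature saturates rather than doubling under a double dose,
and the saddle this leaves between two overlapping footprint centres is
what lets the watershed separate them. An additive mode exists for
robustness experiments.

## Treated-region extraction

Pipeline: nearest-neighbour upsample (default 480×640; replication only,
never interpolation, so no new temperature values appear) → 3×3 median
filter → grayscale morphology → difference image → binarize at `p_r` →
label → keep the largest cluster.

Two design points were genuinely open:

**Morphological operator.** The globalization step must turn the lattice
of warm squares — including cool inter-pulse gaps and untreated holes,
which the errors are *measured against* — into one connected region. A
grayscale **closing** with a flat square element does precisely this (it
fills dark features narrower than the element); an opening cannot, since
it only removes bright features and leaves cool gaps untouched. The
default is therefore closing, with the anti-extensive opening available
behind `roi_morphology="open"`. The element side (2·`se_radius_px`+1)
must exceed the width of an untreated hole to be bridged;
`RunConfig.for_pulse_side` sets the radius to ⌈0.55·(side + 2·gap)⌉ so a
single missed pulse is always recovered. A contiguous *multi-pulse*
omission is wider than any reasonable element, cannot be distinguished
from "outside the field", and is excluded from the detected region — a
structural limitation shared by any largest-cluster approach (see
Limitations).

**Difference reference.** Subtracting the median-filtered image from its
own morphological transform leaves only the gap/peak residue, which
cannot binarize into the full field. The difference image is therefore
taken against a *reference level* — by default the scene-wide median of
the filtered frame, a robust estimate of the pre-treatment skin
temperature (valid while the treated field covers less than half the
frame). The threshold `p_r` is thus an offset in °C above the
pre-treatment skin level. `difference_reference="median"` restores the
literal image-minus-image form, paired with an absolute-value polarity
switch.

`p_r` itself has no unequivocally correct value (see the sweep below).
When not set explicitly it defaults to 40% of the robust elevated range
(99.5th percentile minus background), with a 0.25 °C floor so that an
untreated frame — whose robust range is pure noise — is rejected as "no
treated region" instead of yielding a spurious cluster. The resolved
value is always echoed in the report.

## Pulse geometry

**Angle.** Canny edges (σ = 2, hysteresis 0.1/0.3 °C·px⁻¹ on the
gradient magnitude — uncritical, since footprint edges are ~50× above
the noise floor) are restricted to the dilated region. The Radon
transform is computed by direct summation: each edge pixel adds one
count to the bin at its rounded rotated offset. This conserves mass
exactly per angle (the per-angle total equals the edge count), which
interpolation-based transforms do not on sparse binary inputs; the
interpolating implementation in scikit-image serves as an independent
cross-check in the test suite. The estimate α\* is the angle of the
largest single bin — when the projection direction lines up with a grid
line, all of that line's pixels land in one bin — reported modulo 90°
(square grids are 90°-symmetric), ties broken toward the smaller angle,
and a sinogram whose best peak is under 1.5× the median per-angle peak
is rejected as unidentifiable (a single point or isotropic clutter).
With the default 1° step, recovery on synthetic grids is exact to the
step over the full [0°, 90°) range.

**Detrending.** Before segmentation the constant/slowly-varying
component is removed: a large-window median (computed on a 4× decimated
copy, window defaulting to twice the region's bounding-box extent)
estimates the smooth background, and the residual is re-centred to zero
mean over the region. The window must be wider than the treated field
itself — a window near the pulse pitch would track the grid and flatten
the very topography the watershed needs.

**Watershed.** Markers are the regional maxima after h-maxima
suppression with h = 0.3 °C: large enough to ignore sensor noise
(6σ at the default 0.05 °C), small enough to keep one marker per
footprint given the ≥ 0.75 °C saddles the radial falloff creates between
neighbours. Flooding the inverted topography restricted to the region
partitions it exactly — every region pixel, including untreated holes,
drains to some footprint basin.

**Square fit.** All footprints come from one laser head, so a single
physical side length exists. It is estimated as the median over regions
of √(treated area), where a region's treated area is its intersection
with the warm-support mask (pixels above `p_r` over background) — *not*
the full watershed cell, which absorbs adjacent untreated holes and
would inflate the size. Regions with area outside [0.25, 4]× the median
are discarded as spurious. Centres are intensity-weighted centroids of
the watershed cells. Each footprint is rasterized as a filled square at
the shared angle with a half-open pixel-centre rule (a pixel belongs iff
its centre lies in the rotated square, upper edges exclusive), so
edge-to-edge tilings produce exact partitions.

## Coverage errors

δ_o and δ_z are computed from per-pixel coverage counts: uncovered =
count 0, overlap = count ≥ 2, both intersected with the treated region
and normalised by its pixel count. The count form reduces to the
pairwise inclusion–exclusion expression (|L_R| − Σᵢ|Lᵢ| + |L_Z|) when no
pixel is covered more than twice and remains exact for any multiplicity.
Reports carry the exact integer pixel ledger
(roi = uncovered + single + multi) alongside percentages rounded to two
decimals; serialization is byte-deterministic.

**Threshold sensitivity.** `threshold_sweep` re-runs the analysis over a
grid of `p_r` values. On a standard scene (falloff 0.5, so the response
band spans the sweep) δ_o grows monotonically and almost linearly with
`p_r` (R² ≈ 0.99): a higher cut shrinks every measured footprint, so
more of the region counts as uncovered. This is why no single threshold
is "correct" and why every report echoes the threshold used.

## Synthetic benchmark: scope and problem sizes

Tests and the acceptance study run on 240×320 frames with 3×4 grids of
34 px footprints — the package's chosen working size, preserving the
footprint-to-frame proportions of a camera frame upsampled to 480×640
while keeping the whole suite fast. The acceptance batch uses 40 seeded
scenes (random rotation over [0°, 90°), up to three scattered
non-adjacent omissions, occasional overlapping placements, 0.05 °C
noise); the metric-oracle study uses 200 random pulse/region
configurations; angle recovery uses 20 rotations.

The generator reproduces the features the algorithm *assumes*: flat
baseline, shared footprint size and angle, first-order temporal
response, i.i.d. Gaussian noise. It does not model curved anatomy,
perspiration or hair artifacts, patient motion, vignetting, or the heat
diffusion PDE in dermis — so passing benchmarks demonstrates the
correctness of the algorithmic chain under its stated assumptions, not
clinical performance. On real images the measurement-protocol controls
(camera placement, perpendicular head application, artifact-free field)
take the place of these idealisations.

## Known limitations

- **Undertreatment wider than one pulse pitch** merges with the
  background and is excluded from the detected region: δ_o is then
  underestimated. Same for omissions at the field's outer corners,
  which present as open notches the closing cannot fully bridge.
- **Boundary rasterization of rotated fields** costs a ~1 px ring of the
  region at angles far from the axes; when undertreatment concentrates
  at the field edge this biases δ_o low by a few percentage points at
  the benchmark's scale (the effect shrinks with frame size).
- **Uniformly compressed grids are unidentifiable**: if *every* pulse
  overlaps its neighbours by the same amount, the shared-side estimate
  absorbs the overlap and δ_z reads near zero. Scattered overlaps — the
  realistic operator error — are recovered; a hardware-known footprint
  size would remove the ambiguity entirely.
- The 480×640 default upsampling of a 320×256 frame is anisotropic
  (×1.5 rows, ×2.5 columns), which distorts square footprints into
  rectangles; analyses at the native aspect (as in the test suite) avoid
  this. The pixel-pitch metadata is carried but not yet used to correct
  it.
- δ_z ≤ δ_o recovery accuracy depends on the saddle between overlapping
  footprints; overlaps deeper than about half a footprint merge into one
  watershed basin and are fitted as a single square.
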