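# Methods

This note documents the models, parameter choices and numerical decisions
behind `carotidseg`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic phantoms do and do not
establish about real ultrasound data.

## ECG gating

**Model.** The scanner renders a sweep-style ECG strip chart into a
rectangular sub-region of every frame: a pen advances a fixed number of
columns per frame, an erased redraw gap of a few columns travels just ahead
of it, and old trace remains visible to the right. The user marks the
chart rectangle once; automatic chart localization is deliberately out of
scope (it is unreliable and the rectangle is static).

**Extraction.** The rectangle is thresholded at intensity 72 (trace bright
on a dark chart; the ≥ convention and the value are configurable). The
trace ordinate in a column is the centroid row of the ON pixels — columns
render short vertical strokes connecting consecutive pen positions, so the
centroid is the natural single-valued read-out. A column with no ON pixel
marks the redraw gap; runs shorter than `min_gap = 2` columns are treated
as thresholding dropouts, not the gap.

**Stitching.** Per frame, the `keep_left = 10` columns left of the gap
(circularly: when the gap sits at the left sweep edge the newest content is
at the right edge) are appended to a growing strip. `keep_left` should
equal the scroll speed so consecutive contributions tile the timeline; both
default to 10 columns/frame. When the occluding letter glyph hides the
gap, an unknown-flagged spacer of the same width is appended instead so the
strip stays time-aligned, and per-column provenance (frame, frame-column)
is recorded throughout.

**QRS detection.** Real electrocardiographic detectors (Pan–Tompkins and
kin) assume a sampled voltage signal; here only a low-resolution raster is
available. The detector computes the sample variance (divisor n−1) of the
trace ordinate in a 5-column window stepped by 1 column: flat or slowly
varying stretches give near-zero variance, the QRS oscillation a sharp
maximum. Peaks are picked greedily — take the largest value (earliest
column on ties), suppress a refractory span, repeat — until an expected
count is reached or the remaining maxima fall below a noise floor of 25%
of the global maximum. The refractory span defaults to 40% of the median
inter-peak spacing of a provisional pass; the provisional pass suppresses
2·window + 1 columns around each pick because a single spike elevates
roughly window + spike-width consecutive windows and would otherwise be
counted twice. Windows touching unknown (spacer) columns are excluded
from the search rather than filled.

Detected QRS columns split the strip into periods `[q_i, q_{i+1})`. A
user-chosen position is expressed as a fraction of its own period and
re-applied to every period (heart rate varies, so periods differ in
length), then mapped to frame indices through the provenance table;
positions landing on spacer columns map to the nearest known column and
are flagged approximate.

## Frame repair

Inter-frame offsets are estimated by phase correlation: the argmax of the
inverse transform of the normalized cross-power spectrum, wrapped to signed
shifts. No window is applied by default, which makes the estimate exact
for integer circular shifts; a Hann window and parabolic subpixel
refinement are available for real data with strong edge effects, where the
periodicity assumption breaks. Defective pixels (given by a mask, or
flagged where the frame deviates from the reference mean by more than a
threshold) are replaced by the round-half-up mean of the aligned reference
frames, or by a flat user colour. Reference frames should match the target
in intensity distribution; `histogram_distance` reports an L1 histogram
score to guide that choice but selection is left to the caller.

## Artery detection

B-mode frames are low-contrast; contrast-limited adaptive histogram
equalization (CLAHE, 8×8 tiles, clip limit 2.0 in the relative-slope
convention) restores local dynamic range, and a 5×5 median filter
suppresses speckle while keeping edges. CLAHE is implemented in its
standard tiled form (clipped per-tile histogram, excess redistributed
uniformly, bilinear interpolation between tile mappings) so that the
one-tile unclipped limit coincides with plain histogram equalization — a
property the test suite checks against an independent implementation.

Edges are the unnormalized 3×3 Sobel magnitude, binarized at the ISODATA
(Ridler–Calvard) threshold: T iterates to the midpoint of the two class
means, starting from the global mean. The artery is then the best circle
of a 3-parameter Hough accumulator, radius range defaulting to
[size/10, size/3], scores normalized by circumference. Score ties within
1e-6 break to the smallest row, column, then radius: on clean images the
inner (lumen) and outer wall boundaries can both be complete circles with
normalized score 1.0 differing only by float jitter, and the lumen — the
smaller circle — is the anatomical target. Non-max suppression of one
minimum radius around each accepted centre yields multiple detections when
requested. An empty edge image or no circle above `min_score = 0.25`
raises a detection failure that the pipeline records per frame
(`hough_no_peak`) without aborting the run.

## Shadow-side reconstruction

Calcified plaque at the near wall shadows a sector of the artery side.
Working in polar coordinates about the detected centre, each 1° angle bin
stores the minimum distance to an edge pixel. Binning uses ray semantics:
an edge pixel is a unit square covering the angular interval spanned by its
corners, and a bin records the minimum over the pixels whose footprint
covers it — what a ray cast at the bin angle would hit. Pointwise
`floor(atan2)` binning was rejected because at clinical radii a 1° sector
of the r ± 0.5 annulus frequently contains no lattice point at all, which
would make "every angle covered" and "pixels added at radius r" mutually
unsatisfiable.

An angle whose minimum distance exceeds *t* = *r* + 4 px (or that has no
edge) receives one synthetic ON pixel at distance *r*: among the four
lattice pixels around the exact polar point at the bin-centre angle, those
whose footprint covers the bin, the one with the smallest radial error
(ties to the smaller row, column). This keeps the radial error below half
a pixel for radii in the clinically relevant range (verified numerically
for r = 15…59) while guaranteeing the bin is covered afterwards.
Original edge pixels are never removed. Both constants follow the
pipeline's calibration: the acceptance bound r + 4 and the fill distance r.

## Inner-side segmentation

The frame is median-filtered, cropped to 2r around the centre, and
binarized at the ISODATA threshold shifted by +10 towards brighter tissue,
which biases the boundary into the wall rather than the speckled lumen.
The wall mask is closed with a 3×3 structuring element (sealing
speckle-flipped pin-holes through which the lumen component would leak; a
symmetric closing does not move a smooth boundary), and the inner artery
side is taken as the two-pixel boundary band of the OFF component
containing the centre. The band alone would carry a small outward bias:
median filtering of multiplicative noise at a step lowers the first wall
ring's order statistics, eroding the binarized boundary outward by a few
tenths of a pixel. The GVF substrate therefore weights the band (plus the
reconstructed pixels at full weight) by the gradient magnitude of the
log-compressed intensity: in the log domain speckle is additive with equal
variance on both sides of the step, so the magnitude ridge — and with it
the snake's equilibrium — sits on the true boundary.

**GVF.** The field (u, v) minimizes ∫ μ|∇u|² + |∇v|² + |∇f|²(|u−f_x|² +
|v−f_y|²), integrated by explicit time stepping from the raw gradient with
the diffusion stability bound 4·μ·dt ≤ 1 enforced (μ = 0.2, 80
iterations, dt = 1 by default). Zero iterations return the raw gradient.

**Snake.** A closed contour of 100 vertices, initialized as a circle of
1.2 r, evolves semi-implicitly: internal energy (tension α = 0.1,
rigidity β = 0.05) through the cyclic pentadiagonal system (I − γA)⁻¹
factored once, external force sampled bilinearly from the GVF field each
step with γ = 1.0, stopping when the largest vertex displacement drops
below 0.1 px or after 400 iterations. The sampled GVF vectors are
unit-normalized (standard practice for GVF snakes): the raw field decays
with distance and moves the contour by ~10⁻² px per step ten pixels from
the edge — below the convergence tolerance, so the contour would stall;
normalization gives a capture range independent of distance while the
bilinear interpolation still provides a smooth zero crossing, hence a
stable equilibrium, at the edge. On the canonical test (circle edge map
r = 30, init r = 40) the contour converges in ~40 iterations to mean
radius 30.06 px.

**Plaque area.** The faultless artery outline is the detected circle
(automatic) or a user polygon (semi-automatic; the result records which).
Plaque area is outline area minus contour area, each by the absolute
shoelace formula × (mm/px)²; a negative difference clamps to zero with a
flag rather than reporting negative burden.

## Synthetic phantoms

The artery phantom is a dark lumen disc (intensity 25) inside a bright
wall annulus (170, 8 px thick) on a mid-grey background (80), at 0.1 mm/px
— a 35 px default radius models a 7 mm carotid. A plaque bump is a
raised-cosine intrusion of the wall into the lumen (half-width 45°, depth
8–12 px in the test cohorts), giving ground-truth burdens of 1.5–3.5 mm²,
the clinically reported range. The shadow sector replaces everything
beyond the lumen boundary with a gentle radial ramp — removing the edge
without creating a new one, as an acoustic shadow does. Speckle is
multiplicative log-normal noise (clipped to [0, 255], mean-normalized), a
standard proxy for the granular interference of coherent imaging. The
generator returns the lumen polygon and the plaque area by pixel-counting
the analytic bump region.

The ECG phantom renders the sweep model described under gating, with a
triangular QRS glyph 7 columns wide, a full-height letter glyph, and
Gaussian intensity noise kept below the binarization threshold. The trace
baseline sits on the chart mid-row — also the centroid of the full-height
letter — so an occlusion boundary steps the ordinate only by the baseline
wiggle and does not mimic a QRS. The helper `random_ecg_spec` places
beats with a physiological minimum spacing and away from letter-occluded
and spacer columns: a beat drawn under the occlusion is unrecoverable from
the rendered chart by construction, so detectable placement is part of the
study conditions, not a concession.

**What the phantoms do not show.** No point-spread function, no depth
attenuation or focal zones, no tissue texture, no probe pressure
deformation, and circular cross-sections only. Passing the phantom
cohorts demonstrates the pipeline's internal contracts (exact registration,
reconstruction geometry, gating logic, snake convergence and unbiased area
measurement under speckle); it does not certify accuracy on clinical
recordings, where artery shape, surrounding part-circular structures and
operator-dependent image quality dominate.

## Evaluation cohorts and problem sizes

The acceptance script and end-to-end tests use: 20 phantoms for exact
shift recovery (|shift| ≤ 20 px); 50 phantom geometries reused across
speckle σ ∈ {0.1, 0.3, 0.6, 1.0} for detection (reusing geometries and
noise seeds across levels makes the noise fields nested, so the
degradation trend is measured paired rather than confounded by sampling);
50 shadowed phantoms for the reconstruction contract; 20 strip-chart
videos of 36 frames with 5–8 beats each for gating; 30 speckled plaque
phantoms (σ = 0.3, semi-automatic outline) for the median area error; and
30 shadowed high-noise phantoms (σ = 0.6) for the semi-automatic vs
automatic comparison, where the automatic path both initializes and
references the measurement from the Hough circle. Images are 128×128 px;
one full acceptance run takes ~20 s on one CPU.

## Known limitations

- The stitcher assumes the sweep width is a multiple of the scroll speed
  and `keep_left` equals the scroll speed; other geometries stay aligned
  only approximately (provenance remains exact).
- Circle-based detection and outline: non-circular or compressed arteries
  are out of scope, as is the image-stitching variant of side
  reconstruction.
- The snake has no balloon force; initialization must enclose the target
  boundary (the 1.2 r circle does, given a usable centre).
- `read_video` decodes frame directories and any container imageio can
  open without extra plugins; AVI support depends on an available decoder.
- Plaque areas below ~1 mm² at 0.1 mm/px approach the discretization
  limit of a 100-vertex contour and carry relative errors well above the
  cohort median.
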