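# Methods

## Model and assumptions

The pipeline assumes the inspection geometry it was designed for: a
static camera above a static pad, frames at a fixed interval, and a
fixed linear gray ↔ temperature calibration. Under these conditions
"foreground" is not what moves but what *changes intensity*: pad pixels
warm over the sequence while background pixels hold at ambient. Both
discriminating statistics are therefore temporal, computed per pixel
over a trailing window of n frames:

* history mean Ī_t — separates hot from ambient;
* history population variance S²_t — separates warming from static.

The foreground mask is the pointwise AND of the two thresholded images.
Either condition alone fails in characteristic ways: a mean threshold
alone admits any static hot object (reflections, the scale bar burned
into consumer-camera frames), a variance threshold alone admits flicker
noise. Thresholding uses ≥ throughout, so boundary equality counts as
foreground.

The window covers exactly n frames ending at the current index
(t−n+1 … t) with divisor n — self-consistent population statistics in
which n means the number of frames used. Variance is computed in the
difference-of-squares form and clamped at zero against round-off. By
default the *variance* image is thresholded rather than the standard
deviation: the squared statistic spreads the foreground and background
modes further apart and is the more sensitive discriminator; a `stddev`
mode is kept for when thresholds are more naturally expressed in gray
levels. All history statistics run on raw gray levels — the calibration
is affine, so the resulting mask is identical to one computed in °C,
and integer gray arithmetic is exact.

Classic frame differencing (|I_t − B_t| against a threshold, with the
recursive background update B_t = (1−α)B_{t−1} + αI_t) is provided as
the baseline primitive. The learning update is off by default (α = 0):
the inspection background is static, and learning is only warranted when
the background itself drifts.

## Threshold selection

No fixed threshold pair suits both an early window (pad barely above
ambient) and a late one (pad saturated), so the default is automatic:
Otsu's bimodal histogram split applied independently to the mean image
and the dispersion image, recomputed per window. This is deterministic
for fixed input and reproducible without hand tuning; both thresholds
can be overridden. A constant image has no split and raises an error
directing the caller to manual thresholds rather than guessing.

## Morphological repair

Raw intersection masks carry scattered one-to-few-pixel interior holes
(noise pushed individual pixels below a threshold) and isolated
background speckle. Repair is dilation–erosion–dilation with a square
all-ones element, default 3×3, iterated 3/6/3. The leading dilations
close holes up to ~6 px across; six erosions then annihilate any speckle
the dilations inflated (a lone pixel grows to 7×7 and shrinks
7→5→3→1→gone) and take the pad 3 px below its true boundary; the
trailing dilations restore the size. The schedule validates the
size-restoration identity dilate_pre + dilate_post = erode with a
warning, not an error — a deliberate net grow or shrink is occasionally
useful.

Dilation and erosion follow the set-theoretic definitions (dilation: the
reflected element overlaps ≥ 1 foreground pixel; erosion: the element
fits inside the foreground) and are executed by `scipy.ndimage`; a
hand-written brute-force oracle checks exact pixel-for-pixel agreement
in the tests. Pixels outside the image count as background for both
operations by default, so foreground touching the border erodes inward —
the conservative choice for a measurement mask. `border="replicate"`
switches erosion to the convention in which the outside counts as
foreground (a full mask stays full), matching common imaging libraries.

## Characteristics

All statistics run over included pixels only; an excluded pixel can
never set the minimum, shift the mean or occupy a histogram bin. The
histogram defaults to one bin per representable gray level mapped to °C,
so T_dom has the camera's quantization resolution (20/255 ≈ 0.078 °C at
8 bits). T_dom ties break toward the hotter bin: the tool screens for
burn risk, so it overestimates rather than underestimates. The
full-warming threshold τ_h defaults to 40 °C; it is an inspection-policy
knob, not a physical constant. The median is reported alongside the
moments because it is the more robust center under a skewed foreground.

In sequence mode the *measurement mask* defaults to the refined mask of
the last frame, where the pad is fully warmed, and that single mask is
applied to every frame to produce the time traces (mask selection from
the mask time-sequence is a manual/policy step; automating it is out of
scope). Frames whose foreground is empty yield flagged NaN records
rather than exceptions, so pre-warming frames cannot abort a run.

## Mask evaluation

Agreement between an obtained and an ideal mask is the maximum zero-mean
normalized cross-correlation (Pearson correlation of the two binary
images) over translations up to `max_shift` (default 0 — the rig is
static). This metric is bounded by 1, penalizes both false positives and
false negatives, and degrades gracefully toward 0 for unrelated masks;
Jaccard overlap at the best offset is reported alongside as the standard
segmentation metric. Degenerate constant masks correlate 1 with an
identical mask and 0 otherwise. `ideal_mask_from_reference` builds a
reference mask the way an annotator would start — gradient-magnitude
edges, flood fill from a seed bounded by them — with no manual touch-up
step.

## Synthetic scenes

The generator emulates the bench protocol: 13 frames at 5-minute
intervals, fixed 25–45 °C scale, 8- or 10-bit quantization, pad strictly
inside a 120×160 frame (scaled down from the 320×240 / 640×480 cameras
the protocol uses, to keep tests fast; the geometry is otherwise
faithful). Pad pixels follow exponential-saturation warming
T(t) = ambient + (plateau − ambient)(1 − e^(−t/τ)) with ambient 26 °C,
plateau 42 °C and τ = 15 min, so the pad is ~98 % saturated at the
60-minute mark — a rise-then-saturate trace. A serpentine "circuit"
overlay adds up to +1.5 °C along internal heater lines, scaled by the
same saturation fraction so the circuit pattern emerges only near full
warming. Per-pixel Gaussian sensor noise (default 0.3 °C, an order of
magnitude above industrial thermal cameras' nameplate accuracy) is added
before quantization. Three analytic shapes — ellipse, U-band, annulus —
stand in for abdominal, cervical and patellar pads; arbitrary polygons
are accepted. Lossy acquisition is emulated by JPEG round-tripping each
8-bit frame at a chosen quality.

What the generator does *not* model: spatial warming gradients within
the pad, conductive heating of the floor near the pad rim, camera drift,
and vignetting. Passing tests on these scenes therefore validates the
pipeline's mechanics — segmentation, repair, statistics, determinism —
not camera physics, and scores on real pads will be lower than the
near-perfect fixture scores.

## Numerical and design choices

* All image statistics in float64; gray levels ≤ 1023, so the
  difference-of-squares variance is exact to ~1e-10.
* Quantization is round-half-even with clipping to the representable
  range; temperatures quantize and recover within ±0.5 gray level.
* 10-bit frames live in uint16 TIFF containers with values ≤ 1023.
* Multi-channel inputs collapse to BT.601 luminance before validation.
* The pipeline is deterministic end to end: fixed scene seeds give
  bit-identical sequences, and repeated runs of `inspect` produce
  byte-identical CSV/JSON/TIFF outputs.
* Conventional-BGS adapters (CNT, GMG, GSOC, LSBP, MOG, KNN) are
  strictly optional; without the OpenCV backend they raise
  `BaselineUnavailableError`, and sweep commands record the skip in
  their report rather than passing silently. Their internals are
  third-party and only interface properties are asserted.

## Known limitations

* Automatic Otsu thresholds assume a bimodal image; scenes where the pad
  fills almost the whole frame, or windows taken entirely after
  saturation (low pad variance), weaken the variance split — visible in
  the fixtures as short-window (n = 3) masks scoring below long-window
  (n = 10) masks.
* The measurement mask is chosen by frame index, not automatically
  selected from the mask sequence.
* A cooling target (foreground *colder* than background) needs manually
  inverted logic; only the warming direction is built in.
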