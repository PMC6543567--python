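# Methods

## Scope and model

The package implements a desk-scale version of a smartphone urine-dipstick
reader for nephrotic-syndrome monitoring. It has four computational parts:
a synthetic strip-image generator (the test bench), the two-step
colorimetric pipeline (calibration, then measurement), the urine-protein
log with relapse/remission alerting, and agreement statistics. A phone
camera, GUI, reminders and provider messaging are out of scope; file
export stands in for result transmission.

## Synthetic imaging model

Frames are float RGB rasters on [0, 1]. A frame is painted as: uniform
gray background, near-white strip body, and rectangular reagent pads at
specified HSV colors (hue in degrees). The whole frame is then multiplied
channel-wise by illumination gains (the color cast) and clipped, and
i.i.d. zero-mean Gaussian noise is added per pixel and channel, clipped
again. Ground truth records the exact painted pad rectangle and the
pre-noise hue.

Defaults: 640×480 frame, vertical strip with a distractor pad (orange,
S 0.5) above a 60×60 protein pad (S 0.6, V 0.7); a 160×200 `compact`
variant with 36×36 pads serves Monte Carlo runs where rendering cost
dominates. Pad value 0.7 keeps pad pixels unclipped under exposure-
normalized casts up to ~1.25 relative gain. The fixture hue scale for the
five protein levels is 60/75/95/125/160° (negative → 3+), an invented but
self-consistent yellow→blue-green scale; the commercial strip's true hue
range is proprietary to its chemistry and is not claimed.

What the generator does **not** emulate: demosaicing and tone-mapping
nonlinearity, spatially varying illumination and shadows, perspective and
lens distortion, motion blur, and hue-dependent sensor noise. Passing
tests therefore demonstrate the pipeline's correctness and its averaging
behavior under the stated noise model, not end-to-end performance on real
phone imagery.

## Calibration

White balance is a diagonal model: gains g_c = mean(m)/m_c from the
white-sheet channel means m. This equalizes channel means by
construction and cancels any *multiplicative* cast exactly (up to
clipping); it cannot correct mixed or spatially varying illumination. A
channel mean ≤ 0.05 is rejected as unusable. The verification step reads
an unused strip's pad and passes iff |measured − reference hue| ≤
tolerance, boundary inclusive; tolerance defaults to 5°, large against
the ~15–30° level spacing of the fixture scale but small against a real
cast's uncorrected shift.

## Measurement pipeline

Per frame: apply gains → crop the guide rectangle → HSV. Pad detection
runs on the saturation plane: 3×3 median filter (the noise-reduction
step), convolution with a width-5 discrete Laplacian (−1 off-center,
+24 at center, zero-sum so uniform regions respond exactly zero),
|response| thresholded at 20 % of its maximum, 3×3 morphological closing,
8-connected components, area filter (default 80 px), and the component
whose centroid is nearest the ROI center wins (ties broken by label
order, so detection is deterministic). The pad "center" is the inner-half
rectangle of the component's bounding box; with a sharp step edge the
width-5 Laplacian localizes the box to within ±2 px of the painted pad.

Hue sampling draws 64 distinct pixels uniformly without replacement from
the center region with a per-frame seed derived from the configured seed
via a seed sequence, making a full 30-frame read a pure function of
(frames, config). Hues are averaged arithmetically, not circularly: the
reagent spans roughly 60–160°, far from the 0/360 wrap, and a guard
raises if any sampled hue comes within 20° of the wrap. The grand mean is
the unweighted mean of per-frame means.

Binning is half-open with boundaries assigned upward: hue < e1 →
negative, [e1,e2) → trace, [e2,e3) → 1+, [e3,e4) → 2+, ≥ e4 → 3+;
negative/trace → LOW, 1+ → MEDIUM, 2+/3+ → HIGH. Edges are fitted from a
titration table as midpoints of adjacent level mean hues — the simplest
boundary estimator consistent with per-level replicate measurements; it
requires all five levels present and strictly increasing means.

## Monitoring rules

The relapse rule (≥ 2+ for 3 consecutive days) and remission rule
(negative/trace for 3 consecutive days) are evaluated on *daily*
categories. Three decisions the clinical definition leaves open:

* multiple readings in one day collapse to the most severe category —
  conservative for relapse detection;
* a day with no reading breaks a run ("consecutive days" read literally);
* alerts are edge-triggered: an alert fires only on the first day its
  condition holds, so a sustained relapse produces one alert, not one per
  day.

Relapse and remission can never fire together (a day cannot be both HIGH
and LOW), and both rules depend only on the last three calendar days,
which the tests check by truncation equivalence and by exhaustive
comparison with a brute-force window scan over all 3^5 gap-free 5-day
patterns.

## Agreement statistics

Confusion matrices are reference-method rows × reader columns over the
ordered LOW/MEDIUM/HIGH categories. Cohen's kappa is computed under
unweighted, linear (Cicchetti–Allison, w_ij = 1 − |i−j|/(k−1)) and
quadratic (Fleiss–Cohen, w_ij = 1 − (i−j)²/(k−1)²) agreement weights,
with the Fleiss–Cohen–Everitt large-sample variance and a Wald interval
truncated above at 1. The implementation is cross-checked in the tests
against scikit-learn (point estimates) and statsmodels (SE and CI), and
the Wald interval against a 10,000-resample pair bootstrap; linear is the
default weighting.

`reconstruct_study_validation()` rebuilds the development-study
validation: three phones (two iPhone 7, one iPhone 6S) read 88 patient
urine samples also read by a Urisys 1100 machine; the 6S missed two
samples. The published per-device machine marginals (62/14/12, 62/14/12,
62/12/12) plus the per-sample discordance account — every phone misread
the same two machine-1+ samples as LOW and the same machine-2+ sample as
MEDIUM — fully determine the per-device matrices and the pooled 262-read
matrix with 253 concordant. Two reconstruction decisions:

* the published per-device app-side "high" count (12) contradicts the
  discordance account, which forces 11; the reconstruction follows the
  discordance account because it also reproduces the pooled 253/262, and
  the contradiction is recorded in the validation report's notes;
* the two samples missing on the 6S are taken to be machine-1+ samples
  the other phones read concordantly, the only choice consistent with
  that device's published medium count and the pooled total.

On this matrix the kappa family is 0.922 / 0.946 / 0.966 (unweighted /
linear / quadratic). The study's printed point estimate (0.91) is not
reproducible under any standard weighting — its weighting scheme and
pooling are unstated — so the package reports the whole family and treats
only the printed CI floor (0.85) as a checkable bound.

## Numerical choices and problem sizes

* Images are float64 throughout; PNG I/O quantizes to 8 bits, which
  perturbs hue by well under the 5° calibration tolerance.
* HSV conversion is scikit-image's hexcone transform; saturation-0 pixels
  get hue 0 by convention.
* The 1e-6° zero-noise hue round-trip bound reflects float64 RGB↔HSV
  arithmetic only.
* Monte Carlo suites use the compact layout: 200 seeded 30-frame reads at
  noise sd 0.02, 100-seed titration recovery at sd 2° ×20 reps, and a
  10,000-resample bootstrap — together about a minute of CPU.

## Known limitations

* Diagonal white balance cannot represent non-multiplicative or spatially
  varying casts; gains are estimated from a global mean, so a stained or
  shadowed sheet biases all reads.
* Detection assumes the pad is the dominant saturation structure inside
  the guide; heavily noisy, padless images can yield spurious components
  rather than a clean "pad not found".
* Arithmetic hue averaging limits the reader to reagents away from the
  red wrap; a circular-statistics variant would be needed otherwise.
* The alert engine evaluates calendar days only; time-of-day information
  is stored but never used by the rules.
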