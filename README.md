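# uristrip

Colorimetric reading of the protein pad on a urine reagent test strip,
relapse/remission alerting for nephrotic-syndrome home monitoring, and the
agreement statistics used to validate a camera-based reader against a
bench-top urinalysis machine.

Childhood nephrotic syndrome is managed at home with daily dipstick urine
protein checks: a relapse is signalled by urine protein ≥ 2+ on 3
consecutive days, remission by negative/trace readings on 3 consecutive
days. Reading the pad color by eye is error-prone; a smartphone camera can
instead measure the pad's hue and bin it to a semi-quantitative level.
This package implements that measurement pipeline, the clinical alerting
rules on top of the resulting log, and the validation statistics — with a
synthetic strip-image generator (known ground truth) standing in for the
camera so every stage is testable on a desk.

## The method

**Calibration.** The illumination's color cast is modelled as diagonal
per-channel gains. From a white-sheet image with channel means
(m_R, m_G, m_B), the gain for channel c is m̄/m_c where m̄ is the grand
mean, so the corrected sheet has equal channel means. The calibration is
verified by imaging an unused strip: it passes iff the measured pad hue is
within a tolerance (default 5°) of the dry reagent's reference hue.

**Measurement.** Each of 30 video frames is white-balanced, cropped to the
on-screen guide rectangle, and converted to HSV. The pad is located on the
saturation plane: a 3×3 median filter, a width-5 Laplacian, thresholding
of |response| at 20 % of its maximum, morphological closing, and selection
of the connected component (area ≥ minimum pad area) whose centroid is
nearest the ROI center. Within the inner half of the pad's bounding box,
64 pixel locations are drawn uniformly without replacement and their hues
(H-channel) averaged; the 30 per-frame means are averaged again, giving an
approximately normal estimate of the pad's mean hue H̄.

**Binning.** Titration measurements at known protein levels place four
monotone hue boundaries (each the midpoint of adjacent level mean hues);
H̄ is binned to negative | trace | 1+ | 2+ | 3+, reported to users as
LOW (negative/trace), MEDIUM (1+), HIGH (2+/3+).

**Alerting.** Days with several readings count as their most severe
category; a missing day breaks a run. Relapse (remission) alerts are
edge-triggered: they fire on the first day the 3-consecutive-day HIGH
(LOW) condition becomes true.

**Agreement.** Camera-vs-machine reads are cross-tabulated into a 3×3
confusion matrix; the package computes exact agreement and Cohen's kappa
κ_w = (P_o,w − P_e,w)/(1 − P_e,w) under unweighted, linear and quadratic
weights, with the Fleiss–Cohen–Everitt asymptotic standard error and a
Wald interval truncated at 1. `reconstruct_study_validation()` rebuilds
the development-study validation (88 patient urine samples, three iPhones
vs a Urisys 1100) from its published per-device marginals and per-sample
discordances and runs these statistics on it.

## Worked example

Simulate a strip video whose protein pad sits mid-2+ band (hue 125°),
calibrate, fit bin edges from a simulated titration, and read it:

```bash
uristrip simulate-strip --out sim --compact --level 2+ --noise-sd 0.01 --seed 7
uristrip calibrate --white sim/white.png --ref-strip sim/frame_000.png \
         --ref-hue 125 --out calib.json
uristrip fit-edges --titration titration.csv --out edges.json
uristrip read-strip --frames sim --guide 34,80,96,96 \
         --calib calib.json --edges edges.json --seed 1
```

The read prints (abridged):

```json
{
  "grand_mean_hue_deg": 124.98300693263558,
  "level": "2+",
  "category": "HIGH",
  "calibration_passed": true
}
```

The grand mean hue is within 0.02° of the rendered 125° despite per-pixel
noise, because 64 samples × 30 frames average it away; 125° falls in the
[109.7, 142.3) band of the fitted edges, hence level 2+, category HIGH.
Logging HIGH on three consecutive days then fires the relapse alert once:

```bash
for d in 2024-03-01 2024-03-02 2024-03-03; do
  uristrip log add --log log.csv --date $d --category HIGH --source camera
done
uristrip alerts --log log.csv --as-of 2024-03-03
# {"as_of": "2024-03-03", "relapse_alert": true, "remission_alert": false, "streak_days": 3}
```

`uristrip validate --study` reconstructs the three-phone validation:
exact agreement 253/262 (97 %), inter-device agreement 100 % on the 86
shared samples, and κ = 0.922 / 0.946 / 0.966 (unweighted / linear /
quadratic; linear 95 % CI 0.910–0.981). All three weightings are printed
because the original analysis does not state its scheme; the report also
records a small internal inconsistency in the published per-device
app-side "high" counts (see `docs/methods.md`).

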