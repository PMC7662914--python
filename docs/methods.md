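# Methods

This note documents the models and procedures implemented in `coralrhythm`,
the defaults and why they were chosen, what the synthetic fixtures do and do
not emulate, and the numerical choices that affect reproducibility.

## Imaging

**Enhancement.** Underwater observatory frames are dark and low-contrast.
`enhance_clahe` converts to CIELAB, runs contrast-limited adaptive histogram
equalization on the L channel only and copies the a/b chroma channels
through, so color identity — which the segmentation relies on — is
preserved. `clip_limit` follows the common "multiple of the uniform bin
height" convention (default 2.0, 8×8 tile grid) and is mapped internally to
scikit-image's clipping fraction. A battery of standard point/histogram
transforms (`gamma`, `log`, `sigmoid`, `hist_eq`, `rescale`) is included
only for method comparison.

**Segmentation.** The colony is isolated by an HSV gate: hue in
[0°, 25°] ∪ [340°, 360°], saturation ≥ 0.18, value ≥ 0.12 (all
configurable). The saturation bound is deliberately loose because adaptive
equalization brightens and desaturates the colony; on the synthetic fixtures
the gate reaches ≥ 0.98 foreground recall on mixed scenes (≥ 0.84 in the
worst near-uniform case) with a measured zero false-positive rate, both
before and after enhancement. A 3×3 median filter (reflect padding) removes
isolated mask specks. Masks are {0, 1} in memory and 0/255 PNG on disk.

## Supervision and patches

Manual supervision is represented by half-open, 0-based rectangular region
tags carrying one of three statuses. Per tagged region, 120 foreground and
40 background pixels (configurable) are sampled uniformly without
replacement; each labeled pixel becomes one 30×30 patch centered on it
(center at index 15; borders reflect-padded so counts are deterministic).
This expansion assumes the immediate neighborhood of a labeled pixel shares
its label — reasonable at the patch scale of a colony surface, wrong exactly
at status boundaries, which is the dominant error source in the map stage.
Augmentation is on-the-fly random horizontal/vertical flips and ±10%
translations with reflect fill.

## Patch classifier

The default `CnnSpec` is the full-width network: three blocks of two 3×3
ReLU convolutions (32-32, 64-64, 128-128 channels) with "same" padding, 2×2
max-pooling after each block's second convolution and dropout 0.25 per
block; dense 512 + dropout 0.5; dense 4-way softmax. With "same" padding the
spatial side goes 30 → 15 → 7 → 3 (floor pooling), so the flattened feature
has 3·3·128 = 1152 entries. Training: Adam (lr 10⁻⁴, β₁ 0.9, β₂ 0.999),
categorical cross-entropy, batch 256, 100 epochs, augmentation on.

The engine is a self-contained float32 numpy implementation (im2col
convolutions, explicit backward passes) with a finite-difference gradient
check in the test suite. Determinism is same-seed/same-build: one Generator
drives initialization, dropout and shuffling. `CnnSpec.reduced()` (8-8/16-16
channels, dense 64, same topology) is the variant used by the test suite and
the acceptance script; with it the fixture corpus trains to >95% holdout
accuracy in well under a minute on one CPU, which is the problem size the
shipped experiments use. Tests that exercise the reduced model use a higher
learning rate (10⁻³–2·10⁻³) because the narrow network trains in few epochs.

Evaluation reports the confusion matrix with **targets on rows**, overall
accuracy, per-class producer's accuracy (PA, = recall = diagonal / row sum)
and user's accuracy (UA, = precision = diagonal / column sum), and macro
one-vs-rest AUC from the softmax scores (the averaging scheme had to be
fixed; macro over classes is the choice). Cross-validation is stratified and
shuffled; the reported performance is the mean over validation folds.

## Whole-frame mapping and coverage

`segment_frame` slides the window (default 30 px, step 10) over the frame;
the status map lives on the stride grid, one cell per window position, with
grid dimensions `floor((H−w)/s)+1 × floor((W−w)/s)+1`. Because windows
overlap, each cell's anchor pixel (the center of its own window) is covered
by up to ⌈w/s⌉² windows; their softmax vectors are averaged before the
argmax. Ties break deterministically toward the more active class
(bloated > non-bloated > semi-bloated > background). With step = window the
procedure reduces exactly to independent per-window classification, which
the tests assert. Coverage percentages are computed over coral
(non-background) grid cells only; an all-background map is returned as
(0, 0, 0) with an explicit empty flag. Counting grid cells rather than
upsampled pixels is a documented design choice: it is faithful to the
stride-10 map and cheap.

**Chlorophyll calibration.** Fluorescence is converted to chlorophyll-a by
the sensor's affine day/night calibration (day: 1.050·fl + 1.0129; night:
0.963·fl + 0.2159), with the day window [dawn, dusk) defaulting to
06:00–21:30 (mid-deployment astronomical times for the northern-Norway
site), configurable.

**Compilation.** One row per frame; sensor values joined by nearest
timestamp within a 30-min tolerance (no interpolation — sensor gaps must
survive as gaps); duplicate frame timestamps are an error.

## Chronobiology statistics

**Periodogram.** Classical Lomb–Scargle, computed on an evenly spaced
period grid (default 1-min steps over 600–1620 min, i.e. 10–27 h — a band
covering semidiurnal and diurnal tides plus the day–night cycle; the 1-min
grid resolves peaks a few minutes apart). Power is normalized to the
fraction of total variance explained and displayed as a percentage.
Missing values are dropped; irregular sampling is handled natively; at
least 48 finite samples are required; a constant series returns zero power
and a flag.

Significance: the single-frequency null tail of the variance fraction z is
Beta-distributed, P(> z) = (1 − z)^((N−3)/2). The band-wide false-alarm
probability multiplies in a Davies-bound term for the maximum over the
scanned band, τ(z) ∝ W·(1−z)^((N−4)/2)·√(N·z/2) with W the bandwidth times
the effective timespan √(4π·var(t)). This stays calibrated on densely
oversampled grids, where a naive independent-frequency (Šidák) correction
with M = Δf·T under-counts trials: measured white-noise false-alarm rates
at α = 0.05 are ≈ 0.05 (vs ≈ 0.12 for the naive correction). The α-level
power threshold is found by bisection on the same expression.

**Waveform.** Values are folded by clock time into a 24-h cycle of 60-min
bins (offset configurable so HH:30 samples can sit mid-bin), giving per-bin
mean, SD and n. The MESOR is the mean of the non-empty bin means — exactly
the global mean when every bin has equal n. The phase is the set of bins
strictly above the MESOR ("strictly" so a constant series has an empty
phase); `phase_intervals` reports maximal contiguous runs modulo 24, which
may wrap midnight, with singleton bins as degenerate one-hour intervals.
Monthly summaries are calendar-month mean/SD/n with pairwise missing-value
exclusion.

## Multivariate behavior model

The response is bloated coverage binarized at 50% (≥ 50 → 1). The base
block is (time of day as a unit fraction of 24 h, chlorophyll, temperature,
depth, turbidity, salinity, binary FOV dummy), in that frozen order.
Continuous columns are standardized; the expansion enumerates every unique
monomial of degree ≤ 3 — 119 over seven columns, verified against
brute-force enumeration — degree-ascending, then lexicographic by
provenance tuple. Powers of the binary dummy collapse (FOV² = FOV),
leaving 111 distinct columns. "The first k columns" is well-defined only
because this order is frozen. k itself is chosen where the cross-validated
RMS error curve over candidate counts is minimal, with a reduced inner
iteration budget for the selection runs.

**Partition.** The 70/30 train/test split is the deterministic
Kennard–Stone maximin procedure on Euclidean distances: seed with the two
most distant points, then repeatedly add the point with the largest minimal
distance to the selected set; ties resolve to the lowest index. Distances
are measured on a whole-set-standardized copy (geometry needs commensurable
axes before a training set exists); the modelling standardization is then
re-fit on the training partition only and applied to the test partition —
the test suite asserts the absence of leakage.

**Network and training.** A single hidden layer of 9 sigmoid nodes and a
2-way softmax output. The objective is βE_D + αE_W with E_D the half sum of
squared output residuals and E_W the half squared weight norm, minimized by
L-BFGS with a 10⁻¹⁰ gradient threshold and a 500-iteration budget split
over outer evidence updates. α is re-estimated each outer round from the
Gauss–Newton Hessian (effective parameter count γ = N_w − α·tr(H⁻¹),
α ← γ/2E_W). β is held fixed at 1 by default: this is the classification
form of the evidence framework — 0/1 targets behind a softmax have no free
noise variance, and letting β float rewards driving residuals to zero,
i.e. memorizing label noise (observed directly: with the joint update the
net reaches near-zero training error while test precision drops ~0.05
below the Bayes-optimal rule of the generating model; the fixed-β form
sits at the oracle with γ ≈ 45 effective parameters out of ~1100).
`noise_update=True` restores the joint (α, β) regression-style update; an
ill-conditioned evidence step falls back to a fixed weight decay and is
recorded on the model.

**Reporting.** Precision and recall are computed for the bloated (positive)
class from the confusion matrix with targets on rows, and additionally
truncated — not rounded — to three decimals where printed, matching the
reporting convention of the contingency metrics. `interval_error_summary`
describes where errors sit relative to the ambiguous 20–80% coverage band.
Feature importance of a trained model is the per-column maximum of
|hidden weights|, descending, ties by column index, top 15 with provenance
labels. The sigmoid activation profile sorts observations by bloated
coverage, smooths the standardized covariate with a centered moving average
(shrinking windows at the edges — zero-padding would bias the profile ends
toward σ(0)), maps through the logistic function and reports the Pearson
correlation with the sorted coverage.

## Synthetic fixtures

`fixtures` exists so that every stage is testable without observatory data.

**Scenes.** Colony regions are rectangles filled with status-specific
textures on a dark (value < 0.12) bluish background: bloated = bright red
base plus Poisson-disk near-white dots (extruded polyps catching the lamp),
non-bloated = 0.6× darker red, Gaussian-smoothed, semi-bloated = 10-px
checkerboard tiling of the two. Ground truth is exact by construction, and
generation is byte-deterministic per seed. `scene_for_coverage` splits a
single colony rectangle into vertical status bands matching requested
percentages, which turns a behavioral series into a frame sequence with
known truth. An optional global brightness jitter emulates lamp flicker;
nothing else about underwater optics is modeled.

**Series.** Hourly timestamps; bloated% = MESOR + amplitude·cos with a
default peak at 21.5 h (dusk), amplitude 30%, Gaussian noise SD 5%, clipped
to [0, 100]; the remainder splits 55/45 between non-bloated and
semi-bloated, making both antiphase to the bloated rhythm with semi-bloated
the minor component. Depth is a ~12.4-h (745-min) sinusoid around 250.1 m
(amplitude 1.05 m); temperature, salinity, turbidity and chlorophyll
fluorescence get realistic means, mild cycles and sensor noise;
chlorophyll's diel component shares the behavioral phase (fresh
phytodetritus arriving on the day–night cycle). Gap windows blank the
sensor columns only. A binary FOV dummy flips at random epochs.

**What passing fixture tests do not show.** The textures are far more
separable than real colony imagery, so classifier accuracies on fixtures
say nothing about accuracy on real frames — they validate the machinery
(data flow, training loop, map aggregation, statistics), not field
performance. Real series also contain non-sinusoidal rhythm shapes,
weather-band variability and camera repositioning events that the generator
does not emulate.

## Problem sizes used by the shipped experiments

The test suite and the acceptance script run the pipeline at desk scale,
chosen as the package's own experiment design: 256×256-px scenes, six
training frames per corpus, 60/20 sampled pixels per region (~1440
patches), the reduced network for 10–15 epochs; 30-day hourly series for
rhythm statistics; 1000 white-noise simulations for the false-alarm
calibration; n = 1500 series and five seeds for the multivariate recovery
experiment. The full-width network and the published training settings
remain the library defaults for real data.

## Known limitations

- Training determinism is same-seed/same-BLAS; across BLAS builds,
  reductions may reorder and flip rare argmax ties.
- The evidence framework uses the Gauss–Newton Hessian; far from a minimum
  the γ estimate is rough (mitigated by interleaving updates with L-BFGS
  convergence).
- Status-boundary windows genuinely contain mixed textures; cell-level
  agreement near boundaries is capped regardless of classifier quality.
- The Kennard–Stone partition is O(n²) in memory (fine to ~10⁴ rows).
- `sigmoid_profile` inherits the arbitrariness of its smoothing window; r
  values should be compared only at a fixed window.
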