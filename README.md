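# coralrhythm

Behavioral-rhythm extraction for sessile deep-sea fauna monitored by cabled
observatory cameras.

Cold-water corals such as the bubblegum coral *Paragorgia arborea* expose a
visible behavioral state: polyps fully extruded (**bloated**, a proxy for
filter feeding), fully retracted (**non-bloated**), or a transient spatial mix
(**semi-bloated**). Time-lapse cameras on seafloor observatories record this
continuously, but turning thousands of dark underwater frames into an
analyzable behavioral time series — and relating it to co-registered
oceanographic sensors — requires an automated pipeline. `coralrhythm`
implements that pipeline end to end:

1. **Enhancement** — contrast-limited adaptive histogram equalization (CLAHE)
   applied to the CIELAB luminance channel only, so the hue used for
   segmentation is untouched.
2. **Foreground segmentation** — an HSV red-hue mask plus a 3×3 median filter
   isolates the colony from the dark seafloor.
3. **Supervised tagging** — rectangular region tags carry the activity
   status; within each tagged region, 120 foreground and 40 background pixels
   are sampled and each is expanded into a labeled 30×30 patch centered on it
   (the *Patches-GT* strategy: local label homogeneity).
4. **Patch classification** — a six-convolution CNN
   (3×3 kernels, channel widths 32-32 / 64-64 / 128-128, 2×2 max-pooling and
   dropout 0.25 per block, dense 512 + dropout 0.5, 4-way softmax) trained
   with Adam (lr 10⁻⁴, β₁ 0.9, β₂ 0.999), categorical cross-entropy, batch
   256, flip/shift augmentation; evaluated by stratified 10-fold CV and a
   70/30 holdout with per-class producer's/user's accuracy (PA/UA) and macro
   one-vs-rest AUC. Implemented as a self-contained numpy engine.
5. **Whole-frame mapping** — the classifier slides over each frame (window
   30, step 10); overlapping windows' softmax vectors are averaged per grid
   cell, yielding a status map from which per-status coverage percentages of
   the colony are computed.
6. **Series compilation** — coverage percentages joined with
   temperature, salinity, turbidity, chlorophyll fluorescence (calibrated to
   chlorophyll-a by day/night affine coefficients) and depth records by
   nearest timestamp.
7. **Chronobiology statistics** — Lomb–Scargle periodogram over the
   600–1620 min band (power as % of variance explained, Baluev-style
   false-alarm significance), and waveform analysis: fold into 24-h segments,
   average per clock hour, report the MESOR (re-average of the hourly means)
   and the rhythm's phase as the maximal above-MESOR hour intervals.
8. **Multivariate behavior model (MLFN)** — bloated coverage binarized at
   50%; seven predictors (time of day, chlorophyll, temperature, depth,
   turbidity, salinity, a binary field-of-view dummy) standardized and
   expanded into all unique monomials of degree ≤ 3; feature count chosen by
   the cross-validated RMS curve; deterministic Kennard–Stone (maximin
   Euclidean) 70/30 partition; a single hidden layer of 9 sigmoid nodes with
   2-way softmax output trained by Bayesian-regularized least squares
   (evidence-framework weight decay); precision/recall, confusion matrices,
   hidden-weight feature importance, and sigmoid activation-profile
   correlations.

Because observatory imagery is rarely redistributable, the package ships a
first-class synthetic fixture module (`coralrhythm.fixtures`) that generates
ground-truthed colony frames (status-specific textures) and rhythmic
multiparametric series (24-h behavioral rhythm, ~12.4-h tidal depth cycle,
sensor noise and gaps), so every stage is testable offline.

## Worked example

```python
import numpy as np
from coralrhythm import SeriesSpec, generate_series, lomb_scargle, waveform, phase_intervals
from coralrhythm.mlfn import fit_activity_model

ser = generate_series(SeriesSpec(n_hours=720, rhythm_peak_hour=21.5,
                                 rhythm_amplitude=30, noise_sd=5, seed=1))
res = lomb_scargle(ser["bloated_pct"])
period, power, p = res.top_peak
print(f"dominant period: {period:.0f} min ({power:.1f}% of variance, p = {p:.1e})")

wf = waveform(ser["bloated_pct"])
print(f"MESOR: {wf.mesor:.2f}%  phase: {phase_intervals(wf)}")

fit = fit_activity_model(ser, k=14, seed=0)
print(fit.summary())
```

prints

```
dominant period: 1440 min (94.9% of variance, p = 0.0e+00)
MESOR: 49.70%  phase: [(15, 3)]
MLFN activity model: k=14 features, 9 hidden nodes, Bayesian regularization
train n=504  P=0.961  R=0.954  bad=22 (4.4%)
test  n=216  P=0.913  R=0.969  bad=12 (5.6%)
top features: hour_frac^2, hour_frac, hour_frac*salinity, chlorophyll, hour_frac*fov
```

The periodogram finds the injected circadian period (1440 min) and the
waveform phase `(15, 3)` is the block of clock hours 15:00–03:00 whose mean
coverage lies above the MESOR — a dusk-centered activity peak wrapping
midnight. The behavior model recovers the rhythm-dominated structure: time
of day and chlorophyll carry the largest hidden weights.

## Command-line pipeline

Each stage is also a CLI step over a YAML config (defaults follow the
published settings; every run writes a JSON run record with a config hash):

```sh
coralrhythm simulate  --config cfg.yaml   # synthetic frames + sensor series
coralrhythm all       --config cfg.yaml   # enhance -> tag-sample -> build-patches
                                          # -> train -> evaluate -> map -> compile
                                          # -> periodogram -> waveform -> mlfn
```

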