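# pulsepol

Single-particle polarized light scattering + fluorescence pulse analysis
for phytoplankton and cyanobacteria monitoring.

Flow-through optical instruments for harmful-algal-bloom surveillance
record each particle transit as a brief pulse on four polarization
channels and one chlorophyll-fluorescence channel. `pulsepol` implements
the complete analysis chain for such signals:

1. **Calibration** — estimate the 4×4 instrument matrix *A* mapping the
   measured channel intensities to the Stokes vector,
   *S* = (*I*, *Q*, *U*, *V*)ᵀ = *A* · (*I₁*, *I₂*, *I₃*, *I₄*)ᵀ,
   by least squares over reference states measured with a polarimeter.
2. **Pulse processing** — segment particle transits from the raw stream
   (median/MAD baseline, σ-threshold runs), convert each window to a
   Stokes-domain trace with the normalized components *q* = *Q*/*I*,
   *u* = *U*/*I*, *v* = *V*/*I*, one degree of polarization
   DOP = √(q̄² + ū² + v̄²) ∈ [0, 1] per particle, and one mean
   fluorescence *F*.
3. **Features** — per particle, the six pulse averages
   (Ī, q̄, ū, v̄, DOP, *F*) plus eight statistics (peak-to-peak, variance,
   standard deviation, RMS, skewness, kurtosis, waveform factor
   S = rms/μ, clearance factor L = peak/μ²) of each of the four
   Stokes-domain traces *I*, *q*, *u*, *v* — a 38-dimensional
   feature-enhanced vector, or the 6-dimensional average-only baseline.
4. **Classification** — a backpropagation perceptron with five hidden
   layers (64-128-256-128-64), trained on z-scored features with a
   stratified 60/20/20 train/validation/test split, early stopping on
   validation loss, and confusion-matrix evaluation
   (accuracy = (TP+TN)/(TP+FP+TN+FN) per class, trace/total overall).
5. **Composition** — per-sample category proportions, removal of
   non-algal suspended matter with renormalization to the three phyla,
   dominant (> 10 %) / common (1–10 %) species labeling, and Pearson
   correlation *r* = Cov(x, y)/√(Var(x)·Var(y)) against bulk proxies
   such as chlorophyll-a.

Because real instrument recordings are rarely shareable, the package
includes a synthetic instrument **simulator** (Poisson arrivals,
skew-normal transit envelopes, species archetypes with known Stokes
responses, a known instrument matrix, relative detector noise) that
provides ground truth for every stage.

## Worked example

Averages versus pulse-shape features on a panel of three archetypes that
share identical mean Stokes responses and differ only in within-transit
jitter and envelope asymmetry (`examples/04_pac_vs_pfec.py`):

```
pulse-average (6 features)    test accuracy: 0.337
feature-enhanced (38 features) test accuracy: 0.983
improvement: 64.7 accuracy points
```

Chance level for three balanced classes is 0.333: the average-only model
has nothing to work with by construction, while the pulse-shape
statistics (trace standard deviations, skewness, …) recover the class
structure almost completely. The other scripts in `examples/` walk
through calibration (0.5 % channel noise → 0.78 % matrix error),
detection (recall 0.995, precision 1.000 at default thresholds), feature
extraction, and composition reporting.

The same pipeline is scriptable from the shell:

```bash
pulsepol simulate  --duration 200000 --seed 1 --out-dir run/
pulsepol calibrate --cal-csv run/calibration.csv --out run/A.json
pulsepol extract   --stream run/stream.csv --truth run/truth.csv \
                   --matrix run/A.json --mode pfec --out run/features.csv
pulsepol train     --features run/features.csv --out run/model.joblib
pulsepol classify  --features run/features.csv --model run/model.joblib \
                   --out run/predictions.csv
pulsepol report    --predictions run/predictions.csv --drop other_spm
```

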