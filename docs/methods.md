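# Methods

This note documents the models, estimators, defaults, and numerical
policies behind `pulsepol`, and what the synthetic data used in the test
suite does and does not establish about real instrument recordings.

## Measurement model

A flow-through analyzer splits backscattered light from one particle
into four polarization channels and one fluorescence channel. The
channel intensities relate linearly to the Stokes vector of the light,

&nbsp;&nbsp;&nbsp;&nbsp;S = (I, Q, U, V)ᵀ = A · (I₁, I₂, I₃, I₄)ᵀ,

where A is the 4×4 instrument matrix. The normalized components
q = Q/I, u = U/I, v = V/I each lie in [−1, 1] with q² + u² + v² ≤ 1 for
physical light, and the degree of polarization is
DOP = √(q² + u² + v²) (0 unpolarized, 1 fully polarized). The scattering
volume is assumed small enough that at most one particle occupies it at
a time, so each transit is a clean pulse.

## Calibration estimator

Given n ≥ 4 calibration pairs (reference Stokes vector Sₖ, measured
components mₖ), the instrument matrix is the ordinary least-squares
solution of min_A Σₖ ‖Sₖ − A mₖ‖². With exactly four full-rank states
this reduces to A = S M⁻¹ (stacked matrices); with more states the
pseudo-inverse averages down channel noise. Degenerate state sets
(rank < 4) and fewer than four states are rejected. The estimate carries
its condition number as a diagnostic; matrices with condition number
above 10⁸ are refused as effectively singular.

Physicality handling after applying A: samples whose intensity is
non-positive are dropped; samples whose (q, u, v) norm exceeds 1 are
clipped radially to the unit ball and counted in a QC log. Noise makes
both occur; silently keeping them would bias the per-pulse DOP.

## Pulse detection and Stokes traces

Detection runs on one trigger channel (I₁). The baseline is the channel
median and the noise scale 1.4826 × MAD, both robust to the pulses
themselves; runs above baseline + 5σ (default) that are at least 5
samples long and separated by at least 3 samples become pulse windows,
padded outwards to the nearest near-baseline samples. For noise-free
synthetic records (MAD = 0) the scale falls back to a small fraction of
the record's dynamic range so thresholding remains meaningful. Windows
are 0-based and half-open everywhere.

Each window is baseline-subtracted per channel, mapped through A per
sample, and normalized sample-wise. Samples with intensity below 10 % of
the pulse peak (default) are excluded from the normalized traces:
division by small I has unbounded relative error, and the tails
contribute noise, not signal. The per-pulse DOP uses the
intensity-weighted means of q, u, v rather than the mean of per-sample
DOPs — the per-sample DOP of noisy data is biased upward (a norm of a
noisy vector), while the weighted mean suppresses exactly the unstable
low-intensity samples. Fluorescence F is the plain baseline-subtracted
window mean (the whole fluorescence pulse is deliberately collapsed to
one number).

## Feature definitions

For a per-sample trace X of length N, with μ its mean and population
(1/N) moments throughout (no Bessel correction):

| statistic | formula |
|---|---|
| peak-to-peak | max(X) − min(X) |
| variance | (1/N) Σ (Xᵢ − μ)² |
| standard deviation | √variance |
| RMS | √((1/N) Σ Xᵢ²) |
| skewness | (1/N) Σ (Xᵢ − μ)³ / std³ |
| kurtosis | (1/N) Σ (Xᵢ − μ)⁴ / std⁴ |
| waveform factor S | RMS / μ |
| clearance factor L | peak-to-peak / μ² |

The clearance factor divides by the *squared mean*; this non-standard
form is the definition this pipeline standardizes on, with the
conventional peak/RMS variant available behind a flag. The 38-entry
feature-enhanced vector is the six averages (Ī, q̄, ū, v̄, DOP, F — plain
trace means) followed by the eight statistics of each Stokes-domain
trace I, q, u, v, in a fixed documented column order. The statistics are
computed on the Stokes-domain traces, not the raw channels: the
calibrated traces are instrument-independent, which is the point of
calibrating first.

Degenerate traces (constant, or zero-mean) make some statistics
undefined; they are imputed with their degenerate-signal limits
(skewness 0, kurtosis 3, S = 1, L = 0) and counted in a `qc_imputed`
column, because the classifier requires finite inputs and an imputed
limit is less distorting than an arbitrary sentinel.

## Classifier

A multilayer perceptron with five hidden layers of 64, 128, 256, 128,
64 rectified-linear units, softmax cross-entropy loss, and an
adaptive-moment optimizer (learning rate 10⁻³, batch size 64). Features
are z-scored with training-split statistics only — the feature scales
span orders of magnitude (intensities vs bounded ratios) and unscaled
training does not converge reliably. The labeled table is split
60/20/20 into train/validation/test, stratified by label and
seed-deterministic. Training proceeds one epoch at a time; after each
epoch the validation cross-entropy is measured, and the weights with the
lowest validation loss are restored at the end (early stopping, patience
20, at most 300 epochs by default). The network is built on
scikit-learn's `MLPClassifier` driven by this explicit validation loop.
Argmax ties break toward the lowest class index for determinism.
Evaluation reports the full confusion matrix (rows actual, columns
predicted), overall accuracy trace/total, and per-class one-vs-rest
TP/FN/FP/TN with the binary accuracy (TP+TN)/total.

The average-vs-enhanced comparison (`compare_pac_pfec`) featurizes the
*same* particles both ways and reuses the *same* partition row indices,
so any accuracy difference is attributable to the feature set alone.

## Synthetic instrument simulator

The simulator is the package's ground-truth source, not a physics model:
archetypes are phenomenological (no Mie/Mueller scattering from cell
geometry). One transit is a skew-normal bell in time whose window covers
the central 99 % of the distribution's mass for any asymmetry — the
width parameter alone controls effective transit duration, and the
asymmetry parameter changes only the profile shape. Per particle, the
peak amplitude is log-normal, the pulse-mean Stokes state is drawn
around the archetype mean with a particle-to-particle dispersion, and
per-sample states fluctuate around that pulse mean with a separate
within-transit jitter (modeling orientation/trajectory changes during
the transit); sampled states are clipped back to the physical unit ball,
so the generated DOP never exceeds 1 before noise. Channel-space records
are synthesized through A⁻¹ of a known instrument matrix so the
calibration pathway is exercised end to end; noise is multiplicative
log-normal (relative scale), reflecting detector gain noise and keeping
intensities positive. Streams draw a Poisson particle count at low
occupancy; overlapping transits are rejected by default (the
single-particle regime) and summed only under an explicit coincidence
flag. All randomness flows through one explicit seeded generator.

The instrument publishes no sampling rate, transit statistics, or SNR,
so the defaults (transit width 40 samples, 15 % width dispersion, 2 %
relative noise, arrival rate 0.002 particles/sample) are package
choices exposed as configuration — they are plausible for a flow-through
prototype but must not be read as measured values. Calibration-set noise
is multiplicative Gaussian at 0.5 % by default, matching the precision
class of commercial reference polarimeters.

Two named panels are provided. `demo_panel()` gives four contrasting
categories (green algae, diatoms, cyanobacteria, mineral/plastic
particles) for end-to-end demonstrations. `shape_contrast_panel()` gives
three archetypes with *identical* mean Stokes responses, dispersions,
fluorescence, and width statistics, differing only in within-transit
jitter and envelope asymmetry: by construction the six pulse averages
carry no class information, isolating what the pulse-shape statistics
contribute.

**What passing tests show — and do not.** On simulator data the pipeline
recovers known matrices, known Stokes states, known mixtures, and known
shape contrasts. That validates the estimators and the plumbing. It does
not establish classification accuracy on real organisms: real pulse
shapes, spectral cross-talk, aggregation, debris, and instrument drift
are all outside the generator. Accuracy figures on synthetic panels
measure the panel's separability, nothing more.

## Problem sizes

The test suite and example scripts use streams of 10⁵–1.5×10⁵ samples
(a few hundred particles), classifier datasets of 450–1,800 particles
with 40–60 training epochs, and 100-replicate calibration ensembles —
sizes at which every stochastic check is stable under its stated
tolerance while the full suite stays fast.

## Known limitations

- Coincident particles are flagged/rejected, never deconvolved.
- The fluorescence channel is modeled as a scaled copy of the intensity
  envelope; real chlorophyll fluorescence saturates and bleaches.
- Class-imbalance handling is limited to what the balanced-panel design
  needs; strongly imbalanced field data would need reweighting or
  resampling ahead of `train_classifier`.
- No absolute cell densities: proportions only, plus the correlation
  utility for relating them to external density or chlorophyll-a
  measurements.
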