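"""Simulate a raw particle stream and segment the transit pulses.

Particles arrive at Poisson times and each imprints a bell-shaped pulse on
the four polarization channels and the fluorescence channel.  Detection
estimates the baseline robustly and returns one window per particle, which
the ground-truth table lets us score.
"""

import pulsepol as pp

A = pp.default_instrument_matrix()
panel = pp.demo_panel()

stream = pp.simulate_stream(
    panel, mixture=[0.25] * 4, duration=100_000, arrival_rate=0.002,
    A_true=A, noise_level=0.02, baseline_level=0.01, seed=42,
)
print(f"stream: {stream.n_samples} samples, {len(stream.truth)} true particles")

records = pp.detect_pulses(stream, threshold_sigma=5.0, min_width=5, min_gap=3)
labels = pp.assign_labels(records, stream.truth)
matched = sum(lab is not None for lab in labels)
print(f"detected {len(records)} pulses; {matched} match a truth window")
print(f"recall    = {matched / len(stream.truth):.3f}")
print(f"precision = {matched / len(records):.3f}")

# Each detected pulse becomes a calibrated Stokes trace with one DOP and
# one fluorescence value per particle:
trace = pp.to_stokes_trace(records[0], A)
print(
    f"first pulse: {trace.n_samples} samples, "
    f"qbar={trace.means[1]:+.3f}, DOP={trace.dop:.3f}, F={trace.F:.3f}"
)
# Recall/precision near 1 means the segmentation recovers essentially every
# simulated transit without spurious detections at this noise level.
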