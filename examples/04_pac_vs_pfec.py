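"""What do pulse-shape features add over pulse averages?

Three archetypes share identical mean Stokes responses, dispersions,
fluorescence and transit-width statistics; they differ only in
within-transit jitter and envelope asymmetry.  Averages cannot separate
them — the trace statistics can.  Both feature sets are fed to the same
five-hidden-layer backpropagation network on identical 60/20/20 splits.
"""

import numpy as np

import pulsepol as pp
from pulsepol.simulator import shape_contrast_panel

A = pp.default_instrument_matrix()
panel = shape_contrast_panel()
rng = np.random.default_rng(7)

traces, labels = [], []
for i in range(1500):
    pulse, label = pp.simulate_pulse(panel[i % 3], A, noise_level=0.02, seed=rng)
    traces.append(pp.to_stokes_trace(pulse, A))
    labels.append(label)

cfg = pp.MLPConfig(epochs=60, patience=10, seed=0)
res = pp.compare_pac_pfec(traces, labels, cfg, pp.SplitSpec(seed=0))

print(f"pulse-average (6 features)    test accuracy: {res['pac'].accuracy:.3f}")
print(f"feature-enhanced (38 features) test accuracy: {res['pfec'].accuracy:.3f}")
print(f"improvement: {100 * res['overall_delta']:.1f} accuracy points")
print("\nper-class recall deltas (enhanced minus average):")
for cls, d in res["class_deltas"].items():
    print(f"  {cls:8s} {100 * d:+.1f} points")
# Chance level for three balanced classes is 33%.  The average-only model
# hovers near it by construction; the pulse-shape statistics recover the
# class structure almost completely.
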