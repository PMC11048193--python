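"""From per-particle predictions to a water-sample composition report.

Counts per category become proportions; removing the non-algal suspended
matter and renormalizing gives three-phyla proportions comparable with
microscopy; species proportions of the algal fraction are labeled dominant
(> 10%) or common (1-10%); and a Pearson correlation relates proportions
to an external bulk measurement.
"""

import numpy as np

import pulsepol as pp

categories = ["cyanophyta", "bacillariophyta", "chlorophyta", "other_spm"]
rng = np.random.default_rng(5)
mixture = [0.33, 0.06, 0.09, 0.52]
predictions = rng.choice(categories, size=5000, p=mixture)

comp = pp.summarize_composition(predictions, sample_id="site-1",
                                categories=categories)
print("sample composition:")
for cat, p in comp.proportions.items():
    print(f"  {cat:16s} {100 * p:5.2f}%  ({comp.counts[cat]} particles)")

phyla = pp.renormalize_phyla(comp, {"other_spm"})
print("\nthree phyla after removing non-algal particles:")
for cat, p in phyla.proportions.items():
    print(f"  {cat:16s} {100 * p:5.2f}%")

species = {"N20": 0.45, "N8": 0.12, "N19": 0.08, "N10": 0.02, "N12": 0.004}
print("\ndominance of the algal fraction:")
for lab in pp.label_dominance(species):
    print(f"  {lab.species:4s} {100 * lab.proportion:5.1f}%  -> {lab.status}")

# correlation of a category proportion with a bulk proxy across sites
proportion = np.array([0.33, 0.27, 0.13, 0.05, 0.39, 0.27, 0.08, 0.05])
density = 1e6 * proportion * rng.uniform(0.8, 1.25, size=8)  # cells / L
res = pp.pearson_r(density, proportion)
print(f"\nPearson r between density and proportion: {res.r:.3f} (n={res.n})")
# r near 1 indicates the classifier-derived proportion tracks the
# independent density measurement linearly across sites.
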