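"""Spatial organisation metrics: neighbourhood complexity and purity.

For every cell, complexity counts the distinct cell types within 100 µm
and purity measures the share of the most abundant type.  Comparing the
histograms of these statistics between a prediction and the ground truth
(Jensen–Shannon distance) quantifies how well an annotation preserves
tissue architecture, independently of per-cell accuracy.
"""

import numpy as np

from spatype import generate_synthetic_pair, histogram_js, neighborhood_metrics

_, spatial = generate_synthetic_pair(dropout_rate=0.0, seed=1)
truth = np.array(spatial.labels)

comp, pur = neighborhood_metrics(spatial.coords, truth, radius=100.0)
print(f"complexity: mean {comp.mean():.2f} (a 100 µm ball spans a band and its edges)")
print(f"purity:     mean {pur.mean():.2f}")

# corrupt 10% of labels and measure the architectural distortion
rng = np.random.default_rng(0)
noisy = truth.copy()
flip = rng.random(len(noisy)) < 0.1
noisy[flip] = rng.choice(sorted(set(truth)), flip.sum())
comp_n, pur_n = neighborhood_metrics(spatial.coords, noisy, radius=100.0)

print(f"JS distance (complexity), truth vs 10%-corrupted: "
      f"{histogram_js(comp, comp_n, kind='complexity'):.3f}")
print(f"JS distance (purity),     truth vs 10%-corrupted: "
      f"{histogram_js(pur, pur_n, kind='purity'):.3f}")
print("Even 10% random label noise adds spurious types to nearly every")
print("neighbourhood, so the complexity histograms barely overlap; a faithful")
print("annotation keeps both distances near zero.")
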