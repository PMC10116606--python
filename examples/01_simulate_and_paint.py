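"""Simulate one admixed population under selection and paint it.

A population of 1,000 diploids is founded by a 50/50 admixture pulse; a
beneficial allele fixed in source 1 sits at 20 Mb with s = 0.3.  After 50
generations we sample 200 haplotypes, paint them as a 200 x 200 binary
image (black = ancestry from the source carrying the allele) and place the
11-pixel training target over the variant.

Run:  python examples/01_simulate_and_paint.py
"""

import numpy as np

from paintscan import (
    CoordinateMap,
    SelectedSite,
    SelectionModel,
    rasterize_full,
    run_simulation,
    sample_haplotypes,
    target_bbox,
)
from paintscan import scenarios

model = scenarios.baseline_model(N0=1_000)
selection = SelectionModel((SelectedSite(chromosome=0, position=20e6, s=0.3),))

rng = np.random.default_rng(7)
result = run_simulation(model, selection, rng=rng)
print(f"allele frequency:    {result.allele_frequency[0, 0]:.3f} -> "
      f"{result.allele_frequency[-1, 0]:.3f}")
print(f"ancestry proportion: {result.ancestry_proportion[0, 0]:.3f} -> "
      f"{result.ancestry_proportion[-1, 0]:.3f}")

samples = sample_haplotypes(result, 200, rng)
cmap = CoordinateMap.physical(model.chromosomes[0].length, width=200)
image = rasterize_full(samples, cmap)
target = target_bbox(20e6, cmap, half_width=5, height=samples.n)

print(f"image shape: {image.pixels.shape}, black fraction {image.pixels.mean():.3f}")
print(f"target box:  [{target.x_min}, {target.y_min}, {target.x_max}, {target.y_max}]")

# the selection signal is visible as a black column excess at the target
col = image.pixels.mean(axis=0)
inside = col[target.x_min:target.x_max].mean()
outside = np.delete(col, np.arange(target.x_min, target.x_max)).mean()
print(f"column-mean ancestry inside target {inside:.3f} vs elsewhere {outside:.3f}")
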