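"""Simulate a split-plot sorghum-style field trial with spatial soil structure.

The default configuration mirrors a 24-genotype x 2-watering-treatment x
8-block study on a 16 x 24 plot grid, with soil properties driven by three
latent spatial gradients and sampled on a sparse lattice (~25% of plots).
"""

import numpy as np

from fieldkrige import SimConfig, simulate_field_study

cfg = SimConfig(seed=7)
layout, soil, pheno, otu, truth = simulate_field_study(cfg)

frame = layout.frame
print(f"plots: {len(frame)}  blocks: {frame['block'].nunique()}  "
      f"genotypes: {frame['genotype'].nunique()}  "
      f"treatments: {sorted(frame['treatment'].unique())}")
sampled = soil.frame[soil.properties[0]].notna().sum()
print(f"soil sampled at {sampled}/{len(frame)} plots "
      f"({100 * sampled / len(frame):.0f}% lattice)")
print(f"soil properties: {', '.join(soil.properties)}")
print(f"phenotypes: {', '.join(pheno.traits)}  "
      f"(height mean {pheno.frame['height'].mean():.1f}, "
      f"sd {pheno.frame['height'].std():.2f})")
print(f"OTU table: {otu.n_samples()} samples x {len(otu.otu_ids)} OTUs, "
      f"zero fraction {float((otu.counts.to_numpy() == 0).mean()):.2f}")
print("truth record keys:", sorted(truth.keys()))
# The truth record stores the standardized latent gradients per plot and all
# generating coefficients -- the reference for parameter-recovery checks.
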