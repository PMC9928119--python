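"""Quantify a voxel-level phantom into a subjects x regions signal matrix.

Builds a small synthetic cohort of registered stacks (cuboid atlas regions
painted with known per-region signals), quantifies each stack over the
atlas masks, and checks the matrix against the planted ground truth.
"""

import numpy as np

from mavenpy import NormalizationSpec, build_signal_matrix, synthetic

cfg = synthetic.default_config(
    seed=0, n_subjects=12, n_regions=20, causal_region=3, proxy_region=15,
    voxel_phantom=synthetic.PhantomSpec(voxel_noise_sd=0.01),
)
atlas, stacks, phenotypes, truth = synthetic.simulate_phantom(cfg)
matrix = build_signal_matrix(stacks, atlas, NormalizationSpec("none"))

planted = truth.region_values + cfg.voxel_phantom.background
err = np.abs(matrix.values[:, : cfg.n_regions] - planted).max()

print(f"atlas: {atlas.n_regions} regions in a {atlas.shape} voxel space")
print(f"matrix: {matrix.shape[0]} subjects x {matrix.shape[1]} regions "
      f"(normalization: {matrix.normalization_tag})")
print(f"first subject, first 5 region means: "
      f"{np.round(matrix.values[0, :5], 4)}")
print(f"max |quantified - planted| = {err:.2e}")
print("Voxel noise averages out over each 64-voxel mask, so the recovered")
print("region means sit within a few thousandths of the planted values.")
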