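"""Map per-channel features onto the 4x7 electrode grid and build the
(T=2, N, 4, 7, 1) model input tensors.

The 23 referential electrodes occupy fixed grid cells ordered front-to-back
and left-to-right; 5 cells are empty and carry the standardized mean (0).
"""

import numpy as np

import p3dseize as pz

layout = pz.build_grid_layout(pz.CHB_CHANNELS)
print(f"grid {layout.shape}: {len(layout.mapping)} electrodes, "
      f"{len(layout.empty_cells)} empty cells")
grid_names = np.full((4, 7), "  . ", dtype=object)
for name, (r, c) in layout.mapping.items():
    grid_names[r, c] = f"{name:>4s}"
for row in grid_names:
    print(" ".join(row))

rng = np.random.default_rng(0)
block = pz.FeatureBlock(rng.standard_normal((8, 2, 3, 23)),
                        ("HFD", "FuzzyEn", "ApEn"), pz.CHB_CHANNELS)
stats = pz.fit_scaler(block, layout)
samples = pz.assemble_tensor(block, layout, stats, labels=np.arange(8) % 2)
x, y = pz.stack_samples(samples)
print(f"tensors: {x.shape} (windows, steps, features, rows, cols, 1)")
r, c = layout.mapping["FCz"]
print(f"FCz cell ({r},{c}), window 0, step 0, HFD -> {x[0, 0, 0, r, c, 0]:+.3f}")
print("Each value is the z-scored feature of one electrode; convolutions on")
print("this grid see neighboring electrodes as spatial neighbors.")
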