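"""From block-design scans to a unit-norm 25-D feature map.

Plants per-voxel 25-D selectivity, simulates one scan set per axis (boxcar
responses with a 4-s hemodynamic lag plus noise), runs the Fourier pipeline
(alternation coefficient, population sign rule, control normalization,
significance) and grids the result, then measures recovery.
"""
import warnings

import numpy as np

from cortexmap import selectivity, synthetic
from cortexmap.datatypes import default_block_design

rng = np.random.default_rng(0)
design = default_block_design()
print(f"scan: {design.n_blocks} blocks x {design.block_duration_s:.0f} s = "
      f"{design.total_duration_s:.0f} s, {design.n_volumes} volumes at "
      f"tr = {design.tr_s:.0f} s")

truth = rng.normal(size=(60, 25))
truth /= np.linalg.norm(truth, axis=1, keepdims=True)
flat = np.column_stack([rng.uniform(0, 30, 60), rng.uniform(0, 30, 60)])

scan_sets = [
    synthetic.gen_scan_set(design, truth, axis, phase_lag_s=4.0,
                           noise_sd=0.1, n_scans=4, seed=axis)
    for axis in range(25)
]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fmap = selectivity.feature_map_from_scans(scan_sets, flat)
    tmap = selectivity.resample_to_grid(truth, flat)

cos = np.sum(fmap.vectors() * tmap.vectors(), axis=1)
r = np.corrcoef(fmap.grid[fmap.mask].ravel(), tmap.grid[fmap.mask].ravel())[0, 1]
print(f"grid cells: {int(fmap.mask.sum())}; cosine to planted direction: "
      f"median {np.median(cos):.4f}, min {cos.min():.4f}")
print(f"cell-value correlation with planted map: r = {r:.3f}")
# near-unit cosines mean the pipeline recovers each location's preferred
# feature direction despite noise and the hemodynamic lag.

S = selectivity.similarity_matrix(fmap)
r_cons, bound = selectivity.compare_similarity(
    S, selectivity.similarity_matrix(tmap), n_shuffles=500, seed=0
)
print(f"similarity-matrix consistency with truth: r = {r_cons:.3f} "
      f"(5% shuffle bound {bound:.3f})")
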