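"""Train a self-organizing map on object-space coordinates and score its
topography.

The SOM's Gaussian neighborhood (sigma = 1.25 mm, 10% of peak at 2.7 mm)
drags nearby units toward each winning input; trained on two antipodal
feature clusters it forms spatially contiguous domains, and its feature map
scores low on the orthogonality index — the single-scale signature that
separates such models from multi-gradient maps.
"""
import numpy as np
import scipy.ndimage as ndi

from cortexmap import models, topography

rng = np.random.default_rng(0)
e = np.eye(25)
inputs = np.vstack([np.tile(e[0], (400, 1)), np.tile(-e[0], (400, 1))])
inputs = inputs + 0.2 * rng.normal(size=inputs.shape)
inputs /= np.linalg.norm(inputs, axis=1, keepdims=True)

c = models.SpatialConstraint("gaussian", 1.25)
print(f"neighborhood at 2.7 mm: {models.constraint_value(c, 2.7):.3f} of peak")

state = models.som_train(inputs, np.ones((12, 12), bool), c, T=50_000, seed=0,
                         cell_size_mm=1.0)
print(f"final learning rate after T = {state.T} steps: {state.learning_rate():.3f}")

pref = (state.weights @ e[0] > 0).reshape(12, 12)
for name, side in [("+pole", pref), ("-pole", ~pref)]:
    lab, n = ndi.label(side)
    sizes = np.bincount(lab.ravel())[1:]
    print(f"{name}: {n} connected domain(s), largest holds "
          f"{100 * sizes.max() / sizes.sum():.0f}% of its units")

fmap = models.som_feature_map(state)
freqs = np.arange(0.5, 6.01, 0.5)
vals = topography.sinusoid_fit_spectrum(
    topography.autocorrelation_of_map(fmap, 0), frequencies=freqs
).values
sp = topography.PolarSpectrum(topography.default_angles(), freqs, vals, "fit")
idx = topography.topography_indices(sp)
print(f"SOM map indices: preferred f = {idx.preferred_frequency:.2f}, "
      f"orthogonality = {idx.orthogonality:.2f} (single dominant scale)")

# the generic finite-difference ascender used for stimulus synthesis
u = rng.normal(size=25)
u /= np.linalg.norm(u)
res = models.finite_difference_ascent(
    lambda x: float(x @ u / np.linalg.norm(x)), rng.normal(size=25),
    steps=300, seed=1,
)
print(f"cosine-to-target objective after ascent: {res.trajectory[-1]:.3f}")
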