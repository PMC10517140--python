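"""Explain a neural map with interpretable axes: greedy selection, GOF and
noise ceiling.

Builds a map spanned by two planted orthogonal axes, mixes them with
distractor candidates, and lets the half-split goodness-of-fit decide how
many features are worth keeping; residual PCA then recovers a planted
left-over dimension.
"""
import numpy as np

from cortexmap import features

rng = np.random.default_rng(3)
e = np.eye(25)
w = rng.uniform(-1, 1, size=(300, 2))
truth = w @ np.vstack([e[0], e[1]]) + 0.4 * rng.normal(size=(300, 1)) @ e[2][None, :]
full = truth / np.linalg.norm(truth, axis=1, keepdims=True)


def halves(rg):
    def mk():
        M = truth + 0.12 * rg.normal(size=truth.shape)
        return M / np.linalg.norm(M, axis=1, keepdims=True)
    return mk(), mk()


candidates = [features.FeatureAxis("planted-0", e[0]),
              features.FeatureAxis("planted-1", e[1])] + [
    features.FeatureAxis(f"distractor-{i}", rng.normal(size=25)) for i in range(8)
]
res = features.greedy_select(full, candidates, max_k=5, halves=halves,
                             n_splits=50, seed=0)
print("selection order:", [f.name for f in res.ordered_features])
print("half-split GOF per feature count:", np.round(res.gof_curve, 3))
print(f"optimal feature count: {res.optimal_k}")

F1, F2 = halves(np.random.default_rng(10))
naive, corrected = features.noise_ceiling(F1, F2, seed=0)
print(f"noise ceiling: naive {naive:.3f}, simulation-corrected {corrected:.3f}")
frac = res.gof_curve[res.optimal_k - 1] / corrected
print(f"selected features reach {100 * frac:.1f}% of the corrected ceiling")

residual = features.residual_features(full, res.ordered_features[:2], n_residual=1)
print(f"first residual axis |cos| with the planted left-over direction: "
      f"{abs(residual[0].vector @ e[2]):.3f}")
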