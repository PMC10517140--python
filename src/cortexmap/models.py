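"""Model-side computations: spatial constraint functions, the spatial
correlation loss, response-profile statistics, a self-organizing map with a
decaying neighborhood schedule, and a generic finite-difference gradient
ascender.

The spatial constraints express how response-profile correlation should fall
off with cortical distance d (mm):

* ``reciprocal``: 1 / (1 + d/s)
* ``laplacian_of_gaussian``: (1 - d^2 / 2 s^2) exp(-d^2 / 2 s^2)
* ``gaussian``: exp(-d^2 / 2 s^2); at s = 1.25 mm the value 2.7 mm from the
  center is 10% of the peak, matching the measured cortical point spread.

The spatial loss is the mean over unit pairs of (C_ij - f(d_ij))^2 with C_ij
the Pearson correlation of the two units' response profiles.

The SOM arranges units on the masked grid; per step the winner is the unit
whose weight vector is nearest the input, every unit moves toward the input
with rate eta_v = eta_t * f(d_uv), weights are renormalized to unit length,
and the rate decays as eta_t = T / (T + 2 t).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FlatFeatureMap, map_from_cell_vectors
from .exceptions import ArgumentError, DegenerateDataError

__all__ = [
    "SpatialConstraint",
    "SOMState",
    "DPrimeResult",
    "AscentResult",
    "constraint_value",
    "profile_correlation",
    "spatial_loss",
    "dprime",
    "som_train",
    "som_feature_map",
    "finite_difference_ascent",
]

_KINDS = ("reciprocal", "laplacian_of_gaussian", "gaussian")


@dataclass(frozen=True)
class SpatialConstraint:
    """A distance-falloff function f with f(0) = 1 and scale s in mm."""

    kind: str
    s: float

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ArgumentError(f"unknown constraint kind {self.kind!r}")
        if self.s <= 0:
            raise ArgumentError("scale s must be positive")

    def __call__(self, d):
        return constraint_value(self, d)


def constraint_value(c: SpatialConstraint, d):
    """Evaluate a spatial constraint at distance(s) d >= 0 (mm)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ArgumentError("distances must be nonnegative")
    if c.kind == "reciprocal":
        out = 1.0 / (1.0 + d / c.s)
    elif c.kind == "laplacian_of_gaussian":
        q = d**2 / (2 * c.s**2)
        out = (1.0 - q) * np.exp(-q)
    else:  # gaussian
        out = np.exp(-(d**2) / (2 * c.s**2))
    return float(out) if out.ndim == 0 else out


def profile_correlation(ri: np.ndarray, rj: np.ndarray) -> float:
    """Pearson correlation between two units' response profiles."""
    ri = np.asarray(ri, dtype=float)
    rj = np.asarray(rj, dtype=float)
    if ri.shape != rj.shape or ri.size < 3:
        raise ArgumentError("profiles must have equal length >= 3")
    if ri.std() == 0 or rj.std() == 0:
        raise DegenerateDataError("constant profile; correlation undefined")
    return float(np.corrcoef(ri, rj)[0, 1])


def spatial_loss(
    responses: np.ndarray, positions: np.ndarray, c: SpatialConstraint
) -> float:
    """Mean over unordered unit pairs of (C_ij - f(d_ij))^2.

    Pairs whose profile correlation is undefined (a constant profile) are
    excluded; the count of excluded pairs is reported via a warning attribute
    on the return (see ``spatial_loss.last_excluded``).
    """
    R = np.asarray(responses, dtype=float)
    P = np.asarray(positions, dtype=float)
    if R.shape[0] < 2:
        raise ArgumentError("need at least 2 units")
    if P.shape != (R.shape[0], 2):
        raise ArgumentError("positions must be units x 2 (mm)")
    sd = R.std(axis=1)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(R)
    d = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)
    F = constraint_value(c, d)
    iu, ju = np.triu_indices(R.shape[0], k=1)
    cij = C[iu, ju]
    ok = np.isfinite(cij) & (sd[iu] > 0) & (sd[ju] > 0)
    spatial_loss.last_excluded = int((~ok).sum())
    if not ok.any():
        raise DegenerateDataError("no pair has a defined profile correlation")
    return float(np.mean((cij[ok] - F[iu, ju][ok]) ** 2))


spatial_loss.last_excluded = 0


@dataclass
class DPrimeResult:
    """Face/object preference metric and its selectivity label."""

    d_prime: float
    label: str  # "face" | "object" | "none"
    mu_face: float
    mu_object: float
    var_face: float
    var_object: float


def dprime(
    face_responses: np.ndarray,
    object_responses: np.ndarray,
    threshold: float = 0.85,
) -> DPrimeResult:
    """Standardized mean difference between face and non-face responses.

    ``d' = (mu_face - mu_object) / sqrt((var_face + var_object)/2)``; a unit
    is face-selective when d' >= threshold (inclusive) and object-selective
    when d' <= -threshold.
    """
    f = np.asarray(face_responses, dtype=float)
    o = np.asarray(object_responses, dtype=float)
    if f.size < 2 or o.size < 2:
        raise ArgumentError("both samples need at least 2 responses")
    vf, vo = f.var(ddof=1), o.var(ddof=1)
    if vf == 0 and vo == 0:
        raise DegenerateDataError("both variances are zero; d' undefined")
    d = float((f.mean() - o.mean()) / np.sqrt((vf + vo) / 2))
    label = "face" if d >= threshold else ("object" if d <= -threshold else "none")
    return DPrimeResult(
        d_prime=d, label=label, mu_face=float(f.mean()), mu_object=float(o.mean()),
        var_face=float(vf), var_object=float(vo),
    )


@dataclass
class SOMState:
    """Grid-arranged units with unit-norm weights and the training schedule."""

    positions_mm: np.ndarray  # units x 2
    weights: np.ndarray  # units x n_dims, unit rows
    mask: np.ndarray  # grid mask the units were placed on
    cell_size_mm: float
    neighborhood: SpatialConstraint
    T: int
    t: int

    def learning_rate(self) -> float:
        return self.T / (self.T + 2 * self.t)


def som_train(
    inputs: np.ndarray,
    mask: np.ndarray,
    c: SpatialConstraint,
    T: int = 100_000,
    seed: int = 0,
    cell_size_mm: float = 2.0,
) -> SOMState:
    """Train a self-organizing map on 25-D coordinate samples.

    One unit sits at each valid cell of ``mask``.  Per step t: an input is
    drawn uniformly with replacement, the winner u minimizes the Euclidean
    distance to the input in weight space, every unit v updates
    ``w_v <- normalize(w_v + eta_t f(d_uv) (xi - w_v))`` and the global rate
    decays as ``eta_t = T/(T + 2t)`` (1 at t = 0).
    """
    inputs = np.asarray(inputs, dtype=float)
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ArgumentError("empty mask")
    if T < 1:
        raise ArgumentError("T must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(mask)
    positions = np.column_stack([(cols + 0.5), (rows + 0.5)]) * cell_size_mm
    n_units = positions.shape[0]
    n_dims = inputs.shape[1]
    w = rng.normal(size=(n_units, n_dims))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    draw = rng.integers(0, inputs.shape[0], size=T)
    for t in range(T):
        xi = inputs[draw[t]]
        diff = xi[None, :] - w
        u = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
        d = np.linalg.norm(positions - positions[u], axis=1)
        eta = (T / (T + 2 * t)) * constraint_value(c, d)
        w = w + eta[:, None] * diff
        w /= np.linalg.norm(w, axis=1, keepdims=True)
    return SOMState(
        positions_mm=positions,
        weights=w,
        mask=mask,
        cell_size_mm=cell_size_mm,
        neighborhood=c,
        T=T,
        t=T,
    )


def som_winners(state: SOMState, inputs: np.ndarray) -> np.ndarray:
    """Winner unit index for each input sample."""
    inputs = np.asarray(inputs, dtype=float)
    d2 = ((inputs[:, None, :] - state.weights[None, :, :]) ** 2).sum(axis=-1)
    return np.argmin(d2, axis=1)


def som_feature_map(state: SOMState) -> FlatFeatureMap:
    """Grid feature map from the trained weights (mean per cell, unit norm).

    With one unit per cell (the arrangement ``som_train`` builds) the map
    equals the weights; masked-out cells remain invalid.
    """
    fmap = map_from_cell_vectors(
        state.weights, state.mask, cell_size_mm=state.cell_size_mm, normalize=True
    )
    fmap.meta["som_T"] = state.T
    return fmap


def som_quantization_error(state: SOMState, inputs: np.ndarray) -> float:
    """Mean distance from inputs to their winning unit's weight vector."""
    inputs = np.asarray(inputs, dtype=float)
    win = som_winners(state, inputs)
    return float(np.linalg.norm(inputs - state.weights[win], axis=1).mean())


def fd_gradient_estimate(objective, x, K, sigma, rng):
    """Paired-perturbation gradient estimate sum_k (W+ - W-) p_k / ||p_k||.

    Returns (estimate, finite_flag); the flag is False when the objective
    produced a non-finite value at any perturbed point.
    """
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for _ in range(K):
        p = rng.normal(scale=sigma, size=x.shape)
        wp = objective(x + p)
        wm = objective(x - p)
        if not (np.isfinite(wp) and np.isfinite(wm)):
            return g, False
        g += (wp - wm) * p / np.linalg.norm(p)
    return g, True


@dataclass
class AscentResult:
    """Optimized parameters with the per-step objective trajectory."""

    x: np.ndarray
    trajectory: np.ndarray
    aborted: bool = False


def finite_difference_ascent(
    objective,
    init: np.ndarray,
    K: int = 20,
    sigma: float = 0.1,
    steps: int = 200,
    lr: float = 0.05,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    seed: int = 0,
) -> AscentResult:
    """Maximize a black-box objective by paired-perturbation finite differences.

    Per step, K Gaussian perturbations p_k of scale sigma are drawn; the
    gradient estimate is ``sum_k (W(x + p_k) - W(x - p_k)) p_k / ||p_k||``
    and an adaptive-moment (Adam-style) ascent step is applied.  Paired
    differences cancel even-order terms, so a linear objective yields an
    estimate exactly proportional to its gradient.  A non-finite objective
    value aborts the run, returning the trajectory so far.
    """
    x = np.asarray(init, dtype=float).copy()
    if not np.isfinite(objective(x)):
        raise ArgumentError("objective must be finite at init")
    rng = np.random.default_rng(seed)
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    traj = [float(objective(x))]
    for step in range(1, steps + 1):
        g, ok = fd_gradient_estimate(objective, x, K, sigma, rng)
        if not ok:
            return AscentResult(x=x, trajectory=np.array(traj), aborted=True)
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g**2
        mh = m / (1 - beta1**step)
        vh = v / (1 - beta2**step)
        x = x + lr * mh / (np.sqrt(vh) + eps)
        val = objective(x)
        if not np.isfinite(val):
            return AscentResult(x=x, trajectory=np.array(traj), aborted=True)
        traj.append(float(val))
    return AscentResult(x=x, trajectory=np.array(traj), aborted=False)
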