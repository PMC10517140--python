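"""Interpretable feature axes and how well they explain a neural feature map.

A "feature axis" is a unit 25-D vector in object space.  Axes come from four
constructors: projecting a per-image scalar through the positive/negative
block structure (:func:`label_axis`), contrasting two image groups'
coordinates (:func:`contrast_axis`), image statistics (spatial-frequency band
energies, colorfulness) fed through :func:`label_axis`, and residual
principal axes of the neural map itself (:func:`residual_features`).

Similarity between axes is the squared cosine angle (:func:`sca`), which sums
to 1 over any complete orthonormal basis.  Explanatory power of a feature set
is the goodness of fit ``GOF = 1 - ||f2 - f1'||**2`` where ``f1'`` is one
half-split's preferred feature projected into the span of the selected axes
and ``f2`` the other half's; :func:`greedy_select` adds one axis at a time
(rejecting candidates with |cos| >= 0.5 to any selected axis), and the
optimal count maximizes the split-averaged GOF.  The attainable GOF given
measurement noise is the noise ceiling, estimated by direct cross-half
fitting and bias-corrected by simulation (:func:`noise_ceiling`).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .datatypes import FlatFeatureMap
from .exceptions import ArgumentError, DegenerateDataError, SingularMatrixError
from .space import ImageCoords, ImageSelection

__all__ = [
    "FeatureAxis",
    "SelectionResult",
    "RegionInversion",
    "sca",
    "gof",
    "orthonormalize",
    "label_axis",
    "image_band_energy",
    "default_band_edges",
    "colorfulness",
    "contrast_axis",
    "wordnet_label_screen",
    "greedy_select",
    "noise_ceiling",
    "residual_features",
    "invert_region_axis",
]


@dataclass
class FeatureAxis:
    """A named unit-norm direction in object space."""

    name: str
    vector: np.ndarray
    provenance: str = "label-projection"

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise DegenerateDataError(f"feature axis {self.name!r} has zero norm")
        self.vector = v / n


@dataclass
class SelectionResult:
    """Outcome of greedy feature selection with half-split validation."""

    ordered_features: list[FeatureAxis]
    gof_curve: np.ndarray  # mean split GOF per feature count 1..len
    optimal_k: int
    noise_ceiling: float | None = None
    corrected_fraction: float | None = None


@dataclass
class RegionInversion:
    """Solution of block-difference-matrix * weights = region response."""

    block_diff_matrix: np.ndarray
    region_response: np.ndarray
    weights: np.ndarray
    condition_number: float


# ---------------------------------------------------------------------------
# similarity / fit primitives
# ---------------------------------------------------------------------------

def sca(a: np.ndarray, b: np.ndarray) -> float:
    """Squared cosine angle between two vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ArgumentError("sca is undefined for zero vectors")
    return float((a @ b) ** 2 / (na**2 * nb**2))


def gof(f1_fit: np.ndarray, f2: np.ndarray) -> float:
    """Goodness of fit 1 - ||f2 - f1_fit||**2 for a unit-norm target f2."""
    d = np.asarray(f2, dtype=float) - np.asarray(f1_fit, dtype=float)
    return float(1.0 - d @ d)


def orthonormalize(vectors: list[np.ndarray] | np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Gram-Schmidt in the given order; near-dependent vectors are dropped."""
    basis: list[np.ndarray] = []
    for v in vectors:
        v = np.asarray(v, dtype=float).copy()
        for e in basis:
            v -= (v @ e) * e
        n = np.linalg.norm(v)
        if n > tol:
            basis.append(v / n)
    return np.array(basis)


# ---------------------------------------------------------------------------
# axis constructors
# ---------------------------------------------------------------------------

def label_axis(
    per_image_values: dict,
    selections: list[ImageSelection],
    name: str = "label",
    provenance: str = "label-projection",
) -> FeatureAxis:
    """Project a per-image scalar into object space through the block design.

    Per axis: mean value over its positive images minus mean over its
    negative images; the resulting vector over axes is unit-normalized.
    Shift-invariant in the values; raises on a constant table (zero vector).
    """
    comps = []
    for sel in selections:
        try:
            p = np.mean([per_image_values[i] for i in sel.positive_ids])
            n = np.mean([per_image_values[i] for i in sel.negative_ids])
        except KeyError as e:
            raise ArgumentError(f"missing value for selected image {e}") from None
        comps.append(p - n)
    v = np.array(comps, dtype=float)
    if np.linalg.norm(v) < 1e-12:
        raise DegenerateDataError("constant values project to the zero vector")
    return FeatureAxis(name=name, vector=v, provenance=provenance)


def default_band_edges(n_bands: int = 7, low: float = 2.91 / 32) -> np.ndarray:
    """Octave-spaced spatial-frequency band edges in cycles/degree.

    Seven octave bands anchored so that bands 2 and 5 are 0.18-0.36 and
    1.45-2.91 cyc/degree, spanning 0.09-11.64 overall.
    """
    return low * 2.0 ** np.arange(n_bands + 1)


def image_band_energy(
    images: np.ndarray,
    deg_per_px: float = 11.0 / 227.0,
    band_edges: np.ndarray | None = None,
) -> np.ndarray:
    """Mean power-spectrum magnitude within radial annuli, per image.

    ``images`` is (n, h, w) with h == w; annulus radii map pixel frequencies
    to cycles/degree through ``deg_per_px``.  The DC bin is excluded.
    Returns (n, n_bands) magnitudes.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    n, h, w = images.shape
    if h != w:
        raise ArgumentError("images must be square")
    if band_edges is None:
        band_edges = default_band_edges()
    band_edges = np.asarray(band_edges, dtype=float)
    nyquist = 0.5 / deg_per_px
    if band_edges[-1] > nyquist * np.sqrt(2) + 1e-9:
        raise ArgumentError("top band edge exceeds the spectrum extent")
    fx = np.fft.fftfreq(w)[None, :] / deg_per_px  # cycles/degree
    fy = np.fft.fftfreq(h)[:, None] / deg_per_px
    radius = np.sqrt(fx**2 + fy**2)
    spec = np.abs(np.fft.fft2(images, axes=(1, 2)))
    out = np.zeros((n, len(band_edges) - 1))
    for b in range(len(band_edges) - 1):
        sel = (radius >= band_edges[b]) & (radius < band_edges[b + 1]) & (radius > 0)
        if sel.any():
            out[:, b] = spec[:, sel].mean(axis=1)
    return out


def colorfulness(images: np.ndarray) -> np.ndarray:
    """Mean over pixels of the per-pixel standard deviation across R, G, B.

    ``images`` is (n, h, w, 3) or a single (h, w, 3) array.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ArgumentError("images must have three (RGB) channels")
    return images.std(axis=-1).mean(axis=(1, 2))


def contrast_axis(
    coords_a: np.ndarray, coords_b: np.ndarray, name: str = "contrast"
) -> FeatureAxis:
    """Unit-normalized difference of group-mean coordinates (A minus B)."""
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if coords_a.shape[0] == 0 or coords_b.shape[0] == 0:
        raise ArgumentError("both groups must be non-empty")
    d = coords_a.mean(axis=0) - coords_b.mean(axis=0)
    if np.linalg.norm(d) < 1e-12:
        raise DegenerateDataError("group means coincide")
    return FeatureAxis(name=name, vector=d, provenance="contrast")


def wordnet_label_screen(
    label_table: dict[str, np.ndarray] | "object",
    min_count: int = 100,
    max_count: int = 2000,
) -> list[str]:
    """Keep labels whose positive-image count lies in [min_count, max_count].

    ``label_table`` maps label name -> boolean per-image indicator (or is a
    DataFrame of booleans with labels as columns).
    """
    if hasattr(label_table, "columns"):  # DataFrame
        items = ((c, np.asarray(label_table[c])) for c in label_table.columns)
    else:
        items = label_table.items()
    return [name for name, col in items if min_count <= int(np.sum(col)) <= max_count]


# ---------------------------------------------------------------------------
# selection, ceiling, residuals
# ---------------------------------------------------------------------------

def _mean_projection_gof(F1: np.ndarray, F2: np.ndarray, basis: np.ndarray) -> float:
    if basis.size == 0:
        return float(np.mean(1.0 - np.sum(F2**2, axis=1)))
    proj = F1 @ basis.T @ basis
    d = F2 - proj
    return float(np.mean(1.0 - np.sum(d * d, axis=1)))


def greedy_select(
    neural_map: FlatFeatureMap | np.ndarray,
    candidates: list[FeatureAxis],
    max_k: int | None = None,
    halves=None,
    n_splits: int = 500,
    seed: int = 0,
    dissimilarity_cos: float = 0.5,
) -> SelectionResult:
    """Forward selection of the most explanatory feature axes.

    Step 1 picks the candidate with the largest mean squared cosine angle to
    the cell vectors.  Each later step admits only candidates whose |cos| to
    every already selected axis is below ``dissimilarity_cos``, Gram-Schmidt
    orthogonalizes the tentative set in selection order, and picks the
    candidate maximizing the summed squared cosine angle (ties broken by
    candidate list order).  The optimal count maximizes the half-split GOF:
    ``halves`` is a callable ``rng -> (F1, F2)`` returning aligned cell
    matrices from two data halves (defaults to using the full map as both
    halves, the no-noise limit).
    """
    if len(candidates) < 2:
        raise ArgumentError("need at least 2 candidates")
    cells = neural_map.vectors() if isinstance(neural_map, FlatFeatureMap) else np.asarray(neural_map)
    max_k = max_k or len(candidates)
    vecs = [c.vector for c in candidates]

    selected: list[int] = []
    while len(selected) < max_k:
        best, best_score = None, -np.inf
        for ci in range(len(candidates)):
            if ci in selected:
                continue
            if any(abs(vecs[ci] @ vecs[s]) >= dissimilarity_cos for s in selected):
                continue
            basis = orthonormalize([vecs[s] for s in selected] + [vecs[ci]])
            proj = cells @ basis.T
            score = float(np.mean(np.sum(proj**2, axis=1)))
            if score > best_score + 1e-12:
                best, best_score = ci, score
        if best is None:
            if len(selected) < max_k:
                warnings.warn("no admissible candidate left; stopping early")
            break
        selected.append(best)

    if not selected:
        raise DegenerateDataError("no candidate could be selected")

    rng = np.random.default_rng(seed)
    if halves is None:
        pairs = [(cells, cells)]
    else:
        pairs = [halves(rng) for _ in range(n_splits)]
    n_sel = len(selected)
    curve = np.zeros(n_sel)
    for kk in range(1, n_sel + 1):
        basis = orthonormalize([vecs[s] for s in selected[:kk]])
        curve[kk - 1] = np.mean(
            [_mean_projection_gof(F1, F2, basis) for F1, F2 in pairs]
        )
    optimal_k = int(np.argmax(curve)) + 1
    return SelectionResult(
        ordered_features=[candidates[s] for s in selected],
        gof_curve=curve,
        optimal_k=optimal_k,
    )


def noise_ceiling(
    map_half1: np.ndarray,
    map_half2: np.ndarray,
    n_sim: int = 40,
    n_reps: int = 3,
    n_cells_sim: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """(naive, corrected) noise ceiling from two aligned half-split maps.

    Naive: mean over cells of ``1 - ||f2 - f1||**2`` (one half directly fits
    the other).  Because both halves are noisy this underestimates the GOF
    the ground truth would achieve, so a correction curve is re-estimated by
    simulation: planted maps (unit vectors resampled from the normalized sum
    of the two halves, so the simulation matches the map's own directional
    structure) are perturbed at a range of noise levels, the naive ceiling
    and the true (ground-truth) GOF recorded, and an isotonic regression of
    true on naive is applied to the observed value.
    """
    F1 = np.asarray(map_half1, dtype=float)
    F2 = np.asarray(map_half2, dtype=float)
    if F1.shape != F2.shape:
        raise ArgumentError("halves must be aligned cell-wise (equal shapes)")
    if F1.shape[0] == 0:
        raise ArgumentError("halves share no cells")
    d = F2 - F1
    naive = float(np.mean(1.0 - np.sum(d * d, axis=1)))

    rng = np.random.default_rng(seed)
    n_cells, k = F1.shape
    n_cells_sim = n_cells_sim or max(min(n_cells, 2000), 1000)
    sigmas = np.linspace(0.0, 2.0, n_sim)
    naives, trues = [], []

    def _unit(M):
        nn = np.linalg.norm(M, axis=1, keepdims=True)
        nn[nn == 0] = 1.0
        return M / nn

    pool = _unit(F1 + F2)
    pool = pool[np.linalg.norm(F1 + F2, axis=1) > 1e-12]
    for s in sigmas:
        for _ in range(n_reps):
            g = pool[rng.integers(0, pool.shape[0], n_cells_sim)]
            h1 = _unit(g + s * rng.normal(size=g.shape))
            h2 = _unit(g + s * rng.normal(size=g.shape))
            naives.append(float(np.mean(1.0 - np.sum((h2 - h1) ** 2, axis=1))))
            trues.append(float(np.mean(1.0 - np.sum((h2 - g) ** 2, axis=1))))
    iso = IsotonicRegression(out_of_bounds="clip")
    iso.fit(naives, trues)
    corrected = float(min(iso.predict([naive])[0], 1.0))
    return naive, corrected


def residual_features(
    neural_map: FlatFeatureMap | np.ndarray,
    selected: list[FeatureAxis],
    n_residual: int = 2,
    tol: float = 1e-10,
) -> list[FeatureAxis]:
    """Principal axes of the neural map after removing the selected span.

    Cell vectors are orthogonalized against span(selected); the residuals are
    pooled with their negations (forcing a zero-mean, sign-symmetric PCA) and
    the top ``n_residual`` principal axes returned.  Residual axes are
    orthogonal to every selected axis by construction.
    """
    if not selected:
        raise ArgumentError("selected feature list must be non-empty")
    cells = neural_map.vectors() if isinstance(neural_map, FlatFeatureMap) else np.asarray(neural_map)
    E = orthonormalize([f.vector for f in selected])
    R = cells - cells @ E.T @ E
    if float(np.linalg.norm(R, axis=1).max(initial=0.0)) < tol:
        warnings.warn("residuals are numerically zero; no residual features")
        return []
    pooled = np.vstack([R, -R])
    _, s, Vt = np.linalg.svd(pooled, full_matrices=False)
    out = []
    for i in range(min(n_residual, (s > tol).sum())):
        out.append(FeatureAxis(name=f"residual_pc{i + 1}", vector=Vt[i], provenance="residual"))
    return out


def invert_region_axis(
    block_diff_matrix: np.ndarray,
    region_response: np.ndarray,
    condition_warn: float = 1e6,
) -> RegionInversion:
    """Solve block_diff_matrix @ w = R for the region's image-selection axis.

    Uses the pseudo-inverse; raises on a rank-deficient matrix and warns when
    the condition number exceeds ``condition_warn``.  The returned weights
    feed representative-image selection for the region.
    """
    A = np.asarray(block_diff_matrix, dtype=float)
    R = np.asarray(region_response, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ArgumentError("block_diff_matrix must be square")
    if R.shape != (A.shape[0],):
        raise ArgumentError("region_response length must match the matrix")
    s = np.linalg.svd(A, compute_uv=False)
    if s[-1] <= s[0] * A.shape[0] * np.finfo(float).eps:
        raise SingularMatrixError("block difference matrix is singular")
    cond = float(s[0] / s[-1])
    if cond > condition_warn:
        warnings.warn(f"ill-conditioned inversion (condition number {cond:.3g})")
    w = np.linalg.pinv(A) @ R
    return RegionInversion(
        block_diff_matrix=A, region_response=R, weights=w, condition_number=cond
    )
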