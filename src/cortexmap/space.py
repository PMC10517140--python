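"""Construction of the 25-D object space and stimulus selection.

The object space is built by centering an images x units activation matrix,
whitening it to ``k`` principal components, and rotating the whitened
coordinates with a fixed-point ICA (log-cosh contrast) so each axis is as
non-Gaussian as possible.  Images are then ranked by the angle between their
coordinate vector and each axis; the extremes of the ranking define the
"positive" and "negative" representative stimuli shown in alternating blocks.

Sign convention: the paperless ambiguity of IC polarity is resolved by
orienting every axis so that the skewness of its image coordinates is
positive, which makes pole identity reproducible across runs and seeds.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA

from .exceptions import ArgumentError, DegenerateDataError
from .synthetic import ActivationMatrix

__all__ = [
    "ObjectSpace",
    "ImageCoords",
    "ImageSelection",
    "DifferentialAxis",
    "DuplicateChance",
    "build_object_space",
    "image_coordinates",
    "select_representatives",
    "differential_axis",
    "duplicate_chance",
    "duplicate_chance_closed_form",
    "pairwise_axis_independence",
]


@dataclass
class ObjectSpace:
    """Whitening transform plus IC rotation defining the k object-space axes."""

    mean: np.ndarray  # units
    whitening: np.ndarray  # units x k
    rotation: np.ndarray  # k x k, orthonormal
    axes: np.ndarray  # k x units unmixing rows
    explained_variance_fraction: float

    @property
    def k(self) -> int:
        return self.rotation.shape[0]

    @property
    def n_units(self) -> int:
        return self.mean.shape[0]

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != self.n_units:
            raise ArgumentError(
                f"unit count {values.shape[-1]} does not match space ({self.n_units})"
            )
        return (values - self.mean) @ self.whitening @ self.rotation.T


@dataclass
class ImageCoords:
    """Per-image coordinates in IC space, aligned with the source matrix rows."""

    coords: np.ndarray  # images x k
    image_ids: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.image_ids = np.asarray(self.image_ids)
        if not np.all(np.isfinite(self.coords)):
            raise ArgumentError("coordinates must be finite")
        self._row = {i: r for r, i in enumerate(self.image_ids)}

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def rows_for(self, ids) -> np.ndarray:
        return self.coords[[self._row[i] for i in ids]]


@dataclass
class ImageSelection:
    """Pole-representative images of one axis with their selection angles."""

    axis_id: int
    axis: np.ndarray
    positive_ids: np.ndarray
    negative_ids: np.ndarray
    positive_angles_deg: np.ndarray
    negative_angles_deg: np.ndarray


@dataclass
class DifferentialAxis:
    """Positive-minus-negative mean coordinate direction of a selection."""

    vector: np.ndarray  # unit norm
    cosine_to_nominal: float


@dataclass
class DuplicateChance:
    """Monte-Carlo estimate of the expected multi-group duplicate count."""

    mean: float
    standard_error: float
    n_rounds: int


def build_object_space(acts: ActivationMatrix, k: int = 25, seed: int = 0) -> ObjectSpace:
    """Center, whiten to ``k`` components and ICA-rotate an activation matrix.

    The rotation is re-orthonormalized (polar projection) after the fixed
    point iteration so ``rotation @ rotation.T == I`` holds to machine
    precision, and axes are sign-fixed by positive coordinate skewness.
    """
    if k < 2:
        raise ArgumentError("k must be >= 2")
    X = acts.values
    n, u = X.shape
    if n <= k:
        raise ArgumentError("need more images than components")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(n, u) * np.finfo(float).eps
    if (s > tol).sum() < k:
        raise DegenerateDataError(
            f"centered matrix rank {(s > tol).sum()} is below k={k}"
        )
    lam = s**2 / (n - 1)  # per-component variance
    whitening = Vt[:k].T / np.sqrt(lam[:k])
    Xw = Xc @ whitening  # unit variance columns (ddof=1)
    total_var = lam.sum()
    evf = float(lam[:k].sum() / total_var)

    ica = FastICA(
        n_components=k,
        whiten=False,
        fun="logcosh",
        max_iter=2000,
        tol=1e-10,
        random_state=np.random.default_rng(seed).integers(2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at tight tol
        ica.fit(Xw)
    W = ica.components_  # k x k, approximately orthonormal
    # polar projection onto the orthogonal group
    uw, _, vtw = np.linalg.svd(W)
    W = uw @ vtw
    coords = Xw @ W.T
    sk = stats.skew(coords, axis=0)
    signs = np.where(sk < 0, -1.0, 1.0)
    W = W * signs[:, None]
    axes = W @ whitening.T
    return ObjectSpace(
        mean=mean,
        whitening=whitening,
        rotation=W,
        axes=axes,
        explained_variance_fraction=evf,
    )


def image_coordinates(acts: ActivationMatrix, space: ObjectSpace) -> ImageCoords:
    """Apply the fitted transform to an activation matrix."""
    return ImageCoords(coords=space.transform(acts.values), image_ids=acts.image_ids)


def select_representatives(
    coords: ImageCoords,
    axis: np.ndarray,
    n_per_pole: int = 50,
    axis_id: int = 0,
) -> ImageSelection:
    """Rank images by angle to ``axis``; extremes become the two poles.

    Angles live in [0, 180] degrees; the ``n_per_pole`` smallest angles form
    the positive pole and the largest the negative pole.  Ties are broken by
    ascending image id; zero-norm coordinate rows are excluded with a warning.
    The selection is invariant to rescaling ``axis`` by any positive constant.
    """
    axis = np.asarray(axis, dtype=float)
    an = np.linalg.norm(axis)
    if an == 0:
        raise ArgumentError("axis must be nonzero")
    axis = axis / an
    norms = np.linalg.norm(coords.coords, axis=1)
    valid = norms > 0
    if not valid.any():
        raise DegenerateDataError("all coordinate rows have zero norm")
    if (~valid).any():
        warnings.warn(f"excluding {(~valid).sum()} zero-norm coordinate rows")
    if n_per_pole > valid.sum() // 2:
        raise ArgumentError("n_per_pole must be at most half the valid images")
    idx = np.nonzero(valid)[0]
    cosv = np.clip(coords.coords[idx] @ axis / norms[idx], -1.0, 1.0)
    ang = np.degrees(np.arccos(cosv))
    ids = coords.image_ids[idx]
    order_small = sorted(range(len(idx)), key=lambda i: (ang[i], str(ids[i])))
    order_large = sorted(range(len(idx)), key=lambda i: (-ang[i], str(ids[i])))
    pos = order_small[:n_per_pole]
    neg = order_large[:n_per_pole]
    return ImageSelection(
        axis_id=axis_id,
        axis=axis,
        positive_ids=ids[pos],
        negative_ids=ids[neg],
        positive_angles_deg=ang[pos],
        negative_angles_deg=ang[neg],
    )


def differential_axis(selection: ImageSelection, coords: ImageCoords) -> DifferentialAxis:
    """Unit-normalized difference of pole-mean coordinates.

    Also reports the cosine to the nominal axis, the stability check used to
    verify that independently selected image sets define the same direction.
    """
    if len(selection.positive_ids) == 0 or len(selection.negative_ids) == 0:
        raise ArgumentError("both poles must be non-empty")
    diff = coords.rows_for(selection.positive_ids).mean(axis=0) - coords.rows_for(
        selection.negative_ids
    ).mean(axis=0)
    n = np.linalg.norm(diff)
    if n < 1e-12:
        raise DegenerateDataError("pole means coincide; differential axis undefined")
    v = diff / n
    return DifferentialAxis(vector=v, cosine_to_nominal=float(v @ selection.axis))


def duplicate_chance(
    n_pool: int,
    n_groups: int,
    group_size: int,
    n_rounds: int,
    seed: int = 0,
    batch_rounds: int = 1000,
) -> DuplicateChance:
    """Expected count of pool items drawn into more than one group.

    Per round, ``n_groups`` independent without-replacement samples of
    ``group_size`` are drawn from ``n_pool`` items and the number of items
    appearing in more than one sample is counted; the mean over rounds is
    returned with its Monte-Carlo standard error.  Within-group uniqueness is
    enforced by rejection resampling of offending groups, which is exact.
    """
    if group_size > n_pool:
        raise ArgumentError("group_size must not exceed n_pool")
    if n_rounds < 1:
        raise ArgumentError("n_rounds must be >= 1")
    if n_groups < 1 or group_size < 1:
        raise ArgumentError("counts must be positive")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_rounds, dtype=np.int64)
    done = 0
    while done < n_rounds:
        b = min(batch_rounds, n_rounds - done)
        g = rng.integers(0, n_pool, size=(b, n_groups, group_size))
        while True:
            srt = np.sort(g, axis=-1)
            bad = (srt[..., 1:] == srt[..., :-1]).any(axis=-1)
            if not bad.any():
                break
            g[bad] = rng.integers(0, n_pool, size=(int(bad.sum()), group_size))
        for r in range(b):
            _, c = np.unique(g[r].ravel(), return_counts=True)
            counts[done + r] = int((c > 1).sum())
        done += b
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(n_rounds)) if n_rounds > 1 else float("nan")
    return DuplicateChance(mean=mean, standard_error=se, n_rounds=n_rounds)


def duplicate_chance_closed_form(n_pool: int, n_groups: int, group_size: int) -> float:
    """Analytic expectation: each item is in a given group with p = size/pool,
    independently across groups, so the expected multi-group count is
    ``n_pool * P(Binomial(n_groups, p) >= 2)``."""
    p = group_size / n_pool
    p_ge2 = 1.0 - (1 - p) ** n_groups - n_groups * p * (1 - p) ** (n_groups - 1)
    return n_pool * p_ge2


def pairwise_axis_independence(
    coords: ImageCoords, n_bins: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation and mutual information (bits) for all axis pairs.

    MI uses equal-count (quantile) binning with ``n_bins`` bins per axis.
    Constant columns yield NaN rows/columns (flagged as undefined).
    """
    X = coords.coords
    if X.shape[0] < 100:
        raise ArgumentError("need at least 100 images")
    k = X.shape[1]
    sd = X.std(axis=0)
    const = sd == 0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[const, :] = np.nan
    r[:, const] = np.nan

    # quantile-bin labels per column
    labels = np.zeros(X.shape, dtype=int)
    for j in range(k):
        if const[j]:
            continue
        qs = np.quantile(X[:, j], np.linspace(0, 1, n_bins + 1)[1:-1])
        labels[:, j] = np.searchsorted(qs, X[:, j], side="right")
    n = X.shape[0]
    mi = np.full((k, k), np.nan)
    for i in range(k):
        if const[i]:
            continue
        for j in range(i, k):
            if const[j]:
                continue
            joint = np.zeros((n_bins, n_bins))
            np.add.at(joint, (labels[:, i], labels[:, j]), 1)
            p = joint / n
            pi = p.sum(axis=1, keepdims=True)
            pj = p.sum(axis=0, keepdims=True)
            nz = p > 0
            val = float((p[nz] * np.log2(p[nz] / (pi @ pj)[nz])).sum())
            mi[i, j] = mi[j, i] = val
    return r, mi
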