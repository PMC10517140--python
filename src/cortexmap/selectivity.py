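"""From block-design scans to a signed, normalized, gridded 25-D feature map.

The alternation of positive and negative blocks makes each voxel's response
periodic, so its preference is read off the discrete Fourier coefficient at
the alternation frequency: the magnitude gives response strength and the
phase its polarity.  Polarity is decided relative to a population reference
phase (the circular mean phase of the strongest voxels in the later of the
two phase-histogram peaks, i.e. the negative-preferring population): a voxel
whose phase is within pi/2 of the reference responds negatively, otherwise
positively.  Signed responses are divided by a locally averaged control-block
magnitude to cancel session gain, projected to the flat map, and resampled
into square cells whose mean 25-D vectors are normalized to unit length.

DFT scaling convention: ``c = (2/N) * sum_n x[n] exp(-2*pi*i*k*n/N)``, so a
pure cosine of amplitude A at the analysis frequency has magnitude A.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .datatypes import BlockDesign, FlatFeatureMap, map_from_cell_vectors
from .exceptions import ArgumentError, ConfigurationError, DegenerateDataError
from .synthetic import ScanSet

__all__ = [
    "fourier_response",
    "control_response",
    "population_sign_reference",
    "signed_response",
    "control_normalize",
    "voxel_significance",
    "resample_to_grid",
    "similarity_matrix",
    "compare_similarity",
    "feature_map_from_scans",
]


def _window_coefficient(x: np.ndarray, k: int) -> tuple[float, float]:
    """Magnitude and phase of the k-cycle DFT coefficient of a window."""
    x = np.asarray(x, dtype=float)
    n = x.size
    c = (2.0 / n) * np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
    return float(np.abs(c)), float(np.angle(c) % (2 * np.pi))


def _analysis_window(design: BlockDesign) -> tuple[int, int]:
    blocks = sorted(design.analysis_blocks)
    if blocks != list(range(blocks[0], blocks[-1] + 1)):
        raise ConfigurationError("analysis blocks must be contiguous")
    vpb = design.volumes_per_block
    return blocks[0] * vpb, (blocks[-1] + 1) * vpb


def fourier_response(timeseries: np.ndarray, design: BlockDesign) -> tuple[float, float]:
    """(magnitude, phase) at the positive/negative alternation frequency.

    The analysis window spans the contiguous analysis blocks; the coefficient
    is taken at the bin whose cycle count equals the number of alternation
    cycles in the window (six for the default twelve-block window).
    """
    v0, v1 = _analysis_window(design)
    timeseries = np.asarray(timeseries, dtype=float)
    if timeseries.size != design.n_volumes:
        raise ArgumentError("timeseries length must equal design volume count")
    return _window_coefficient(timeseries[v0:v1], design.n_alternation_cycles)


def control_response(timeseries: np.ndarray, design: BlockDesign) -> tuple[float, float]:
    """(magnitude, phase) of the one-cycle coefficient over control + next gray block."""
    labels = design.block_labels
    try:
        ci = labels.index("control")
    except ValueError:
        raise ConfigurationError("design has no control block") from None
    if ci + 1 >= len(labels) or labels[ci + 1] != "gray":
        raise ConfigurationError("control block must be followed by a gray block")
    vpb = design.volumes_per_block
    window = np.asarray(timeseries, dtype=float)[ci * vpb : (ci + 2) * vpb]
    return _window_coefficient(window, 1)


def _circular_mean(phases: np.ndarray) -> float:
    return float(np.angle(np.exp(1j * np.asarray(phases)).mean()) % (2 * np.pi))


def _circular_distance(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + np.pi) % (2 * np.pi) - np.pi)


def population_sign_reference(
    phases: np.ndarray,
    magnitudes: np.ndarray,
    top_n: int = 100,
    smoothing_rad: float = 0.25,
    bimodality_ratio: float = 0.2,
) -> float:
    """Reference phase from the negative-preferring peak of the population.

    A kernel-smoothed circular histogram of voxel phases is scanned for its
    two largest modes; the right peak — the mode at the larger raw phase in
    [0, 2*pi) — designates the negative-preferring population (the
    hemodynamic delay puts the positive-preferring peak below pi for any
    physiological lag, so the antipodal negative peak sits to its right).
    The circular mean phase of the ``top_n`` largest-magnitude voxels
    assigned to that mode is returned.

    Falls back, with a warning, to the global circular mean plus pi/2 when
    the histogram is effectively unimodal.
    """
    phases = np.asarray(phases, dtype=float) % (2 * np.pi)
    magnitudes = np.asarray(magnitudes, dtype=float)
    if phases.size != magnitudes.size:
        raise ArgumentError("phases and magnitudes must have equal length")

    grid = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    d = _circular_distance(grid[:, None], phases[None, :])
    density = np.exp(-0.5 * (d / smoothing_rad) ** 2).sum(axis=1)
    is_max = (density > np.roll(density, 1)) & (density >= np.roll(density, -1))
    peaks = grid[is_max]
    heights = density[is_max]
    order = np.argsort(heights)[::-1]
    if len(peaks) < 2 or heights[order[1]] < bimodality_ratio * heights[order[0]]:
        warnings.warn("phase histogram looks unimodal; using circular mean + pi/2")
        return (_circular_mean(phases) + np.pi / 2) % (2 * np.pi)
    a, b = peaks[order[0]], peaks[order[1]]
    later = max(a, b)
    other = min(a, b)
    assign_later = _circular_distance(phases, later) <= _circular_distance(phases, other)
    cand = np.nonzero(assign_later)[0]
    if cand.size == 0:
        warnings.warn("no voxels in the later peak; using peak location")
        return float(later)
    if cand.size < top_n:
        warnings.warn(
            f"only {cand.size} voxels in the later peak (< {top_n}); using all of them"
        )
    top = cand[np.argsort(magnitudes[cand])[::-1][:top_n]]
    return _circular_mean(phases[top])


def signed_response(phase, reference: float):
    """Sign rule: circular distance to the reference below pi/2 means the voxel
    prefers the negative blocks (-1); at or beyond pi/2 it is positive (+1)."""
    d = _circular_distance(phase, reference)
    out = np.where(d < np.pi / 2, -1.0, 1.0)
    return float(out) if np.isscalar(phase) else out


def control_normalize(
    signed_values: np.ndarray,
    control_magnitudes: np.ndarray,
    positions: np.ndarray,
    significant: np.ndarray,
    radius: float = 5.0,
) -> np.ndarray:
    """Divide signed responses by a locally averaged control magnitude.

    The denominator for a voxel is the mean absolute control magnitude over
    the significant voxels within Euclidean distance ``radius`` (in voxel
    units, including the voxel itself when significant); averaging avoids
    blow-ups from individually small denominators.  Voxels with no significant
    neighbor get NaN.
    """
    signed_values = np.asarray(signed_values, dtype=float)
    control = np.abs(np.asarray(control_magnitudes, dtype=float))
    positions = np.asarray(positions, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    n = signed_values.shape[0]
    if not (control.shape[0] == positions.shape[0] == significant.shape[0] == n):
        raise ArgumentError("all per-voxel inputs must have equal length")
    sig_idx = np.nonzero(significant)[0]
    out = np.full(n, np.nan)
    if sig_idx.size == 0:
        warnings.warn("no significant voxels; all outputs undefined")
        return out
    tree = cKDTree(positions[sig_idx])
    neighbors = tree.query_ball_point(positions, r=radius)
    for v, nb in enumerate(neighbors):
        if nb:
            out[v] = signed_values[v] / control[sig_idx[nb]].mean()
    return out


def voxel_significance(scans: ScanSet, phase_lag_s: float = 0.0) -> np.ndarray:
    """Paired two-tailed t-test, control-block vs gray-block mean signal.

    Per scan and voxel, the mean volume signal over control blocks is paired
    with the mean over gray blocks; the t-test runs across scans.  Degenerate
    zero-variance differences resolve to p=0 for a nonzero mean difference
    and p=1 otherwise (the noiseless limits).  ``phase_lag_s`` optionally
    shifts the volume labeling to compensate a known hemodynamic delay.
    """
    if scans.n_scans < 2:
        raise ArgumentError("need at least 2 scans for a paired test")
    design = scans.design
    t = np.arange(design.n_volumes) * design.tr_s - phase_lag_s
    labels = np.array([design.block_at_time(ti) or "gray" for ti in t], dtype=object)
    ctrl = labels == "control"
    gray = labels == "gray"
    if not ctrl.any() or not gray.any():
        raise ConfigurationError("design must contain control and gray volumes")
    c = np.stack([s[:, ctrl].mean(axis=1) for s in scans.scans])  # scans x voxels
    g = np.stack([s[:, gray].mean(axis=1) for s in scans.scans])
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_rel(c, g, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    diff = c - g
    zero_var = diff.std(axis=0) == 0
    p[zero_var & (np.abs(diff.mean(axis=0)) > 0)] = 0.0
    p[zero_var & (diff.mean(axis=0) == 0)] = 1.0
    return p


def resample_to_grid(
    vertex_values: np.ndarray,
    flat_coords: np.ndarray,
    cell_size_mm: float = 2.0,
    min_count: int = 1,
) -> FlatFeatureMap:
    """Average per-vertex vectors within square cells; normalize to unit length.

    Cells with fewer than ``min_count`` vertices, or whose mean vector has
    zero norm (e.g. two opposite vertices), are masked out.
    """
    vertex_values = np.asarray(vertex_values, dtype=float)
    flat_coords = np.asarray(flat_coords, dtype=float)
    if vertex_values.ndim != 2 or flat_coords.shape != (vertex_values.shape[0], 2):
        raise ArgumentError("vertex_values must be n x k with matching n x 2 coords")
    finite = np.all(np.isfinite(vertex_values), axis=1)
    vertex_values = vertex_values[finite]
    flat_coords = flat_coords[finite]
    if vertex_values.shape[0] == 0:
        raise DegenerateDataError("no finite vertex values to resample")
    x0, y0 = flat_coords.min(axis=0)
    col = np.floor((flat_coords[:, 0] - x0) / cell_size_mm).astype(int)
    row = np.floor((flat_coords[:, 1] - y0) / cell_size_mm).astype(int)
    n_rows, n_cols = row.max() + 1, col.max() + 1
    k = vertex_values.shape[1]
    sums = np.zeros((n_rows, n_cols, k))
    counts = np.zeros((n_rows, n_cols), dtype=int)
    np.add.at(sums, (row, col), vertex_values)
    np.add.at(counts, (row, col), 1)
    occupied = counts >= max(min_count, 1)
    if not occupied.any():
        raise DegenerateDataError("all cells empty after resampling")
    means = np.zeros_like(sums)
    means[occupied] = sums[occupied] / counts[occupied][:, None]
    fmap = map_from_cell_vectors(
        means[occupied], occupied, cell_size_mm=cell_size_mm, normalize=True
    )
    fmap.provenance = counts
    return fmap


def similarity_matrix(fmap: FlatFeatureMap) -> np.ndarray:
    """k x k Pearson correlations between component maps over valid cells.

    Constant components produce NaN rows/columns (flagged undefined).
    """
    V = fmap.vectors()
    if V.shape[0] < 2:
        raise ArgumentError("need at least 2 valid cells")
    sd = V.std(axis=0)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(V, rowvar=False)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    return r


def compare_similarity(
    A: np.ndarray, B: np.ndarray, n_shuffles: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Consistency of two similarity matrices and its 5% shuffle null bound.

    Consistency is the Pearson correlation between the off-diagonal entries;
    the null bound is the 95th percentile of the same statistic after jointly
    permuting the component labels (rows and columns) of ``B``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ArgumentError("A and B must be square with equal shape")
    k = A.shape[0]
    off = ~np.eye(k, dtype=bool)

    def _corr(x, y):
        m = np.isfinite(x) & np.isfinite(y)
        return float(np.corrcoef(x[m], y[m])[0, 1])

    r = _corr(A[off], B[off])
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(k)
        Bp = B[np.ix_(perm, perm)]
        null[i] = _corr(A[off], Bp[off])
    return r, float(np.quantile(null, 0.95))


def feature_map_from_scans(
    scan_sets: list[ScanSet],
    flat_coords: np.ndarray,
    cell_size_mm: float = 2.0,
    p_threshold: float = 0.001,
    neighborhood_radius: float = 5.0,
    positions: np.ndarray | None = None,
    min_count: int = 1,
) -> FlatFeatureMap:
    """End-to-end convenience: one ScanSet per axis -> merged unit-norm map.

    Per axis: scans are averaged, the alternation coefficient and control
    coefficient extracted per voxel, the population sign reference computed,
    signed responses control-normalized with the significance mask from the
    paired t-test, and the per-axis values stacked into per-vertex 25-D
    vectors which are then gridded.  ``positions`` (voxel-unit coordinates for
    the normalization neighborhood) defaults to the flat coordinates.
    """
    if positions is None:
        positions = np.asarray(flat_coords, dtype=float)
    n_vox = scan_sets[0].n_voxels
    values = np.zeros((n_vox, len(scan_sets)))
    for a, ss in enumerate(scan_sets):
        mean_scan = ss.mean_scan()
        mags = np.empty(n_vox)
        phases = np.empty(n_vox)
        cmags = np.empty(n_vox)
        for v in range(n_vox):
            mags[v], phases[v] = fourier_response(mean_scan[v], ss.design)
            cmags[v], _ = control_response(mean_scan[v], ss.design)
        ref = population_sign_reference(phases, mags)
        signed = signed_response(phases, ref) * mags
        if ss.n_scans >= 2:
            sig = voxel_significance(ss) < p_threshold
        else:
            sig = np.ones(n_vox, dtype=bool)
        values[:, a] = control_normalize(
            signed, cmags, positions, sig, radius=neighborhood_radius
        )
    return resample_to_grid(values, flat_coords, cell_size_mm, min_count=min_count)
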