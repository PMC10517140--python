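"""Spatial organization of a feature map: autocorrelation, oriented spectra
and scalar gradient indices.

For each component map, the 2-D spatial autocorrelation at lag (dx, dy) is
the Pearson correlation between feature values of all cell pairs with that
relative location (pairwise-complete over the mask).  Two spectral summaries
are derived from the autocorrelation map:

* ``rectangle_spectrum`` — correlation values inside an oriented rectangle
  (66 mm x 22 mm by default) are projected onto its long edge and Fourier
  transformed, giving magnitudes per (orientation, cycles per rectangle
  length);
* ``sinusoid_fit_spectrum`` — plane sinusoids at each (frequency,
  orientation) are least-squares fitted to the defined lags, giving explained
  variance per (orientation, cycles per map length).

Four indices condense a spectrum: the explained-variance weighted preferred
frequency, the frequency tuning width (area under the peak-normalized tuning
curve), the orientation selectivity |F(1)|/F(0) of the orientation tuning
curve (180-degree period), and the orthogonality index — the maximum cross
product length among per-frequency orientation vectors, which is high when
gradients at two frequencies run at right angles.  Orientation vectors use
raw (not doubled) angles: doubling would send orthogonal orientations to
antiparallel vectors with zero cross product, defeating the index.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import FlatFeatureMap
from .exceptions import ArgumentError, DegenerateDataError

__all__ = [
    "AutocorrMap",
    "PolarSpectrum",
    "TopographyIndices",
    "spatial_autocorrelation",
    "rectangle_spectrum",
    "sinusoid_fit_spectrum",
    "topography_indices",
    "default_angles",
]


def default_angles(step_deg: float = 5.0) -> np.ndarray:
    """Orientation sampling over [-90, 90) degrees (default 36 steps of 5)."""
    return np.arange(-90.0, 90.0, step_deg)


@dataclass
class AutocorrMap:
    """Correlation per relative cell lag; NaN where too few pairs exist."""

    r: np.ndarray  # (2*max_lag+1)^2 grid, center = zero lag
    n_pairs: np.ndarray
    cell_size_mm: float
    map_length_mm: float  # longer side of the source map (for fit frequencies)

    @property
    def max_lag_cells(self) -> int:
        return (self.r.shape[0] - 1) // 2

    def lag_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(dx, dy) in mm for every lag-grid entry."""
        m = self.max_lag_cells
        d = np.arange(-m, m + 1) * self.cell_size_mm
        dx, dy = np.meshgrid(d, d, indexing="xy")
        return dx, dy


@dataclass
class PolarSpectrum:
    """Magnitude or explained variance over (orientation, frequency)."""

    angles_deg: np.ndarray
    frequencies: np.ndarray  # cycles per rectangle length (fourier) or map length (fit)
    values: np.ndarray  # n_angles x n_frequencies, >= 0
    mode: str  # "fourier" | "fit"
    flagged_angles: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


@dataclass
class TopographyIndices:
    """Scalar summaries of a polar spectrum's gradient structure."""

    preferred_frequency: float
    tuning_width: float
    orientation_selectivity: float
    orthogonality: float
    per_frequency_os: np.ndarray
    per_frequency_orientation_deg: np.ndarray
    orientation_vectors: np.ndarray  # n_freq x 2, magnitude = OS


def spatial_autocorrelation(
    component_map: np.ndarray,
    mask: np.ndarray | None = None,
    cell_size_mm: float = 2.0,
    max_lag_mm: float | None = None,
    min_pairs: int = 10,
) -> AutocorrMap:
    """Pearson correlation over co-valid cell pairs at every relative lag.

    ``component_map`` may carry NaN outside the mask; pairs are
    pairwise-complete.  Lags with fewer than ``min_pairs`` pairs, or with a
    constant map on either side, are NaN.  r(0,0) is 1 and the map is
    symmetric under lag negation by construction.
    """
    f = np.asarray(component_map, dtype=float)
    if mask is None:
        mask = np.isfinite(f)
    mask = np.asarray(mask, bool) & np.isfinite(f)
    if mask.sum() < min_pairs:
        raise ArgumentError("too few valid cells at zero lag")
    rows, cols = f.shape
    if max_lag_mm is None:
        m = max(rows, cols) - 1
    else:
        m = int(np.floor(max_lag_mm / cell_size_mm))
    r = np.full((2 * m + 1, 2 * m + 1), np.nan)
    n_pairs = np.zeros((2 * m + 1, 2 * m + 1), dtype=int)
    for di in range(-m, m + 1):
        for dj in range(-m, m + 1):
            # overlap of the map with itself shifted by (di, dj)
            i0, i1 = max(0, di), min(rows, rows + di)
            j0, j1 = max(0, dj), min(cols, cols + dj)
            if i0 >= i1 or j0 >= j1:
                continue
            a = f[i0:i1, j0:j1]
            b = f[i0 - di : i1 - di, j0 - dj : j1 - dj]
            va = mask[i0:i1, j0:j1] & mask[i0 - di : i1 - di, j0 - dj : j1 - dj]
            n = int(va.sum())
            n_pairs[m + di, m + dj] = n
            if n < min_pairs:
                continue
            x, y = a[va], b[va]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r[m + di, m + dj] = float(np.corrcoef(x, y)[0, 1])
    r[m, m] = 1.0
    if np.isnan(r).all(axis=None) or (np.isfinite(r).sum() == 1 and mask.sum() > min_pairs):
        warnings.warn("autocorrelation undefined away from zero lag (constant map?)")
    return AutocorrMap(
        r=r,
        n_pairs=n_pairs,
        cell_size_mm=cell_size_mm,
        map_length_mm=max(rows, cols) * cell_size_mm,
    )


def autocorrelation_of_map(fmap: FlatFeatureMap, component: int, **kw) -> AutocorrMap:
    """Autocorrelation of one component of a FlatFeatureMap."""
    return spatial_autocorrelation(
        fmap.component(component), fmap.mask, cell_size_mm=fmap.cell_size_mm, **kw
    )


def _bilinear_nan(grid: np.ndarray, xi: np.ndarray, yi: np.ndarray) -> np.ndarray:
    """Bilinear interpolation returning NaN when any corner is NaN/outside."""
    rows, cols = grid.shape
    out = np.full(xi.shape, np.nan)
    x0 = np.floor(xi).astype(int)
    y0 = np.floor(yi).astype(int)
    inside = (x0 >= 0) & (x0 + 1 < cols) & (y0 >= 0) & (y0 + 1 < rows)
    if not inside.any():
        return out
    xs, ys, x0s, y0s = xi[inside], yi[inside], x0[inside], y0[inside]
    fx, fy = xs - x0s, ys - y0s
    v00 = grid[y0s, x0s]
    v01 = grid[y0s, x0s + 1]
    v10 = grid[y0s + 1, x0s]
    v11 = grid[y0s + 1, x0s + 1]
    val = (
        v00 * (1 - fx) * (1 - fy)
        + v01 * fx * (1 - fy)
        + v10 * (1 - fx) * fy
        + v11 * fx * fy
    )
    out[inside] = val
    return out


def rectangle_spectrum(
    acorr: AutocorrMap,
    rect_length_mm: float = 66.0,
    rect_width_mm: float = 22.0,
    angles_deg: np.ndarray | None = None,
    step_mm: float | None = None,
    n_harmonics: int = 5,
    impute: bool = True,
    undefined_tolerance: float = 0.5,
) -> PolarSpectrum:
    """Oriented-rectangle Fourier spectrum of an autocorrelation map.

    For each orientation, correlation values are bilinearly resampled inside
    a centered rotated rectangle, averaged across the short edge (ignoring
    undefined lags), and Fourier transformed along the long edge; magnitudes
    at integer cycle counts 1..n_harmonics per rectangle length are kept.
    Fully undefined long-edge columns are mean-imputed from the defined ones
    (configurable off); orientations with more than ``undefined_tolerance``
    undefined samples are flagged.
    """
    if angles_deg is None:
        angles_deg = default_angles()
    angles_deg = np.asarray(angles_deg, dtype=float)
    step = step_mm or acorr.cell_size_mm
    n_u = max(int(round(rect_length_mm / step)), 2 * n_harmonics + 1)
    n_v = max(int(round(rect_width_mm / step)), 1)
    u = (np.arange(n_u) + 0.5) * rect_length_mm / n_u - rect_length_mm / 2
    v = (np.arange(n_v) + 0.5) * rect_width_mm / n_v - rect_width_mm / 2
    uu, vv = np.meshgrid(u, v, indexing="ij")
    m = acorr.max_lag_cells
    values = np.zeros((len(angles_deg), n_harmonics))
    flagged = np.zeros(len(angles_deg), dtype=bool)
    k = np.arange(1, n_harmonics + 1)
    phase = np.exp(-2j * np.pi * np.outer(k, np.arange(n_u)) / n_u)
    for ai, ang in enumerate(angles_deg):
        th = np.deg2rad(ang)
        dx = uu * np.cos(th) - vv * np.sin(th)
        dy = uu * np.sin(th) + vv * np.cos(th)
        xi = dx / acorr.cell_size_mm + m
        yi = dy / acorr.cell_size_mm + m
        samp = _bilinear_nan(acorr.r, xi, yi)  # n_u x n_v
        undef = np.isnan(samp)
        if undef.mean() > undefined_tolerance:
            flagged[ai] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN columns handled below
            proj = np.nanmean(samp, axis=1)
        bad_cols = np.isnan(proj)
        if bad_cols.any():
            if impute and (~bad_cols).any():
                proj[bad_cols] = proj[~bad_cols].mean()
            else:
                flagged[ai] = True
                proj[bad_cols] = 0.0
        coeff = (2.0 / n_u) * (phase @ proj)
        values[ai] = np.abs(coeff)
    return PolarSpectrum(
        angles_deg=angles_deg,
        frequencies=k.astype(float),
        values=values,
        mode="fourier",
        flagged_angles=flagged,
    )


def sinusoid_fit_spectrum(
    acorr: AutocorrMap,
    frequencies: np.ndarray,
    angles_deg: np.ndarray | None = None,
    map_length_mm: float | None = None,
    min_lags: int = 50,
) -> PolarSpectrum:
    """Explained variance of plane-sinusoid fits to the autocorrelation map.

    For each (frequency, orientation), ``A*cos(2*pi*f*p/L + phi) + c`` with
    ``p = dx*cos(theta) + dy*sin(theta)`` is least-squares fitted over the
    defined lags; the value is the explained variance 1 - SSres/SStot,
    floored at 0.  ``L`` defaults to the source map length recorded in the
    autocorrelation map, so frequencies are in cycles per map length.
    """
    if angles_deg is None:
        angles_deg = default_angles()
    angles_deg = np.asarray(angles_deg, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    L = map_length_mm or acorr.map_length_mm
    dx, dy = acorr.lag_mm()
    defined = np.isfinite(acorr.r)
    if defined.sum() < min_lags:
        raise ArgumentError(f"need at least {min_lags} defined lags")
    z = acorr.r[defined]
    dxv, dyv = dx[defined], dy[defined]
    sstot = float(((z - z.mean()) ** 2).sum())
    if sstot == 0:
        raise DegenerateDataError("autocorrelation is constant; fit undefined")
    values = np.zeros((len(angles_deg), len(frequencies)))
    ones = np.ones_like(z)
    for ai, ang in enumerate(angles_deg):
        th = np.deg2rad(ang)
        p = dxv * np.cos(th) + dyv * np.sin(th)
        for fi, f in enumerate(frequencies):
            arg = 2 * np.pi * f * p / L
            A = np.column_stack([np.cos(arg), np.sin(arg), ones])
            coef, *_ = np.linalg.lstsq(A, z, rcond=None)
            ssres = float(((z - A @ coef) ** 2).sum())
            values[ai, fi] = max(0.0, 1.0 - ssres / sstot)
    return PolarSpectrum(
        angles_deg=angles_deg,
        frequencies=frequencies,
        values=values,
        mode="fit",
        flagged_angles=np.zeros(len(angles_deg), dtype=bool),
    )


def _orientation_os(tuning: np.ndarray) -> float:
    """|F(1)|/F(0) of an orientation tuning curve sampled over one 180-deg period."""
    F = np.fft.fft(tuning)
    if np.abs(F[0]) == 0:
        return 0.0
    return float(np.abs(F[1]) / np.abs(F[0]))


def topography_indices(
    spectrum: PolarSpectrum, high_freq_cutoff: float = 3.0
) -> TopographyIndices:
    """Condense a polar spectrum into the four gradient indices.

    * preferred frequency: value-weighted mean frequency of the tuning curve
      ``v(f) = max over orientations``;
    * tuning width: area under the peak-normalized ``v(f)`` curve;
    * orientation selectivity: max over frequencies above the cutoff of
      |F(1)|/F(0) of that frequency's orientation tuning curve;
    * orthogonality: max |cross product| among the per-frequency vectors
      ``OS * (cos theta_pref, sin theta_pref)`` (raw preferred orientation).
    """
    v = spectrum.values
    if v.shape[0] < 8 or v.shape[1] < 3:
        raise ArgumentError("spectrum must cover >= 8 angles and >= 3 frequencies")
    freqs = spectrum.frequencies
    tuning_f = v.max(axis=0)
    total = tuning_f.sum()
    if total == 0:
        raise DegenerateDataError("all-zero spectrum; indices undefined")
    pref_f = float((freqs * tuning_f).sum() / total)
    width = float(np.trapezoid(tuning_f / tuning_f.max(), freqs))
    os_per_f = np.array([_orientation_os(v[:, fi]) for fi in range(len(freqs))])
    theta_pref = spectrum.angles_deg[np.argmax(v, axis=0)]
    vecs = os_per_f[:, None] * np.column_stack(
        [np.cos(np.deg2rad(theta_pref)), np.sin(np.deg2rad(theta_pref))]
    )
    above = freqs > high_freq_cutoff
    os_index = float(os_per_f[above].max()) if above.any() else float(os_per_f.max())
    cross = np.abs(
        vecs[:, 0][:, None] * vecs[:, 1][None, :]
        - vecs[:, 1][:, None] * vecs[:, 0][None, :]
    )
    orth = float(cross.max())
    return TopographyIndices(
        preferred_frequency=pref_f,
        tuning_width=width,
        orientation_selectivity=os_index,
        orthogonality=orth,
        per_frequency_os=os_per_f,
        per_frequency_orientation_deg=theta_pref,
        orientation_vectors=vecs,
    )
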