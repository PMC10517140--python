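"""Synthetic inputs with planted ground truth for every pipeline stage.

Real acquisitions for this kind of study (deep-feature activation matrices,
block-design scans, cortical flat maps and surface meshes) are not freely
redistributable, so each generator here emulates the statistical structure the
downstream stage relies on and keeps the planted parameters, making recovery
testable end to end:

* :func:`gen_latent_sources` — linear mixtures of independent non-Gaussian
  (Laplace) sources, the identifiable regime for ICA.
* :func:`gen_scan_set` — block-design voxel time series with planted 25-D
  selectivity, a hemodynamic phase lag and white noise.
* :func:`gen_gradient_map` — flat-map grids superposing oriented sinusoidal
  feature gradients plus spatially filtered noise.
* :func:`gen_surface_strip` — small triangulated surface strips, optionally
  bent onto a cylinder, with exact flat coordinates.

All generators are deterministic given their ``seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .datatypes import N_DIMS, BlockDesign, FlatFeatureMap, default_block_design, map_from_cell_vectors
from .exceptions import ArgumentError

__all__ = [
    "ActivationMatrix",
    "ScanSet",
    "GradientSpec",
    "SurfaceMesh",
    "gen_latent_sources",
    "gen_scan_set",
    "gen_gradient_map",
    "gen_surface_strip",
    "default_block_design",
]


@dataclass
class ActivationMatrix:
    """An images x units activation matrix, optionally with planted sources."""

    values: np.ndarray  # images x units
    image_ids: np.ndarray  # images
    truth_sources: np.ndarray | None = None  # images x sources
    truth_mixing: np.ndarray | None = None  # sources x units

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.image_ids = np.asarray(self.image_ids)
        if self.values.ndim != 2:
            raise ArgumentError("values must be 2-D (images x units)")
        if len(self.image_ids) != self.values.shape[0]:
            raise ArgumentError("image_ids length must match image count")
        if not np.all(np.isfinite(self.values)):
            raise ArgumentError("values must be finite")
        if self.truth_sources is not None:
            if self.values.shape[0] < 2 * self.truth_sources.shape[1]:
                raise ArgumentError("need images >= 2 x sources when truth present")

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]


@dataclass
class ScanSet:
    """Repeated block-design scans sharing one design and one planted truth."""

    scans: list[np.ndarray]  # each voxels x volumes
    design: BlockDesign
    truth_selectivity: np.ndarray | None = None  # voxels x 25
    axis_index: int | None = None
    phase_lag_s: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        nv = self.design.n_volumes
        for s in self.scans:
            if s.shape[1] != nv:
                raise ArgumentError(
                    f"each scan must have {nv} volumes (total duration / tr)"
                )

    @property
    def n_voxels(self) -> int:
        return self.scans[0].shape[0]

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def mean_scan(self) -> np.ndarray:
        return np.mean(self.scans, axis=0)


@dataclass(frozen=True)
class GradientSpec:
    """One oriented sinusoidal feature gradient on the flat map.

    ``frequency`` is in cycles per map length (longer side of the mask's
    bounding box); ``orientation`` in degrees within [-90, 90).
    """

    axis: np.ndarray  # 25-D unit vector
    frequency: float  # cycles per map length
    orientation_deg: float
    amplitude: float = 1.0
    phase: float = 0.0

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ArgumentError("gradient axis must be nonzero")
        object.__setattr__(self, "axis", axis / n)
        if self.frequency <= 0:
            raise ArgumentError("frequency must be positive")


@dataclass
class SurfaceMesh:
    """A triangulated surface patch with matched flat-map coordinates."""

    vertices_3d: np.ndarray  # n x 3 mm
    vertices_2d: np.ndarray  # n x 2 mm
    faces: np.ndarray  # m x 3 vertex indices

    def __post_init__(self):
        self.vertices_3d = np.asarray(self.vertices_3d, dtype=float)
        self.vertices_2d = np.asarray(self.vertices_2d, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices_3d.shape[0] != self.vertices_2d.shape[0]:
            raise ArgumentError("2-D and 3-D vertex tables must have equal length")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= self.vertices_3d.shape[0]
        ):
            raise ArgumentError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertices_3d.shape[0]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_latent_sources(
    n_images: int,
    n_units: int,
    n_sources: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    mixing: np.ndarray | None = None,
) -> ActivationMatrix:
    """Linear mixture of independent Laplace sources plus Gaussian noise.

    Sources are zero-mean, unit-scale Laplace (super-Gaussian), the canonical
    identifiable family for ICA.  ``mixing`` defaults to a random Gaussian
    sources x units matrix; pass an explicit matrix (e.g. identity) for exact
    round-trip fixtures.
    """
    if min(n_images, n_units, n_sources) <= 0:
        raise ArgumentError("counts must be positive")
    if n_sources > n_units:
        raise ArgumentError("n_sources must not exceed n_units")
    if n_images < 4 * n_sources:
        raise ArgumentError("need n_images >= 4 x n_sources")
    rng = np.random.default_rng(seed)
    sources = rng.laplace(loc=0.0, scale=1.0, size=(n_images, n_sources))
    if mixing is None:
        mixing = rng.normal(size=(n_sources, n_units))
    else:
        mixing = np.asarray(mixing, dtype=float)
        if mixing.shape != (n_sources, n_units):
            raise ArgumentError("mixing must be sources x units")
    values = sources @ mixing
    if noise_sd > 0:
        values = values + rng.normal(scale=noise_sd, size=values.shape)
    ids = np.array([f"img{i:06d}" for i in range(n_images)])
    return ActivationMatrix(values, ids, truth_sources=sources, truth_mixing=mixing)


def gen_scan_set(
    design: BlockDesign,
    truth_selectivity: np.ndarray,
    axis_index: int,
    phase_lag_s: float = 4.0,
    noise_sd: float = 0.1,
    n_scans: int = 2,
    seed: int = 0,
    control_amplitude: float = 1.0,
    baseline: float = 0.0,
) -> ScanSet:
    """Block-design scans with planted selectivity along one object-space axis.

    Each voxel's signal is a boxcar: ``+s`` over positive blocks and ``-s``
    over negative blocks, where ``s = truth_selectivity[voxel, axis_index]``;
    the control block carries a uniform positive boxcar of height
    ``control_amplitude`` and gray blocks carry baseline only.  Hemodynamics
    are modeled as a pure delay of ``phase_lag_s`` (the Fourier stage only
    uses phase, not response shape), then white Gaussian noise is added.
    """
    truth = np.asarray(truth_selectivity, dtype=float)
    if truth.ndim != 2:
        raise ArgumentError("truth_selectivity must be voxels x n_dims")
    if not np.all(np.isfinite(truth)):
        raise ArgumentError("truth_selectivity must be finite")
    if not (0 <= axis_index < truth.shape[1]):
        raise ArgumentError(f"axis_index {axis_index} out of range")
    if n_scans < 1:
        raise ArgumentError("n_scans must be >= 1")
    rng = np.random.default_rng(seed)
    sel = truth[:, axis_index]

    n_vol = design.n_volumes
    t = np.arange(n_vol) * design.tr_s - phase_lag_s
    pos = np.zeros(n_vol)
    ctrl = np.zeros(n_vol)
    for i, ti in enumerate(t):
        lab = design.block_at_time(ti)
        if lab == "positive":
            pos[i] = 1.0
        elif lab == "negative":
            pos[i] = -1.0
        elif lab == "control":
            ctrl[i] = 1.0
    clean = sel[:, None] * pos[None, :] + control_amplitude * ctrl[None, :] + baseline
    scans = []
    for _ in range(n_scans):
        noise = rng.normal(scale=noise_sd, size=clean.shape) if noise_sd > 0 else 0.0
        scans.append(clean + noise)
    return ScanSet(
        scans=scans,
        design=design,
        truth_selectivity=truth,
        axis_index=axis_index,
        phase_lag_s=phase_lag_s,
        noise_sd=noise_sd,
    )


def gen_gradient_map(
    mask: np.ndarray,
    gradients: list[GradientSpec],
    noise_amplitude: float = 0.0,
    noise_filter_width_mm: float = 3.0,
    cell_size_mm: float = 2.0,
    seed: int = 0,
) -> FlatFeatureMap:
    """Flat-map grid superposing oriented sinusoidal gradients plus noise.

    Per cell, the 25-D vector is the sum over gradients of
    ``amplitude * sin(2*pi*f*(x cos(theta) + y sin(theta))/L + phase) * axis``
    with ``L`` the longer side of the mask's bounding box, plus spatially
    filtered Gaussian noise (isotropic Gaussian kernel of the given width,
    rescaled to unit standard deviation over valid cells before applying
    ``noise_amplitude``).  Cell vectors are then normalized to unit length;
    cells landing at exactly zero norm (sine zero crossings with no noise)
    are dropped from the mask.  The planted specs are kept in ``meta``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ArgumentError("empty mask")
    if mask.sum() < 100:
        raise ArgumentError("mask must contain at least 100 valid cells")
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(mask)
    x = (cols + 0.5) * cell_size_mm
    y = (rows + 0.5) * cell_size_mm
    h = (rows.max() - rows.min() + 1) * cell_size_mm
    w = (cols.max() - cols.min() + 1) * cell_size_mm
    L = float(max(h, w))

    n_dims = gradients[0].axis.shape[0] if gradients else N_DIMS
    field_vals = np.zeros((mask.sum(), n_dims))
    for g in gradients:
        theta = np.deg2rad(g.orientation_deg)
        proj = x * np.cos(theta) + y * np.sin(theta)
        wave = g.amplitude * np.sin(2 * np.pi * g.frequency * proj / L + g.phase)
        field_vals += wave[:, None] * g.axis[None, :]

    if noise_amplitude > 0:
        white = rng.normal(size=mask.shape + (n_dims,))
        sigma = noise_filter_width_mm / cell_size_mm
        filt = gaussian_filter(white, sigma=(sigma, sigma, 0))
        sd = filt[mask].std()
        if sd > 0:
            field_vals += noise_amplitude * filt[mask] / sd

    fmap = map_from_cell_vectors(field_vals, mask, cell_size_mm=cell_size_mm)
    fmap.meta["truth_gradients"] = list(gradients)
    fmap.meta["map_length_mm"] = L
    fmap.meta["noise_amplitude"] = noise_amplitude
    return fmap


def gen_surface_strip(
    rows: int,
    cols: int,
    spacing_mm: float = 0.5,
    bend_radius_mm: float | None = None,
) -> SurfaceMesh:
    """Regular triangulated strip; optionally bent onto a cylinder.

    The flat-map coordinates are the regular lattice.  When bent, the x
    coordinate becomes arc length along a cylinder of the given radius (axis
    parallel to y), so geodesic distances along x equal flat distances while
    3-D chords are shorter.
    """
    if rows < 2 or cols < 2:
        raise ArgumentError("rows and cols must both be >= 2")
    if spacing_mm <= 0:
        raise ArgumentError("spacing must be positive")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = cc.ravel() * spacing_mm
    y = rr.ravel() * spacing_mm
    v2 = np.column_stack([x, y])
    if bend_radius_mm is None:
        v3 = np.column_stack([x, y, np.zeros_like(x)])
    else:
        if bend_radius_mm <= 0:
            raise ArgumentError("bend radius must be positive")
        R = bend_radius_mm
        v3 = np.column_stack([R * np.sin(x / R), y, R * (1 - np.cos(x / R))])
    faces = []
    for r in range(rows - 1):
        for c in range(cols - 1):
            v = r * cols + c
            faces.append((v, v + 1, v + cols))
            faces.append((v + 1, v + cols + 1, v + cols))
    return SurfaceMesh(vertices_3d=v3, vertices_2d=v2, faces=np.array(faces))
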