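"""Shared containers: the block design of a scan and the gridded feature map.

Both types are consumed by several modules (generation, selectivity extraction,
parcellation, topography), so they live here rather than in any single stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ArgumentError

#: labels a block may carry
BLOCK_LABELS = ("positive", "negative", "control", "gray")

#: dimensionality of the object space used throughout
N_DIMS = 25


@dataclass(frozen=True)
class BlockDesign:
    """Timing and labeling of one block-design scan.

    A scan is a sequence of equal-length blocks, each labeled ``positive``,
    ``negative``, ``control`` or ``gray``.  ``analysis_blocks`` are the block
    indices entering the positive/negative alternation Fourier analysis; they
    must contain equal numbers of positive and negative blocks.
    """

    block_labels: tuple[str, ...]
    block_duration_s: float
    tr_s: float
    analysis_blocks: tuple[int, ...]

    def __post_init__(self):
        for lab in self.block_labels:
            if lab not in BLOCK_LABELS:
                raise ArgumentError(f"unknown block label {lab!r}")
        if self.block_duration_s <= 0 or self.tr_s <= 0:
            raise ArgumentError("block_duration_s and tr_s must be positive")
        ratio = self.block_duration_s / self.tr_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ArgumentError("block_duration_s must be divisible by tr_s")
        labs = [self.block_labels[i] for i in self.analysis_blocks]
        n_pos = labs.count("positive")
        n_neg = labs.count("negative")
        if n_pos != n_neg or n_pos == 0:
            raise ArgumentError(
                "analysis_blocks must contain equal, nonzero counts of "
                f"positive and negative blocks (got {n_pos} vs {n_neg})"
            )
        if any(i < 0 or i >= len(self.block_labels) for i in self.analysis_blocks):
            raise ArgumentError("analysis_blocks index out of range")

    # -- derived timing ------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.block_labels)

    @property
    def total_duration_s(self) -> float:
        return self.n_blocks * self.block_duration_s

    @property
    def volumes_per_block(self) -> int:
        return int(round(self.block_duration_s / self.tr_s))

    @property
    def n_volumes(self) -> int:
        return self.n_blocks * self.volumes_per_block

    @property
    def n_alternation_cycles(self) -> int:
        """Number of positive/negative cycles inside the analysis window."""
        labs = [self.block_labels[i] for i in self.analysis_blocks]
        return labs.count("positive")

    def volume_labels(self) -> np.ndarray:
        """Block label of every volume (sampling at the volume start time)."""
        return np.repeat(np.array(self.block_labels, dtype=object), self.volumes_per_block)

    def block_at_time(self, t_s: float) -> str | None:
        """Label of the block covering time ``t_s``; None outside the scan."""
        if t_s < 0 or t_s >= self.total_duration_s:
            return None
        return self.block_labels[int(t_s // self.block_duration_s)]


def default_block_design() -> BlockDesign:
    """The canonical seventeen-block, 408-s scan sampled at 2-s volumes.

    Layout: two lead-in positive blocks, a twelve-block negative/positive
    alternation (six cycles, the analysis window), then a control block, the
    gray block that follows it (used for control normalization), and a final
    gray block.  Eight positive and six negative blocks in total; 204 volumes.
    """
    labels = ("positive", "positive") + ("negative", "positive") * 6 + (
        "control",
        "gray",
        "gray",
    )
    return BlockDesign(
        block_labels=labels,
        block_duration_s=24.0,
        tr_s=2.0,
        analysis_blocks=tuple(range(2, 14)),
    )


@dataclass
class FlatFeatureMap:
    """A flattened cortical sheet resampled to square cells.

    ``grid`` holds one ``n_dims`` preference vector per cell; wherever ``mask``
    is true the vector has unit norm.  ``provenance`` counts the vertices that
    fell into each cell (zero for synthetic maps built directly on the grid).
    """

    grid: np.ndarray  # rows x cols x n_dims
    mask: np.ndarray  # rows x cols bool
    cell_size_mm: float = 2.0
    provenance: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.ndim != 3 or self.grid.shape[:2] != self.mask.shape:
            raise ArgumentError("grid must be rows x cols x n_dims matching mask")

    @property
    def n_dims(self) -> int:
        return self.grid.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def vectors(self) -> np.ndarray:
        """Valid-cell vectors, shape (n_valid, n_dims), row-major cell order."""
        return self.grid[self.mask]

    def cell_centers_mm(self) -> np.ndarray:
        """(x, y) centers of the valid cells in mm, matching ``vectors`` order."""
        rows, cols = np.nonzero(self.mask)
        return np.column_stack([(cols + 0.5), (rows + 0.5)]) * self.cell_size_mm

    def component(self, i: int) -> np.ndarray:
        """Scalar map of component ``i`` with NaN outside the mask."""
        out = np.where(self.mask, self.grid[:, :, i], np.nan)
        return out

    def map_length_mm(self) -> float:
        """Longer side of the valid-cell bounding box, in mm."""
        rows, cols = np.nonzero(self.mask)
        if rows.size == 0:
            raise ArgumentError("empty mask")
        h = (rows.max() - rows.min() + 1) * self.cell_size_mm
        w = (cols.max() - cols.min() + 1) * self.cell_size_mm
        return float(max(h, w))


def map_from_cell_vectors(
    vectors: np.ndarray,
    mask: np.ndarray,
    cell_size_mm: float = 2.0,
    normalize: bool = True,
    meta: dict | None = None,
) -> FlatFeatureMap:
    """Assemble a FlatFeatureMap from per-valid-cell vectors (row-major order).

    Cells whose vector has (numerically) zero norm are removed from the mask.
    """
    vectors = np.asarray(vectors, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if vectors.shape[0] != int(mask.sum()):
        raise ArgumentError("vector count must equal number of valid cells")
    norms = np.linalg.norm(vectors, axis=1)
    good = norms > 1e-12
    out_vectors = vectors.copy()
    if normalize:
        out_vectors[good] = vectors[good] / norms[good, None]
    grid = np.zeros(mask.shape + (vectors.shape[1],))
    grid[mask] = out_vectors
    new_mask = mask.copy()
    new_mask[mask] = good
    grid[~new_mask] = 0.0
    return FlatFeatureMap(
        grid=grid, mask=new_mask, cell_size_mm=cell_size_mm, meta=meta or {}
    )
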