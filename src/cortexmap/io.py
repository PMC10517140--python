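"""Serialization of the core containers.

HDF5 for dense numeric containers (object spaces, feature maps), CSV for
tabular artifacts (selections, vertex tables, feature axes), plain-text 0/1
grids for masks.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import FlatFeatureMap
from .space import ImageSelection, ObjectSpace
from .synthetic import SurfaceMesh

__all__ = [
    "save_feature_map",
    "load_feature_map",
    "save_object_space",
    "load_object_space",
    "selections_to_csv",
    "feature_map_to_csv",
    "save_mesh_csv",
    "load_mesh_csv",
    "save_mask_txt",
    "load_mask_txt",
]


def save_feature_map(path, fmap: FlatFeatureMap) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("grid", data=fmap.grid)
        f.create_dataset("mask", data=fmap.mask)
        f.attrs["cell_size_mm"] = fmap.cell_size_mm
        if fmap.provenance is not None:
            f.create_dataset("provenance", data=fmap.provenance)


def load_feature_map(path) -> FlatFeatureMap:
    import h5py

    with h5py.File(path, "r") as f:
        prov = f["provenance"][...] if "provenance" in f else None
        return FlatFeatureMap(
            grid=f["grid"][...],
            mask=f["mask"][...].astype(bool),
            cell_size_mm=float(f.attrs["cell_size_mm"]),
            provenance=prov,
        )


def save_object_space(path, space: ObjectSpace) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("mean", "whitening", "rotation", "axes"):
            f.create_dataset(name, data=getattr(space, name))
        f.attrs["explained_variance_fraction"] = space.explained_variance_fraction


def load_object_space(path) -> ObjectSpace:
    import h5py

    with h5py.File(path, "r") as f:
        return ObjectSpace(
            mean=f["mean"][...],
            whitening=f["whitening"][...],
            rotation=f["rotation"][...],
            axes=f["axes"][...],
            explained_variance_fraction=float(f.attrs["explained_variance_fraction"]),
        )


def selections_to_csv(path, selections: list[ImageSelection]) -> None:
    rows = []
    for sel in selections:
        for pole, ids, angs in (
            ("positive", sel.positive_ids, sel.positive_angles_deg),
            ("negative", sel.negative_ids, sel.negative_angles_deg),
        ):
            for i, a in zip(ids, angs):
                rows.append(
                    {"axis_id": sel.axis_id, "pole": pole, "image_id": i, "angle_deg": a}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def feature_map_to_csv(path, fmap: FlatFeatureMap) -> None:
    """Long format: one row per (row, col, component, value) over valid cells."""
    rows_i, cols_i = np.nonzero(fmap.mask)
    recs = []
    for r, c in zip(rows_i, cols_i):
        for k in range(fmap.n_dims):
            recs.append({"row": r, "col": c, "ic": k, "value": fmap.grid[r, c, k]})
    pd.DataFrame(recs).to_csv(path, index=False)


def save_mesh_csv(vertex_path, face_path, mesh: SurfaceMesh) -> None:
    pd.DataFrame(
        {
            "x2d": mesh.vertices_2d[:, 0],
            "y2d": mesh.vertices_2d[:, 1],
            "x3d": mesh.vertices_3d[:, 0],
            "y3d": mesh.vertices_3d[:, 1],
            "z3d": mesh.vertices_3d[:, 2],
        }
    ).to_csv(vertex_path, index=False)
    pd.DataFrame(mesh.faces, columns=["v0", "v1", "v2"]).to_csv(face_path, index=False)


def load_mesh_csv(vertex_path, face_path) -> SurfaceMesh:
    v = pd.read_csv(vertex_path)
    faces = pd.read_csv(face_path).to_numpy()
    return SurfaceMesh(
        vertices_3d=v[["x3d", "y3d", "z3d"]].to_numpy(),
        vertices_2d=v[["x2d", "y2d"]].to_numpy(),
        faces=faces,
    )


def save_mask_txt(path, mask: np.ndarray) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")


def load_mask_txt(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).astype(bool)
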