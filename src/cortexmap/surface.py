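"""Geodesics on a cortical surface patch via shortest paths on a vertex graph.

The surface is modeled as a graph whose nodes are mesh vertices.  An edge
joins two vertices when their 3-D Euclidean distance is below 1 mm AND their
flat-map 2-D distance is below 1.5 mm (both strict); the edge weight is the
3-D distance.  Because this leaves many connected components, component
pairs within the smallest 1% of inter-component distances are merged (single
pass) by adding an edge between their closest vertex pair, subject to the
same 1.5 mm flat-map check.  Geodesic distance between two vertices is then
the Dijkstra shortest-path length; comparing it with the straight flat-map
distance along different orientations quantifies flattening distortion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import ArgumentError, DegenerateDataError, UnreachableError
from .synthetic import SurfaceMesh

__all__ = [
    "SurfaceGraph",
    "GeodesicPath",
    "build_graph",
    "merge_components",
    "geodesic",
    "geodesic_vs_flat",
    "line_centers",
]


@dataclass
class SurfaceGraph:
    """Weighted vertex graph plus stable connected-component labels."""

    graph: nx.Graph
    component_labels: np.ndarray  # per-vertex component id

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1

    def largest_component(self) -> np.ndarray:
        ids, counts = np.unique(self.component_labels, return_counts=True)
        return np.nonzero(self.component_labels == ids[np.argmax(counts)])[0]


@dataclass
class GeodesicPath:
    """A shortest along-surface path between two vertices."""

    vertices: list[int]
    length_mm: float
    flat_distance_mm: float


def _component_labels(g: nx.Graph, n_vertices: int) -> np.ndarray:
    labels = np.full(n_vertices, -1, dtype=int)
    comps = sorted(nx.connected_components(g), key=min)
    for lab, comp in enumerate(comps):
        for v in comp:
            labels[v] = lab
    return labels


def build_graph(mesh: SurfaceMesh, d3_max: float = 1.0, d2_max: float = 1.5) -> SurfaceGraph:
    """Edges between all vertex pairs meeting both distance criteria.

    Both thresholds are strict ("less than"); the 3-D distance is the weight.
    """
    v3, v2 = mesh.vertices_3d, mesh.vertices_2d
    tree = cKDTree(v3)
    pairs = np.array(sorted(tree.query_pairs(d3_max)), dtype=int)
    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_vertices))
    n_edges = 0
    if pairs.size:
        d3 = np.linalg.norm(v3[pairs[:, 0]] - v3[pairs[:, 1]], axis=1)
        d2 = np.linalg.norm(v2[pairs[:, 0]] - v2[pairs[:, 1]], axis=1)
        ok = (d3 < d3_max) & (d2 < d2_max)
        for (i, j), w in zip(pairs[ok], d3[ok]):
            g.add_edge(int(i), int(j), weight=float(w))
            n_edges += 1
    if n_edges == 0:
        raise DegenerateDataError("no edges satisfy the distance criteria")
    return SurfaceGraph(graph=g, component_labels=_component_labels(g, mesh.n_vertices))


def merge_components(
    sgraph: SurfaceGraph,
    mesh: SurfaceMesh,
    percentile: float = 1.0,
    d2_max: float = 1.5,
) -> SurfaceGraph:
    """Single-pass merge of the closest component pairs.

    Inter-component distance is the minimum pairwise 3-D vertex distance.
    Pairs within the smallest ``percentile`` percent are joined by an edge
    between their closest vertex pair, provided the flat-map distance of that
    pair is below ``d2_max``; closest-pair ties break toward the lowest
    vertex-id pair.  The graph may legitimately stay disconnected.
    """
    labels = sgraph.component_labels
    comps = [np.nonzero(labels == c)[0] for c in range(labels.max() + 1)]
    if len(comps) < 2:
        return sgraph
    v3, v2 = mesh.vertices_3d, mesh.vertices_2d
    trees = [cKDTree(v3[c]) for c in comps]
    cand = []  # (distance, vi, vj) per component pair
    for a in range(len(comps)):
        for b in range(a + 1, len(comps)):
            # query the smaller side against the larger side's tree
            if len(comps[a]) <= len(comps[b]):
                small, tree, big = comps[a], trees[b], comps[b]
            else:
                small, tree, big = comps[b], trees[a], comps[a]
            d, idx = tree.query(v3[small])
            best = np.nanmin(d)
            ties = np.nonzero(d == best)[0]
            pairs = sorted(
                (min(small[t], big[idx[t]]), max(small[t], big[idx[t]])) for t in ties
            )
            vi, vj = pairs[0]
            cand.append((float(best), int(vi), int(vj)))
    dists = np.array([c[0] for c in cand])
    thr = np.percentile(dists, percentile)
    g = sgraph.graph.copy()
    for dist, vi, vj in cand:
        if dist <= thr and np.linalg.norm(v2[vi] - v2[vj]) < d2_max:
            g.add_edge(vi, vj, weight=dist)
    return SurfaceGraph(graph=g, component_labels=_component_labels(g, mesh.n_vertices))


def geodesic(sgraph: SurfaceGraph, src: int, dst: int, mesh: SurfaceMesh | None = None) -> GeodesicPath:
    """Dijkstra shortest path; raises UnreachableError across components."""
    labels = sgraph.component_labels
    if labels[src] != labels[dst]:
        raise UnreachableError(int(labels[src]), int(labels[dst]))
    path = nx.dijkstra_path(sgraph.graph, src, dst)
    length = float(nx.dijkstra_path_length(sgraph.graph, src, dst))
    flat = float("nan")
    if mesh is not None:
        flat = float(np.linalg.norm(mesh.vertices_2d[src] - mesh.vertices_2d[dst]))
    return GeodesicPath(vertices=[int(v) for v in path], length_mm=length, flat_distance_mm=flat)


def line_centers(
    center_xy: tuple[float, float], angle_deg: float, n: int, spacing_mm: float
) -> np.ndarray:
    """Square centers evenly spaced along a line through ``center_xy``."""
    t = (np.arange(n) - (n - 1) / 2) * spacing_mm
    th = np.deg2rad(angle_deg)
    return np.column_stack(
        [center_xy[0] + t * np.cos(th), center_xy[1] + t * np.sin(th)]
    )


def _representative_vertex(
    mesh: SurfaceMesh, center: np.ndarray, half: float, largest: np.ndarray
) -> int | None:
    v2 = mesh.vertices_2d
    inside = np.nonzero(
        (np.abs(v2[:, 0] - center[0]) <= half) & (np.abs(v2[:, 1] - center[1]) <= half)
    )[0]
    if inside.size == 0:
        return None
    mean3 = mesh.vertices_3d[inside].mean(axis=0)
    rep = int(inside[np.argmin(np.linalg.norm(mesh.vertices_3d[inside] - mean3, axis=1))])
    if rep not in set(largest.tolist()):
        # fall back to the nearest vertex of the largest component
        d = np.linalg.norm(mesh.vertices_3d[largest] - mesh.vertices_3d[rep], axis=1)
        rep = int(largest[np.argmin(d)])
    return rep


def geodesic_vs_flat(
    sgraph: SurfaceGraph,
    mesh: SurfaceMesh,
    centers_by_orientation: dict,
    square_size_mm: float = 2.0,
    min_pairs: int = 1,
) -> pd.DataFrame:
    """Geodesic / flat distance ratios for square pairs along orientations.

    ``centers_by_orientation`` maps an orientation label to an array of 2-D
    square centers; each square is represented by the vertex closest (3-D) to
    the mean 3-D coordinate of the square's vertices, constrained to the
    largest connected component.  Rows: orientation, pair indices, geodesic
    and flat distances, their ratio.  Orientations with too few valid pairs
    are flagged with a warning and omitted.
    """
    largest = sgraph.largest_component()
    half = square_size_mm / 2
    rows = []
    for label, centers in centers_by_orientation.items():
        centers = np.asarray(centers, dtype=float)
        reps = [
            _representative_vertex(mesh, c, half, largest) for c in centers
        ]
        reps = [r for r in reps if r is not None]
        reps = list(dict.fromkeys(reps))  # drop duplicates, keep order
        n_pairs = 0
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                try:
                    p = geodesic(sgraph, reps[i], reps[j], mesh)
                except UnreachableError:
                    continue
                if p.flat_distance_mm <= 0:
                    continue
                rows.append(
                    {
                        "orientation": label,
                        "i": reps[i],
                        "j": reps[j],
                        "geodesic_mm": p.length_mm,
                        "flat_mm": p.flat_distance_mm,
                        "ratio": p.length_mm / p.flat_distance_mm,
                    }
                )
                n_pairs += 1
        if n_pairs < min_pairs:
            warnings.warn(f"orientation {label!r}: too few valid square pairs")
    return pd.DataFrame(rows)
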