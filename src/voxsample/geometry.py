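"""Spatial context: nucleus neighbour graphs and geometry distances.

Neighbourhood is defined by the Delaunay tetrahedralization of nuclear
centres, pruned by a physical distance cutoff (raw Delaunay links distant
hull points). Distances to the exposed tissue surface and to user regions of
interest are exact Euclidean point-to-voxel-centre / point-to-segment
distances in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .io import ROISet


@dataclass
class NeighbourGraph:
    nodes: list = field(default_factory=list)
    edges: list = field(default_factory=list)  # (id_lo, id_hi) pairs
    distances: dict = field(default_factory=dict)  # edge -> µm

    def neighbours(self, node):
        out = []
        for i, j in self.edges:
            if i == node:
                out.append(j)
            elif j == node:
                out.append(i)
        return sorted(out)


def _delaunay_edges(points: np.ndarray) -> set:
    """Edge set of the Delaunay triangulation, robust to degenerate rank.

    Collinear input falls back to consecutive-neighbour edges; coplanar input
    to a 2D triangulation in the plane's principal basis.
    """
    n = len(points)
    if n < 2:
        return set()
    if n == 2:
        return {(0, 1)}
    centred = points - points.mean(axis=0)
    # effective rank decides the triangulation dimension
    svals = np.linalg.svd(centred, compute_uv=False)
    tol = max(points.shape) * np.finfo(float).eps * (svals[0] if svals[0] > 0 else 1)
    rank = int(np.sum(svals > max(tol, 1e-9)))
    if rank <= 1:
        axis = np.argmax(points.max(axis=0) - points.min(axis=0))
        order = np.argsort(points[:, axis], kind="stable")
        return {tuple(sorted((order[k], order[k + 1]))) for k in range(n - 1)}
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    dim = min(rank, 3)
    if n <= dim + 1:
        return {(i, j) for i in range(n) for j in range(i + 1, n)}
    proj = centred @ vt[:dim].T
    try:
        tri = Delaunay(proj)
    except QhullError:
        if dim == 2:
            raise
        return _delaunay_edges_2d_fallback(centred, vt)
    edges = set()
    for simplex in tri.simplices:
        for a in range(len(simplex)):
            for b in range(a + 1, len(simplex)):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    return edges


def _delaunay_edges_2d_fallback(centred, vt):
    proj = centred @ vt[:2].T
    tri = Delaunay(proj)
    edges = set()
    for simplex in tri.simplices:
        for a in range(len(simplex)):
            for b in range(a + 1, len(simplex)):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    return edges


def build_neighbour_graph(nuclei, max_edge_um=np.inf) -> NeighbourGraph:
    """Delaunay edges of nucleus centres pruned to <= ``max_edge_um``."""
    nuclei = sorted(nuclei, key=lambda n: n.id)
    graph = NeighbourGraph(nodes=[n.id for n in nuclei])
    if len(nuclei) < 2:
        return graph
    pts = np.stack([n.centre_um for n in nuclei])
    ids = [n.id for n in nuclei]
    for a, b in sorted(_delaunay_edges(pts)):
        d = float(np.linalg.norm(pts[a] - pts[b]))
        if 0 < d <= max_edge_um:
            edge = (min(ids[a], ids[b]), max(ids[a], ids[b]))
            graph.edges.append(edge)
            graph.distances[edge] = d
    return graph


def distance_to_surface(point_um, surface) -> float | None:
    """Minimum Euclidean distance (µm) from a point to any exposed-surface
    voxel centre; None when the surface is empty."""
    coords = surface.coords_um if hasattr(surface, "coords_um") else np.asarray(surface)
    if coords.size == 0:
        return None
    d = np.linalg.norm(coords - np.asarray(point_um, dtype=float), axis=1)
    return float(d.min())


def _point_segment_distance(p, a, b) -> float:
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def distance_to_roi(point_um, roi: ROISet) -> list:
    """Distance (µm) to every ROI in file order.

    Point ROIs use the Euclidean distance; polyline ROIs the minimum over
    their segments (exact point-to-segment formula).
    """
    p = np.asarray(point_um, dtype=float)
    out = []
    for kind, coords in roi.rois:
        if kind == "point":
            out.append(float(np.linalg.norm(p - coords)))
        else:
            out.append(min(_point_segment_distance(p, coords[k], coords[k + 1])
                           for k in range(len(coords) - 1)))
    return out
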