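"""Adaptive facet decomposition: 1-to-3 barycentric splits of large triangles.

As the surface inflates, the dual (virtual) triangles grow; once a facet
cannot fit into a narrow protrusion the mesh stops tracking it.  A pass over
the dual triangulation inserts a vertex at the gravity center of every
triangle whose area exceeds a threshold, replacing it by three triangles of
one third the area each, and then rebuilds the simplex mesh from the refined
triangulation.  Splitting is purely geometric — no image term is consulted;
the next deformation step moves the new vertices.

Splits are decided against the triangulation snapshot taken at pass start
(no cascading within a pass), so every pass reduces the maximum oversized
area by a factor of 3 and repeated passes on a static mesh terminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simplex_mesh import (
    DualTriangulation,
    SimplexMesh,
    _simplex_from_tri,
    dual_triangulation,
)

__all__ = ["RefineParams", "RefineResult", "triangle_area", "decompose_pass"]

log = logging.getLogger(__name__)


@dataclass
class RefineParams:
    """area_threshold in voxel^2 (default 8, about a 4-voxel edge scale, so
    facets stay at the narrowest-feature scale the model is meant to track);
    max_vertices caps runaway subdivision."""

    area_threshold: float = 8.0
    max_vertices: int = 20000

    def __post_init__(self) -> None:
        if self.area_threshold <= 0:
            raise ValueError("area_threshold must be > 0")
        if self.max_vertices <= 0:
            raise ValueError("max_vertices must be > 0")


@dataclass
class RefineResult:
    mesh: SimplexMesh
    n_splits: int
    vertex_parent: np.ndarray  # (V_new,) old simplex-vertex id per new vertex
    triangulation: DualTriangulation | None = None  # the refined dual, at split time


def triangle_area(tri) -> float | np.ndarray:
    """Area(s) of triangle(s) given as (..., 3 corners, 3 coords)."""
    tri = np.asarray(tri, np.float64)
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)
    return float(area) if np.ndim(area) == 0 else area


def decompose_pass(mesh: SimplexMesh, params: RefineParams) -> RefineResult:
    """One decomposition pass; returns the refined mesh and split count.

    Each split adds one vertex, two faces and three edges to the dual
    triangulation (and two degree-3 vertices to the simplex mesh); the total
    surface area is unchanged at split time.  Unsplit triangles keep their
    simplex vertex's position; the three children of a split triangle get
    simplex vertices at the child barycenters.
    """
    tri = dual_triangulation(mesh)
    verts = tri.tri_vertices
    faces = tri.triangles
    areas = triangle_area(verts[faces])
    to_split = np.where(areas > params.area_threshold)[0]

    budget = (params.max_vertices - mesh.n_vertices) // 2  # each split adds 2 simplex vertices
    if len(to_split) > max(budget, 0):
        log.warning(
            "refinement cap: %d of %d oversized facets split (max_vertices=%d)",
            max(budget, 0), len(to_split), params.max_vertices,
        )
        to_split = to_split[: max(budget, 0)]
    if len(to_split) == 0:
        return RefineResult(mesh=mesh, n_splits=0,
                            vertex_parent=np.arange(mesh.n_vertices),
                            triangulation=tri)

    split_set = set(to_split.tolist())
    new_verts = [verts]
    new_faces = []
    parent = []
    positions = []
    next_vid = len(verts)
    for fi, (a, b, c) in enumerate(faces):
        if fi in split_set:
            g = verts[[a, b, c]].mean(axis=0)
            new_verts.append(g[None, :])
            m = next_vid
            next_vid += 1
            # children keep the parent vertex's offset from its dual triangle,
            # so the represented surface is unchanged by the split (dual
            # barycenters lie inside the surface; placing children there
            # would dent the mesh inward at every split)
            offset = mesh.positions[fi] - g
            children = [(a, b, m), (b, c, m), (c, a, m)]
            for ch in children:
                new_faces.append(ch)
                parent.append(fi)
                corner = np.vstack([verts[ch[0]], verts[ch[1]], g])
                positions.append(corner.mean(axis=0) + offset)
        else:
            new_faces.append((a, b, c))
            parent.append(fi)
            positions.append(mesh.positions[fi])

    all_verts = np.vstack(new_verts)
    refined_tri = DualTriangulation(all_verts, np.asarray(new_faces, np.int64))
    refined = _simplex_from_tri(refined_tri.tri_vertices, refined_tri.triangles,
                                positions=np.asarray(positions, np.float64))
    return RefineResult(mesh=refined, n_splits=len(to_split),
                        vertex_parent=np.asarray(parent, np.int64),
                        triangulation=refined_tri)
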