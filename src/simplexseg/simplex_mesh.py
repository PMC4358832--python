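"""The 2-simplex mesh: a closed surface where every vertex has 3 neighbors.

A 2-simplex mesh is the topological dual of a closed triangulation: each
simplex vertex corresponds to a triangle (and sits near its gravity center),
each simplex face corresponds to a triangulation vertex, and simplex edges
correspond to triangulation edges.  The constant degree-3 connectivity is
what makes the per-vertex geometry (neighbor plane, circumcircle, simplex
angle) well defined at every vertex.

Orientation convention: each neighbor triple is ordered counterclockwise
when viewed from outside the surface, so the cyclic cross-product normal of
the neighbor triangle points outward.  This fixes the sign of the vertex
normal and hence the balloon direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "SimplexMesh",
    "DualTriangulation",
    "ValidationReport",
    "MeshTopologyError",
    "init_simplex_sphere",
    "dual_triangulation",
    "rebuild_from_triangulation",
    "validate",
]


class MeshTopologyError(ValueError):
    """Open, non-manifold, or otherwise invalid mesh topology."""


@dataclass
class SimplexMesh:
    positions: np.ndarray  # (V, 3) float, voxel-index coordinates
    neighbors: np.ndarray  # (V, 3) int, ordered CCW from outside
    faces: list  # list of cyclic vertex-id lists (polygonal simplex faces)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.neighbors = np.asarray(self.neighbors, dtype=np.int64)
        self.faces = [list(map(int, f)) for f in self.faces]

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_edges(self) -> int:
        return 3 * len(self.positions) // 2

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class DualTriangulation:
    """The (virtual) triangle mesh dual to a simplex mesh.

    ``tri_vertices[j]`` is the barycenter of simplex face j; ``triangles[i]``
    is the triangle of face-barycenters surrounding simplex vertex i, wound
    so its normal points outward.
    """

    tri_vertices: np.ndarray  # (F, 3) float
    triangles: np.ndarray  # (V, 3) int

    def __post_init__(self) -> None:
        self.tri_vertices = np.asarray(self.tri_vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)


@dataclass
class ValidationReport:
    ok: bool
    violations: list


# ---------------------------------------------------------------------------
# construction from a triangulation (the defining duality)
# ---------------------------------------------------------------------------


def _edge_face_map(faces: np.ndarray) -> dict:
    """Map each undirected edge to the (<=2) triangles containing it."""
    edge_faces: dict = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((min(u, v), max(u, v)), []).append(fi)
    return edge_faces


def _simplex_from_tri(tri_vertices: np.ndarray, tri_faces: np.ndarray,
                      positions: np.ndarray | None = None) -> SimplexMesh:
    """Build the dual simplex mesh of a closed, consistently wound triangulation.

    One simplex vertex per triangle (at its barycenter unless ``positions``
    overrides), neighbors ordered by the triangle's directed edges
    (v0v1, v1v2, v2v0) — CCW from outside when the triangulation is wound
    outward — and one polygonal simplex face per triangulation vertex,
    obtained by orbiting its incident triangles.
    """
    tri_vertices = np.asarray(tri_vertices, dtype=np.float64)
    tri_faces = np.asarray(tri_faces, dtype=np.int64)
    edge_faces = _edge_face_map(tri_faces)
    for edge, fs in edge_faces.items():
        if len(fs) != 2:
            raise MeshTopologyError(
                f"edge {edge} belongs to {len(fs)} triangles; need a closed 2-manifold"
            )

    nF = len(tri_faces)
    neighbors = np.empty((nF, 3), dtype=np.int64)
    for fi, (a, b, c) in enumerate(tri_faces):
        for k, (u, v) in enumerate(((a, b), (b, c), (c, a))):
            fs = edge_faces[(min(u, v), max(u, v))]
            neighbors[fi, k] = fs[0] if fs[1] == fi else fs[1]

    # simplex faces: orbit of triangles around each triangulation vertex.
    # From triangle (v, b, c) (rotated so v is first) step across the directed
    # edge (c, v), i.e. the undirected edge {v, c}; consistent winding makes
    # this a single cycle per vertex.
    incident: dict = {}
    for fi, tri in enumerate(tri_faces):
        for v in tri:
            incident.setdefault(int(v), fi)
    faces = []
    for v in range(len(tri_vertices)):
        if v not in incident:
            raise MeshTopologyError(f"triangulation vertex {v} is isolated")
        start = incident[v]
        cycle = [start]
        fi = start
        while True:
            tri = list(tri_faces[fi])
            i = tri.index(v)
            c = tri[(i + 2) % 3]  # vertex preceding v in the cycle
            fs = edge_faces[(min(v, c), max(v, c))]
            fi = fs[0] if fs[1] == fi else fs[1]
            if fi == start:
                break
            cycle.append(fi)
            if len(cycle) > nF:
                raise MeshTopologyError(f"non-closing orbit around vertex {v}")
        faces.append(cycle)

    if positions is None:
        positions = tri_vertices[tri_faces].mean(axis=1)
    return SimplexMesh(positions=positions, neighbors=neighbors, faces=faces)


def rebuild_from_triangulation(tri: DualTriangulation) -> SimplexMesh:
    """Dual construction: gravity centers of triangles become simplex vertices,
    vertices of edge-adjacent triangles are connected."""
    return _simplex_from_tri(tri.tri_vertices, tri.triangles)


def init_simplex_sphere(center, radius: float, level: int = 2) -> SimplexMesh:
    """Spherical seed mesh: the dual of an icosphere, radially projected.

    ``level`` is the icosphere subdivision count, giving 20 * 4**level
    triangles and therefore that many simplex vertices (level 0: 20 vertices,
    level 2: 320).  All simplex vertices lie exactly on the sphere.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if level < 0:
        raise ValueError("level must be >= 0")
    center = np.asarray(center, dtype=np.float64)
    ico = trimesh.creation.icosphere(subdivisions=int(level), radius=1.0)
    mesh = _simplex_from_tri(np.asarray(ico.vertices), np.asarray(ico.faces))
    # barycenters of unit-sphere triangles lie inside; project radially out
    p = mesh.positions
    mesh.positions = p / np.linalg.norm(p, axis=1, keepdims=True) * radius + center
    return mesh


# ---------------------------------------------------------------------------
# dual triangulation of a (possibly deformed) simplex mesh
# ---------------------------------------------------------------------------


def _vertex_normals(mesh: SimplexMesh) -> np.ndarray:
    """Outward normals of the neighbor triangles (cyclic cross-product sum)."""
    p = mesh.positions[mesh.neighbors]  # (V, 3 neighbors, 3)
    p1, p2, p3 = p[:, 0], p[:, 1], p[:, 2]
    n = np.cross(p1, p2) + np.cross(p2, p3) + np.cross(p3, p1)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def dual_triangulation(mesh: SimplexMesh) -> DualTriangulation:
    """One triangle vertex per simplex face (at its barycenter), one triangle
    per simplex vertex connecting its three incident faces.

    Winding is fixed combinatorially from the vertex's ordered neighbor
    triple (j1, j2, j3): the triangle lists the face lying between j1 and
    j2, then between j2 and j3, then between j3 and j1.  Because neighbor
    triples are CCW from outside, this yields a globally consistent outward
    orientation regardless of how contorted the geometry is (a per-triangle
    geometric flip would not).
    """
    report = validate(mesh)
    if not report.ok:
        raise MeshTopologyError(f"invalid simplex mesh: {report.violations[:3]}")
    bary = np.array([mesh.positions[f].mean(axis=0) for f in mesh.faces])
    # for each vertex, map the unordered pair of its cycle-neighbors within a
    # face to that face id
    wedge: list[dict] = [dict() for _ in range(mesh.n_vertices)]
    for fj, cycle in enumerate(mesh.faces):
        k = len(cycle)
        for idx, v in enumerate(cycle):
            a, b = cycle[idx - 1], cycle[(idx + 1) % k]
            wedge[v][frozenset((a, b))] = fj
    triangles = np.empty((mesh.n_vertices, 3), dtype=np.int64)
    for v in range(mesh.n_vertices):
        j1, j2, j3 = mesh.neighbors[v]
        w = wedge[v]
        try:
            triangles[v] = (w[frozenset((j1, j2))], w[frozenset((j2, j3))],
                            w[frozenset((j3, j1))])
        except KeyError:
            raise MeshTopologyError(
                f"faces around vertex {v} do not match its neighbor triple"
            ) from None
    return DualTriangulation(tri_vertices=bary, triangles=triangles)


# ---------------------------------------------------------------------------
# validity checking
# ---------------------------------------------------------------------------


def validate(mesh: SimplexMesh) -> ValidationReport:
    """Check degree-3 regularity, adjacency symmetry, closedness (Euler
    formula with the stored faces), duplicate vertices, and finiteness."""
    v: list = []
    V = mesh.n_vertices
    if V == 0:
        return ValidationReport(ok=False, violations=["empty mesh"])
    if not np.all(np.isfinite(mesh.positions)):
        bad = np.where(~np.isfinite(mesh.positions).all(axis=1))[0]
        v.append(f"non-finite coordinates at vertices {bad[:5].tolist()}")
    if mesh.neighbors.shape != (V, 3):
        v.append(f"neighbors shape {mesh.neighbors.shape} != ({V}, 3)")
        return ValidationReport(ok=False, violations=v)
    for i in range(V):
        trip = mesh.neighbors[i]
        if len(set(trip.tolist())) != 3 or i in trip:
            v.append(f"vertex {i} has neighbor triple {trip.tolist()} (need 3 distinct others)")
    adj = {(i, int(j)) for i in range(V) for j in mesh.neighbors[i]}
    asym = [(i, j) for (i, j) in adj if (j, i) not in adj]
    if asym:
        v.append(f"asymmetric adjacency pairs, e.g. {asym[:3]}")
    E = len(adj) // 2
    F = mesh.n_faces
    if 2 * E != 3 * V:
        v.append(f"degree-3 count broken: 2E={2 * E} != 3V={3 * V}")
    if V - E + F != 2:
        v.append(f"Euler characteristic V-E+F = {V - E + F} != 2 (surface not a closed sphere)")
    # faces must tile the adjacency: every edge appears in exactly 2 face cycles
    edge_count: dict = {}
    for cycle in mesh.faces:
        if len(cycle) < 3:
            v.append(f"face with fewer than 3 vertices: {cycle}")
            continue
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            key = (min(a, b), max(a, b))
            edge_count[key] = edge_count.get(key, 0) + 1
    bad_edges = [e for e, c in edge_count.items() if c != 2]
    if bad_edges:
        v.append(f"edges not shared by exactly 2 faces, e.g. {bad_edges[:3]}")
    if np.all(np.isfinite(mesh.positions)):
        rounded = np.round(mesh.positions, 9)
        uniq = np.unique(rounded, axis=0)
        if len(uniq) != V:
            v.append(f"{V - len(uniq)} duplicated vertex positions")
    return ValidationReport(ok=not v, violations=v)
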