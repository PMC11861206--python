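"""Low-level triangle-mesh helpers shared across the pipeline.

All functions operate on plain ``(V, d)`` float vertex arrays and ``(F, 3)``
integer face arrays; the higher-level :class:`~leafatlas.digitizer_io.LeafMesh`
wraps them with role tags and units.
"""

from __future__ import annotations

import numpy as np

from .errors import TopologyError

__all__ = [
    "triangle_areas",
    "signed_areas_2d",
    "face_normals",
    "undirected_edges",
    "boundary_edges",
    "boundary_loop",
    "face_adjacency",
    "vertex_adjacency",
    "euler_characteristic",
]


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unsigned area of every triangle (2D or 3D vertices)."""
    p0, p1, p2 = (vertices[faces[:, k]] for k in range(3))
    e1, e2 = p1 - p0, p2 - p0
    if vertices.shape[1] == 2:
        return 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def signed_areas_2d(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Signed area of every triangle of a 2D mesh (positive = CCW winding)."""
    p0, p1, p2 = (vertices[faces[:, k]] for k in range(3))
    e1, e2 = p1 - p0, p2 - p0
    return 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])


def face_normals(vertices: np.ndarray, faces: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Per-face normal vectors of a 3D mesh."""
    p0, p1, p2 = (vertices[faces[:, k]] for k in range(3))
    n = np.cross(p1 - p0, p2 - p0)
    if normalize:
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        n = n / norms
    return n


def undirected_edges(faces: np.ndarray):
    """Unique undirected edges and the per-edge face count.

    Returns ``(edges, counts, edge_to_faces)`` where ``edges`` is ``(E, 2)``
    with ``edges[:, 0] < edges[:, 1]``, ``counts[e]`` is the number of incident
    faces, and ``edge_to_faces`` maps each edge row index to the list of
    ``(face_index, a, b)`` incidences with ``a -> b`` the directed edge as it
    appears in the face winding.
    """
    raw = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(raw, axis=1)
    edges, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    edge_to_faces: dict[int, list[tuple[int, int, int]]] = {}
    F = len(faces)
    for row, e in enumerate(inverse):
        f = row % F
        a, b = raw[row]
        edge_to_faces.setdefault(int(e), []).append((int(f), int(a), int(b)))
    return edges, counts, edge_to_faces


def boundary_edges(faces: np.ndarray) -> np.ndarray:
    """Undirected edges incident to exactly one face, as an ``(B, 2)`` array."""
    edges, counts, _ = undirected_edges(faces)
    return edges[counts == 1]


def boundary_loop(faces: np.ndarray) -> np.ndarray:
    """Vertex indices of the single boundary loop, in cyclic order.

    Raises :class:`TopologyError` if the mesh has zero or multiple boundary
    loops, or a non-manifold boundary vertex.
    """
    be = boundary_edges(faces)
    if len(be) == 0:
        raise TopologyError("mesh is closed: no boundary edges")
    adj: dict[int, list[int]] = {}
    for a, b in be:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    for v, nbrs in adj.items():
        if len(nbrs) != 2:
            raise TopologyError(f"non-manifold boundary at vertex {v}")
    start = int(be[0, 0])
    loop = [start]
    prev, cur = None, start
    while True:
        nxt = [n for n in adj[cur] if n != prev]
        nxt = nxt[0] if nxt else adj[cur][0]
        if nxt == start:
            break
        loop.append(nxt)
        prev, cur = cur, nxt
        if len(loop) > len(adj):
            raise TopologyError("boundary chaining did not close")
    if len(loop) != len(adj):
        raise TopologyError(f"mesh has more than one boundary loop "
                            f"({len(adj) - len(loop)} boundary vertices unreached)")
    return np.asarray(loop, dtype=np.int64)


def face_adjacency(faces: np.ndarray) -> list[list[int]]:
    """For each face, the list of edge-adjacent face indices."""
    _, _, edge_to_faces = undirected_edges(faces)
    adj: list[list[int]] = [[] for _ in range(len(faces))]
    for incidences in edge_to_faces.values():
        if len(incidences) == 2:
            (f1, *_), (f2, *_) = incidences
            adj[f1].append(f2)
            adj[f2].append(f1)
    return adj


def vertex_adjacency(faces: np.ndarray, n_vertices: int) -> list[set]:
    """For each vertex, the set of edge-connected neighbor vertices."""
    adj: list[set] = [set() for _ in range(n_vertices)]
    edges, _, _ = undirected_edges(faces)
    for a, b in edges:
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    return adj


def euler_characteristic(faces: np.ndarray, n_vertices: int) -> int:
    """V - E + F (a disk has characteristic 1)."""
    edges, _, _ = undirected_edges(faces)
    return int(n_vertices) - len(edges) + len(faces)
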