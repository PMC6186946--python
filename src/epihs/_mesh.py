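"""Low-level triangle-mesh utilities: icospheres, edge graphs, geodesic discs,
and exact point-to-mesh distances.

These are deliberately dependency-light (numpy + scipy only); no mesh library
in the target environment provides them.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "icosphere",
    "unique_edges",
    "edge_adjacency",
    "vertex_areas",
    "vertex_normals",
    "triangle_areas",
    "geodesic_disc",
    "point_mesh_distance",
    "is_connected_subset",
]


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


@lru_cache(maxsize=8)
def icosphere(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere with 10*4**level + 2 vertices.

    Deterministic vertex ordering: each subdivision appends midpoint vertices
    in sorted-edge order, so repeated calls are bit-identical.
    """
    if level < 0:
        raise ValueError("subdivision level must be >= 0")
    verts, faces = _icosahedron()
    for _ in range(level):
        edges = unique_edges(faces)
        edge_index = {tuple(e): len(verts) + i for i, e in enumerate(edges)}
        mids = verts[edges[:, 0]] + verts[edges[:, 1]]
        mids /= np.linalg.norm(mids, axis=1, keepdims=True)
        verts = np.vstack([verts, mids])
        new_faces = []
        for a, b, c in faces:
            ab = edge_index[tuple(sorted((a, b)))]
            bc = edge_index[tuple(sorted((b, c)))]
            ca = edge_index[tuple(sorted((c, a)))]
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = np.asarray(new_faces, dtype=np.int64)
    verts.setflags(write=False)
    faces.setflags(write=False)
    return verts, faces


def unique_edges(faces: np.ndarray) -> np.ndarray:
    """Sorted unique undirected edges (E, 2) of a triangle list."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def edge_adjacency(n_vertices: int, edges: np.ndarray,
                   weights: np.ndarray | None = None) -> sparse.csr_matrix:
    """Symmetric sparse adjacency over undirected edges."""
    if weights is None:
        weights = np.ones(len(edges))
    i, j = edges[:, 0], edges[:, 1]
    a = sparse.coo_matrix(
        (np.concatenate([weights, weights]),
         (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n_vertices, n_vertices),
    )
    return a.tocsr()


def triangle_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a = verts[faces[:, 1]] - verts[faces[:, 0]]
    b = verts[faces[:, 2]] - verts[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def vertex_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident triangle."""
    ta = triangle_areas(verts, faces) / 3.0
    va = np.zeros(len(verts))
    for k in range(3):
        np.add.at(va, faces[:, k], ta)
    return va


def vertex_normals(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Outward vertex normals as area-weighted means of incident face normals."""
    fn = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                  verts[faces[:, 2]] - verts[faces[:, 0]])  # |fn| = 2*area
    vn = np.zeros_like(verts)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def geodesic_disc(verts: np.ndarray, faces: np.ndarray, seed: int,
                  radius_mm: float) -> np.ndarray:
    """Vertex indices within graph-geodesic distance ``radius_mm`` of ``seed``."""
    edges = unique_edges(faces)
    lengths = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
    g = edge_adjacency(len(verts), edges, lengths)
    d = dijkstra(g, indices=seed, limit=radius_mm * 1.001)
    return np.flatnonzero(np.isfinite(d) & (d <= radius_mm))


def is_connected_subset(faces: np.ndarray, subset: np.ndarray,
                        n_vertices: int) -> bool:
    """True if ``subset`` induces a single edge-connected component."""
    if len(subset) == 0:
        return False
    edges = unique_edges(faces)
    keep = np.zeros(n_vertices, bool)
    keep[subset] = True
    e = edges[keep[edges[:, 0]] & keep[edges[:, 1]]]
    remap = -np.ones(n_vertices, np.int64)
    remap[subset] = np.arange(len(subset))
    g = edge_adjacency(len(subset), remap[e]) if len(e) else sparse.csr_matrix(
        (len(subset), len(subset)))
    n_comp, _ = connected_components(g, directed=False)
    return n_comp == 1


def _closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                                c: np.ndarray) -> np.ndarray:
    """Vectorised Ericson closest-point-on-triangle; all inputs (..., 3)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("...i,...i", ab, ap)
    d2 = np.einsum("...i,...i", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i", ab, bp)
    d4 = np.einsum("...i,...i", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i", ab, cp)
    d6 = np.einsum("...i,...i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom

    out = a + v_in[..., None] * ab + w_in[..., None] * ac  # interior default
    sel = lambda cond, val: np.where(cond[..., None], val, out)  # noqa: E731
    out = sel((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
              b + np.nan_to_num(w_bc)[..., None] * (c - b))
    out = sel((vb <= 0) & (d2 >= 0) & (d6 <= 0),
              a + np.nan_to_num(w_ac)[..., None] * ac)
    out = sel((vc <= 0) & (d1 >= 0) & (d3 <= 0),
              a + np.nan_to_num(v_ab)[..., None] * ab)
    out = sel((d6 >= 0) & (d5 <= d6), c)
    out = sel((d3 >= 0) & (d4 <= d3), b)
    out = sel((d1 <= 0) & (d2 <= 0), a)
    return out


def point_mesh_distance(points: np.ndarray, verts: np.ndarray,
                        faces: np.ndarray, k: int = 12) -> np.ndarray:
    """Exact minimum distance from each point to a triangle mesh.

    Candidate triangles are pruned with a KD-tree over face centroids
    (k nearest), then the exact point-triangle distance is evaluated.
    k=12 is conservative for near-uniform meshes.
    """
    centroids = verts[faces].mean(axis=1)
    tree = cKDTree(centroids)
    k = min(k, len(faces))
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx)
    tri = faces[idx]                                # (n, k, 3)
    p = points[:, None, :]
    closest = _closest_point_on_triangles(
        np.broadcast_to(p, tri.shape[:2] + (3,)),
        verts[tri[..., 0]], verts[tri[..., 1]], verts[tri[..., 2]])
    d = np.linalg.norm(closest - p, axis=-1)
    return d.min(axis=1)
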