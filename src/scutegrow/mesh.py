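"""Minimal triangle-mesh container and primitives.

Meshes are stored as an (V, 3) float64 vertex array and an (F, 3) int
face array with consistent winding.  Faces may carry an integer label
(one tile id per face).  All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components


@dataclass
class SurfaceMesh:
    """Triangulated surface with optional per-face tile labels."""

    vertices: np.ndarray  # (V, 3) float64, mm
    faces: np.ndarray  # (F, 3) int
    face_labels: Optional[np.ndarray] = None  # (F,) int or None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.face_labels is not None:
            self.face_labels = np.asarray(self.face_labels, dtype=np.int64)
            if self.face_labels.shape != (len(self.faces),):
                raise ValueError("face_labels must be (F,)")

    # -- geometry -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_areas(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_centroids(self) -> np.ndarray:
        a, b, c = self.triangle_corners()
        return (a + b + c) / 3.0

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        if normalized:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        fn = self.face_normals(normalized=False)  # magnitude = 2 * area
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def signed_volume(self) -> float:
        """Positive for outward-wound closed meshes (divergence theorem)."""
        a, b, c = self.triangle_corners()
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    # -- topology -----------------------------------------------------

    def edges(self) -> np.ndarray:
        """All directed edges, (3F, 2)."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def unique_edges(self) -> np.ndarray:
        e = np.sort(self.edges(), axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.unique_edges()) + self.n_faces

    def is_closed_manifold(self) -> bool:
        """Every undirected edge used by exactly two faces."""
        e = np.sort(self.edges(), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def face_adjacency(self) -> np.ndarray:
        """(K, 2) pairs of face indices sharing an edge."""
        f = self.faces
        n_f = len(f)
        e = np.sort(self.edges(), axis=1)
        face_idx = np.tile(np.arange(n_f), 3)
        # group by edge key
        key = e[:, 0].astype(np.int64) * (self.n_vertices + 1) + e[:, 1]
        order = np.argsort(key, kind="stable")
        key_s = key[order]
        fidx_s = face_idx[order]
        same = key_s[:-1] == key_s[1:]
        return np.column_stack([fidx_s[:-1][same], fidx_s[1:][same]])

    def split_components(self) -> list[np.ndarray]:
        """Face-index arrays of edge-connected components."""
        adj = self.face_adjacency()
        n_f = self.n_faces
        if len(adj) == 0:
            return [np.array([i]) for i in range(n_f)]
        g = sparse.coo_matrix(
            (np.ones(len(adj)), (adj[:, 0], adj[:, 1])), shape=(n_f, n_f)
        )
        n_comp, comp = connected_components(g, directed=False)
        return [np.flatnonzero(comp == i) for i in range(n_comp)]

    def submesh(self, face_indices: np.ndarray) -> "SurfaceMesh":
        faces = self.faces[face_indices]
        used = np.unique(faces)
        remap = np.full(self.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        labels = None
        if self.face_labels is not None:
            labels = self.face_labels[face_indices]
        return SurfaceMesh(self.vertices[used], remap[faces], labels)

    def scaled(self, factor: float) -> "SurfaceMesh":
        labels = None if self.face_labels is None else self.face_labels.copy()
        return SurfaceMesh(self.vertices * float(factor), self.faces.copy(), labels)


# ---------------------------------------------------------------------
# icosphere construction


_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=np.float64,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def icosphere(subdivisions: int = 4) -> SurfaceMesh:
    """Unit icosphere: subdivided icosahedron projected to the sphere.

    subdivisions=s gives 20*4**s faces.  Winding is outward.
    """
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
        verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    mesh = SurfaceMesh(verts, faces)
    if mesh.signed_volume() < 0:  # defensive: enforce outward winding
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, inverse = np.unique(e, axis=0, return_inverse=True)
    mid = (verts[uniq[:, 0]] + verts[uniq[:, 1]]) / 2.0
    mid_idx = inverse.reshape(3, -1).T + len(verts)  # midpoint of edges 01,12,20
    new_verts = np.vstack([verts, mid])
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    ab, bc, ca = mid_idx[:, 0], mid_idx[:, 1], mid_idx[:, 2]
    new_faces = np.concatenate(
        [
            np.column_stack([a, ab, ca]),
            np.column_stack([b, bc, ab]),
            np.column_stack([c, ca, bc]),
            np.column_stack([ab, bc, ca]),
        ]
    )
    return new_verts, new_faces
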