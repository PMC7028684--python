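"""Triangulated surface meshes standing in for the cortical GM-WM interface.

All coordinates are world millimetres.  Faces are triangles indexing into the
vertex array; a consistently oriented closed mesh has outward normals and
Euler characteristic ``V - E + F = 2`` (genus 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


@dataclass
class SurfaceMesh:
    """Triangle mesh: ``vertices`` (V, 3) float mm, ``faces`` (F, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3) triangles")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    # -- basic counts ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        if "edges" not in self._cache:
            e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                           self.faces[:, [2, 0]]])
            e = np.sort(e, axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    # -- differential quantities ------------------------------------------
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            v = self.vertices
            a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
            b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
            self._cache["face_areas"] = 0.5 * np.linalg.norm(
                np.cross(a, b), axis=1)
        return self._cache["face_areas"]

    def area(self) -> float:
        return float(self.face_areas().sum())

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of each incident face."""
        if "vertex_areas" not in self._cache:
            va = np.zeros(self.n_vertices)
            fa = self.face_areas() / 3.0
            for k in range(3):
                np.add.at(va, self.faces[:, k], fa)
            self._cache["vertex_areas"] = va
        return self._cache["vertex_areas"]

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        n = np.cross(v[self.faces[:, 1]] - v[self.faces[:, 0]],
                     v[self.faces[:, 2]] - v[self.faces[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        if "vertex_normals" not in self._cache:
            fn = self.face_normals() * self.face_areas()[:, None]
            vn = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(vn, self.faces[:, k], fn)
            norm = np.linalg.norm(vn, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._cache["vertex_normals"] = vn / norm
        return self._cache["vertex_normals"]

    # -- graph structure ---------------------------------------------------
    def edge_graph(self) -> sp.csr_matrix:
        """Sparse symmetric adjacency weighted by Euclidean edge length."""
        if "edge_graph" not in self._cache:
            e = self.edges()
            w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                               axis=1)
            n = self.n_vertices
            g = sp.coo_matrix(
                (np.concatenate([w, w]),
                 (np.concatenate([e[:, 0], e[:, 1]]),
                  np.concatenate([e[:, 1], e[:, 0]]))),
                shape=(n, n))
            self._cache["edge_graph"] = g.tocsr()
        return self._cache["edge_graph"]

    def adjacency(self) -> sp.csr_matrix:
        """Unweighted 0/1 vertex adjacency."""
        if "adjacency" not in self._cache:
            g = self.edge_graph().copy()
            g.data = np.ones_like(g.data)
            self._cache["adjacency"] = g
        return self._cache["adjacency"]

    def mean_edge_length(self) -> float:
        e = self.edges()
        return float(np.linalg.norm(
            self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean())

    def n_components(self) -> int:
        return int(connected_components(self.adjacency(), directed=False)[0])

    def is_connected(self) -> bool:
        return self.n_components() == 1
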