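"""Discrete unit spheres for ODF sampling and peak finding.

An icosahedral tessellation is centrally symmetric, so every vertex has an
exact antipode in the vertex set; ODFs (even functions) can therefore be
evaluated on the full sphere and peaks identified modulo the antipodal map.
Vertex quadrature weights are barycentric face-area thirds, accurate enough
to integrate the band-limited (L <= 4) functions used here to ~1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import trimesh
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class Sphere:
    """Symmetric triangulated unit sphere.

    Attributes
    ----------
    vertices : (N, 3) unit vectors.
    faces : (F, 3) triangle vertex indices.
    weights : (N,) quadrature weights summing to 4*pi.
    neighbors : (N, Kmax) int array of adjacent vertex indices, padded with -1.
    antipode : (N,) index of each vertex's antipodal partner.
    """

    vertices: np.ndarray
    faces: np.ndarray
    weights: np.ndarray
    neighbors: np.ndarray
    antipode: np.ndarray

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def hemisphere_indices(self) -> np.ndarray:
        """Indices of one representative per antipodal pair.

        Representative choice: lexicographically, the vertex with z > 0; on
        the equator z == 0 the one with y > 0, then x > 0.
        """
        v = self.vertices
        key = (v[:, 2] > 1e-12) | (
            (np.abs(v[:, 2]) <= 1e-12)
            & ((v[:, 1] > 1e-12) | ((np.abs(v[:, 1]) <= 1e-12) & (v[:, 0] > 0)))
        )
        return np.nonzero(key)[0]

    def integrate(self, values: np.ndarray) -> float:
        return float(np.dot(self.weights, values))


@lru_cache(maxsize=4)
def make_sphere(subdivisions: int = 4) -> Sphere:
    """Subdivided icosahedron (4 subdivisions -> 2562 vertices)."""
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(mesh.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.asarray(mesh.faces, dtype=np.int64)

    # quadrature: one third of each incident spherical-triangle area
    areas = np.asarray(mesh.area_faces, dtype=float)
    weights = np.zeros(len(verts))
    for k in range(3):
        np.add.at(weights, faces[:, k], areas / 3.0)
    weights *= 4.0 * np.pi / weights.sum()

    # vertex adjacency, padded
    nbr_lists = [[] for _ in range(len(verts))]
    for a, b, c in faces:
        for i, j in ((a, b), (b, c), (c, a)):
            nbr_lists[i].append(j)
            nbr_lists[j].append(i)
    nbr_lists = [sorted(set(l)) for l in nbr_lists]
    kmax = max(len(l) for l in nbr_lists)
    neighbors = np.full((len(verts), kmax), -1, dtype=np.int64)
    for i, l in enumerate(nbr_lists):
        neighbors[i, : len(l)] = l

    # antipodal pairing (exact for icosahedral meshes)
    tree = cKDTree(verts)
    dist, antipode = tree.query(-verts)
    if dist.max() > 1e-9:
        raise RuntimeError("tessellation is not centrally symmetric")

    return Sphere(verts, faces, weights, neighbors, antipode)


def cart2sphere(xyz: np.ndarray):
    """Unit vectors -> (theta polar, phi azimuth)."""
    xyz = np.atleast_2d(xyz)
    theta = np.arccos(np.clip(xyz[:, 2], -1.0, 1.0))
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    return theta, phi


def angle_between_axes(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two axes (antipodally identified)."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(min(c, 1.0))))
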