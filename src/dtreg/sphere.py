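"""Unit-sphere discretizations for direction posteriors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SphereSampling", "icosphere"]


@dataclass
class SphereSampling:
    """Discrete unit directions with quadrature weights summing to 1.

    Points cover the full sphere; antipodal handling is explicit at each
    point of use (tensor likelihoods are antipodally symmetric, the
    streamline prior is not).
    """

    points: np.ndarray  # (K, 3)
    weights: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        norms = np.linalg.norm(self.points, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sphere points must be unit vectors")
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return self.points.shape[0]


def icosphere(subdivisions: int = 3) -> SphereSampling:
    """Subdivided icosahedron: 12, 42, 162, 642, ... vertices.

    Each subdivision splits every triangle in four and reprojects the new
    vertices onto the sphere.  Weights are uniform (the mesh is nearly
    area-uniform, and consumers normalize posteriors anyway).
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]

    def midpoint(cache, a, b):
        key = (min(a, b), max(a, b))
        if key not in cache:
            m = np.array(verts[a]) + np.array(verts[b])
            m /= np.linalg.norm(m)
            verts.append(tuple(m))
            cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(subdivisions):
        cache: dict = {}
        new_faces = []
        for a, b, c in faces:
            ab = midpoint(cache, a, b)
            bc = midpoint(cache, b, c)
            ca = midpoint(cache, c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces

    pts = np.asarray(verts, dtype=float)
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    w = np.full(len(pts), 1.0 / len(pts))
    return SphereSampling(pts, w)
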