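"""Direction sets on the unit sphere.

Provides the tessellated-icosahedron direction sets used to sample spin
distribution functions (by default a 321-axis set, the antipodally reduced
642-vertex icosphere) and quasi-uniform hemisphere point sets used as
synthetic diffusion gradient schemes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["icosphere_vertices", "antipodal_reduce", "default_direction_units", "golden_hemisphere"]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    p = _GOLDEN
    verts = np.array(
        [
            [-1, p, 0], [1, p, 0], [-1, -p, 0], [1, -p, 0],
            [0, -1, p], [0, 1, p], [0, -1, -p], [0, 1, -p],
            [p, 0, -1], [p, 0, 1], [-p, 0, -1], [-p, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return verts, faces


def icosphere_vertices(n_subdiv: int = 3) -> np.ndarray:
    """Vertices of an icosahedron subdivided ``n_subdiv`` times.

    Each subdivision splits every triangle into four and reprojects the new
    midpoints onto the sphere; the vertex count is 10 * 4**n + 2
    (12, 42, 162, 642, ...).
    """
    verts, faces = _icosahedron()
    verts = list(verts)
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key in cache:
            return cache[key]
        m = verts[i] + verts[j]
        m /= np.linalg.norm(m)
        verts.append(m)
        cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(n_subdiv):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = np.asarray(new_faces, dtype=int)
    return np.asarray(verts)


def antipodal_reduce(units: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Keep one representative per antipodal pair (axes, not vectors).

    Canonical hemisphere: z > 0, ties broken by y > 0 then x > 0.
    """
    units = np.asarray(units, dtype=float)
    keep = (
        (units[:, 2] > tol)
        | ((np.abs(units[:, 2]) <= tol) & (units[:, 1] > tol))
        | ((np.abs(units[:, 2]) <= tol) & (np.abs(units[:, 1]) <= tol) & (units[:, 0] > tol))
    )
    return units[keep]


def default_direction_units(n_subdiv: int = 3) -> np.ndarray:
    """The default SDF sampling axes: antipodally reduced icosphere.

    ``n_subdiv=3`` gives 642 vertices, i.e. 321 axes.
    """
    return antipodal_reduce(icosphere_vertices(n_subdiv))


def golden_hemisphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the upper hemisphere.

    Golden-spiral construction; used for synthetic gradient schemes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n) + 0.5
    z = k / n  # (0, 1): upper hemisphere
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = 2.0 * np.pi * k / _GOLDEN
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
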