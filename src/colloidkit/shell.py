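"""Trivalent spherical carbon shells (Goldberg polyhedra) for pseudo-proteins.

A pseudo-protein scaffold is the vertex set of a Goldberg polyhedron
GP(h, k): a convex trivalent cage with 12 pentagonal and otherwise
hexagonal faces and ``20 * (h^2 + h*k + k^2)`` vertices, plus one atom at
the geometric center.  The default scaffold used throughout the package is
GP(3, 2) with 1.42 Angstrom bonds: 380 surface atoms and a diameter of
about 1.8 nm, comparable to a small globular protein domain.

Construction route: the icosahedral geodesic sphere of frequency (h, k) is
built from the triangular (Eisenstein) lattice mapped onto the 20 faces of
an icosahedron, its convex hull provides the triangulation, and the
Goldberg vertices are the face centroids of that triangulation.  The raw
cage is then relaxed with a minimal sp2-carbon force field (harmonic bonds,
harmonic 120-degree angles, and a spherical radial restraint) so that all
bonded distances agree within 5% and the cage stays spherical within 2%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist, pdist

__all__ = ["ShellGeometry", "build_goldberg_shell", "neighbor_counts", "shell_diameter"]

#: canonical bond length (Angstrom) at which cages are relaxed; other bond
#: lengths are obtained by homogeneous scaling, which preserves all angles
#: and relative deviations.
_CANONICAL_BOND = 1.42

# force-field weights for the cage relaxation (bond term has weight 1)
_ANGLE_WEIGHT = 0.15
_RADIAL_WEIGHT = 10.0

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class ShellGeometry:
    """Geometry of a spherical trivalent shell plus one central atom.

    Attributes
    ----------
    surface_positions:
        ``(n_surface, 3)`` array of surface-atom coordinates, Angstrom.
    central_position:
        Coordinates of the central atom (the geometric center).
    bond_length:
        Mean bonded surface-atom distance, Angstrom.
    goldberg_indices:
        The ``(h, k)`` pair the cage was built from.
    bonds:
        ``(n_surface, 3)`` integer array; row ``i`` lists the three bonded
        neighbors of surface atom ``i``.
    face_sizes:
        Sizes of the polyhedron faces (ring sizes of the cage); exactly 12
        entries are 5, the rest 6.
    """

    surface_positions: np.ndarray
    central_position: np.ndarray
    bond_length: float
    goldberg_indices: tuple[int, int]
    bonds: np.ndarray = field(repr=False, default=None)
    face_sizes: np.ndarray = field(repr=False, default=None)

    @property
    def n_surface(self) -> int:
        return len(self.surface_positions)

    def scaled(self, factor: float) -> "ShellGeometry":
        """Return a homogeneously scaled copy (scales bond length too)."""
        return ShellGeometry(
            surface_positions=self.surface_positions * factor,
            central_position=self.central_position * factor,
            bond_length=self.bond_length * factor,
            goldberg_indices=self.goldberg_indices,
            bonds=self.bonds,
            face_sizes=self.face_sizes,
        )


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Unit icosahedron vertices and outward-oriented faces."""
    v = []
    for a in (-1.0, 1.0):
        for b in (-_PHI, _PHI):
            v += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    verts = np.asarray(v)
    verts /= np.linalg.norm(verts[0])
    faces = ConvexHull(verts).simplices
    oriented = []
    for f in faces:
        a, b, c = verts[f]
        if np.dot(np.cross(b - a, c - a), a + b + c) < 0:
            f = f[[0, 2, 1]]
        oriented.append(f)
    return verts, np.asarray(oriented)


def _geodesic_vertices(h: int, k: int) -> np.ndarray:
    """Vertices of the icosahedral geodesic sphere of frequency (h, k).

    Lattice points of the triangular lattice inside the (h, k) master
    triangle are mapped barycentrically onto every icosahedron face and
    projected onto the unit sphere.  Points shared between faces (corners,
    edge lattice points) coincide exactly and are removed by rounding-based
    deduplication.  The result has ``10 T + 2`` points, ``T = h^2+hk+k^2``.
    """
    verts, faces = _icosahedron()
    e1 = np.array([1.0, 0.0])
    e2 = np.array([0.5, np.sqrt(3.0) / 2.0])
    p1 = h * e1 + k * e2
    # second corner: p1 rotated by +60 degrees
    c60, s60 = 0.5, np.sqrt(3.0) / 2.0
    p2 = np.array([c60 * p1[0] - s60 * p1[1], s60 * p1[0] + c60 * p1[1]])
    minv = np.linalg.inv(np.column_stack([p1, p2]))

    bary = []
    span = range(-(h + 2 * k) - 2, h + 2 * k + 3)
    eps = 1e-9
    for i in span:
        for j in span:
            b1, b2 = minv @ (i * e1 + j * e2)
            b0 = 1.0 - b1 - b2
            if b0 >= -eps and b1 >= -eps and b2 >= -eps:
                bary.append((b0, b1, b2))
    bary = np.asarray(bary)

    pts = np.vstack([bary @ verts[f] for f in faces])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    _, idx = np.unique(np.round(pts, 6), axis=0, return_index=True)
    return pts[np.sort(idx)]


def _relax_cage(pos: np.ndarray, bonds: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Minimize harmonic bond + angle + radial energy (analytic gradient)."""
    n = len(pos)
    l0 = _CANONICAL_BOND
    th0 = np.deg2rad(120.0)

    def energy_grad(x: np.ndarray):
        p = x.reshape(n, 3)
        g = np.zeros_like(p)

        bv = p[bonds[:, 1]] - p[bonds[:, 0]]
        bl = np.linalg.norm(bv, axis=1)
        e = float(((bl - l0) ** 2).sum())
        gb = (2.0 * (bl - l0) / bl)[:, None] * bv
        np.add.at(g, bonds[:, 1], gb)
        np.add.at(g, bonds[:, 0], -gb)

        v1 = p[angles[:, 0]] - p[angles[:, 1]]
        v2 = p[angles[:, 2]] - p[angles[:, 1]]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        cos = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1 + 1e-12, 1 - 1e-12)
        th = np.arccos(cos)
        e += _ANGLE_WEIGHT * float(((th - th0) ** 2).sum())
        pref = (-_ANGLE_WEIGHT * 2.0 * (th - th0) / np.sqrt(1.0 - cos**2))[:, None]
        d1 = v2 / (n1 * n2)[:, None] - (cos / n1**2)[:, None] * v1
        d2 = v1 / (n1 * n2)[:, None] - (cos / n2**2)[:, None] * v2
        np.add.at(g, angles[:, 0], pref * d1)
        np.add.at(g, angles[:, 2], pref * d2)
        np.add.at(g, angles[:, 1], -pref * (d1 + d2))

        ctr = p.mean(axis=0)
        rv = p - ctr
        r = np.linalg.norm(rv, axis=1)
        dev = r - r.mean()
        e += _RADIAL_WEIGHT * float((dev**2).sum())
        g += _RADIAL_WEIGHT * 2.0 * (dev - dev.mean())[:, None] * (rv / r[:, None])
        return e, g.ravel()

    res = minimize(
        energy_grad,
        pos.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.x.reshape(n, 3)


@lru_cache(maxsize=8)
def _canonical_cage(h: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Relaxed cage at the canonical bond length; (positions, bonds)."""
    t = h * h + h * k + k * k
    geo = _geodesic_vertices(h, k)
    if len(geo) != 10 * t + 2:
        raise RuntimeError(
            f"geodesic construction for ({h},{k}) yielded {len(geo)} vertices, "
            f"expected {10 * t + 2}"
        )
    hull = ConvexHull(geo)
    if len(hull.simplices) != 20 * t:
        raise RuntimeError(
            f"triangulation for ({h},{k}) has {len(hull.simplices)} faces, "
            f"expected {20 * t}"
        )
    cent = geo[hull.simplices].mean(axis=1)
    cent /= np.linalg.norm(cent, axis=1, keepdims=True)
    neighbors = hull.neighbors  # triangle adjacency == cage bonds
    # each geodesic vertex corresponds to one cage face; its degree in the
    # triangulation is the ring size
    face_sizes = np.bincount(hull.simplices.ravel())

    # initial scale: mean bonded distance -> canonical bond length
    d = np.linalg.norm(cent[neighbors] - cent[:, None, :], axis=2)
    pos = cent * (_CANONICAL_BOND / d.mean())

    bond_pairs = np.array(
        sorted({(min(i, int(j)), max(i, int(j))) for i, row in enumerate(neighbors) for j in row})
    )
    angle_triples = []
    for i, row in enumerate(neighbors):
        a, b, c = (int(x) for x in row)
        angle_triples += [(a, i, b), (a, i, c), (b, i, c)]
    angle_triples = np.asarray(angle_triples)

    pos = _relax_cage(pos, bond_pairs, angle_triples)
    pos -= pos.mean(axis=0)
    bl = np.linalg.norm(pos[bond_pairs[:, 1]] - pos[bond_pairs[:, 0]], axis=1)
    pos *= _CANONICAL_BOND / bl.mean()

    pos.setflags(write=False)
    neighbors.setflags(write=False)
    face_sizes.setflags(write=False)
    return pos, neighbors, face_sizes


def build_goldberg_shell(h: int, k: int, bond_length: float = 1.42) -> ShellGeometry:
    """Build the Goldberg polyhedron GP(h, k) cage scaled to ``bond_length``.

    Parameters
    ----------
    h, k:
        Goldberg indices; ``h >= 1``, ``k >= 0``.  The number of surface
        atoms is ``20 * (h^2 + h*k + k^2)``.
    bond_length:
        Target mean bonded distance in Angstrom.

    Returns
    -------
    ShellGeometry
        Surface atoms centered on the origin, central atom at the centroid.
    """
    if not (isinstance(h, (int, np.integer)) and isinstance(k, (int, np.integer))):
        raise TypeError("Goldberg indices h, k must be integers")
    if h < 1 or k < 0:
        raise ValueError(f"invalid Goldberg indices ({h},{k}); need h >= 1, k >= 0")
    if not bond_length > 0:
        raise ValueError("bond_length must be positive")

    pos, neighbors, face_sizes = _canonical_cage(int(h), int(k))
    scale = bond_length / _CANONICAL_BOND
    surface = pos * scale
    return ShellGeometry(
        surface_positions=surface,
        central_position=surface.mean(axis=0),
        bond_length=float(bond_length),
        goldberg_indices=(int(h), int(k)),
        bonds=np.asarray(neighbors),
        face_sizes=np.asarray(face_sizes),
    )


def neighbor_counts(geom: ShellGeometry, d_cut: float) -> np.ndarray:
    """Per-surface-atom count of surface atoms within ``d_cut`` (self included).

    Strict inequality ``r_ij < d_cut`` is used; the central atom is excluded.
    """
    if not d_cut > 0:
        raise ValueError("d_cut must be positive")
    d = cdist(geom.surface_positions, geom.surface_positions)
    return (d < d_cut).sum(axis=1)


def shell_diameter(geom: ShellGeometry) -> float:
    """Maximum pairwise distance between surface atoms, Angstrom."""
    return float(pdist(geom.surface_positions).max())
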