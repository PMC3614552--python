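"""Deterministic synthetic inputs: toy proteins, solubility tables, PMF curves.

The toy proteins are not physically realistic folds; residues are small
rigid templates (3-8 pseudo-atoms with element, name and radius) placed on
a jittered spherical lattice.  They exist so that every descriptor
operation in the package can be exercised end-to-end without downloading
anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from colloidkit.structure import Atom, MolecularStructure, ONE_TO_THREE
from colloidkit.solubility import PMFCurve

__all__ = [
    "FixtureSpec",
    "RESIDUE_TEMPLATES",
    "make_peptide",
    "make_toy_protein",
    "simulate_solubility",
    "make_pmf_curve",
    "DEFAULT_PMF_GRID",
]

# idealized rigid residue templates: (atom name, element, radius A, offset A)
# offsets are relative to CA; backbone N/CA/C/O plus up to 4 side-chain
# pseudo-atoms including each charged type's formal-charge site atom
_BB = [
    ("N", "N", 1.55, (-1.2, 0.8, 0.0)),
    ("CA", "C", 1.70, (0.0, 0.0, 0.0)),
    ("C", "C", 1.70, (1.3, 0.6, 0.0)),
    ("O", "O", 1.52, (2.2, -0.1, 0.4)),
]

RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, float, tuple[float, float, float]]]] = {
    "GLY": _BB,
    "ALA": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1))],
    "SER": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("OG", "O", 1.52, (-0.2, -2.3, 1.6))],
    "VAL": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("CG1", "C", 1.70, (-1.6, -1.8, 1.6)),
                  ("CG2", "C", 1.70, (0.8, -1.9, 1.4))],
    "LEU": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("CG", "C", 1.70, (-0.3, -2.4, 1.7)),
                  ("CD1", "C", 1.70, (-1.5, -3.2, 2.2)), ("CD2", "C", 1.70, (0.9, -3.1, 2.0))],
    "PHE": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("CG", "C", 1.70, (-0.3, -2.4, 1.7)),
                  ("CZ", "C", 1.70, (-0.2, -4.9, 2.8))],
    "THR": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("OG1", "O", 1.52, (-1.5, -1.9, 1.5)),
                  ("CG2", "C", 1.70, (0.9, -1.8, 1.5))],
    "ASP": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("CG", "C", 1.70, (-0.3, -2.4, 1.7)),
                  ("OD1", "O", 1.52, (-1.3, -3.1, 2.0)), ("OD2", "O", 1.52, (0.9, -3.0, 1.9))],
    "GLU": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("CG", "C", 1.70, (-0.3, -2.4, 1.7)),
                  ("CD", "C", 1.70, (-0.2, -3.6, 2.5)), ("OE1", "O", 1.52, (-1.2, -4.3, 2.8)),
                  ("OE2", "O", 1.52, (1.0, -4.1, 2.7))],
    "LYS": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("CG", "C", 1.70, (-0.3, -2.4, 1.7)),
                  ("CE", "C", 1.70, (-0.2, -4.5, 2.9)), ("NZ", "N", 1.55, (-0.1, -5.8, 3.4))],
    "ARG": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("CG", "C", 1.70, (-0.3, -2.4, 1.7)),
                  ("CD", "C", 1.70, (-0.2, -3.7, 2.4)), ("NE", "N", 1.55, (-0.1, -4.8, 3.0)),
                  ("CZ", "C", 1.70, (0.0, -6.0, 3.5))],
    "HIS": _BB + [("CB", "C", 1.70, (-0.4, -1.0, 1.1)), ("CG", "C", 1.70, (-0.3, -2.4, 1.7)),
                  ("NE2", "N", 1.55, (-0.2, -4.4, 2.6))],
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a deterministic toy protein."""

    n_residues: int
    composition: dict[str, float] = field(
        default_factory=lambda: {"GLY": 0.3, "ALA": 0.2, "ASP": 0.125, "GLU": 0.1,
                                 "LYS": 0.1, "ARG": 0.075, "SER": 0.1}
    )
    compactness: float | None = None  # target shell radius, A; None -> auto
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"composition frequencies sum to {total}, expected 1")
        for r in self.composition:
            if r not in RESIDUE_TEMPLATES:
                raise ValueError(f"no template for residue type {r}")


def _auto_radius(n_residues: int) -> float:
    """Shell radius giving roughly 6 A anchor spacing plus side-chain room."""
    return 5.0 + 2.6 * np.sqrt(n_residues)


#: template direction along which side chains extend (roughly -y, tilted +z)
_SIDECHAIN_AXIS = np.array([0.0, -0.9, 0.45]) / np.linalg.norm([0.0, -0.9, 0.45])


def _outward_rotation(direction: np.ndarray, spin: float) -> np.ndarray:
    """Rotation taking the template side-chain axis onto ``direction``.

    ``spin`` adds a rotation about the side-chain axis first, so residues
    are not all in the same azimuthal orientation.
    """
    u = np.asarray(direction) / np.linalg.norm(direction)
    a = _SIDECHAIN_AXIS
    c, s = np.cos(spin), np.sin(spin)
    # rotation about a (Rodrigues)
    ax = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    r_spin = np.eye(3) * c + s * ax + (1 - c) * np.outer(a, a)
    v = np.cross(a, u)
    cos_t = float(np.dot(a, u))
    if np.linalg.norm(v) < 1e-12:
        r_align = np.eye(3) if cos_t > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        r_align = np.eye(3) + vx + vx @ vx / (1.0 + cos_t)
    return r_align @ r_spin


def _fibonacci_shell(n: int, radius: float) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return radius * np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def make_peptide(
    sequence: str,
    compactness: float | None = None,
    seed: int = 0,
    chain: str = "A",
) -> MolecularStructure:
    """Build a toy structure for an explicit one-letter sequence.

    Residue *i* (1-based numbering) is the template for ``sequence[i-1]``,
    anchored on a jittered spherical lattice of radius ``compactness``
    (auto-scaled with length when omitted) with its side chain pointing
    outward and a random azimuthal spin.  Deterministic per seed.
    """
    seq3 = []
    for letter in sequence:
        res3 = ONE_TO_THREE.get(letter.upper())
        if res3 is None or res3 not in RESIDUE_TEMPLATES:
            raise ValueError(f"unsupported residue letter {letter!r}")
        seq3.append(res3)

    if compactness is None:
        compactness = _auto_radius(len(seq3))
    rng = np.random.default_rng(seed)
    anchors = _fibonacci_shell(len(seq3), compactness)
    anchors = anchors + rng.normal(scale=0.3, size=anchors.shape)

    atoms: list[Atom] = []
    serial = 1
    for idx, (res3, anchor) in enumerate(zip(seq3, anchors), start=1):
        rot = _outward_rotation(anchor, rng.uniform(0.0, 2.0 * np.pi))
        for name, element, radius, offset in RESIDUE_TEMPLATES[res3]:
            pos = anchor + rot @ np.asarray(offset)
            atoms.append(
                Atom(serial=serial, name=name, element=element, res_name=res3,
                     res_num=idx, chain=chain, position=pos, radius=radius)
            )
            serial += 1

    s = MolecularStructure(atoms=atoms, source_format="PDB", identifier=f"toy-{seed}")
    _check_clashes(s)
    return s


def _check_clashes(s: MolecularStructure) -> None:
    """Reject structures with severe (> 50%) pairwise overlap between residues."""
    pos = s.positions()
    radii = s.radii()
    resnum = np.array([a.res_num for a in s.atoms])
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(pos))
    limit = 0.5 * (radii[:, None] + radii[None, :])
    severe = (d < limit) & (resnum[:, None] != resnum[None, :])
    if severe.any():
        i, j = np.argwhere(severe)[0]
        raise ValueError(
            "compactness too small: severe overlap between residues "
            f"{resnum[i]} and {resnum[j]}"
        )


def make_toy_protein(spec: FixtureSpec) -> MolecularStructure:
    """Sample a toy protein from a composition recipe (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    types = sorted(spec.composition)
    probs = np.array([spec.composition[t] for t in types])
    seq3 = rng.choice(types, size=spec.n_residues, p=probs / probs.sum())
    one = {v: k for k, v in ONE_TO_THREE.items()}
    sequence = "".join(one[t] for t in seq3)
    # structure placement uses an independent stream so composition and
    # geometry stay decoupled
    return make_peptide(sequence, compactness=spec.compactness, seed=spec.seed + 1)


def simulate_solubility(
    records,
    c1: float,
    c2: float,
    c3: float,
    sigma: float,
    seed: int,
    descriptor: str = "p",
) -> pd.DataFrame:
    """Generate ``sol = c1*desc + c2*q + c3 + N(0, sigma)`` per record."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        desc = {"p": rec.p, "nsap": rec.nsap, "sapmax": rec.sap_max}[descriptor]
        sol = c1 * desc + c2 * rec.q + c3
        if sigma > 0:
            sol += rng.normal(scale=sigma)
        rows.append({"id": rec.id, "q": rec.q, "p": rec.p, "nsap": rec.nsap,
                     "sapmax": rec.sap_max, "sol": sol})
    return pd.DataFrame(rows)


#: default PMF sampling grid: 15.5 to 28.0 A in 0.5 A steps (26 points)
DEFAULT_PMF_GRID = np.arange(15.5, 28.0 + 0.25, 0.5)


def make_pmf_curve(
    depth: float,
    location: float,
    width: float = 1.0,
    grid: np.ndarray | None = None,
) -> PMFCurve:
    """Gaussian-well-plus-soft-wall free-energy curve on the default grid.

    ``depth`` is the well energy (kJ/mol, negative for a bound minimum) at
    ``location`` (A); the repulsive wall rises below 16 A and vanishes
    exactly beyond it, so a well at >= 17 A keeps its nominal depth.
    """
    if grid is None:
        grid = DEFAULT_PMF_GRID
    grid = np.asarray(grid, dtype=float)
    if not (grid.min() <= location <= grid.max()):
        raise ValueError("well location must lie within the grid")
    wall = 20.0 * np.clip(16.0 - grid, 0.0, None) ** 2
    well = depth * np.exp(-(((grid - location) / width) ** 2))
    return PMFCurve(separations=grid, free_energy=wall + well)
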