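"""Descriptors for real protein structures.

Net charge, dipole moment, solvent-accessible surface area (Shrake-Rupley)
and the SAP family of surface-hydrophobicity descriptors (per-residue SAP,
its maximum SAPmax, and the SASA-normalized positive sum nSAP).

Charges come either from a PQR file (kept verbatim) or from a simple
formal-charge model at pH 7: ASP/GLU side chains -1, LYS/ARG +1, HIS 0,
chain termini +1/-1.  The charge is placed on a residue-type-specific site
atom (carboxylate carbon, terminal amine nitrogen, guanidinium carbon)
with side-chain-centroid / CB / CA fallbacks.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "MolecularStructure",
    "DescriptorRecord",
    "assign_formal_charges",
    "net_charge",
    "structure_dipole",
    "sasa",
    "residue_sasa",
    "sap_profile",
    "sap_max",
    "nsap",
    "compute_descriptors",
]

# van der Waals radii by element (A); fallback 1.70
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
_DEFAULT_RADIUS = 1.70

# standard atomic masses; unit mass when the element is unknown
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# Normalized side-chain hydrophobicity scale (0 = most polar, 1 = most
# hydrophobic); shifted downstream so that GLY scores zero.
HYDROPHOBICITY = {
    "ALA": 0.616, "ARG": 0.000, "ASN": 0.236, "ASP": 0.028, "CYS": 0.680,
    "GLN": 0.251, "GLU": 0.043, "GLY": 0.501, "HIS": 0.165, "ILE": 0.943,
    "LEU": 0.943, "LYS": 0.283, "MET": 0.738, "PHE": 1.000, "PRO": 0.711,
    "SER": 0.359, "THR": 0.450, "TRP": 0.878, "TYR": 0.880, "VAL": 0.825,
}
_H_SHIFT = HYDROPHOBICITY["GLY"]

# Reference SASA (A^2) of a fully exposed side chain, per residue type.
MAX_SIDECHAIN_SASA = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "GLY": 1.0, "HIS": 151.0, "ILE": 140.0,
    "LEU": 137.0, "LYS": 167.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0,
    "SER": 80.0, "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}

# formal-charge site atom per (residue type at pH 7): (site atom, charge)
CHARGE_SITES = {
    "ASP": ("CG", -1.0),
    "GLU": ("CD", -1.0),
    "LYS": ("NZ", +1.0),
    "ARG": ("CZ", +1.0),
}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_num: int
    chain: str
    position: np.ndarray
    icode: str = ""
    radius: float | None = None
    charge: float | None = None
    occupancy: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)

    @property
    def is_sidechain(self) -> bool:
        return self.name not in BACKBONE_NAMES

    @property
    def vdw_radius(self) -> float:
        if self.radius is not None:
            return self.radius
        return VDW_RADII.get(self.element, _DEFAULT_RADIUS)

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element, 1.0)


@dataclass
class Residue:
    chain: str
    res_num: int
    icode: str
    res_name: str
    atom_indices: list[int]

    @property
    def key(self) -> tuple:
        return (self.chain, self.res_num, self.icode)


@dataclass
class MolecularStructure:
    """Flat atom list with a residue/chain hierarchy derived on demand."""

    atoms: list[Atom]
    source_format: str = "PDB"
    identifier: str = ""

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def charges(self) -> np.ndarray:
        return np.array([a.charge if a.charge is not None else 0.0 for a in self.atoms])

    def radii(self) -> np.ndarray:
        r = np.array([a.vdw_radius for a in self.atoms])
        if np.any(r <= 0):
            bad = [a.serial for a, x in zip(self.atoms, r) if x <= 0]
            raise ValueError(f"atoms with non-positive radius: {bad}")
        return r

    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        last = None
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.res_num, a.icode)
            if last is None or key != last.key:
                last = Residue(a.chain, a.res_num, a.icode, a.res_name, [])
                out.append(last)
            last.atom_indices.append(i)
        return out

    def copy(self) -> "MolecularStructure":
        return copy.deepcopy(self)


@dataclass
class DescriptorRecord:
    """One protein's descriptor set (units: e, eA, A^2; nSAP in 1/A^2)."""

    id: str
    q: float
    p: float
    total_sasa: float
    sap_max: float
    nsap: float
    sol_observed: float | None = None


def charge_site_position(s: MolecularStructure, res: Residue, target_type: str) -> np.ndarray:
    """Position of the formal-charge site of ``res`` treated as ``target_type``.

    Falls back from the canonical site atom to the side-chain centroid,
    then CB, then CA.
    """
    site_name = CHARGE_SITES[target_type][0]
    atoms = [s.atoms[i] for i in res.atom_indices]
    by_name = {a.name: a for a in atoms}
    if site_name in by_name:
        return by_name[site_name].position
    side = [a.position for a in atoms if a.is_sidechain]
    if side:
        return np.mean(side, axis=0)
    for fb in ("CB", "CA"):
        if fb in by_name:
            return by_name[fb].position
    raise ValueError(
        f"residue {res.res_name} {res.chain}{res.res_num}: no usable charge site"
    )


def assign_formal_charges(
    s: MolecularStructure,
    pH: float = 7.0,
    capped_termini: bool = False,
) -> MolecularStructure:
    """Assign pH-7 formal charges; PQR inputs keep their file charges.

    ASP/GLU side chains get -1 (carboxylate carbon), LYS +1 (NZ), ARG +1
    (CZ), HIS 0.  Unless ``capped_termini``, the first residue of each
    chain gets +1 on N and the last -1 on OXT (or C).  All other atoms get
    zero.  Unknown residues trigger a warning and stay neutral.
    """
    if pH != 7.0:
        raise ValueError("only pH 7 is supported by the formal-charge model")
    if s.source_format.upper() == "PQR":
        return s.copy()

    out = s.copy()
    for a in out.atoms:
        a.charge = 0.0
    residues = out.residues()
    for res in residues:
        atoms = [out.atoms[i] for i in res.atom_indices]
        by_name = {a.name: a for a in atoms}
        if res.res_name not in AMINO_ACIDS_3:
            warnings.warn(f"unknown residue {res.res_name}; assigned charge 0")
            continue
        if res.res_name in CHARGE_SITES:
            site_name, q = CHARGE_SITES[res.res_name]
            target = by_name.get(site_name)
            if target is None:
                # centroid fallback has no atom; park the charge on the
                # atom nearest the fallback position instead
                pos = charge_site_position(out, res, res.res_name)
                idx = int(np.argmin([np.linalg.norm(a.position - pos) for a in atoms]))
                target = atoms[idx]
            target.charge = (target.charge or 0.0) + q

    if not capped_termini:
        by_chain: dict[str, list[Residue]] = {}
        for res in residues:
            by_chain.setdefault(res.chain, []).append(res)
        for chain_res in by_chain.values():
            first, last = chain_res[0], chain_res[-1]
            f_atoms = {out.atoms[i].name: out.atoms[i] for i in first.atom_indices}
            l_atoms = {out.atoms[i].name: out.atoms[i] for i in last.atom_indices}
            n_atom = f_atoms.get("N") or f_atoms.get("CA")
            c_atom = l_atoms.get("OXT") or l_atoms.get("C") or l_atoms.get("CA")
            if n_atom is not None:
                n_atom.charge = (n_atom.charge or 0.0) + 1.0
            if c_atom is not None:
                c_atom.charge = (c_atom.charge or 0.0) - 1.0
    return out


def net_charge(s: MolecularStructure) -> float:
    """Sum of atomic charges, e (unset charges count as zero)."""
    return float(s.charges().sum())


def structure_dipole(s: MolecularStructure, origin: np.ndarray | None = None) -> float:
    """Dipole moment magnitude about the mass-weighted center, eA."""
    pos = s.positions()
    if len(pos) == 0:
        return 0.0
    if origin is None:
        masses = np.array([a.mass for a in s.atoms])
        origin = masses @ pos / masses.sum()
    vec = s.charges() @ (pos - np.asarray(origin, dtype=float))
    return float(np.linalg.norm(vec))


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(s: MolecularStructure, probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake-Rupley), A^2."""
    pos = s.positions()
    radii = s.radii() + probe_radius
    n = len(pos)
    pts = _sphere_points(n_points)
    areas = np.zeros(n)
    d = cdist(pos, pos)
    for i in range(n):
        neighbors = np.where((d[i] < radii[i] + radii) & (np.arange(n) != i))[0]
        sphere = pos[i] + radii[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            accessible &= np.linalg.norm(sphere - pos[j], axis=1) >= radii[j]
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
    return areas


def residue_sasa(s: MolecularStructure, atom_sasa: np.ndarray) -> pd.Series:
    """Per-residue SASA (sum over the residue's atoms), A^2."""
    keys, vals = [], []
    for res in s.residues():
        keys.append(res.key)
        vals.append(float(np.sum([atom_sasa[i] for i in res.atom_indices])))
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(keys, names=["chain", "resnum", "icode"]))


def sap_profile(
    s: MolecularStructure,
    R: float = 5.0,
    atom_sasa: np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Per-residue spatial-aggregation-propensity scores.

    Per atom *i*, side-chain atoms *j* within ``R`` contribute
    ``SASA_j / maxSASA_sidechain(res_j) * H(res_j)`` where *H* is the
    hydrophobicity scale shifted so H(GLY) = 0; the per-residue score is
    the mean over the residue's atoms.  Residue types missing from the
    reference tables are excluded from the sums with a warning.
    """
    if not s.atoms:
        raise ValueError("empty structure")
    if atom_sasa is None:
        atom_sasa = sasa(s, probe_radius=probe_radius, n_points=n_points)
    pos = s.positions()
    contrib = np.zeros(len(s.atoms))
    unknown: set[str] = set()
    for j, a in enumerate(s.atoms):
        if not a.is_sidechain:
            continue
        if a.res_name not in HYDROPHOBICITY or a.res_name not in MAX_SIDECHAIN_SASA:
            unknown.add(a.res_name)
            continue
        h = HYDROPHOBICITY[a.res_name] - _H_SHIFT
        contrib[j] = atom_sasa[j] / MAX_SIDECHAIN_SASA[a.res_name] * h
    if unknown:
        warnings.warn(f"residues missing from SAP reference tables: {sorted(unknown)}")

    d = cdist(pos, pos)
    within = d < R
    sap_atom = within @ contrib

    rows = []
    for res in s.residues():
        rows.append(
            {
                "chain": res.chain,
                "resnum": res.res_num,
                "icode": res.icode,
                "resname": res.res_name,
                "sap": float(np.mean([sap_atom[i] for i in res.atom_indices])),
            }
        )
    return pd.DataFrame(rows)


def sap_max(profile: pd.DataFrame) -> float:
    """Largest per-residue SAP score."""
    if len(profile) == 0:
        raise ValueError("empty SAP profile")
    return float(profile["sap"].max())


def nsap(profile: pd.DataFrame, res_sasa: pd.Series) -> float:
    """Positive-SAP sum normalized by total residue SASA, 1/A^2."""
    if len(profile) == 0:
        raise ValueError("empty SAP profile")
    total = float(res_sasa.sum())
    if total <= 0:
        raise ValueError("total SASA is zero")
    pos_sum = float(profile.loc[profile["sap"] > 0, "sap"].sum())
    return pos_sum / total


def compute_descriptors(
    s: MolecularStructure,
    identifier: str = "",
    sap_radius: float = 5.0,
    probe_radius: float = 1.4,
    n_points: int = 960,
    sol_observed: float | None = None,
) -> DescriptorRecord:
    """Full descriptor record (q, p, SASA, SAPmax, nSAP) for one structure."""
    if s.source_format.upper() != "PQR" and all(a.charge is None for a in s.atoms):
        s = assign_formal_charges(s)
    atom_areas = sasa(s, probe_radius=probe_radius, n_points=n_points)
    profile = sap_profile(s, R=sap_radius, atom_sasa=atom_areas)
    res_areas = residue_sasa(s, atom_areas)
    return DescriptorRecord(
        id=identifier or s.identifier,
        q=net_charge(s),
        p=structure_dipole(s),
        total_sasa=float(atom_areas.sum()),
        sap_max=sap_max(profile),
        nsap=nsap(profile, res_areas),
        sol_observed=sol_observed,
    )
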