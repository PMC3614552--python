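"""File formats: PDB and PQR structures, XYZ shells, topology CSV, PMF text.

Conventions: coordinates in Angstrom, charges in e, dipoles in eA.  PDB
reading keeps MODEL 1 only, resolves altLocs by highest occupancy (ties to
'A'), and skips waters and hetero groups by default.  PQR is whitespace
separated with charge and radius as the final two numeric columns; the
chain-id column may be absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from colloidkit.shell import ShellGeometry
from colloidkit.solubility import PMFCurve
from colloidkit.structure import Atom, MolecularStructure
from colloidkit.topology import Topology

__all__ = [
    "read_structure",
    "read_pdb",
    "read_pqr",
    "write_pqr",
    "write_shell_xyz",
    "write_topology",
    "read_topology",
    "read_pmf",
    "write_sidecar",
]

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "SOL"}


class StructureParseError(ValueError):
    """Malformed structure file; message carries the line number."""


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_pdb(path, include_hetero: bool = False) -> MolecularStructure:
    """Parse ATOM (and optionally HETATM) records of MODEL 1."""
    atoms: list[Atom] = []
    seen_altloc: dict[tuple, tuple[float, str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM", "HETATM"):
                continue
            if rec == "HETATM" and not include_hetero:
                continue
            try:
                name = line[12:16].strip()
                altloc = line[16:17].strip()
                res_name = line[17:20].strip()
                chain = line[21:22].strip() or "A"
                res_num = int(line[22:26])
                icode = line[26:27].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_str = line[54:60].strip()
                occupancy = float(occ_str) if occ_str else 1.0
                element = line[76:78].strip().upper() or _element_from_name(name)
                serial = int(line[6:11])
            except (ValueError, IndexError) as exc:
                raise StructureParseError(f"{path}: malformed record at line {lineno}: {exc}")
            if res_name in _WATER_NAMES:
                continue
            atom = Atom(serial=serial, name=name, element=element, res_name=res_name,
                        res_num=res_num, chain=chain, position=(x, y, z),
                        icode=icode, occupancy=occupancy)
            key = (chain, res_num, icode, name)
            if altloc:
                prev = seen_altloc.get(key)
                if prev is not None:
                    prev_occ, prev_alt, prev_idx = prev
                    better = occupancy > prev_occ or (occupancy == prev_occ and altloc < prev_alt)
                    if better:
                        atoms[prev_idx] = atom
                        seen_altloc[key] = (occupancy, altloc, prev_idx)
                    continue
                seen_altloc[key] = (occupancy, altloc, len(atoms))
            atoms.append(atom)
    if not atoms:
        raise StructureParseError(f"{path}: no ATOM records found")
    return MolecularStructure(atoms=atoms, source_format="PDB",
                              identifier=Path(path).stem)


def read_pqr(path) -> MolecularStructure:
    """Parse whitespace-separated PQR; charge then radius end each record."""
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0] not in ("ATOM", "HETATM"):
                continue
            try:
                serial = int(fields[1])
                name = fields[2]
                res_name = fields[3]
                rest = fields[4:]
                # chain id column is optional
                if rest and not rest[0].lstrip("-").replace(".", "", 1).isdigit():
                    chain = rest[0]
                    rest = rest[1:]
                else:
                    chain = "A"
                res_num = int(rest[0])
                x, y, z, charge, radius = (float(v) for v in rest[1:6])
            except (ValueError, IndexError) as exc:
                raise StructureParseError(f"{path}: malformed record at line {lineno}: {exc}")
            if res_name in _WATER_NAMES:
                continue
            atoms.append(
                Atom(serial=serial, name=name, element=_element_from_name(name),
                     res_name=res_name, res_num=res_num, chain=chain,
                     position=(x, y, z), radius=radius, charge=charge)
            )
    if not atoms:
        raise StructureParseError(f"{path}: no ATOM records found")
    return MolecularStructure(atoms=atoms, source_format="PQR",
                              identifier=Path(path).stem)


def read_structure(path, fmt: str | None = None, include_hetero: bool = False) -> MolecularStructure:
    """Read a PDB or PQR file, auto-detecting the format when unspecified."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix == ".pqr":
            fmt = "PQR"
        elif suffix in (".pdb", ".ent"):
            fmt = "PDB"
        else:
            fmt = _sniff_format(path)
    fmt = fmt.upper()
    if fmt == "PQR":
        return read_pqr(path)
    if fmt == "PDB":
        return read_pdb(path, include_hetero=include_hetero)
    raise ValueError(f"unsupported structure format {fmt!r}")


def _sniff_format(path) -> str:
    """PQR records split into >= 10 whitespace fields with trailing floats."""
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                fields = line.split()
                if len(fields) >= 10:
                    try:
                        float(fields[-1]), float(fields[-2])
                        return "PQR"
                    except ValueError:
                        return "PDB"
                return "PDB"
    return "PDB"


def write_pqr(s: MolecularStructure, path) -> None:
    with open(path, "w") as fh:
        for a in s.atoms:
            charge = a.charge if a.charge is not None else 0.0
            fh.write(
                f"ATOM  {a.serial:5d} {a.name:<4s} {a.res_name:<3s} {a.chain:1s} "
                f"{a.res_num:4d}    {a.position[0]:12.6f} {a.position[1]:12.6f} "
                f"{a.position[2]:12.6f} {charge:10.6f} {a.vdw_radius:9.6f}\n"
            )
        fh.write("END\n")


def write_shell_xyz(geom: ShellGeometry, path) -> None:
    """XYZ export: 'C' for surface atoms, 'X' for the central atom."""
    h, k = geom.goldberg_indices
    with open(path, "w") as fh:
        fh.write(f"{geom.n_surface + 1}\n")
        fh.write(f"goldberg shell h={h} k={k} bond_length={geom.bond_length}\n")
        for p in geom.surface_positions:
            fh.write(f"C {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        c = geom.central_position
        fh.write(f"X {c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")


def write_topology(top: Topology, csv_path) -> None:
    """Topology as CSV (index, x, y, z, charge) plus a JSON sidecar."""
    geom = top.geometry
    df = pd.DataFrame(
        {
            "index": np.arange(geom.n_surface),
            "x": geom.surface_positions[:, 0],
            "y": geom.surface_positions[:, 1],
            "z": geom.surface_positions[:, 2],
            "charge": top.surface_charges,
        }
    )
    df.to_csv(csv_path, index=False)
    h, k = geom.goldberg_indices
    meta = {
        "label": top.label,
        "seed": top.seed,
        "q": top.q,
        "p": top.p,
        "central_charge": top.central_charge,
        "h": h,
        "k": k,
        "bond_length": geom.bond_length,
    }
    Path(str(csv_path) + ".json").write_text(json.dumps(meta, indent=1))


def read_topology(csv_path) -> Topology:
    """Rebuild a topology written by :func:`write_topology`."""
    from colloidkit.shell import build_goldberg_shell

    meta = json.loads(Path(str(csv_path) + ".json").read_text())
    df = pd.read_csv(csv_path)
    geom = build_goldberg_shell(meta["h"], meta["k"], meta["bond_length"])
    return Topology(
        geometry=geom,
        surface_charges=df["charge"].to_numpy(),
        central_charge=meta["central_charge"],
        label=meta["label"],
        seed=meta["seed"],
    )


def read_pmf(path) -> PMFCurve:
    """Two- or three-column whitespace text: separation, energy[, error]."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 or 3 columns")
    errors = data[:, 2] if data.shape[1] >= 3 else None
    return PMFCurve(separations=data[:, 0], free_energy=data[:, 1], errors=errors)


def write_sidecar(out_path, config: dict) -> None:
    """JSON sidecar recording the full resolved run configuration."""
    from colloidkit import __version__

    payload = {"version": __version__, "config": config}
    Path(str(out_path) + ".json").write_text(json.dumps(payload, indent=1, default=str))
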