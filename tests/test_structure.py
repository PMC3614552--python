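import numpy as np
import pandas as pd
import pytest

from colloidkit.fixtures import make_peptide
from colloidkit.structure import (
    Atom,
    MolecularStructure,
    assign_formal_charges,
    net_charge,
    nsap,
    residue_sasa,
    sap_max,
    sap_profile,
    sasa,
    structure_dipole,
)


def atom(serial, name, element, res_name, res_num, pos, chain="A", radius=None, charge=None):
    return Atom(serial=serial, name=name, element=element, res_name=res_name,
                res_num=res_num, chain=chain, position=pos, radius=radius, charge=charge)


def point_structure(specs):
    """specs: list of (pos, charge, element, mass proxy via element)."""
    atoms = [
        atom(i + 1, "CA", el, "GLY", i + 1, pos, charge=q)
        for i, (pos, q, el) in enumerate(specs)
    ]
    return MolecularStructure(atoms=atoms, source_format="PQR")


class TestFormalCharges:
    def test_single_arg_capped(self):
        s = make_peptide("R", seed=0)
        s = assign_formal_charges(s, capped_termini=True)
        assert net_charge(s) == pytest.approx(1.0)

    def test_tripeptide_free_termini(self):
        s = make_peptide("DGR", seed=0)
        s = assign_formal_charges(s)
        # (-1 ASP) + (+1 ARG) + (+1 N-term) + (-1 C-term)
        assert net_charge(s) == pytest.approx(0.0)

    def test_three_asp_one_lys_capped(self):
        s = make_peptide("DDDK", seed=0)
        s = assign_formal_charges(s, capped_termini=True)
        assert net_charge(s) == pytest.approx(-2.0)

    def test_his_neutral(self):
        s = make_peptide("H", seed=0)
        s = assign_formal_charges(s, capped_termini=True)
        assert net_charge(s) == pytest.approx(0.0)

    def test_unknown_residue_warns(self):
        s = MolecularStructure(atoms=[atom(1, "CA", "C", "XYZ", 1, (0, 0, 0))])
        with pytest.warns(UserWarning, match="XYZ"):
            out = assign_formal_charges(s, capped_termini=True)
        assert net_charge(out) == 0.0

    def test_pqr_charges_kept(self):
        s = point_structure([((0, 0, 0), 0.42, "C")])
        out = assign_formal_charges(s)
        assert out.atoms[0].charge == 0.42

    def test_only_ph7(self):
        s = make_peptide("G", seed=0)
        with pytest.raises(ValueError):
            assign_formal_charges(s, pH=5.0)

    def test_charge_lands_on_site_atom(self):
        s = make_peptide("K", seed=0)
        s = assign_formal_charges(s, capped_termini=True)
        by_name = {a.name: a for a in s.atoms}
        assert by_name["NZ"].charge == pytest.approx(1.0)


class TestChargeDipole:
    def test_unit_pair(self):
        s = point_structure([((0, 0, 0), 1.0, "C"), ((10, 0, 0), -1.0, "C")])
        assert net_charge(s) == pytest.approx(0.0)
        assert structure_dipole(s) == pytest.approx(10.0, abs=1e-12)

    def test_all_zero(self):
        s = point_structure([((0, 0, 0), 0.0, "C"), ((5, 0, 0), 0.0, "C")])
        assert net_charge(s) == 0.0
        assert structure_dipole(s) == 0.0

    def test_direct_summation_oracle(self):
        rng = np.random.default_rng(4)
        specs = [(tuple(rng.normal(scale=8, size=3)), float(rng.normal()), "N") for _ in range(30)]
        s = point_structure(specs)
        masses = np.array([a.mass for a in s.atoms])
        pos = s.positions()
        com = masses @ pos / masses.sum()
        vec = sum(q * (np.asarray(p) - com) for p, q, _ in specs)
        assert structure_dipole(s) == pytest.approx(float(np.linalg.norm(vec)), abs=1e-9)

    def test_neutral_dipole_translation_invariant(self):
        s = point_structure([((0, 0, 0), 1.0, "C"), ((10, 0, 0), -1.0, "C")])
        p0 = structure_dipole(s)
        rng = np.random.default_rng(1)
        for _ in range(3):
            t = rng.normal(scale=50, size=3)
            shifted = s.copy()
            for a in shifted.atoms:
                a.position = a.position + t
            assert structure_dipole(shifted) == pytest.approx(p0, abs=1e-9)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        s = point_structure([((0, 0, 0), 0.0, "C")])
        s.atoms[0].radius = 1.9
        area = sasa(s, probe_radius=1.4)
        assert area[0] == pytest.approx(4 * np.pi * 3.3**2, rel=1e-9)

    def test_two_distant_atoms_unperturbed(self):
        s = point_structure([((0, 0, 0), 0.0, "C"), ((100, 0, 0), 0.0, "C")])
        areas = sasa(s)
        iso = 4 * np.pi * (1.70 + 1.4) ** 2
        np.testing.assert_allclose(areas, iso, rtol=1e-9)

    def test_fully_buried_atom(self):
        # cage of 60 overlapping atoms around a central one
        i = np.arange(60) + 0.5
        phi = np.arccos(1 - 2 * i / 60)
        theta = np.pi * (1 + np.sqrt(5)) * i
        shell = 2.0 * np.column_stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
        )
        specs = [((0.0, 0.0, 0.0), 0.0, "C")] + [(tuple(p), 0.0, "S") for p in shell]
        s = point_structure(specs)
        areas = sasa(s)
        assert areas[0] == 0.0

    def test_rotation_invariance(self):
        s = make_peptide("DGRKA", seed=2)
        total = sasa(s).sum()
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        r = s.copy()
        for a in r.atoms:
            a.position = rot @ a.position
        assert sasa(r).sum() == pytest.approx(total, rel=0.005)

    def test_pair_area_monotone_on_approach(self):
        iso = 4 * np.pi * (1.70 + 1.4) ** 2
        prev = 2 * iso + 1.0
        for d in (6.0, 5.0, 4.0, 3.0, 2.0, 1.0):
            s = point_structure([((0, 0, 0), 0.0, "C"), ((d, 0, 0), 0.0, "C")])
            total = sasa(s).sum()
            assert total <= prev + 1e-9
            prev = total

    def test_zero_radius_is_error(self):
        s = point_structure([((0, 0, 0), 0.0, "C")])
        s.atoms[0].radius = 0.0
        with pytest.raises(ValueError):
            sasa(s)


class TestSap:
    def test_all_glycine_is_zero(self):
        s = make_peptide("GGGG", seed=0)
        prof = sap_profile(s)
        np.testing.assert_allclose(prof["sap"].to_numpy(), 0.0, atol=1e-12)

    def test_buried_sidechain_contributes_nothing(self):
        s = make_peptide("GAG", seed=1)
        areas = sasa(s)
        # bury ALA's side chain artificially
        for i, a in enumerate(s.atoms):
            if a.res_name == "ALA" and a.is_sidechain:
                areas[i] = 0.0
        prof = sap_profile(s, atom_sasa=areas)
        np.testing.assert_allclose(prof["sap"].to_numpy(), 0.0, atol=1e-12)

    def test_single_residue_hand_enumeration(self):
        from colloidkit.structure import HYDROPHOBICITY, MAX_SIDECHAIN_SASA, _H_SHIFT

        s = make_peptide("L", seed=3)
        areas = sasa(s)
        prof = sap_profile(s, R=5.0, atom_sasa=areas)
        # independent hand enumeration with explicit loops
        h = HYDROPHOBICITY["LEU"] - _H_SHIFT
        ref = MAX_SIDECHAIN_SASA["LEU"]
        pos = s.positions()
        sap_atoms = []
        for i, ai in enumerate(s.atoms):
            acc = 0.0
            for j, aj in enumerate(s.atoms):
                if aj.is_sidechain and np.linalg.norm(pos[i] - pos[j]) < 5.0:
                    acc += areas[j] / ref * h
            sap_atoms.append(acc)
        assert prof["sap"].iloc[0] == pytest.approx(float(np.mean(sap_atoms)), abs=1e-12)

    def test_unknown_residue_warns_and_excluded(self):
        atoms = [
            atom(1, "CA", "C", "GLY", 1, (0, 0, 0)),
            atom(2, "XX", "C", "UNK", 2, (2, 0, 0)),
        ]
        s = MolecularStructure(atoms=atoms)
        with pytest.warns(UserWarning, match="UNK"):
            prof = sap_profile(s)
        np.testing.assert_allclose(prof["sap"].to_numpy(), 0.0, atol=1e-12)


class TestSapSummaries:
    def _profile(self, saps):
        return pd.DataFrame(
            {"chain": "A", "resnum": range(1, len(saps) + 1), "icode": "",
             "resname": "ALA", "sap": saps}
        )

    def test_nonpositive_profile(self):
        prof = self._profile([-0.5, -0.1, 0.0])
        res_area = pd.Series([50.0, 60.0, 70.0])
        assert nsap(prof, res_area) == 0.0
        assert sap_max(prof) == 0.0

    def test_single_residue_arithmetic(self):
        prof = self._profile([0.5])
        assert nsap(prof, pd.Series([100.0])) == pytest.approx(0.005)

    def test_two_residue_hand_computation(self):
        prof = self._profile([0.4, -0.2])
        res_area = pd.Series([120.0, 80.0])
        assert nsap(prof, res_area) == pytest.approx(0.4 / 200.0)
        assert sap_max(prof) == pytest.approx(0.4)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            sap_max(self._profile([]))

    def test_residue_sasa_sums_atoms(self):
        s = make_peptide("GA", seed=0)
        areas = sasa(s)
        per_res = residue_sasa(s, areas)
        assert per_res.sum() == pytest.approx(areas.sum(), abs=1e-9)
        assert len(per_res) == 2
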