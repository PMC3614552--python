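import numpy as np
import pytest

from colloidkit.patches import PatchParams, summarize_patches
from colloidkit.structure import Atom, MolecularStructure
from colloidkit.topology import (
    ChargeDistribution,
    build_charge_histogram,
    default_charge_distribution,
    dipole_moment,
    generate_ensemble,
    sample_topology,
    select_dipole_series,
    select_varied_set,
    set_central_charge,
)

from .conftest import make_topology


def point_mass_at_zero():
    return ChargeDistribution(bin_edges=np.array([-1e-12, 1e-12]), weights=np.array([1.0]))


def _structure_with(charges):
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", res_name="GLY", res_num=i + 1,
             chain="A", position=(float(i) * 4.0, 0.0, 0.0), charge=c)
        for i, c in enumerate(charges)
    ]
    return MolecularStructure(atoms=atoms, source_format="PQR")


class TestChargeDistribution:
    def test_weights_normalized(self):
        d = ChargeDistribution(np.array([0.0, 1.0, 2.0]), np.array([1.0, 3.0]))
        np.testing.assert_allclose(d.weights, [0.25, 0.75])

    def test_rejects_decreasing_edges(self):
        with pytest.raises(ValueError):
            ChargeDistribution(np.array([1.0, 0.0]), np.array([1.0]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            ChargeDistribution(np.array([0.0]), np.array([]))

    def test_default_distribution_valid(self, charge_dist):
        assert charge_dist.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(charge_dist.bin_edges) > 0)


class TestChargeHistogram:
    def test_sasa_proportional_weights(self):
        s = _structure_with([+0.5, -0.5])
        dist = build_charge_histogram([s], [np.array([10.0, 30.0])], bin_width=0.1)
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        w_pos = dist.weights[np.argmin(np.abs(centers - 0.5))]
        w_neg = dist.weights[np.argmin(np.abs(centers + 0.5))]
        assert w_pos == pytest.approx(0.25)
        assert w_neg == pytest.approx(0.75)

    def test_single_atom_single_bin(self):
        s = _structure_with([0.3])
        dist = build_charge_histogram([s], [np.array([5.0])])
        assert dist.weights.max() == pytest.approx(1.0)

    def test_all_buried_is_error(self):
        s = _structure_with([0.1, -0.1])
        with pytest.raises(ValueError, match="no solvent-exposed"):
            build_charge_histogram([s], [np.zeros(2)])

    def test_matches_hand_tally(self):
        # three atoms, charges/-exposures chosen by hand
        s = _structure_with([0.1, 0.1, -0.3])
        sas = np.array([2.0, 6.0, 4.0])
        dist = build_charge_histogram([s], [sas], bin_width=0.2)
        # hand tally: bin of +0.1 has 8/12, bin of -0.3 has 4/12
        assert sorted(np.round(dist.weights[dist.weights > 0], 6)) == [
            pytest.approx(4 / 12), pytest.approx(8 / 12)]


class TestSampleTopology:
    def test_point_mass_gives_uniform_shift(self, gp32):
        top = sample_topology(gp32, point_mass_at_zero(), -2.0, seed=0)
        np.testing.assert_allclose(top.surface_charges, -2.0 / 380, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_net_charge_exact(self, gp32, charge_dist, seed):
        top = sample_topology(gp32, charge_dist, -2.0, seed=seed)
        assert top.q == pytest.approx(-2.0, abs=1e-9)

    def test_deterministic(self, gp32, charge_dist):
        a = sample_topology(gp32, charge_dist, -2.0, seed=42)
        b = sample_topology(gp32, charge_dist, -2.0, seed=42)
        np.testing.assert_array_equal(a.surface_charges, b.surface_charges)

    def test_rejects_nonfinite_target(self, gp32, charge_dist):
        with pytest.raises(ValueError):
            sample_topology(gp32, charge_dist, np.inf, seed=0)


class TestDipole:
    def test_neutral_pair(self, two_point_geometry):
        top = make_topology(two_point_geometry, [0.5, -0.5])
        assert dipole_moment(top) == pytest.approx(5.0, abs=1e-12)
        # origin independence for a neutral topology
        rng = np.random.default_rng(0)
        for _ in range(3):
            origin = rng.normal(scale=20.0, size=3)
            assert dipole_moment(top, origin) == pytest.approx(5.0, abs=1e-9)

    def test_central_charge_only(self, gp32):
        top = make_topology(gp32, np.zeros(380), central_charge=-4.0)
        assert dipole_moment(top) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle(self, gp11, charge_dist):
        for seed in range(5):
            top = sample_topology(gp11, charge_dist, -2.0, seed=seed)
            origin = gp11.central_position
            vec = np.zeros(3)
            for q, r in zip(top.surface_charges, gp11.surface_positions):
                vec += q * (r - origin)
            assert dipole_moment(top) == pytest.approx(np.linalg.norm(vec), abs=1e-9)


class TestCentralCharge:
    def test_net_charge_shifts(self, gp32, charge_dist):
        top = sample_topology(gp32, charge_dist, -2.0, seed=3)
        assert set_central_charge(top, -4.0).q == pytest.approx(-6.0, abs=1e-9)
        assert set_central_charge(top, -8.0).q == pytest.approx(-10.0, abs=1e-9)

    def test_dipole_unchanged(self, gp32, charge_dist):
        top = sample_topology(gp32, charge_dist, -2.0, seed=3)
        for qc in (-4.0, -8.0, 3.0):
            assert set_central_charge(top, qc).p == pytest.approx(top.p, abs=1e-12)

    def test_patch_descriptors_bit_identical(self, gp32, charge_dist):
        top = sample_topology(gp32, charge_dist, -2.0, seed=3)
        shifted = set_central_charge(top, -4.0)
        for params in (PatchParams(5.0, 0), PatchParams(2.65, 0), PatchParams(5.0, 2)):
            a = summarize_patches(top, params)
            b = summarize_patches(shifted, params)
            assert a.mlssc == b.mlssc and a.mlsc == b.mlsc


class TestEnsemble:
    def test_reproducible_and_distinct(self, gp32, charge_dist):
        a = generate_ensemble(gp32, charge_dist, 5, -2.0, seed=11, annotate=False)
        b = generate_ensemble(gp32, charge_dist, 5, -2.0, seed=11, annotate=False)
        assert [t.label for t in a] == [t.label for t in b]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.surface_charges, y.surface_charges)
        charges = {tuple(np.round(t.surface_charges, 12)) for t in a}
        assert len(charges) == 5

    def test_point_mass_zero_target_gives_zero_dipole(self, gp32):
        tops = generate_ensemble(gp32, point_mass_at_zero(), 3, 0.0, seed=0, annotate=False)
        for t in tops:
            assert t.p == pytest.approx(0.0, abs=1e-6)

    def test_annotations_and_range_flags(self, gp32, charge_dist):
        tops = generate_ensemble(gp32, charge_dist, 20, -2.0, seed=0)
        ps = np.array([t.descriptors["p"] for t in tops])
        assert ps.std() > 0  # dipoles actually spread out
        for t in tops:
            expected = (-10.0 <= t.q <= 0.0) and (0.0 <= t.p <= 70.0)
            assert t.descriptors["in_range"] == expected
            assert "mlssc" in t.descriptors and "mlsc" in t.descriptors

    def test_rejects_zero_count(self, gp32, charge_dist):
        with pytest.raises(ValueError):
            generate_ensemble(gp32, charge_dist, 0, -2.0, seed=0)


def _fake_top(geom, label, mlssc, mlsc, q=-2.0, p=18.0):
    """Duck-typed topology stub with preset descriptors (selection only
    reads label/q/p/descriptors)."""
    from types import SimpleNamespace

    return SimpleNamespace(label=label, q=q, p=p, descriptors={"mlssc": mlssc, "mlsc": mlsc})


class TestVariedSelection:
    def test_two_eligible_returns_both(self, two_point_geometry):
        cands = [_fake_top(two_point_geometry, f"T{i}", float(i), -float(i)) for i in range(2)]
        out = select_varied_set(cands, -2.0, 18.0, 2.0, 2)
        assert {t.label for t in out} == {"T0", "T1"}

    def test_identical_descriptors_tie_break_by_label(self, two_point_geometry):
        cands = [_fake_top(two_point_geometry, f"T{i}", 1.0, -1.0) for i in range(5)]
        out = select_varied_set(cands, -2.0, 18.0, 2.0, 3)
        assert [t.label for t in out] == ["T0", "T1", "T2"]

    def test_two_clusters_one_each(self, two_point_geometry):
        near = [_fake_top(two_point_geometry, f"A{i}", 0.1 + 0.001 * i, -0.1) for i in range(5)]
        far = [_fake_top(two_point_geometry, f"B{i}", 5.0 + 0.001 * i, -9.0) for i in range(5)]
        out = select_varied_set(near + far, -2.0, 18.0, 2.0, 2)
        labels = {t.label[0] for t in out}
        assert labels == {"A", "B"}

    def test_shortfall_raises(self, two_point_geometry):
        cands = [_fake_top(two_point_geometry, "T0", 1.0, -1.0)]
        with pytest.raises(ValueError, match="need 2"):
            select_varied_set(cands, -2.0, 18.0, 2.0, 2)


class TestDipoleSeries:
    def test_trivial_two_bins(self, two_point_geometry):
        cands = [
            _fake_top(two_point_geometry, "LO", 0.0, 0.0, p=1.0),
            _fake_top(two_point_geometry, "HI", 0.0, 0.0, p=18.0),
        ]
        out = select_dipole_series(cands, -2.0, [(0.0, 5.0), (15.0, 20.0)])
        assert [t.label for t in out] == ["LO", "HI"]

    def test_midpoint_preference(self, two_point_geometry):
        cands = [
            _fake_top(two_point_geometry, "A", 0.0, 0.0, p=16.0),
            _fake_top(two_point_geometry, "B", 0.0, 0.0, p=17.5),
        ]
        out = select_dipole_series(cands, -2.0, [(15.0, 20.0)])
        assert out[0].label == "B"

    def test_empty_bin_named_in_error(self, two_point_geometry):
        cands = [_fake_top(two_point_geometry, "A", 0.0, 0.0, p=1.0)]
        with pytest.raises(ValueError, match=r"\(30\.0, 40\.0\)"):
            select_dipole_series(cands, -2.0, [(0.0, 5.0), (30.0, 40.0)])

    def test_series_from_real_ensemble(self, gp32, charge_dist):
        tops = generate_ensemble(gp32, charge_dist, 300, -2.0, seed=0, annotate=False)
        bins = [(0.0, 12.0), (15.0, 21.0), (30.0, 40.0), (50.0, 60.0), (60.0, 68.0), (68.0, 85.0)]
        out = select_dipole_series(tops, -2.0, bins)
        ps = [t.p for t in out]
        assert len(out) == 6
        assert all(a < b for a, b in zip(ps, ps[1:]))
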