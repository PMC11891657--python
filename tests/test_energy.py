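"""Energy terms: closed forms, brute-force oracles, and invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dockem.density import DensityGrid, extract_local_map, ligand_region_cc
from dockem.energy import (
    CLASH_DISTANCE,
    EnergyModel,
    EnergyWeights,
    e_dis,
    e_inter,
    e_intra,
    e_total,
    select_interface_atoms,
)
from dockem.errors import ParameterError
from dockem.structio import (
    Atom,
    Bond,
    Ligand,
    Protein,
    Residue,
    assign_parameters,
)
from tests_helpers import random_parameterized_ligand


def single_atom_protein(element, xyz, charge=None):
    atom = Atom(index=1, name=element, element=element, coords=xyz)
    prot = Protein([atom], [Residue("A", 1, "", "RES", [0])])
    assign_parameters(prot)
    if charge is not None:
        prot.atoms[0].charge = charge
    return prot


def single_atom_ligand(element, xyz, charge=0.0):
    # a second far-away dummy keeps the bond graph valid while leaving the
    # pair sums dominated by the first atom is avoided: use a real 1-atom
    # ligand instead (bonds empty is fine for a single atom)
    lig = Ligand([Atom(index=1, name=element, element=element,
                       coords=xyz, charge=charge)], [])
    assign_parameters(lig)
    return lig


class TestPairTerms:
    @pytest.mark.parametrize("e1,e2", [("C", "C"), ("C", "O"), ("N", "S")])
    def test_lj_minimum_is_minus_epsilon(self, e1, e2):
        prot = single_atom_protein(e1, (0, 0, 0), charge=0.0)
        lig = single_atom_ligand(e2, (0, 0, 0))
        d = prot.atoms[0].vdw_radius + lig.atoms[0].vdw_radius
        lig.atoms[0].coords = np.array([d, 0.0, 0.0])
        w = EnergyWeights(w21=1.0, w22=0.0)
        expected = -np.sqrt(prot.atoms[0].well_depth * lig.atoms[0].well_depth)
        assert e_intra(prot, np.array([0]), lig.coords, lig, w) == \
            pytest.approx(expected, abs=1e-12)

    def test_coulomb_spot_value(self):
        # unit charges at distance 1: q_i q_j / (4 d) = 0.25
        prot = single_atom_protein("C", (0, 0, 0), charge=1.0)
        lig = single_atom_ligand("C", (1.0, 0, 0), charge=1.0)
        w = EnergyWeights(w21=0.0, w22=1.0)
        assert e_intra(prot, np.array([0]), lig.coords, lig, w) == \
            pytest.approx(0.25, abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(8)
        prot_atoms = []
        for i in range(5):
            a = Atom(index=i + 1, name=f"P{i}", element="C",
                     coords=rng.uniform(-3, 3, 3))
            prot_atoms.append(a)
        prot = Protein(prot_atoms, [Residue("A", 1, "", "POC",
                                            list(range(5)))])
        assign_parameters(prot)
        for a in prot.atoms:
            a.charge = float(rng.uniform(-0.5, 0.5))
        lig = random_parameterized_ligand(9, n=8)
        w = EnergyWeights(w21=0.7, w22=1.3)
        got = e_intra(prot, np.arange(5), lig.coords, lig, w)
        # brute force
        total = 0.0
        for pa in prot.atoms:
            for la in lig.atoms:
                d = max(float(np.linalg.norm(pa.coords - la.coords)), CLASH_DISTANCE)
                R = pa.vdw_radius + la.vdw_radius
                eps = np.sqrt(pa.well_depth * la.well_depth)
                total += w.w21 * (eps * R**12 / d**12 - 2 * eps * R**6 / d**6)
                total += w.w22 * pa.charge * la.charge / (4 * d)
        assert got == pytest.approx(total, abs=1e-10)


class TestEInter:
    def test_bonded_pair_excluded(self):
        lig = Ligand([
            Atom(index=1, name="C1", element="C", coords=(0, 0, 0)),
            Atom(index=2, name="C2", element="C", coords=(1.5, 0, 0)),
        ], [Bond(1, 2, "1")])
        assign_parameters(lig)
        assert e_inter(lig.coords, lig) == 0.0

    def test_nonbonded_pair_at_minimum(self):
        lig = random_parameterized_ligand(10, n=4)
        # place atoms 1 and 4 (a 1-4 pair, not excluded) at the LJ minimum,
        # others far away
        r = lig.vdw_radii
        d = r[0] + r[3]
        coords = np.array([[0, 0, 0], [100, 0, 0], [200, 0, 0], [d, 0, 0]],
                          dtype=float)
        eps = np.sqrt(lig.well_depths[0] * lig.well_depths[3])
        assert e_inter(coords, lig) == pytest.approx(-eps, abs=1e-9)

    def test_matches_brute_force_with_exclusions(self):
        import networkx as nx

        lig = random_parameterized_ligand(11, n=10)
        got = e_inter(lig.coords, lig)
        g = lig.bond_graph()
        paths = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
        total = 0.0
        atoms = lig.atoms
        for i in range(10):
            for j in range(i + 1, 10):
                if paths[atoms[i].index].get(atoms[j].index, 99) <= 2:
                    continue
                s = max(float(np.linalg.norm(atoms[i].coords - atoms[j].coords)),
                        CLASH_DISTANCE)
                R = atoms[i].vdw_radius + atoms[j].vdw_radius
                eps = np.sqrt(atoms[i].well_depth * atoms[j].well_depth)
                total += eps * R**12 / s**12 - 2 * eps * R**6 / s**6
        assert got == pytest.approx(total, abs=1e-10)

    def test_literal_mode_includes_bonded(self):
        lig = Ligand([
            Atom(index=1, name="C1", element="C", coords=(0, 0, 0)),
            Atom(index=2, name="C2", element="C", coords=(1.5, 0, 0)),
        ], [Bond(1, 2, "1")])
        assign_parameters(lig)
        assert e_inter(lig.coords, lig, literal_pairs=True) > 0.0


class TestEDis:
    def test_piecewise_values(self):
        c0 = np.zeros(3)
        c_lim = 2.0
        assert e_dis(c0, c0, c_lim) == 0.0
        assert e_dis((1.99, 0, 0), c0, c_lim) == 0.0
        # at the boundary the restraint switches on and returns the distance
        assert e_dis((2.0, 0, 0), c0, c_lim) == pytest.approx(2.0)
        assert e_dis((4.0, 0, 0), c0, c_lim) == pytest.approx(4.0)

    def test_invalid_c_lim(self):
        with pytest.raises(ParameterError):
            e_dis((0, 0, 0), (0, 0, 0), 0.0)


class TestInterfaceSelection:
    def test_atom_inside_cube_selected(self, toy_fixture):
        fx = toy_fixture
        local = extract_local_map(fx.grid, fx.site_center, fx.ligand.diameter)
        prot = Protein([Atom(index=1, name="C", element="C",
                             coords=local.center)],
                       [Residue("A", 1, "", "POC", [0])])
        assign_parameters(prot)
        assert list(select_interface_atoms(prot, local, fx.ligand)) == [0]

    def test_boundary_is_strict(self):
        # exactly representable geometry: cube [3, 7]^3, c_lim = 1.5, atom at
        # distance exactly 1.5 from the face -> excluded by the strict rule
        grid = DensityGrid(np.zeros((11, 11, 11)), (0, 0, 0), 1.0, resolution=3.0)
        local = extract_local_map(grid, (5.0, 5.0, 5.0), 4.0)
        lig = Ligand([
            Atom(index=1, name="C1", element="C", coords=(0, 0, 0)),
            Atom(index=2, name="C2", element="C", coords=(3.0, 0, 0)),
        ], [Bond(1, 2, "1")])
        assign_parameters(lig)
        from dockem.structio import ligand_diameter
        ligand_diameter(lig)
        at = Atom(index=1, name="C", element="C", coords=(8.5, 5.0, 5.0))
        inside = Atom(index=2, name="C", element="C", coords=(8.4, 5.0, 5.0))
        prot = Protein([at, inside], [Residue("A", 1, "", "POC", [0, 1])])
        assign_parameters(prot)
        assert list(select_interface_atoms(prot, local, lig)) == [1]

    def test_matches_brute_force_box_distance(self, toy_fixture):
        fx = toy_fixture
        local = extract_local_map(fx.grid, fx.site_center, fx.ligand.diameter)
        got = set(select_interface_atoms(fx.protein, local, fx.ligand))
        lo, hi = local.cube_bounds()
        expected = set()
        for i, a in enumerate(fx.protein.atoms):
            d = np.linalg.norm(a.coords - np.clip(a.coords, lo, hi))
            if d < fx.ligand.c_lim:
                expected.add(i)
        assert got == expected


class TestETotal:
    def test_zero_weights(self, toy_fixture):
        fx = toy_fixture
        local = extract_local_map(fx.grid, fx.site_center, fx.ligand.diameter)
        w = EnergyWeights(w1=0, w2=0, w3=0, w4=0)
        bd = e_total(fx.true_coords, fx.protein, local, fx.ligand, w)
        assert bd.total == 0.0

    def test_cc_self_consistency(self, toy_fixture):
        fx = toy_fixture
        local = extract_local_map(fx.grid, fx.site_center, fx.ligand.diameter)
        w = EnergyWeights(w1=1, w2=0, w3=0, w4=0)
        bd = e_total(fx.true_coords, fx.protein, local, fx.ligand, w)
        assert bd.total < 0.01

    def test_recomposition(self, toy_fixture):
        fx = toy_fixture
        lig = fx.ligand
        local = extract_local_map(fx.grid, fx.site_center, lig.diameter)
        rng = np.random.default_rng(12)
        w = EnergyWeights()
        for _ in range(3):
            coords = fx.true_coords + rng.normal(0, 1.0, fx.true_coords.shape)
            bd = e_total(coords, fx.protein, local, lig, w)
            subset = select_interface_atoms(fx.protein, local, lig)
            ecc = 1.0 - float(ligand_region_cc(coords, local, masses=lig.masses))
            ei = e_intra(fx.protein, subset, coords, lig, w)
            ev = e_inter(coords, lig)
            ed = e_dis(coords.mean(axis=0), local.center, lig.c_lim)
            manual = w.w1 * ecc + w.w2 * ei + w.w3 * ev + w.w4 * ed
            assert bd.total == pytest.approx(manual, abs=1e-10)
            assert bd.e_cc == pytest.approx(ecc, abs=1e-12)

    def test_rigid_invariance_of_physics_terms(self):
        lig = random_parameterized_ligand(13, n=9)
        rot = Rotation.from_rotvec([0.3, -0.8, 0.5])
        shifted = rot.apply(lig.coords) + np.array([3.0, -2.0, 1.0])
        assert e_inter(shifted, lig) == pytest.approx(e_inter(lig.coords, lig),
                                                      rel=1e-9)

    def test_e_cc_bounds(self, toy_fixture):
        fx = toy_fixture
        local = extract_local_map(fx.grid, fx.site_center, fx.ligand.diameter)
        model = EnergyModel(fx.protein, fx.ligand, local)
        rng = np.random.default_rng(14)
        for _ in range(5):
            coords = fx.true_coords + rng.normal(0, 2.0, fx.true_coords.shape)
            bd = model.breakdown(coords)
            assert 0.0 <= bd.e_cc <= 2.0
            assert bd.e_dis >= 0.0

    def test_fast_cc_path_bitwise_equals_generic(self, toy_fixture):
        fx = toy_fixture
        local = extract_local_map(fx.grid, fx.site_center, fx.ligand.diameter)
        model = EnergyModel(fx.protein, fx.ligand, local)
        rng = np.random.default_rng(15)
        for _ in range(10):
            coords = fx.true_coords + rng.normal(0, 1.5, fx.true_coords.shape)
            assert model.cc(coords) == float(
                ligand_region_cc(coords, local, masses=fx.ligand.masses))


class TestWeights:
    def test_validation(self):
        with pytest.raises(ParameterError):
            EnergyWeights(w1=-1)
        with pytest.raises(ParameterError):
            EnergyWeights(K=0)
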