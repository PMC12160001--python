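"""Core structure machinery: XYZ I/O, partitioning, inertia, volumes."""

import math

import numpy as np
import pytest

from solvmode import elements
from solvmode.structure import (AtomicStructure, MoleculePartition,
                                XYZParseError, assign_solute, detect_molecules,
                                molecular_volume, principal_moments, read_xyz,
                                write_xyz)

from conftest import random_structure


class TestXYZ:
    def test_round_trip_preserves_coordinates(self, water, tmp_path):
        path = tmp_path / "w.xyz"
        write_xyz(water, path)
        back = read_xyz(path)
        assert back.symbols == ("O", "H", "H")
        np.testing.assert_allclose(back.coordinates, water.coordinates,
                                   atol=1e-6)

    def test_empty_structure(self, tmp_path):
        path = tmp_path / "empty.xyz"
        write_xyz(AtomicStructure((), np.zeros((0, 3))), path)
        assert path.read_text() == "0\n\n"
        assert read_xyz(path).n_atoms == 0

    def test_atom_count_matches_line_count(self, tmp_path):
        sys100 = random_structure(np.random.default_rng(0), 100)
        path = tmp_path / "d.xyz"
        write_xyz(sys100, path)
        assert len(path.read_text().splitlines()) == 102

    @pytest.mark.parametrize("content,fragment", [
        ("5\n\nO 0 0 0\nH 1 0 0\nH 0 1 0\nH 1 1 0\n", "expected 5 atom"),
        ("x\n\n", "malformed atom count"),
        ("1\n\nXx 0 0 0\n", "unknown element"),
        ("1\n\nO a b c\n", "non-numeric"),
    ])
    def test_malformed_inputs_name_the_line(self, tmp_path, content, fragment):
        path = tmp_path / "bad.xyz"
        path.write_text(content)
        with pytest.raises(XYZParseError, match=fragment):
            read_xyz(path)

    def test_comment_metadata(self, tmp_path):
        path = tmp_path / "ion.xyz"
        path.write_text("1\ncharge=-1 multiplicity=2\nCl 0 0 0\n")
        st = read_xyz(path)
        assert (st.charge, st.multiplicity) == (-1, 2)


class TestElementTable:
    @pytest.mark.parametrize("symbol,radius", [
        ("H", 0.31), ("O", 0.66), ("Cl", 1.02)])
    def test_covalent_radii(self, symbol, radius):
        assert elements.covalent_radius(symbol) == pytest.approx(radius)

    def test_unknown_element(self):
        with pytest.raises(elements.UnknownElementError):
            elements.covalent_radius("Zz")


class TestDetectMolecules:
    def test_two_separated_waters(self, water):
        shifted = water.coordinates + np.array([5.0, 0, 0])
        pair = AtomicStructure(water.symbols * 2,
                               np.vstack([water.coordinates, shifted]))
        part = detect_molecules(pair)
        assert sorted(len(m) for m in part.molecules) == [3, 3]

    def test_single_atom(self):
        part = detect_molecules(AtomicStructure(("Ar",), np.zeros((1, 3))))
        assert part.molecules == (frozenset({0}),)

    def test_oh_bond_inequality(self):
        st = AtomicStructure(("O", "H"), np.array([[0, 0, 0], [0.96, 0, 0]]))
        assert len(detect_molecules(st, 1.2).molecules) == 1
        # 0.96 > 1.2 * 0.97 is false; shrink tolerance to break the bond
        assert len(detect_molecules(st, 0.9).molecules) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_bruteforce_bond_scan(self, seed):
        rng = np.random.default_rng(seed)
        st = random_structure(rng, 50)
        part = detect_molecules(st)
        # independent oracle: union-find over an all-pairs scan
        parent = list(range(50))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(50):
            for j in range(i + 1, 50):
                d = np.linalg.norm(st.coordinates[i] - st.coordinates[j])
                cut = 1.2 * (elements.covalent_radius(st.symbols[i])
                             + elements.covalent_radius(st.symbols[j]))
                if d <= cut:
                    parent[find(i)] = find(j)
        expected = {}
        for i in range(50):
            expected.setdefault(find(i), set()).add(i)
        assert {frozenset(m) for m in part.molecules} == \
            {frozenset(m) for m in expected.values()}

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_is_disjoint_cover(self, seed, toy_rc):
        from solvmode.synthetic import DropletConfig, make_droplet
        system = make_droplet(toy_rc, DropletConfig(n_solvent=6, seed=seed),
                              reactive_atoms={0, 1})
        part = detect_molecules(system.structure)
        atoms = [a for m in part.molecules for a in m]
        assert len(atoms) == len(set(atoms)) == system.n_atoms

    def test_assign_solute(self, water):
        shifted = water.coordinates + np.array([5.0, 0, 0])
        pair = AtomicStructure(water.symbols * 2,
                               np.vstack([water.coordinates, shifted]))
        part = assign_solute(detect_molecules(pair), {0})
        assert len(part.solute_ids) == 1
        assert part.solvent_ids == frozenset({1})

    def test_overlapping_molecules_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            MoleculePartition((frozenset({0, 1}), frozenset({1, 2})))


class TestInertia:
    def test_single_atom_is_point_mass(self):
        st = AtomicStructure(("C",), np.zeros((1, 3)))
        np.testing.assert_allclose(principal_moments(st), 0.0)

    def test_textbook_diatomic(self):
        st = AtomicStructure(("H", "H"),
                             np.array([[0, 0, 1.0], [0, 0, -1.0]]),
                             masses=np.array([1.0, 1.0]))
        np.testing.assert_allclose(principal_moments(st), [0.0, 2.0, 2.0],
                                   atol=1e-12)

    def test_water_has_three_distinct_moments(self, water):
        a, b, c = principal_moments(water)
        assert 0 < a < b < c
        # oracle: direct diagonalization of the inertia tensor
        x = water.coordinates - water.center_of_mass()
        m = water.masses
        t = np.zeros((3, 3))
        for mi, xi in zip(m, x):
            t += mi * (np.dot(xi, xi) * np.eye(3) - np.outer(xi, xi))
        np.testing.assert_allclose([a, b, c], np.linalg.eigvalsh(t),
                                   rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_perpendicular_axis_inequality(self, seed):
        st = random_structure(np.random.default_rng(seed), 12)
        a, b, c = principal_moments(st)
        assert c <= a + b + 1e-9


class TestMolecularVolume:
    def test_single_atom_converges_to_sphere(self):
        st = AtomicStructure(("C",), np.zeros((1, 3)))
        sphere = 4.0 / 3.0 * math.pi * 1.70 ** 3
        coarse = molecular_volume(st, 128)
        fine = molecular_volume(st, 4096)
        assert coarse < fine < sphere
        # inscribed-polyhedron error shrinks like 1/n_points
        assert fine == pytest.approx(sphere, rel=3e-3)
        assert sphere - fine < sphere - coarse

    def test_rigid_motion_invariance(self, water):
        v0 = molecular_volume(water)
        shifted = water.with_coordinates(water.coordinates + [10.0, -3.0, 2.0])
        assert molecular_volume(shifted) == pytest.approx(v0, abs=1e-9)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        rotated = water.with_coordinates(water.coordinates @ rot.T)
        assert molecular_volume(rotated) == pytest.approx(v0, rel=1e-6)

    def test_hull_grows_with_added_atoms(self):
        one = AtomicStructure(("C",), np.zeros((1, 3)))
        two = AtomicStructure(("C", "C"),
                              np.array([[0, 0, 0], [4.0, 0, 0]]))
        assert molecular_volume(two) > molecular_volume(one)

    def test_deterministic(self, water):
        assert molecular_volume(water) == molecular_volume(water)
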