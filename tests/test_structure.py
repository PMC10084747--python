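"""PDB parsing, Kabsch superposition, residue distances and Shrake–Rupley
solvent accessibility, checked against analytic values and naive oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from oracles import naive_sasa_point_count
from gpxprx.structure import (
    Structure,
    StructureError,
    kabsch_superpose,
    read_pdb,
    relative_accessibility,
    residue_pair_distance,
    residue_sasa,
    shrake_rupley_sasa,
    sphere_points,
)


def _pdb_line(serial, name, resname, chain, resseq, x, y, z, element, altloc=" "):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(
        _pdb_line(1, "N", "CYS", "A", 61, 0.0, 0.0, 0.0, "N")
        + _pdb_line(2, "CA", "CYS", "A", 61, 1.5, 0.0, 0.0, "C")
        + _pdb_line(3, "SG", "CYS", "A", 61, 2.5, 1.0, 0.0, "S")
        + _pdb_line(4, "CA", "GLY", "A", 62, 4.0, 0.0, 0.0, "C")
        + "END\n"
    )
    return p


def _structure(coords, radii):
    n = len(coords)
    return Structure(
        chains=["A"] * n,
        res_seqs=list(range(1, n + 1)),
        res_names=["GLY"] * n,
        atom_names=["X"] * n,
        elements=["C"] * n,
        coords=np.asarray(coords, dtype=float),
        radii=np.asarray(radii, dtype=float),
    )


class TestReadPdb:
    def test_toy_file_coordinates_verbatim(self, toy_pdb):
        s = read_pdb(toy_pdb)
        assert s.n_atoms == 4
        assert s.coords[2].tolist() == [2.5, 1.0, 0.0]
        assert s.radii[2] == 1.80  # sulfur

    def test_altloc_keeps_a_or_blank(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            _pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C", altloc="A")
            + _pdb_line(2, "CA", "ALA", "A", 1, 9, 9, 9, "C", altloc="B")
            + _pdb_line(3, "CA", "ALA", "A", 2, 3, 0, 0, "C")
            + "END\n"
        )
        s = read_pdb(p)
        assert s.n_atoms == 2
        assert s.coords[0].tolist() == [0.0, 0.0, 0.0]

    def test_atom_filter(self, toy_pdb):
        s = read_pdb(toy_pdb, atom_filter={"CA"})
        assert s.n_atoms == 2 and set(s.atom_names) == {"CA"}

    def test_empty_after_filter_rejected(self, toy_pdb):
        with pytest.raises(StructureError, match="filter"):
            read_pdb(toy_pdb, atom_filter={"FE"})

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureError, match="no such file"):
            read_pdb(tmp_path / "nope.pdb")


class TestKabsch:
    def test_self_superposition_zero_rmsd(self, rng):
        A = np.array([[rng.uniform(-5, 5) for _ in range(3)] for _ in range(8)])
        res = kabsch_superpose(A, A)
        assert res.rmsd < 1e-12

    def test_rigid_motion_invariance(self, rng):
        A = np.array([[rng.uniform(-5, 5) for _ in range(3)] for _ in range(10)])
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        B = A @ R.T + np.array([1.0, -2.0, 3.0])
        res = kabsch_superpose(A, B)
        assert res.rmsd < 1e-8
        assert not res.degenerate

    def test_rotation_orthonormal_det_plus_one(self, rng):
        A = np.array([[rng.uniform(-5, 5) for _ in range(3)] for _ in range(6)])
        B = np.array([[rng.uniform(-5, 5) for _ in range(3)] for _ in range(6)])
        res = kabsch_superpose(A, B)
        R = res.rotation
        assert np.abs(R @ R.T - np.eye(3)).max() < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        A = np.array([[rng.uniform(-5, 5) for _ in range(3)] for _ in range(7)])
        B = np.array([[rng.uniform(-5, 5) for _ in range(3)] for _ in range(7)])
        assert kabsch_superpose(A, B).rmsd == pytest.approx(
            kabsch_superpose(B, A).rmsd, abs=1e-9
        )

    def test_matches_numeric_minimization_oracle(self):
        """RMSD equals brute-force minimization over rotations (random
        starts + local refinement), to 1e-3."""
        A = np.array(
            [[0.0, 0, 0], [2, 0, 0], [0, 3, 0], [0.5, 0.5, 2.5]]
        )
        B = np.array(
            [[0.2, 0.1, 0], [2.1, -0.3, 0.4], [-0.3, 2.8, 0.2], [0.6, 0.4, 2.2]]
        )
        A0 = A - A.mean(axis=0)
        B0 = B - B.mean(axis=0)

        def objective(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sqrt(((A0 @ R.T - B0) ** 2).sum() / len(A))

        rng = np.random.default_rng(0)
        best = np.inf
        for _ in range(50):
            x0 = rng.uniform(-np.pi, np.pi, 3)
            r = minimize(objective, x0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, r.fun)
        assert kabsch_superpose(A, B).rmsd == pytest.approx(best, abs=1e-3)

    def test_collinear_sets_flagged_degenerate(self):
        A = np.array([[float(i), 0, 0] for i in range(4)])
        res = kabsch_superpose(A, A)
        assert res.degenerate

    def test_too_few_atoms(self):
        with pytest.raises(StructureError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestResiduePairDistance:
    def test_three_four_five(self):
        s = _structure([[0, 0, 0], [3, 4, 0]], [1.7, 1.7])
        d = residue_pair_distance(s, ("A", 1), ("A", 2), atom_name="X")
        assert d.distance == pytest.approx(5.0)

    def test_same_atom_zero(self):
        s = _structure([[1, 2, 3]], [1.7])
        d = residue_pair_distance(s, ("A", 1), ("A", 1), atom_name="X")
        assert d.distance == 0.0

    def test_disulfide_fixture(self, tmp_path):
        p = tmp_path / "ss.pdb"
        p.write_text(
            _pdb_line(1, "CA", "CYS", "A", 61, 0, 0, 0, "C")
            + _pdb_line(2, "SG", "CYS", "A", 61, 1, 0, 0, "S")
            + _pdb_line(3, "CA", "CYS", "A", 107, 14, 0, 0, "C")
            + _pdb_line(4, "SG", "CYS", "A", 107, 15.3, 0, 0, "S")
            + "END\n"
        )
        s = read_pdb(p)
        d = residue_pair_distance(s, ("A", 61), ("A", 107))
        assert d.distance == pytest.approx(14.3)
        assert (d.atom_a, d.atom_b) == ("SG", "SG")

    def test_ca_fallback_reported(self, toy_pdb):
        s = read_pdb(toy_pdb)
        d = residue_pair_distance(s, ("A", 61), ("A", 62), atom_name="SG")
        assert d.atom_b == "CA"  # Gly62 has no SG

    def test_missing_atom_error_names_residue(self, toy_pdb):
        s = read_pdb(toy_pdb)
        with pytest.raises(StructureError, match="A:62"):
            residue_pair_distance(s, ("A", 61), ("A", 62), "SG", fallback_atom=None)


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        s = _structure([[0, 0, 0]], [1.7])
        area = shrake_rupley_sasa(s, probe=1.4, n_points=960)[0]
        exact = 4 * np.pi * 3.1**2
        assert abs(area - exact) / exact < 0.01

    def test_separated_atoms_sum_of_spheres(self):
        s = _structure([[0, 0, 0], [100, 0, 0]], [1.7, 1.52])
        areas = shrake_rupley_sasa(s)
        exact = 4 * np.pi * (np.array([1.7, 1.52]) + 1.4) ** 2
        assert np.allclose(areas, exact, rtol=0.01)

    def test_enclosed_atom_has_no_area(self):
        # central atom caged by a dense shell of neighbors
        shell = sphere_points(60) * 2.2
        coords = np.vstack([[0, 0, 0], shell])
        s = _structure(coords, [1.0] + [1.0] * 60)
        areas = shrake_rupley_sasa(s, probe=1.4, n_points=500)
        assert areas[0] == 0.0

    def test_monotone_under_added_neighbor(self):
        lone = _structure([[0, 0, 0]], [1.7])
        paired = _structure([[0, 0, 0], [2.5, 0, 0]], [1.7, 1.7])
        assert shrake_rupley_sasa(paired)[0] <= shrake_rupley_sasa(lone)[0]

    def test_matches_naive_point_count_exactly(self):
        """Culled implementation equals the all-pairs point-in-sphere count."""
        coords = np.array(
            [[0, 0, 0], [2.0, 0.5, 0], [-1.5, 1.0, 0.5], [0.5, -2.0, 1.0]]
        )
        radii = np.array([1.7, 1.52, 1.55, 1.8])
        s = _structure(coords, radii)
        ours = shrake_rupley_sasa(s, probe=1.4, n_points=100)
        oracle = naive_sasa_point_count(coords, radii, 1.4, sphere_points(100))
        assert np.array_equal(ours, oracle)

    def test_invalid_parameters(self):
        s = _structure([[0, 0, 0]], [1.7])
        with pytest.raises(StructureError):
            shrake_rupley_sasa(s, probe=-1)
        with pytest.raises(StructureError):
            shrake_rupley_sasa(s, n_points=10)


class TestRelativeAccessibility:
    def test_fully_exposed_residue_near_100(self):
        s = _structure([[0, 0, 0]], [1.7])
        s.res_names = ["GLY"]
        isolated = float(shrake_rupley_sasa(s)[0])
        rel = relative_accessibility(s, [("A", 1)], reference_max={"GLY": isolated})
        assert rel == pytest.approx(100.0)

    def test_buried_residue_near_zero(self):
        shell = sphere_points(60) * 2.2
        coords = np.vstack([[0, 0, 0], shell])
        s = _structure(coords, [1.0] * 61)
        rel = relative_accessibility(
            s, [("A", 1)], reference_max={"GLY": 104.0}, n_points=500
        )
        assert rel < 1.0

    def test_missing_residue_type_rejected(self):
        s = _structure([[0, 0, 0]], [1.7])
        s.res_names = ["XYZ"]
        with pytest.raises(StructureError, match="XYZ"):
            relative_accessibility(s, [("A", 1)], reference_max={"GLY": 104.0})
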