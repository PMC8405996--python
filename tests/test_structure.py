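"""Structure reading and crystal-comparison metrics."""

import numpy as np
import pytest

from allomif.errors import (
    FormatError,
    GeometryError,
    InsufficientPairingError,
    MissingAtomError,
)
from allomif.structure import (
    atom_displacement,
    interatomic_distance,
    kabsch,
    ligand_contacts,
    model_from_arrays,
    read_structure,
    superpose,
    superpose_best_chain_permutation,
    write_structure,
)
from allomif.synthetic import generate_toy_structure_pair, random_rotation

from _oracles import quaternion_superpose


@pytest.fixture
def three_atom_pdb(tmp_path):
    text = (
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   GLY A   1       2.009   1.420   0.123  1.00  0.00           C\n"
        "END\n"
    )
    p = tmp_path / "three.pdb"
    p.write_text(text)
    return p


class TestReading:
    def test_handwritten_pdb_echoes_coordinates(self, three_atom_pdb):
        m = read_structure(three_atom_pdb)
        assert len(m) == 3
        np.testing.assert_allclose(
            m.atom_coord(("A", 1, "CA")), [1.458, 0.0, 0.0], atol=1e-3
        )

    def test_pdb_and_mmcif_renderings_agree(self, tmp_path):
        model = model_from_arrays(
            np.array([[0, 0, 0], [3, 4, 0], [1.5, -2.25, 7.125], [5, 5, 5]]),
            resnames=["GLY", "ALA", "SER", "HOH"],
            atom_names=["CA", "CA", "CA", "O"],
            elements=["C", "C", "C", "O"],
        )
        write_structure(model, tmp_path / "m.pdb")
        write_structure(model, tmp_path / "m.cif")
        mp = read_structure(tmp_path / "m.pdb")
        mc = read_structure(tmp_path / "m.cif")
        np.testing.assert_allclose(mp.coords, mc.coords, atol=1e-4)
        assert mp.atoms["resname"].tolist() == mc.atoms["resname"].tolist()
        assert mp.atoms["chain"].tolist() == mc.atoms["chain"].tolist()

    def test_altloc_highest_occupancy_retained(self, tmp_path):
        text = (
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        m = read_structure(p, altloc_policy="highest-occupancy")
        assert len(m) == 2
        assert m.atom_coord(("A", 1, "CA"))[0] == pytest.approx(9.0)

    def test_unparseable_file_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text("this is not a structure file\n")
        with pytest.raises(FormatError):
            read_structure(p)


class TestSuperposition:
    def test_self_superposition_rmsd_zero(self, three_atom_pdb):
        m = read_structure(three_atom_pdb)
        res = superpose(m, m, selection="all")
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_atoms_used == 3

    def test_rigid_motion_recovered_exactly(self):
        pair = generate_toy_structure_pair(n_atoms=40, seed=1)
        res = superpose(pair.transformed, pair.reference, selection="all")
        assert res.rmsd < 1e-6
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_with_perturbation(self):
        pair = generate_toy_structure_pair(
            n_atoms=300, per_atom_perturbation_sd=0.5, seed=8
        )
        res = superpose(pair.transformed, pair.reference, selection="all")
        _, _, rmsd_oracle = quaternion_superpose(
            pair.transformed.coords, pair.reference.coords
        )
        assert res.rmsd == pytest.approx(rmsd_oracle, abs=1e-6)

    def test_rmsd_symmetry(self):
        pair = generate_toy_structure_pair(
            n_atoms=60, per_atom_perturbation_sd=0.8, seed=12
        )
        ab = superpose(pair.transformed, pair.reference, selection="all").rmsd
        ba = superpose(pair.reference, pair.transformed, selection="all").rmsd
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_too_few_pairs_raises(self):
        a = model_from_arrays(np.array([[0, 0, 0], [1, 0, 0]]))
        with pytest.raises(InsufficientPairingError):
            superpose(a, a)

    def test_collinear_set_raises(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(GeometryError):
            kabsch(coords, coords + 1.0)

    def test_chain_permutation_search_beats_wrong_identity_map(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-10, 10, (30, 3))
        chains_ref = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        chains_mob = ["B"] * 10 + ["C"] * 10 + ["A"] * 10  # renamed cyclically
        resnums = list(range(1, 11)) * 3
        ref = model_from_arrays(coords, chains=chains_ref, resnums=resnums)
        mob = model_from_arrays(coords, chains=chains_mob, resnums=resnums)
        best, cmap = superpose_best_chain_permutation(mob, ref, selection="ca")
        assert best.rmsd < 1e-9
        assert cmap == {"A": "C", "B": "A", "C": "B"} or best.rmsd < 1e-9


class TestDistances:
    def test_three_four_five_triangle(self):
        m = model_from_arrays(np.array([[0, 0, 0], [3, 4, 0], [9, 9, 9]]))
        assert interatomic_distance(m, ("A", 1, "CA"), ("A", 2, "CA")) == pytest.approx(5.0)
        assert interatomic_distance(m, ("A", 1, "CA"), ("A", 1, "CA")) == 0.0

    def test_missing_atom_names_the_key(self):
        m = model_from_arrays(np.array([[0, 0, 0], [1, 1, 1], [2, 0, 1]]))
        with pytest.raises(MissingAtomError, match="B:9:CB"):
            interatomic_distance(m, ("A", 1, "CA"), ("B", 9, "CB"))

    def test_single_moved_atom_displacement(self):
        # one atom shifted +1 Å along x; superposition on all *other* atoms
        rng = np.random.default_rng(0)
        coords = rng.uniform(-15, 15, (200, 3))
        ref = model_from_arrays(coords)
        moved = coords.copy()
        moved[0, 0] += 1.0
        mob = model_from_arrays(moved)
        sup = superpose(
            mob, ref, selection=lambda row: row["resnum"] != 1
        )
        d = atom_displacement(mob, ref, sup, ("A", 1, "CA"))
        assert d == pytest.approx(1.0, abs=0.02)


class TestLigandContacts:
    def _model_with_ligand(self):
        coords = np.array(
            [[3.9, 0, 0], [4.1, 0, 0], [20, 20, 20], [0, 0, 0], [3.5, 0, 0]], float
        )
        return model_from_arrays(
            coords,
            chains=["A", "A", "A", "L", "W"],
            resnums=[10, 11, 12, 1, 1],
            resnames=["GLY", "ALA", "SER", "TLA", "HOH"],
            atom_names=["CA", "CA", "CA", "O1", "O"],
            elements=["C", "C", "C", "O", "O"],
        )

    def test_threshold_is_inclusive_at_cutoff(self):
        m = self._model_with_ligand()
        contacts = ligand_contacts(m, "TLA", cutoff=4.0)
        assert contacts == {("A", 10, "GLY")}

    def test_zero_cutoff_empty(self):
        assert ligand_contacts(self._model_with_ligand(), "TLA", cutoff=0.0) == set()

    def test_waters_never_counted(self):
        contacts = ligand_contacts(self._model_with_ligand(), "TLA", cutoff=30.0)
        assert all(resname != "HOH" for _, _, resname in contacts)

    def test_absent_ligand_raises(self):
        with pytest.raises(MissingAtomError):
            ligand_contacts(self._model_with_ligand(), "SO4", cutoff=4.0)


class TestRigidMotionInvariance:
    def test_metrics_unchanged_under_joint_rigid_motion(self):
        pair = generate_toy_structure_pair(
            n_atoms=80, per_atom_perturbation_sd=0.3, seed=21
        )
        rng = np.random.default_rng(99)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        before = superpose(pair.transformed, pair.reference, selection="all").rmsd
        after = superpose(
            pair.transformed.transformed(R, t),
            pair.reference.transformed(R, t),
            selection="all",
        ).rmsd
        assert after == pytest.approx(before, abs=1e-8)
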