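import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from conftest import make_model
from loopbind.model_core import (PDBParseError, apply_move, apply_torsion,
                                 backbone_rmsd, parse_selection, read_pdb,
                                 ring_center, write_pdb)

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.176  -4.988  1.00  0.00           C
END
"""


class TestPDBIO:
    def test_three_atom_roundtrip(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(THREE_ATOM_PDB)
        model = read_pdb(path)
        assert len(model) == 3
        out = tmp_path / "out.pdb"
        write_pdb(model, out)
        again = read_pdb(out)
        np.testing.assert_allclose(again.coord, model.coord, atol=5e-4)
        assert list(again.name) == list(model.name)
        assert list(again.res_name) == list(model.res_name)

    def test_chain_roles_from_residue_names(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  C4' U   B   1       5.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "mix.pdb"
        path.write_text(text)
        model = read_pdb(path)
        assert model.chain_roles == {"A": "protein", "B": "RNA"}

    def test_toy_roundtrip_counts_match_manifest(self, tmp_path, toy):
        path = tmp_path / "toy.pdb"
        write_pdb(toy["truth"], path)
        model = read_pdb(path)
        assert len(model) == toy["manifest"]["n_atoms"]
        for chain, count in toy["manifest"]["atoms_per_chain"].items():
            assert int(np.sum(model.chain_id == chain)) == count
        np.testing.assert_allclose(model.coord, toy["truth"].coord, atol=5e-4)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(PDBParseError):
            read_pdb(path)

    def test_malformed_record_names_line(self, tmp_path):
        bad = THREE_ATOM_PDB.replace("11.639", "xx.yyy")
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(path)

    def test_insertion_codes_rejected(self, tmp_path):
        line = list(THREE_ATOM_PDB.splitlines()[0])
        line[26] = "A"
        path = tmp_path / "ins.pdb"
        path.write_text("".join(line) + "\nEND\n")
        with pytest.raises(PDBParseError, match="insertion"):
            read_pdb(path)


class TestRingCenter:
    @staticmethod
    def _phe(offset=(0.0, 0.0, 0.0)):
        ang = np.deg2rad(60.0 * np.arange(6))
        ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)]) + offset
        return make_model(
            ring,
            names=["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
            res_ids=[1] * 6, res_names=["PHE"] * 6,
        )

    def test_unit_hexagon_center_origin(self):
        np.testing.assert_allclose(ring_center(self._phe(), ("A", 1)),
                                   [0, 0, 0], atol=1e-12)

    def test_translation_equivariance(self):
        np.testing.assert_allclose(ring_center(self._phe((1, 2, 3)), ("A", 1)),
                                   [1, 2, 3], atol=1e-12)

    def test_toy_phe_matches_direct_mean(self, toy):
        truth = toy["truth"]
        ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        mask = truth.residue_mask("A", 17) & np.isin(truth.name, ring_names)
        expected = truth.coord[mask].mean(axis=0)
        np.testing.assert_allclose(ring_center(truth, ("A", 17)), expected, atol=1e-12)

    def test_missing_ring_atom_listed(self):
        model = self._phe()
        model = make_model(model.coord[:5], names=list(model.name[:5]),
                           res_ids=[1] * 5, res_names=["PHE"] * 5)
        with pytest.raises(ValueError, match="CZ"):
            ring_center(model, ("A", 1))


def _two_residue_backbone(shift=(0, 0, 0), jitter=None):
    coords = np.array([
        [0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.3, 1.2, 0.0], [2.1, 2.4, 0.3],
        [3.8, 0.9, 0.1], [5.0, 1.5, 0.6], [6.2, 0.7, 0.2], [6.4, -0.5, 0.4],
    ]) + np.asarray(shift, dtype=float)
    if jitter is not None:
        coords = coords + jitter
    return make_model(
        coords,
        names=["N", "CA", "C", "O"] * 2,
        elements=["N", "C", "C", "O"] * 2,
        res_ids=[1] * 4 + [2] * 4,
        res_names=["ALA"] * 8,
    )


class TestBackboneRMSD:
    def test_identical_models_zero(self):
        m = _two_residue_backbone()
        assert backbone_rmsd(m, m) == pytest.approx(0.0, abs=1e-9)

    def test_translation_superpose_flag(self):
        a = _two_residue_backbone()
        b = _two_residue_backbone(shift=(5, 0, 0))
        assert backbone_rmsd(a, b, superpose_first=True) == pytest.approx(0.0, abs=1e-7)
        assert backbone_rmsd(a, b, superpose_first=False) == pytest.approx(5.0, abs=1e-9)

    def test_matches_bruteforce_formula(self):
        rng = np.random.default_rng(7)
        a = _two_residue_backbone()
        b = _two_residue_backbone(jitter=rng.normal(scale=0.3, size=(8, 3)))
        expected = np.sqrt(np.mean(np.sum((a.coord - b.coord) ** 2, axis=1)))
        assert backbone_rmsd(a, b, superpose_first=False) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        a = _two_residue_backbone()
        b = _two_residue_backbone(jitter=rng.normal(scale=0.5, size=(8, 3)))
        assert backbone_rmsd(a, b) == pytest.approx(backbone_rmsd(b, a), rel=1e-9)

    def test_empty_selection_errors(self):
        m = _two_residue_backbone()
        with pytest.raises(ValueError, match="empty"):
            backbone_rmsd(m, m, selection="Z:1-2")


class TestMoves:
    def test_identity_move_is_noop(self, toy):
        moved = apply_move(toy["truth"], toy["partition"], "RRM2")
        np.testing.assert_array_equal(moved.coord, toy["truth"].coord)

    def test_180_rotation_twice_is_involution(self, toy):
        rot = Rotation.from_rotvec([0, 0, np.pi]).as_matrix()
        once = apply_move(toy["truth"], toy["partition"], "RRM2", rotation=rot)
        twice = apply_move(once, toy["partition"], "RRM2", rotation=rot)
        np.testing.assert_allclose(twice.coord, toy["truth"].coord, atol=1e-6)

    def test_rigid_move_preserves_intragroup_distances(self, toy):
        rng = np.random.default_rng(3)
        rot = Rotation.random(random_state=5).as_matrix()
        moved = apply_move(toy["truth"], toy["partition"], "RRM2",
                           rotation=rot, translation=rng.normal(size=3))
        mask = toy["partition"].atom_mask(toy["truth"], "RRM2")
        d_before = pdist(toy["truth"].coord[mask])
        d_after = pdist(moved.coord[mask])
        np.testing.assert_allclose(d_after, d_before, atol=1e-6)
        # atoms outside the group untouched, inter-group distances changed
        np.testing.assert_array_equal(moved.coord[~mask], toy["truth"].coord[~mask])
        assert not np.allclose(moved.coord[mask], toy["truth"].coord[mask])

    def test_improper_rotation_rejected(self, toy):
        with pytest.raises(ValueError, match="proper"):
            apply_move(toy["truth"], toy["partition"], "RRM2", rotation=-np.eye(3))

    def test_torsion_preserves_chain_bond_lengths(self, toy):
        truth, part = toy["truth"], toy["partition"]
        residue = part.flexible[len(part.flexible) // 2]
        moved = apply_torsion(truth, part, residue, 25.0)
        # consecutive CA distances along the protein chain are conserved
        ca = truth.name == "CA"
        order = np.argsort(truth.res_id[ca])
        d0 = np.linalg.norm(np.diff(truth.coord[ca][order], axis=0), axis=1)
        d1 = np.linalg.norm(np.diff(moved.coord[ca][order], axis=0), axis=1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)


def test_selection_minilanguage_forms():
    assert parse_selection("A:5-10") == ("A", 5, 10, None)
    assert parse_selection("B") == ("B", None, None, None)
    assert parse_selection("A:7") == ("A", 7, 7, None)
    assert parse_selection("A:1-3:CA,N") == ("A", 1, 3, ("CA", "N"))
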