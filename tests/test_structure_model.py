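import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rnatopo.fixtures import HelixParams, generate_a_form_helix, rigid_copy
from rnatopo.geometry import RigidTransform
from rnatopo.structure_model import (
    AtomRecord,
    Residue,
    ResidueRepresentation,
    load_representation_config,
    parse_structure,
    residue_triple,
    select_residues,
    write_superposed,
)

MINIMAL_PDB = """\
ATOM      1  OP1   G A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  O5'   G A   1       2.000   0.000   0.000  1.00  0.00           O
ATOM      3  C2'   G A   1       1.000   2.000   0.000  1.00  0.00           C
ATOM      4  C4'   G A   1       3.000   2.000   0.000  1.00  0.00           C
ATOM      5  C3'   G A   1       2.000   3.000   0.000  1.00  0.00           C
ATOM      6  N9    G A   1       1.000   1.000   4.000  1.00  0.00           N
END
"""

MIXED_PDB = MINIMAL_PDB.replace("END\n", "") + """\
ATOM      7  N   ALA B   1       9.000   9.000   9.000  1.00  0.00           N
ATOM      8  CA  ALA B   1      10.000   9.000   9.000  1.00  0.00           C
ATOM      9  C   ALA B   1      11.000   9.000   9.000  1.00  0.00           C
ATOM     10  O   ALA B   1      12.000   9.000   9.000  1.00  0.00           O
END
"""

def _atom_line(serial, name, altloc, resname, chain, seq, x, y, z, occ, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
        f"{seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


ALTLOC_PDB = "\n".join([
    _atom_line(1, " C3'", "A", "G", "A", 1, 0.0, 0.0, 0.0, 0.40, "C"),
    _atom_line(2, " C3'", "B", "G", "A", 1, 5.0, 0.0, 0.0, 0.60, "C"),
    "END",
]) + "\n"


@pytest.fixture
def minimal_model(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(MINIMAL_PDB)
    return parse_structure(p)


class TestParsing:
    def test_minimal_pdb(self, minimal_model):
        assert len(minimal_model) == 1
        (res,) = minimal_model.residues()
        assert res.res_name == "G" and res.chain_id == "A"
        assert {a.name for a in res.atoms} == {"OP1", "O5'", "C2'", "C4'", "C3'", "N9"}

    def test_mmcif_equals_pdb(self, tmp_path, minimal_model):
        cif = tmp_path / "one.cif"
        write_superposed(minimal_model, RigidTransform.identity(), cif, format="mmcif")
        model2 = parse_structure(cif)
        r1, r2 = minimal_model.residues()[0], model2.residues()[0]
        for a1 in r1.atoms:
            a2 = r2.atom(a1.name)
            assert a2 is not None
            assert np.allclose(a1.coord, a2.coord, atol=1e-3)

    def test_protein_chain_excluded(self, tmp_path):
        p = tmp_path / "mixed.pdb"
        p.write_text(MIXED_PDB)
        model = parse_structure(p)
        assert list(model.chains) == ["A"]
        assert len(model) == 1

    def test_zero_nucleic_residues_is_error(self, tmp_path):
        p = tmp_path / "prot.pdb"
        p.write_text("\n".join(MIXED_PDB.splitlines()[6:]) + "\n")
        with pytest.raises(ValueError, match="no nucleic acid"):
            parse_structure(p)

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        model = parse_structure(p)
        (res,) = model.residues()
        assert len(res.atoms) == 1
        assert res.atoms[0].coord[0] == pytest.approx(5.0)

    def test_parse_write_parse_idempotent(self, helix10, tmp_path):
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_superposed(helix10, RigidTransform.identity(), p1)
        m1 = parse_structure(p1)
        write_superposed(m1, RigidTransform.identity(), p2)
        m2 = parse_structure(p2)
        for r1, r2 in zip(m1.residues(), m2.residues()):
            assert r1.res_name == r2.res_name
            for a1 in r1.atoms:
                assert np.allclose(a1.coord, r2.atom(a1.name).coord, atol=1e-3)


class TestSelection:
    def test_no_spec_selects_everything(self, helix10):
        assert len(select_residues(helix10)) == 20

    def test_single_chain(self, helix10):
        res = select_residues(helix10, "A")
        assert len(res) == 10 and all(r.chain_id == "A" for r in res)

    def test_number_range(self, helix10):
        res = select_residues(helix10, "A:5-10")
        assert [r.seq_number for r in res] == [5, 6, 7, 8, 9, 10]

    def test_union_and_composition(self, helix10):
        both = select_residues(helix10, "A:1-3,B")
        assert len(both) == 13
        # selecting chain then range equals selecting "chain:range"
        chain_then_range = [
            r for r in select_residues(helix10, "A") if 1 <= r.seq_number <= 3
        ]
        assert select_residues(helix10, "A:1-3") == chain_then_range

    def test_unknown_chain_raises(self, helix10):
        with pytest.raises(KeyError):
            select_residues(helix10, "Z")

    def test_empty_selection_raises(self, helix10):
        with pytest.raises(ValueError):
            select_residues(helix10, "A:99-100")


def _residue(atoms: dict[str, tuple]) -> Residue:
    return Residue(
        chain_id="A", seq_number=1, insertion_code="", res_name="G",
        atoms=[AtomRecord(n, n[0], np.array(c, dtype=float)) for n, c in atoms.items()],
    )


class TestResidueTriple:
    FULL = {
        "OP1": (0, 0, 0), "O5'": (2, 0, 0), "C2'": (1, 2, 0),
        "C4'": (3, 2, 0), "C3'": (2, 3, 0), "N9": (1, 1, 4),
    }

    def test_phosphate_is_midpoint(self):
        t = residue_triple(_residue(self.FULL))
        assert np.allclose(t.p_point, [1, 0, 0])
        assert np.allclose(t.r_point, [2, 2, 0])

    def test_glycosidic_atom_purine_vs_pyrimidine(self):
        purine = residue_triple(_residue(self.FULL))
        assert np.allclose(purine.b_point, [1, 1, 4])
        atoms = dict(self.FULL)
        atoms["N1"] = atoms.pop("N9")
        pyr = _residue(atoms)
        pyr.res_name = "U"
        assert np.allclose(residue_triple(pyr).b_point, [1, 1, 4])

    def test_five_prime_terminus_yields_no_triple(self):
        atoms = {k: v for k, v in self.FULL.items() if k not in ("OP1", "O5'")}
        assert residue_triple(_residue(atoms)) is None

    def test_missing_c3_yields_no_triple(self):
        atoms = {k: v for k, v in self.FULL.items() if k != "C3'"}
        assert residue_triple(_residue(atoms)) is None

    def test_partial_group_uses_present_atom(self):
        atoms = {k: v for k, v in self.FULL.items() if k != "OP1"}
        t = residue_triple(_residue(atoms))
        assert np.allclose(t.p_point, [2, 0, 0])

    def test_rigid_equivariance(self):
        rng = np.random.default_rng(11)
        R = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3)
        res = _residue(self.FULL)
        moved = _residue({k: R @ np.array(v, dtype=float) + shift
                          for k, v in self.FULL.items()})
        t0, t1 = residue_triple(res), residue_triple(moved)
        assert np.allclose(t1.points, t0.points @ R.T + shift, atol=1e-12)

    def test_modified_residue_maps_to_parent(self):
        res = _residue(self.FULL)
        res.res_name = "7MG"
        t = residue_triple(res)
        assert t is not None and np.allclose(t.b_point, [1, 1, 4])

    def test_unknown_residue_without_recipe(self):
        res = _residue(self.FULL)
        res.res_name = "XXX"
        assert residue_triple(res) is None


class TestRepresentationConfig:
    def test_parent_and_recipe_lines(self, tmp_path):
        cfg = tmp_path / "repr.cfg"
        cfg.write_text(
            "# custom\nXYZ = parent G\nQQQ = OP1,O5' | C2',C4' | N1\n"
        )
        repr_ = load_representation_config(cfg)
        assert repr_.recipe_for("XYZ") == repr_.recipes["G"]
        assert repr_.recipe_for("QQQ") == (["OP1", "O5'"], ["C2'", "C4'"], ["N1"])

    def test_default_covers_standard_nucleotides(self):
        repr_ = ResidueRepresentation()
        for name in ("A", "G", "C", "U", "T", "DA", "DG", "DC", "DT"):
            assert repr_.is_nucleic(name)
        assert not repr_.is_nucleic("ALA")


class TestWriteSuperposed:
    def test_pure_translation(self, helix10, tmp_path):
        t = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
        out = tmp_path / "t.pdb"
        write_superposed(helix10, t, out)
        moved = parse_structure(out)
        for r0, r1 in zip(helix10.residues(), moved.residues()):
            for a0 in r0.atoms:
                assert np.allclose(
                    r1.atom(a0.name).coord, a0.coord + [1, 2, 3], atol=1e-3
                )

    def test_rotation_round_trip(self, helix10, tmp_path):
        R = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        t = RigidTransform(R, np.zeros(3))
        out = tmp_path / "r.pdb"
        write_superposed(helix10, t, out)
        moved = parse_structure(out)
        for r0, r1 in zip(helix10.residues(), moved.residues()):
            for a0 in r0.atoms:
                assert np.allclose(r1.atom(a0.name).coord, R @ a0.coord, atol=1e-3)

    def test_inverse_recovers_input(self, helix10, tmp_path):
        rng = np.random.default_rng(13)
        t = RigidTransform(Rotation.random(rng=rng).as_matrix(), rng.normal(size=3))
        out = tmp_path / "fwd.pdb"
        write_superposed(helix10, t, out)
        back = parse_structure(out)
        inv = t.inverse()
        for r0, r1 in zip(helix10.residues(), back.residues()):
            for a0 in r0.atoms:
                assert np.allclose(
                    inv.apply(r1.atom(a0.name).coord), a0.coord, atol=1e-3
                )

    def test_save_selection_restricts_output(self, helix10, tmp_path):
        out = tmp_path / "sel.pdb"
        write_superposed(helix10, RigidTransform.identity(), out,
                         save_selection="A:1-3")
        assert len(parse_structure(out)) == 3
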