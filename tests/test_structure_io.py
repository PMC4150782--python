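import warnings

import numpy as np
import pytest

from hydrna.structure_io import (
    ChainModel,
    FilterError,
    Residue,
    apply_length_filters,
    classify_chain,
    parse_structure,
    write_pdb,
)
from hydrna.synthetic import GeneratorSpec, make_complex

from conftest import make_atom


def _atom_line(serial, name, res, chain, seq, x, y, z, occ=1.0, rec="ATOM  ",
               alt=" ", element=None):
    element = element or name.strip()[0]
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (f"{rec}{serial:5d} {padded}{alt}{res:>3s} {chain}{seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}")


class TestParse:
    def test_empty_input_gives_empty_model(self):
        model = parse_structure("END\n")
        assert model.chains == [] and model.waters == []

    def test_modified_residue_renamed_to_parent_and_kept_as_polymer(self):
        lines = [_atom_line(i + 1, n, "PSU", "B", 1, *xyz) for i, (n, xyz) in
                 enumerate([("N1", (0, 0, 0)), ("C2", (1.4, 0, 0)),
                            ("O2'", (2.0, 1.0, 0))])]
        model = parse_structure("\n".join(lines) + "\nEND\n",
                                residue_map={"PSU": "U"})
        assert len(model.nucleic_side) == 1
        res = model.nucleic_side[0].residues[0]
        assert res.res_name == "U"
        assert all(not a.is_hetero for a in res.atoms)

    def test_counts_match_line_scanning_oracle(self, bridging_complex):
        pdb, _, model, _ = bridging_complex
        # independent flat line scan of the same text
        n_hoh = sum(1 for l in pdb.splitlines()
                    if l.startswith(("ATOM", "HETATM")) and l[17:20].strip() == "HOH")
        chains = {l[21] for l in pdb.splitlines()
                  if l.startswith("ATOM") and l[17:20].strip() != "HOH"}
        n_atoms = sum(1 for l in pdb.splitlines()
                      if l.startswith(("ATOM", "HETATM")) and l[17:20].strip() != "HOH")
        assert len(model.waters) == n_hoh
        assert {c.chain_id for c in model.chains} == chains
        assert sum(1 for _ in model.polymer_atoms()) == n_atoms

    def test_malformed_coordinates_raise_with_line_number(self):
        bad = _atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0).replace("   0.000", "  xx.000", 1)
        with pytest.raises(ValueError, match="line 1"):
            parse_structure(bad)

    def test_only_first_model_is_read(self):
        text = "\n".join([
            "MODEL        1",
            _atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0),
            "ENDMDL",
            "MODEL        2",
            _atom_line(2, "CA", "ALA", "A", 1, 9, 9, 9),
            "ENDMDL", "END"])
        model = parse_structure(text)
        atoms = list(model.polymer_atoms())
        assert len(atoms) == 1 and atoms[0].xyz[0] == 0.0


class TestAltlocs:
    def test_highest_occupancy_wins_and_count_never_increases(self):
        text = "\n".join([
            _atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, occ=0.3, alt="A"),
            _atom_line(2, "CA", "ALA", "A", 1, 5, 0, 0, occ=0.7, alt="B"),
            _atom_line(3, "CB", "ALA", "A", 1, 1, 1, 1, occ=0.5, alt="A"),
            _atom_line(4, "CB", "ALA", "A", 1, 2, 2, 2, occ=0.5, alt="B"),
            "END"])
        model = parse_structure(text)
        atoms = list(model.polymer_atoms())
        assert len(atoms) == 2
        ca = next(a for a in atoms if a.name == "CA")
        cb = next(a for a in atoms if a.name == "CB")
        assert ca.xyz[0] == 5.0          # higher occupancy
        assert cb.xyz[0] == 1.0          # tie -> first in file
        # exactly one atom per (chain, res_seq, name)
        keys = [(a.chain_id, a.res_seq, a.name) for a in atoms]
        assert len(keys) == len(set(keys))


class TestRoundTrip:
    def test_write_then_reparse_is_identical(self, bridging_complex):
        _, _, model, _ = bridging_complex
        text = write_pdb(model)
        model2 = parse_structure(text)
        a1 = list(model.polymer_atoms()) + list(model.waters)
        a2 = list(model2.polymer_atoms()) + list(model2.waters)
        assert len(a1) == len(a2)
        for x, y in zip(a1, a2):
            assert x.name == y.name and x.res_name == y.res_name
            assert np.allclose(x.xyz, y.xyz, atol=1.5e-3)

    def test_generator_output_reparses_without_warnings(self):
        pdb, _ = make_complex(GeneratorSpec(seed=3, n_waters=6, n_bridging_planted=3))
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            model = parse_structure(pdb)
        assert model.protein_side and model.nucleic_side


class TestClassify:
    def _chain(self, res_names, with_o2p=False):
        ch = ChainModel("X", "other")
        for i, rn in enumerate(res_names, start=1):
            atoms = [make_atom("CA" if len(rn) == 3 else "C1'", "C", rn, "X", i,
                               (float(i), 0, 0))]
            if with_o2p:
                atoms.append(make_atom("O2'", "O", rn, "X", i, (float(i), 1, 0)))
            ch.residues.append(Residue(rn, i, "", atoms))
        return ch

    def test_protein_rna_dna_other(self):
        assert classify_chain(self._chain(["ALA"] * 30)) == "protein"
        assert classify_chain(self._chain(list("GCAUU"), with_o2p=True)) == "RNA"
        assert classify_chain(self._chain(["DA", "DT"] * 3)) == "DNA"
        assert classify_chain(self._chain(["XXX"] * 4)) == "other"

    def test_invariant_to_residue_order(self):
        import random
        names = ["ALA"] * 25 + ["XXX"] * 3
        rng = random.Random(0)
        for _ in range(5):
            rng.shuffle(names)
            assert classify_chain(self._chain(names)) == "protein"


class TestLengthFilters:
    def _model(self, n_aa, n_nt):
        from hydrna.structure_io import ComplexModel
        prot = ChainModel("A", "protein",
                          [Residue("ALA", i, "", [make_atom("CA", "C", "ALA", "A", i)])
                           for i in range(1, n_aa + 1)])
        rna = ChainModel("B", "RNA",
                         [Residue("A", i, "", [make_atom("C1'", "C", "A", "B", i)])
                          for i in range(1, n_nt + 1)])
        return ComplexModel(protein_side=[prot], nucleic_side=[rna])

    def test_boundaries(self):
        kept = apply_length_filters(self._model(30, 5))
        assert len(kept.protein_side[0]) == 30 and len(kept.nucleic_side[0]) == 5
        with pytest.raises(FilterError, match="protein"):
            apply_length_filters(self._model(29, 5))
        with pytest.raises(FilterError, match="nucleic"):
            apply_length_filters(self._model(100, 4))


class TestGemmiCrossCheck:
    def test_atom_count_and_coordinates_agree_with_gemmi(self, bridging_complex):
        gemmi = pytest.importorskip("gemmi")
        pdb, _, model, _ = bridging_complex
        st = gemmi.read_pdb_string(pdb)
        g_atoms = [(a.name, cra.residue.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                   for cra in st[0].all() for a in [cra.atom]]
        ours = list(model.polymer_atoms()) + list(model.waters)
        assert len(ours) == len(g_atoms)
        ours_sorted = sorted(ours, key=lambda a: a.serial)
        for mine, (gname, gres, gxyz) in zip(ours_sorted, g_atoms):
            assert mine.name == gname.strip() or mine.name == gname
            assert np.allclose(mine.xyz, gxyz, atol=1e-3)
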