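import itertools

import numpy as np
import pytest

from hydrna.hbond import (
    DEFAULT_SCHEMA,
    HBondCriteria,
    classify_endpoint,
    detect_hbonds,
    detect_wc_pairs,
    groove_of,
    polar_template,
)
from hydrna.structure_io import ChainModel, ComplexModel, Residue, parse_structure
from hydrna.synthetic import GeneratorSpec, make_complex

from conftest import make_atom


def brute_force_hbonds(model, criteria=HBondCriteria()):
    """Independent O(n^2) enumeration of donor/acceptor pairs under the
    hydrogen-free distance rule (no spatial index, no symmetry tricks)."""
    entries = []
    for ch in model.chains:
        for res in ch.residues:
            tmpl = polar_template(res.res_name)
            if tmpl is None:
                continue
            donors, acceptors = tmpl
            for a in res.atoms:
                if a.is_hydrogen:
                    continue
                entries.append((a, a.name in donors, a.name in acceptors))
    for w in model.waters:
        entries.append((w, True, True))
    found = set()
    for (a, da, ca), (b, db, cb) in itertools.combinations(entries, 2):
        if a.res_key == b.res_key:
            continue
        d = float(np.linalg.norm(a.xyz - b.xyz))
        if criteria.d_min <= d <= criteria.d_max and ((da and cb) or (db and ca)):
            found.add(frozenset({a.atom_key, b.atom_key}))
    return found


class TestDetection:
    def test_outside_window_no_bond(self):
        model = ComplexModel(waters=[make_atom("O", "O", "HOH", "W", 1, (0, 0, 0)),
                                     make_atom("O", "O", "HOH", "W", 2, (5.0, 0, 0))])
        assert detect_hbonds(model) == []

    def test_water_to_ribose_hydroxyl(self):
        rna = ChainModel("B", "RNA", [Residue("A", 1, "", [
            make_atom("O2'", "O", "A", "B", 1, (0, 0, 0))])])
        model = ComplexModel(nucleic_side=[rna],
                             waters=[make_atom("O", "O", "HOH", "W", 1, (2.8, 0, 0))])
        bonds = detect_hbonds(model)
        assert len(bonds) == 1
        assert bonds[0].kinds == frozenset({"water", "nucleic"})
        assert bonds[0].da_distance == pytest.approx(2.8)

    def test_same_residue_and_steric_floor_excluded(self):
        rna = ChainModel("B", "RNA", [Residue("G", 1, "", [
            make_atom("O2'", "O", "G", "B", 1, (0, 0, 0)),
            make_atom("O3'", "O", "G", "B", 1, (3.0, 0, 0))])])
        model = ComplexModel(nucleic_side=[rna],
                             waters=[make_atom("O", "O", "HOH", "W", 1, (0, 2.2, 0))])
        bonds = detect_hbonds(model)
        # O2'-O3' same residue; water at 2.2 below the 2.4 steric floor
        assert bonds == []

    def test_matches_exhaustive_enumeration_on_generated_complex(self, bridging_complex):
        _, _, model, bundle = bridging_complex
        ours = {frozenset({r.donor.atom_key, r.acceptor.atom_key})
                for r in bundle.hbonds}
        assert ours == brute_force_hbonds(model)

    def test_angular_criteria_with_explicit_hydrogen(self):
        # donor N with H pointing at the acceptor: bond at 3.7 A (beyond the
        # hydrogen-free 3.5 limit but inside the with-H 3.9 limit)
        prot = ChainModel("A", "protein", [Residue("ALA", 1, "", [
            make_atom("N", "N", "ALA", "A", 1, (0, 0, 0)),
            make_atom("H", "H", "ALA", "A", 1, (1.0, 0, 0)),
            make_atom("CA", "C", "ALA", "A", 1, (-0.8, 1.2, 0))])])
        acc = ChainModel("B", "RNA", [Residue("U", 2, "", [
            make_atom("O4", "O", "U", "B", 2, (3.4, 0, 0))])])
        model = ComplexModel(protein_side=[prot], nucleic_side=[acc])
        bonds = detect_hbonds(model)
        assert len(bonds) == 1 and bonds[0].dha_angle == pytest.approx(180.0, abs=1e-6)
        # H pointing away: same distance, no bond
        prot.residues[0].atoms[1] = make_atom("H", "H", "ALA", "A", 1, (-1.0, 0, 0))
        assert detect_hbonds(model) == []


class TestEndpointChemistry:
    @pytest.mark.parametrize("res,name,expected", [
        ("ARG", "NH1", "charged_side"),
        ("LYS", "NZ", "charged_side"),
        ("ASP", "OD1", "charged_side"),
        ("ASN", "ND2", "neutral_side"),
        ("SER", "OG", "neutral_side"),
        ("MET", "SD", "neutral_side"),
        ("GLY", "O", "main_chain_O"),
        ("TRP", "N", "main_chain_N"),
        ("A", "O5'", "sugar"),
        ("U", "O2'", "sugar"),
        ("G", "O1P", "phosphate"),
        ("C", "P", "phosphate"),
        ("G", "O6", "base"),
        ("DT", "O4", "base"),
    ])
    def test_group_labels(self, res, name, expected):
        atom = make_atom(name, name[0], res, "X", 1)
        assert classify_endpoint(atom) == expected

    def test_unknown_polar_atom_warns_and_returns_other(self):
        atom = make_atom("OXX", "O", "ALA", "X", 1)
        with pytest.warns(UserWarning):
            assert classify_endpoint(atom) == "other"

    def test_nucleic_polar_atoms_partition_into_three_groups(self, bridging_complex):
        _, _, model, _ = bridging_complex
        import warnings
        for ch in model.nucleic_side:
            for res in ch.residues:
                donors, acceptors = polar_template(res.res_name)
                for a in res.atoms:
                    if a.name in donors | acceptors:
                        with warnings.catch_warnings():
                            warnings.simplefilter("error")
                            label = classify_endpoint(a)
                        assert label in ("phosphate", "sugar", "base")


class TestWatsonCrick:
    def test_single_strand_has_no_pairs(self):
        pdb, _ = make_complex(GeneratorSpec(
            seed=2, rna_form="single_strand", n_waters=4, n_bridging_planted=2))
        model = parse_structure(pdb)
        assert detect_wc_pairs(model.nucleic_side) == []

    def test_ideal_duplex_pairs_every_base(self, bridging_complex):
        _, _, model, bundle = bridging_complex
        n_nt = len(model.nucleic_side[0])
        assert len(bundle.wc_pairs) == n_nt
        # each base in at most one pair
        keys = [k for bp in bundle.wc_pairs for k in bp.member_keys()]
        assert len(keys) == len(set(keys))

    def test_gu_at_pairing_distance_is_not_wc(self):
        g = Residue("G", 1, "", [make_atom("N1", "N", "G", "B", 1, (0, 0, 0))])
        u = Residue("U", 2, "", [make_atom("N3", "N", "U", "C", 2, (2.9, 0, 0)),
                                 make_atom("O2", "O", "U", "C", 2, (2.9, 1.2, 0))])
        chains = [ChainModel("B", "RNA", [g]), ChainModel("C", "RNA", [u])]
        assert detect_wc_pairs(chains) == []
        # the wobble flag accepts it via the N1(G)-O2(U) contact
        wob = detect_wc_pairs(chains, include_wobble=True)
        assert len(wob) == 1


class TestGrooves:
    def test_major_minor_and_unpaired(self, bridging_complex):
        _, _, model, bundle = bridging_complex
        pairs = bundle.wc_pairs
        byname = {}
        for ch in model.nucleic_side:
            for res in ch.residues:
                for a in res.atoms:
                    byname.setdefault((res.res_name, a.name), a)
        assert groove_of(byname[("G", "N7")], pairs) == "major"
        assert groove_of(byname[("C", "O2")], pairs) == "minor"
        assert groove_of(byname[("G", "O2'")], pairs) == "none"
        # an unpaired base gets no groove label even for groove atoms
        lone = make_atom("N3", "N", "A", "Z", 99)
        assert groove_of(lone, pairs) == "none"

    def test_major_minor_atom_sets_disjoint(self):
        s = DEFAULT_SCHEMA
        assert not (s.major_purine & s.minor_purine)
        assert not (s.major_pyrimidine & s.minor_pyrimidine)
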