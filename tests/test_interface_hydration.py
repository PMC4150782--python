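import math

import numpy as np
import pytest
from scipy import stats as sps

from hydrna.hbond import HBondRecord
from hydrna.interface_hydration import (
    build_water_profiles,
    chemistry_table,
    compute_dr,
    density_per_1000,
    groove_hydration,
    hydration_summary,
    hydroxyl_stats,
    multiplicity_histogram,
    one_way_anova,
    select_interface_waters,
    ss_hydration,
    two_tailed_ttest,
)
from hydrna.sasa import InterfaceModel
from hydrna.structure_io import ChainModel, ComplexModel, Residue
import hydrna.interface_hydration as ih

from conftest import make_atom


def _iface(atoms, centroid=None, B=1000.0):
    if centroid is None:
        centroid = np.mean([a.xyz for a in atoms], axis=0)
    prot = [a for a in atoms if a.res_name not in ("A", "C", "G", "U")]
    nuc = [a for a in atoms if a.res_name in ("A", "C", "G", "U")]
    return InterfaceModel(B=B, protein_interface_atoms=prot,
                          nucleic_interface_atoms=nuc,
                          f_np_protein=0.5, f_np_nucleic=0.3,
                          centroid=np.asarray(centroid, dtype=float),
                          per_atom_loss={a.atom_key: 1.0 for a in atoms})


def _hb(donor, acceptor, d=2.8, dkind="water", akind="protein", certain=True):
    return HBondRecord(donor=donor, acceptor=acceptor, da_distance=d,
                       dha_angle=None, donor_kind=dkind, acceptor_kind=akind,
                       donor_is_certain=certain)


class TestWaterSelection:
    def _model_and_iface(self):
        pa = make_atom("O", "O", "ALA", "A", 1, (0, 0, 0))
        na = make_atom("O2'", "O", "A", "B", 1, (8.0, 0, 0))
        prot = ChainModel("A", "protein", [Residue("ALA", 1, "", [pa])])
        nuc = ChainModel("B", "RNA", [Residue("A", 1, "", [na])])
        model = ComplexModel(protein_side=[prot], nucleic_side=[nuc])
        return model, _iface([pa, na])

    def test_far_water_excluded(self):
        model, iface = self._model_and_iface()
        model.waters = [make_atom("O", "O", "HOH", "W", 1, (4.0, 50.0, 0))]
        assert select_interface_waters(model, iface) == []

    def test_boundary_water_included(self):
        model, iface = self._model_and_iface()
        model.waters = [make_atom("O", "O", "HOH", "W", 1, (4.0, math.sqrt(4.4**2 - 4.0**2), 0))]
        # 4.4 A from the protein atom, 4.4+ from nucleic? compute: place between
        model.waters = [make_atom("O", "O", "HOH", "W", 1, (4.0, 0, 0))]
        # 4.0 from protein, 4.0 from nucleic at x=8
        assert len(select_interface_waters(model, iface, cutoff=4.5)) == 1

    def test_one_sided_water_excluded(self):
        model, iface = self._model_and_iface()
        model.waters = [make_atom("O", "O", "HOH", "W", 1, (-3.0, 0, 0))]
        # 3.0 from protein side but 11.0 from the nucleic atom
        assert select_interface_waters(model, iface, cutoff=4.5) == []

    def test_any_atom_rule_is_more_permissive(self):
        model, iface = self._model_and_iface()
        # shrink the interface-atom set to the protein atom only
        iface.nucleic_interface_atoms = []
        model.waters = [make_atom("O", "O", "HOH", "W", 1, (4.0, 0, 0))]
        assert select_interface_waters(model, iface, rule="interface_atoms") == []
        assert len(select_interface_waters(model, iface, rule="any_atom")) == 1

    def test_count_nondecreasing_in_cutoff(self, bridging_complex):
        _, _, model, bundle = bridging_complex
        counts = [len(select_interface_waters(model, bundle.iface, cutoff=c))
                  for c in (3.0, 3.5, 4.0, 4.5, 5.0)]
        assert counts == sorted(counts)


class TestProfiles:
    def test_no_bonds_water(self):
        w = make_atom("O", "O", "HOH", "W", 1)
        profs = build_water_profiles([w], [])
        assert (profs[0].n_hb_protein, profs[0].n_hb_nucleic, profs[0].n_hb_water) == (0, 0, 0)
        assert not profs[0].is_bridging

    def test_main_chain_O_plus_ribose_makes_bridging(self):
        w = make_atom("O", "O", "HOH", "W", 1)
        o = make_atom("O", "O", "GLY", "A", 2)
        o2p = make_atom("O2'", "O", "A", "B", 3)
        bonds = [_hb(w, o, akind="protein"), _hb(w, o2p, akind="nucleic")]
        prof = build_water_profiles([w], bonds)[0]
        assert prof.is_bridging and prof.n_hb_protein == 1 and prof.n_hb_nucleic == 1

    def test_planted_bridging_recovered_exactly(self, bridging_complex):
        _, truth, _, bundle = bridging_complex
        assert sum(p.is_bridging for p in bundle.profiles) == truth["n_bridging"]

    def test_bridging_subset_of_interface(self, bridging_complex):
        _, _, _, bundle = bridging_complex
        iface_keys = {w.atom_key for w in bundle.interface_waters}
        for p in bundle.profiles:
            if p.is_bridging:
                assert p.water.atom_key in iface_keys

    def test_histogram_zero_bin_and_cap(self):
        w1 = make_atom("O", "O", "HOH", "W", 1)
        w2 = make_atom("O", "O", "HOH", "W", 2)
        na = make_atom("O2'", "O", "A", "B", 1)
        pa = make_atom("O", "O", "GLY", "A", 1)
        bonds = [_hb(w1, na, akind="nucleic")] + \
            [_hb(w2, make_atom("O", "O", "GLY", "A", 10 + i), akind="protein")
             for i in range(6)]
        profs = build_water_profiles([w1, w2], bonds)
        hist_p = multiplicity_histogram(profs, "protein")
        # w1: zero to protein but bonded to RNA -> zero bin; w2: 6 capped at 4
        assert hist_p[0] == 1 and hist_p[4] == 1
        assert max(p.n_hb_protein for p in profs) == 6   # raw count retained


class TestDr:
    def test_waters_at_centroid(self):
        atoms = [make_atom("CA", "C", "ALA", "A", i, (10 * math.cos(t), 10 * math.sin(t), 0))
                 for i, t in enumerate(np.linspace(0, 2 * math.pi, 8, endpoint=False), 1)]
        iface = _iface(atoms, centroid=(0, 0, 0))
        w = [make_atom("O", "O", "HOH", "W", 1, (0, 0, 0))]
        d_r, wet = compute_dr(w, iface)
        assert d_r == pytest.approx(0.0) and wet

    def test_waters_at_atom_positions_give_unity(self):
        atoms = [make_atom("CA", "C", "ALA", "A", i, (float(i), 2.0, 0)) for i in range(1, 6)]
        iface = _iface(atoms)
        waters = [make_atom("O", "O", "HOH", "W", i, tuple(a.xyz)) for i, a in enumerate(atoms, 1)]
        d_r, wet = compute_dr(waters, iface)
        assert d_r == pytest.approx(1.0) and wet

    def test_ring_construction_gives_exact_ratio(self):
        ts = np.linspace(0, 2 * math.pi, 12, endpoint=False)
        atoms = [make_atom("CA", "C", "ALA", "A", i, (10 * math.cos(t), 10 * math.sin(t), 0))
                 for i, t in enumerate(ts, 1)]
        iface = _iface(atoms, centroid=(0, 0, 0))
        waters = [make_atom("O", "O", "HOH", "W", i, (12 * math.cos(t), 12 * math.sin(t), 0))
                  for i, t in enumerate(ts, 1)]
        d_r, wet = compute_dr(waters, iface)
        assert d_r == pytest.approx(1.2, rel=1e-12)
        assert not wet

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=6.0, size=(10, 3))
        wpts = rng.normal(scale=7.0, size=(5, 3))
        atoms = [make_atom("CA", "C", "ALA", "A", i, p) for i, p in enumerate(pts, 1)]
        waters = [make_atom("O", "O", "HOH", "W", i, p) for i, p in enumerate(wpts, 1)]
        d1, _ = compute_dr(waters, _iface(atoms))
        atoms2 = [make_atom("CA", "C", "ALA", "A", i, 3.7 * p) for i, p in enumerate(pts, 1)]
        waters2 = [make_atom("O", "O", "HOH", "W", i, 3.7 * p) for i, p in enumerate(wpts, 1)]
        d2, _ = compute_dr(waters2, _iface(atoms2))
        assert d2 == pytest.approx(d1, rel=1e-9)

    def test_no_waters_is_absent(self):
        atoms = [make_atom("CA", "C", "ALA", "A", 1)]
        assert compute_dr([], _iface(atoms)) == (None, None)


class TestDensities:
    def test_density_formula_and_report_rounding(self):
        # 27 interface waters on a 2460 A^2 interface -> 11.0 per 1000 A^2;
        # 39 on 4185 -> 9.3 (the tRNA-class value)
        assert round(density_per_1000(27, 2460.0), 1) == 11.0
        assert round(density_per_1000(39, 4185.0), 1) == 9.3
        assert density_per_1000(5, 0.0) is None

    def test_summary_row_consistency(self, bridging_complex):
        _, truth, _, bundle = bridging_complex
        s = bundle.summary
        assert s.n_interface_waters == truth["n_interface_waters"]
        assert s.n_bridging == truth["n_bridging"]
        assert s.n_bridging <= s.n_interface_waters
        assert s.water_density == pytest.approx(1000 * s.n_interface_waters / s.B)
        assert s.wm_hbond_density == pytest.approx(1000 * s.n_wm_hbonds / s.B)
        assert s.wet == (s.d_r <= 1.0)

    def test_zero_waters_give_zero_densities(self):
        pa = make_atom("O", "O", "ALA", "A", 1, (0, 0, 0))
        na = make_atom("O2'", "O", "A", "B", 1, (3.0, 0, 0))
        prot = ChainModel("A", "protein", [Residue("ALA", 1, "", [pa])])
        nuc = ChainModel("B", "RNA", [Residue("A", 1, "", [na])])
        model = ComplexModel(protein_side=[prot], nucleic_side=[nuc], source_id="t")
        iface = _iface([pa, na], B=500.0)
        s = hydration_summary(model, iface, [], [])
        assert s.n_interface_waters == 0 and s.water_density == 0.0


class TestChemistryTables:
    def test_empty_set_all_zero(self):
        out = chemistry_table([], [])
        assert out["water_mediated"]["total"] == 0
        assert all(v == 0 for v in out["water_mediated"]["protein_group_counts"].values())

    def test_hand_tally_of_ten_bonds(self):
        w = make_atom("O", "O", "HOH", "W", 1)
        mk = make_atom
        bonds = [
            _hb(w, mk("O", "O", "GLY", "A", 1), akind="protein"),      # main O
            _hb(w, mk("O", "O", "ALA", "A", 2), akind="protein"),      # main O
            _hb(mk("N", "N", "ALA", "A", 3), w, dkind="protein", akind="water"),  # main N
            _hb(mk("NH1", "N", "ARG", "A", 4), w, dkind="protein", akind="water"),  # charged
            _hb(w, mk("OD1", "O", "ASP", "A", 5), akind="protein"),    # charged
            _hb(w, mk("OG", "O", "SER", "A", 6), akind="protein"),     # neutral
            _hb(w, mk("O1P", "O", "G", "B", 1), akind="nucleic"),      # phosphate
            _hb(w, mk("O2'", "O", "G", "B", 2), akind="nucleic"),      # sugar
            _hb(w, mk("O4'", "O", "A", "B", 3), akind="nucleic"),      # sugar
            _hb(w, mk("O6", "O", "G", "B", 4), akind="nucleic"),       # base (G)
        ]
        out = chemistry_table(bonds, [])["water_mediated"]
        assert out["total"] == 10
        assert out["with_protein"] == 6 and out["with_nucleic"] == 4
        assert out["protein_group_counts"] == {
            "main_chain_O": 2, "main_chain_N": 1, "charged_side": 2, "neutral_side": 1}
        assert out["nucleic_group_counts"] == {"phosphate": 1, "sugar": 2, "base": 1}
        assert out["base_identity_counts"]["guanine"] == 1
        assert out["nucleic_group_pct"]["sugar"] == pytest.approx(50.0)

    def test_group_percentages_sum_to_100(self, bridging_complex):
        _, _, _, bundle = bridging_complex
        wm = bundle.chemistry["water_mediated"]
        if wm["with_nucleic"]:
            assert sum(wm["nucleic_group_pct"].values()) == pytest.approx(100.0)
        if wm["with_protein"]:
            assert sum(wm["protein_group_pct"].values()) == pytest.approx(100.0)


class TestHydroxyl:
    def test_counts_and_percentages(self):
        w = make_atom("O", "O", "HOH", "W", 1)
        mk = make_atom
        wm = [_hb(w, mk("O2'", "O", "G", "B", 1), akind="nucleic"),
              _hb(w, mk("O2'", "O", "A", "B", 2), akind="nucleic"),
              _hb(w, mk("O3'", "O", "A", "B", 3), akind="nucleic"),
              _hb(w, mk("O1P", "O", "A", "B", 4), akind="nucleic")]
        out = hydroxyl_stats(wm, [])["water_mediated"]
        assert out["overall"] == 4 and out["with_ribose"] == 3 and out["with_2OH"] == 2
        assert out["pct_of_all"] == pytest.approx(50.0)
        assert out["pct_within_sugar"] == pytest.approx(200.0 / 3.0)

    def test_dna_has_no_2oh(self):
        w = make_atom("O", "O", "HOH", "W", 1)
        wm = [_hb(w, make_atom("O3'", "O", "DT", "B", 1), akind="nucleic")]
        out = hydroxyl_stats(wm, [])["water_mediated"]
        assert out["with_2OH"] == 0 and out["pct_within_sugar"] == 0.0

    def test_planted_2oh_contacts_counted(self, bridging_complex):
        _, truth, _, bundle = bridging_complex
        planted_o2p = sum(1 for w in truth["water_partners"]
                          for key in w["nucleic"] if key[3] == "O2'")
        out = bundle.hydroxyl["water_mediated"]
        assert out["with_2OH"] == planted_o2p


class TestSSHydration:
    def _records(self, chain_id, res_seqs):
        w = make_atom("O", "O", "HOH", "W", 1)
        return [_hb(w, make_atom("O", "O", "ALA", chain_id, s), akind="protein")
                for s in res_seqs]

    def _residue_ss(self, classes):
        from hydrna.secstruct import ResidueSS
        out = []
        for i, cls in enumerate(classes, 1):
            label = {"helices": "H", "strands": "E", "other": "-"}[cls]
            out.append(ResidueSS(Residue("ALA", i, "", []), "A", label, cls))
        return out

    def test_equal_area_split_preserves_bond_ratio(self):
        # residues 1-2 helical, 3-4 strand; equal ASA loss; bonds 2:1
        atoms = [make_atom("O", "O", "ALA", "A", i) for i in range(1, 5)]
        iface = InterfaceModel(B=400.0, protein_interface_atoms=atoms,
                               nucleic_interface_atoms=[], f_np_protein=0.5,
                               f_np_nucleic=0.3, centroid=np.zeros(3),
                               per_atom_loss={a.atom_key: 100.0 for a in atoms})
        ss = self._residue_ss(["helices", "helices", "strands", "strands"])
        wm = self._records("A", [1, 2, 1, 2]) + self._records("A", [3, 4])
        out = ss_hydration(wm, [], ss, iface)
        assert out["water_mediated"]["helices"] == pytest.approx(
            2.0 * out["water_mediated"]["strands"])

    def test_class_without_buried_area_is_absent(self):
        atoms = [make_atom("O", "O", "ALA", "A", 1)]
        iface = InterfaceModel(B=100.0, protein_interface_atoms=atoms,
                               nucleic_interface_atoms=[], f_np_protein=0.5,
                               f_np_nucleic=0.3, centroid=np.zeros(3),
                               per_atom_loss={atoms[0].atom_key: 100.0})
        ss = self._residue_ss(["helices"])
        out = ss_hydration(self._records("A", [1]), [], ss, iface)
        assert out["water_mediated"]["strands"] is None
        assert out["water_mediated"]["helices"] == pytest.approx(10.0)

    def test_empty_bonds_zero_density(self):
        atoms = [make_atom("O", "O", "ALA", "A", 1)]
        iface = InterfaceModel(B=100.0, protein_interface_atoms=atoms,
                               nucleic_interface_atoms=[], f_np_protein=0.5,
                               f_np_nucleic=0.3, centroid=np.zeros(3),
                               per_atom_loss={atoms[0].atom_key: 100.0})
        out = ss_hydration([], [], self._residue_ss(["helices"]), iface)
        assert out["water_mediated"]["helices"] == 0.0


class TestGrooveHydration:
    def test_planted_split_recovered(self, groove_complex):
        _, truth, _, bundle = groove_complex
        assert bundle.groove["n_major"] == truth["n_major_contacts"]
        assert bundle.groove["n_minor"] == truth["n_minor_contacts"]
        total = truth["n_major_contacts"] + truth["n_minor_contacts"]
        assert bundle.groove["major_pct"] == pytest.approx(
            100.0 * truth["n_major_contacts"] / total)

    def test_three_major_two_minor_gives_60_40(self, bridging_complex):
        _, _, model, bundle = bridging_complex
        pairs = bundle.wc_pairs
        # pick real paired-base atoms from the duplex
        atoms = {}
        for ch in model.nucleic_side:
            for res in ch.residues:
                for a in res.atoms:
                    atoms.setdefault((res.res_name, a.name), a)
        w = make_atom("O", "O", "HOH", "W", 50)
        wm = [_hb(w, atoms[("G", "N7")], akind="nucleic"),
              _hb(w, atoms[("G", "O6")], akind="nucleic"),
              _hb(w, atoms[("A", "N7")], akind="nucleic"),
              _hb(w, atoms[("C", "O2")], akind="nucleic"),
              _hb(w, atoms[("U", "O2")], akind="nucleic")]
        out = groove_hydration(wm, pairs)
        assert out["major_pct"] == pytest.approx(60.0)
        assert out["minor_pct"] == pytest.approx(40.0)

    def test_no_groove_bonds_absent(self):
        out = groove_hydration([], [])
        assert out["major_pct"] is None and out["minor_pct"] is None


class TestSignificance:
    def test_identical_groups(self):
        assert one_way_anova([[1, 2, 3], [1, 2, 3]]) == (0.0, 1.0)
        assert two_tailed_ttest([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)

    def test_two_group_anova_equals_t_squared(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        F, pF = one_way_anova([a, b])
        t, pt = two_tailed_ttest(a, b)
        assert F == pytest.approx(t * t, rel=1e-12)
        assert pF == pytest.approx(pt, rel=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(9)
        groups = [list(rng.normal(loc=m, size=7)) for m in (0.0, 0.4, 1.1)]
        F, p = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)
        t, pt = two_tailed_ttest(groups[0], groups[2])
        ref_t = sps.ttest_ind(groups[0], groups[2])
        assert t == pytest.approx(ref_t.statistic, abs=1e-8)
        assert pt == pytest.approx(ref_t.pvalue, abs=1e-8)

    def test_clear_separation_is_significant(self):
        a = [1.0, 2.0, 3.0]
        b = [101.0, 102.0, 103.0]
        _, p = two_tailed_ttest(a, b)
        assert p < 1e-6

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            two_tailed_ttest([1.0], [2.0, 3.0])
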