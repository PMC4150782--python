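"""Geometric hydrogen-bond detection and endpoint chemistry.

Hydrogen bonds are detected from donor/acceptor heavy-atom templates per
residue.  Crystallographic structures (and all waters) usually lack
hydrogens, so the default rule is the standard distance-only convention:
a donor/acceptor heavy-atom pair at 2.4–3.5 Å.  When the donor carries an
explicit hydrogen, the angular criteria apply instead (D–A <= 3.9 Å,
H–A <= 2.5 Å, D–H–A >= 90 deg).  All thresholds are configurable.

Endpoint chemistry follows the interface-hydration bookkeeping:

* protein polar atoms split into main-chain O, main-chain N, charged side
  chains (N of Arg/Lys, O of Asp/Glu) and neutral side chains (N of
  Asn/Gln/His/Trp, O of Asn/Gln, OH of Ser/Thr/Tyr, S of Cys/Met);
* nucleic polar atoms split into phosphate ({P, O1P, O2P}), sugar
  ({O2', O3', O4', O5'}) and base;
* groove atoms of Watson-Crick paired bases: major groove N6/O6 and N7 of
  purines, O4/N4 of pyrimidines; minor groove N2/N3 of purines, O2 of
  pyrimidines.

Watson-Crick pairs (G-C, A-U, A-T; wobble excluded by default) are
detected from the N1(purine)-N3(pyrimidine) distance, greedily by
shortest distance with each base in at most one pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import RNA_CODES, DNA_CODES, STANDARD_AA

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "GroupSchema",
    "DEFAULT_SCHEMA",
    "BasePair",
    "detect_hbonds",
    "classify_endpoint",
    "detect_wc_pairs",
    "groove_of",
    "polar_template",
]

PURINES = frozenset({"A", "G", "DA", "DG"})
PYRIMIDINES = frozenset({"C", "U", "DC", "DT"})

# ---------------------------------------------------------------------------
# Donor / acceptor heavy-atom templates

_MAIN_CHAIN_DONORS = {"N"}
_MAIN_CHAIN_ACCEPTORS = {"O", "OXT"}

_SIDE_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
_SIDE_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    "MET": {"SD"},
}

_SUGAR_DONORS = {"O2'"}
_SUGAR_ACCEPTORS = {"O2'", "O3'", "O4'", "O5'"}
_PHOSPHATE_ACCEPTORS = {"O1P", "O2P", "OP1", "OP2"}

_BASE_DONORS = {
    "A": {"N6"}, "G": {"N1", "N2"}, "C": {"N4"}, "U": {"N3"},
    "DA": {"N6"}, "DG": {"N1", "N2"}, "DC": {"N4"}, "DT": {"N3"},
}
_BASE_ACCEPTORS = {
    "A": {"N1", "N3", "N7"}, "G": {"N3", "N7", "O6"},
    "C": {"N3", "O2"}, "U": {"O2", "O4"},
    "DA": {"N1", "N3", "N7"}, "DG": {"N3", "N7", "O6"},
    "DC": {"N3", "O2"}, "DT": {"O2", "O4"},
}


def polar_template(res_name: str) -> tuple[frozenset, frozenset] | None:
    """Donor and acceptor atom-name sets for a residue, or None if unknown."""
    if res_name in STANDARD_AA:
        donors = set(_MAIN_CHAIN_DONORS) if res_name != "PRO" else set()
        donors |= _SIDE_DONORS.get(res_name, set())
        acceptors = set(_MAIN_CHAIN_ACCEPTORS) | _SIDE_ACCEPTORS.get(res_name, set())
        return frozenset(donors), frozenset(acceptors)
    if res_name in RNA_CODES | DNA_CODES:
        donors = set(_BASE_DONORS.get(res_name, set()))
        acceptors = set(_PHOSPHATE_ACCEPTORS) | _BASE_ACCEPTORS.get(res_name, set())
        if res_name in RNA_CODES:
            donors |= _SUGAR_DONORS
            acceptors |= _SUGAR_ACCEPTORS
        else:
            acceptors |= {"O3'", "O4'", "O5'"}
        return frozenset(donors), frozenset(acceptors)
    return None


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric thresholds (Å / degrees) for H-bond detection."""

    d_min: float = 2.4          # heavy-atom minimum (steric floor)
    d_max: float = 3.5          # heavy-atom D-A maximum, hydrogen-free rule
    da_max_with_h: float = 3.9  # D-A maximum with explicit hydrogen
    ha_max: float = 2.5         # H-A maximum
    dha_min_deg: float = 90.0   # D-H-A minimum angle


@dataclass(frozen=True)
class HBondRecord:
    """One donor-acceptor contact.

    ``donor_is_certain`` is False when both endpoints could play either
    role under the hydrogen-free rule (e.g. water-hydroxyl contacts); the
    recorded direction is then a convention, not an observation.
    """

    donor: object
    acceptor: object
    da_distance: float
    dha_angle: float | None
    donor_kind: str     # protein | nucleic | water
    acceptor_kind: str
    donor_is_certain: bool = True

    @property
    def kinds(self) -> frozenset:
        return frozenset({self.donor_kind, self.acceptor_kind})

    def polymer_atom(self):
        """The non-water endpoint of a water-polymer bond (None otherwise)."""
        if self.donor_kind == "water" and self.acceptor_kind != "water":
            return self.acceptor
        if self.acceptor_kind == "water" and self.donor_kind != "water":
            return self.donor
        return None

    def water_atom(self):
        if self.donor_kind == "water":
            return self.donor
        if self.acceptor_kind == "water":
            return self.acceptor
        return None


def _endpoint_kind(atom, water_keys: set) -> str:
    if atom.atom_key in water_keys:
        return "water"
    if atom.res_name in STANDARD_AA:
        return "protein"
    return "nucleic"


def _collect_polar_atoms(model):
    """(atom, can_donate, can_accept, hydrogens on donor) for every polar atom."""
    entries = []
    warned = set()
    for ch in model.chains:
        for res in ch.residues:
            tmpl = polar_template(res.res_name)
            if tmpl is None:
                if res.res_name not in warned:
                    warnings.warn(f"no donor/acceptor template for residue {res.res_name}; skipped")
                    warned.add(res.res_name)
                continue
            donors, acceptors = tmpl
            hydrogens = [a for a in res.atoms if a.is_hydrogen]
            for a in res.atoms:
                if a.is_hydrogen:
                    continue
                d = a.name in donors
                c = a.name in acceptors
                if d or c:
                    hs = [h for h in hydrogens if np.linalg.norm(h.xyz - a.xyz) < 1.25] if d else []
                    entries.append((a, d, c, hs))
    for w in model.waters:
        hs = [h for h in model.water_hydrogens
              if h.chain_id == w.chain_id and h.res_seq == w.res_seq and h.i_code == w.i_code]
        entries.append((w, True, True, hs))
    return entries


def detect_hbonds(model, criteria: HBondCriteria = HBondCriteria()) -> list:
    """All donor-acceptor contacts in the model satisfying the criteria.

    Waters act as both donor and acceptor; at most one H-bond is recorded
    per unordered atom pair; atoms of the same residue (or the same water)
    never bond each other.
    """
    entries = _collect_polar_atoms(model)
    if not entries:
        return []
    water_keys = {w.atom_key for w in model.waters}
    coords = np.array([e[0].xyz for e in entries])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=criteria.da_max_with_h, output_type="ndarray")
    out = []
    for i, j in pairs:
        ai, di, ci, hi = entries[i]
        aj, dj, cj, hj = entries[j]
        if ai.res_key == aj.res_key:
            continue
        d = float(np.linalg.norm(ai.xyz - aj.xyz))
        if d < criteria.d_min:
            continue
        rec = _best_direction(ai, di, ci, hi, aj, dj, cj, hj, d, criteria, water_keys)
        if rec is not None:
            out.append(rec)
    out.sort(key=lambda r: (r.donor.atom_key, r.acceptor.atom_key))
    return out


def _geometry_ok(donor, hydrogens, acceptor, d, criteria):
    """(passes, dha_angle) for one donor->acceptor direction."""
    if hydrogens:
        if d > criteria.da_max_with_h:
            return False, None
        best = None
        for h in hydrogens:
            ha = float(np.linalg.norm(h.xyz - acceptor.xyz))
            if ha > criteria.ha_max:
                continue
            v1 = donor.xyz - h.xyz
            v2 = acceptor.xyz - h.xyz
            cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang >= criteria.dha_min_deg and (best is None or ang > best):
                best = ang
        return (best is not None), best
    return d <= criteria.d_max, None


def _best_direction(ai, di, ci, hi, aj, dj, cj, hj, d, criteria, water_keys):
    candidates = []
    if di and cj:
        ok, ang = _geometry_ok(ai, hi, aj, d, criteria)
        if ok:
            candidates.append((ai, aj, ang))
    if dj and ci:
        ok, ang = _geometry_ok(aj, hj, ai, d, criteria)
        if ok:
            candidates.append((aj, ai, ang))
    if not candidates:
        return None
    donor, acceptor, ang = candidates[0]
    return HBondRecord(
        donor=donor,
        acceptor=acceptor,
        da_distance=d,
        dha_angle=ang,
        donor_kind=_endpoint_kind(donor, water_keys),
        acceptor_kind=_endpoint_kind(acceptor, water_keys),
        donor_is_certain=len(candidates) == 1,
    )


# ---------------------------------------------------------------------------
# Chemical-group schema

_CHARGED_SIDE = {
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}
_NEUTRAL_SIDE = {
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("CYS", "SG"), ("MET", "SD"),
}


@dataclass(frozen=True)
class GroupSchema:
    """Atom-to-chemical-group assignments used by the hydration tables."""

    phosphate: frozenset = frozenset({"P", "O1P", "O2P", "OP1", "OP2"})
    sugar: frozenset = frozenset({"O2'", "O3'", "O4'", "O5'"})
    major_purine: frozenset = frozenset({"N6", "O6", "N7"})
    major_pyrimidine: frozenset = frozenset({"O4", "N4"})
    minor_purine: frozenset = frozenset({"N2", "N3"})
    minor_pyrimidine: frozenset = frozenset({"O2"})


DEFAULT_SCHEMA = GroupSchema()


def classify_endpoint(atom, schema: GroupSchema = DEFAULT_SCHEMA) -> str:
    """Chemical-group label of a polymer H-bond endpoint.

    Protein atoms map to main_chain_O / main_chain_N / charged_side /
    neutral_side; nucleic atoms to phosphate / sugar / base (O3' and O5'
    belong to the sugar, not the phosphate).  Unknown polar atoms map to
    ``other`` with a warning.
    """
    res, name = atom.res_name, atom.name
    if res in STANDARD_AA:
        if name in ("O", "OXT"):
            return "main_chain_O"
        if name == "N":
            return "main_chain_N"
        if (res, name) in _CHARGED_SIDE:
            return "charged_side"
        if (res, name) in _NEUTRAL_SIDE:
            return "neutral_side"
    elif res in RNA_CODES | DNA_CODES:
        if name in schema.phosphate:
            return "phosphate"
        if name in schema.sugar:
            return "sugar"
        base_polar = _BASE_DONORS.get(res, set()) | _BASE_ACCEPTORS.get(res, set())
        if name in base_polar:
            return "base"
    warnings.warn(f"polar atom {name} of {res} not in chemical-group schema; labelled other")
    return "other"


# ---------------------------------------------------------------------------
# Watson-Crick pairs and grooves

def _is_wc_complement(pu: str, py: str) -> bool:
    pu = pu[-1]                      # DA -> A, DG -> G
    py = "T" if py == "DT" else py[-1]
    return (pu, py) in {("G", "C"), ("A", "U"), ("A", "T")}


@dataclass(frozen=True)
class BasePair:
    purine: object      # Residue
    pyrimidine: object  # Residue
    purine_chain: str
    pyrimidine_chain: str
    n1_n3_distance: float

    def member_keys(self) -> set:
        return {(self.purine_chain, self.purine.res_seq, self.purine.i_code),
                (self.pyrimidine_chain, self.pyrimidine.res_seq, self.pyrimidine.i_code)}


def detect_wc_pairs(chains, d_window=(2.5, 3.5), include_wobble: bool = False) -> list:
    """Watson-Crick base pairs among the nucleic chains.

    A candidate pair is a complementary purine/pyrimidine (G-C, A-U, A-T)
    whose N1(purine)-N3(pyrimidine) distance lies in ``d_window``;
    candidates are accepted greedily by shortest distance, each base in at
    most one pair.  With ``include_wobble``, G-U pairs are also accepted
    via the N1(G)-O2(U) distance (wobble geometry).
    """
    purines, pyrimidines = [], []
    for ch in chains:
        for res in ch.residues:
            if res.res_name in PURINES and res.atom("N1") is not None:
                purines.append((ch.chain_id, res))
            elif res.res_name in PYRIMIDINES and res.atom("N3") is not None:
                pyrimidines.append((ch.chain_id, res))
    candidates = []
    for pc, pu in purines:
        n1 = pu.atom("N1").xyz
        for yc, py in pyrimidines:
            if _is_wc_complement(pu.res_name, py.res_name):
                d = float(np.linalg.norm(n1 - py.atom("N3").xyz))
                if d_window[0] <= d <= d_window[1]:
                    candidates.append(BasePair(pu, py, pc, yc, d))
            elif include_wobble and pu.res_name == "G" and py.res_name == "U":
                o2 = py.atom("O2")
                if o2 is not None:
                    d = float(np.linalg.norm(n1 - o2.xyz))
                    if d_window[0] <= d <= d_window[1]:
                        candidates.append(BasePair(pu, py, pc, yc, d))
    candidates.sort(key=lambda bp: bp.n1_n3_distance)
    used = set()
    pairs = []
    for bp in candidates:
        keys = bp.member_keys()
        if keys & used:
            continue
        used |= keys
        pairs.append(bp)
    return pairs


def paired_base_keys(pairs) -> set:
    keys = set()
    for bp in pairs:
        keys |= bp.member_keys()
    return keys


def groove_of(atom, pairs, schema: GroupSchema = DEFAULT_SCHEMA) -> str:
    """Groove label (major / minor / none) of a base atom.

    Groove labels apply only to bases that are members of a detected
    Watson-Crick pair; atoms of unpaired bases return ``none``.
    """
    if atom.res_key not in paired_base_keys(pairs):
        return "none"
    res, name = atom.res_name, atom.name
    if res in PURINES:
        if name in schema.major_purine:
            return "major"
        if name in schema.minor_purine:
            return "minor"
    elif res in PYRIMIDINES:
        if name in schema.major_pyrimidine:
            return "major"
        if name in schema.minor_pyrimidine:
            return "minor"
    return "none"
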