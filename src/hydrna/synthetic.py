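"""Deterministic toy protein-RNA complexes with known hydration ground truth.

The generator builds ideal-geometry polymers — an alpha-helix
(phi = -57, psi = -47), a two-strand antiparallel sheet, or an extended
coil for the protein; an A-form-like duplex (rise 2.81 Å, twist 32.7 deg,
planar Watson-Crick pairs) or a single strand for the RNA/DNA — places
them in van der Waals contact, and then plants water oxygens with
controlled H-bond geometry:

* ``bridging`` mode puts each planted water 2.8 Å from one protein polar
  atom and one nucleic polar atom (and >= 3.55 Å from every other polar
  atom, so the planted H-bond set is exactly the intended one);
  remaining waters sit in the 3.6-4.4 Å shell of both sides: interface
  waters with no H-bonds.
* ``central`` / ``peripheral`` modes place waters at ``radial_scale``
  times the radial spread of the contact atoms, forcing the wet/dry
  statistic d_r below / above 1.
* ``uniform`` scatters waters over the contact strip.

Base geometry is idealized: rings are regular polygons with 1.38 Å
edges, pairs are planar with a 2.9 Å N1-N3 bond, and base planes stay
perpendicular to the helix axis.  This is deliberately not a physically
realistic nucleic acid — it is a fixture whose every downstream statistic
(bridging count, groove contacts, preserved waters, wet/dry) is known by
construction.  Identical spec + seed yields byte-identical PDB output;
the seed is recorded in a REMARK for provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .structure_io import (
    AtomRecord,
    ChainModel,
    ComplexModel,
    Residue,
    write_pdb,
)

__all__ = ["GeneratorSpec", "GenerationError", "make_complex",
           "make_bound_unbound_pair", "make_complex_retry",
           "make_bound_unbound_pair_retry"]


class GenerationError(RuntimeError):
    """Raised when a water cannot be placed without clashes."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic complex (identical spec + seed -> identical PDB)."""

    seed: int = 0
    protein_form: str = "alpha_helix"      # alpha_helix | beta_hairpin | coil
    protein_length: int = 30
    rna_form: str = "a_form_duplex"        # a_form_duplex | single_strand
    rna_length: int = 10                   # nucleotides per strand
    nucleic_type: str = "RNA"              # RNA | DNA
    n_waters: int = 12
    water_mode: str = "bridging"           # bridging | central | peripheral | uniform
    n_bridging_planted: int = 6
    n_preserved_planted: int = 0
    n_major_contacts: int = 0              # bridging waters anchored on major-groove atoms
    n_minor_contacts: int = 0              # ... and on minor-groove atoms
    radial_scale: float = 1.0

    def validate(self):
        if self.n_bridging_planted > self.n_waters:
            raise ValueError("n_bridging_planted exceeds n_waters")
        if self.n_preserved_planted > self.n_waters:
            raise ValueError("n_preserved_planted exceeds n_waters")
        if self.n_major_contacts + self.n_minor_contacts > self.n_bridging_planted:
            raise ValueError("groove contacts exceed planted bridging waters")
        if self.water_mode not in ("bridging", "central", "peripheral", "uniform"):
            raise ValueError(f"unknown water_mode {self.water_mode!r}")


# ---------------------------------------------------------------------------
# geometry primitives

def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D from positions A, B, C with internal coordinates."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


_BB = dict(n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231,
           n_ca_c=111.2, ca_c_n=116.2, c_n_ca=121.7, ca_c_o=120.8)


def _build_backbone(phi_psi):
    """Backbone N/CA/C/O coordinates for a list of (phi, psi) per residue."""
    coords = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["n_ca"], 0.0, 0.0])
    c = _nerf(np.array([0.0, 1.0, 0.0]), n, ca, _BB["ca_c"], _BB["n_ca_c"], 120.0)
    for i, (phi, psi) in enumerate(phi_psi):
        if i > 0:
            n = _nerf(prev_n, prev_ca, prev_c, _BB["c_n"], _BB["ca_c_n"], prev_psi)
            ca = _nerf(prev_ca, prev_c, n, _BB["n_ca"], _BB["c_n_ca"], 180.0)  # omega
            c = _nerf(prev_c, n, ca, _BB["ca_c"], _BB["n_ca_c"], phi)
        coords.append({"N": n, "CA": ca, "C": c})
        prev_n, prev_ca, prev_c, prev_psi = n, ca, c, psi
    # carbonyl O: trans to the next N (torsion psi + 180 about N-CA-C)
    for i, res in enumerate(coords):
        psi = phi_psi[i][1]
        res["O"] = _nerf(res["N"], res["CA"], res["C"], _BB["c_o"], _BB["ca_c_o"], psi + 180.0)
        # CB for non-GLY: tetrahedral branch off CA
        res["CB"] = _nerf(res["C"], res["N"], res["CA"], 1.53, 110.5, 122.5)
    return coords


_FORM_ANGLES = {"alpha_helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}


def _protein_coords(form: str, length: int):
    """Residue coordinate dicts for the requested ideal form."""
    if form == "alpha_helix":
        return _build_backbone([_FORM_ANGLES["alpha_helix"]] * length)
    if form == "coil":
        # alternating extended-ish angles: no repetitive H-bond pattern
        angles = [(-139.0, 135.0) if i % 2 == 0 else (-75.0, 145.0) for i in range(length)]
        return _build_backbone(angles)
    if form == "beta_hairpin":
        half = max(length // 2, 3)
        strand = _build_backbone([_FORM_ANGLES["strand"]] * half)
        return _register_sheet(strand, half)
    raise ValueError(f"unknown protein_form {form!r}")


def _ks_energy(don_n, don_h, acc_c, acc_o):
    q = 0.084 * 332.0
    r_on = np.linalg.norm(acc_o - don_n)
    r_ch = np.linalg.norm(acc_c - don_h)
    r_oh = np.linalg.norm(acc_o - don_h)
    r_cn = np.linalg.norm(acc_c - don_n)
    return q * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def _amide_h(res, prev):
    v = prev["C"] - prev["O"]
    return res["N"] + 1.01 * v / np.linalg.norm(v)


def _strand_frame(strand):
    axis = strand[-1]["CA"] - strand[0]["CA"]
    axis /= np.linalg.norm(axis)
    origin = strand[0]["CA"]
    perp = np.array([0.0, 0.0, 1.0])
    perp = perp - np.dot(perp, axis) * axis
    perp /= np.linalg.norm(perp)
    third = np.cross(axis, perp)
    return origin, axis, perp, third


def _screw_copy(strand, shift_par, shift_perp):
    """Rigid copy of the strand translated along and across its axis:
    the parallel two-strand sheet arrangement."""
    origin, axis, perp, third = _strand_frame(strand)
    out = []
    for res in strand:
        new = {}
        for name, xyz in res.items():
            v = xyz - origin
            a, p, t = np.dot(v, axis), np.dot(v, perp), np.dot(v, third)
            new[name] = origin + (a + shift_par) * axis + (p + shift_perp) * perp + t * third
        out.append(new)
    return out


@lru_cache(maxsize=8)
def _sheet_transform(half: int):
    """Scan the rigid placement of a parallel partner strand that
    maximizes the number of Kabsch-Sander inter-strand H-bonds.

    A rigidly transformed copy of a twisted ideal strand registers as a
    parallel ladder (every-other-residue bridge pattern); the rigid
    antiparallel arrangements of the same strand never register more
    than isolated bridges, so the sheet form is built parallel.
    """
    strand = _build_backbone([_FORM_ANGLES["strand"]] * half)
    best = None
    for sp in np.arange(-3.0, 3.0, 0.1):
        for sq in np.arange(3.6, 5.5, 0.05):
            other = _screw_copy(strand, sp, sq)
            nhb = 0
            for i in range(1, half):
                hi = _amide_h(strand[i], strand[i - 1])
                for j in range(half - 1):
                    if _ks_energy(strand[i]["N"], hi, other[j]["C"], other[j]["O"]) < -0.5:
                        nhb += 1
            for j in range(1, half):
                hj = _amide_h(other[j], other[j - 1])
                for i in range(half - 1):
                    if _ks_energy(other[j]["N"], hj, strand[i]["C"], strand[i]["O"]) < -0.5:
                        nhb += 1
            if best is None or nhb > best[0]:
                best = (nhb, sp, sq)
    return best[1], best[2]


def _register_sheet(strand, half):
    sp, sq = _sheet_transform(half)
    return strand + _screw_copy(strand, sp, sq)


# ---------------------------------------------------------------------------
# nucleic acid construction

_RING_EDGE = 1.38
_PAIR_N1N3 = 2.9


def _hexagon():
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    pos = {}
    for k, name in enumerate(names):
        ang = math.radians(90.0 - 60.0 * k)
        pos[name] = np.array([_RING_EDGE * math.cos(ang), _RING_EDGE * math.sin(ang)])
    return pos


def _pyrimidine_template(base: str):
    """Planar 2D template; attachment direction is center->N1."""
    pos = _hexagon()
    center = np.zeros(2)
    for name, sub, bond in (("C2", "O2", 1.23), ("C4", "N4" if base in ("C", "DC") else "O4", 1.23)):
        d = pos[name] - center
        pos[sub] = pos[name] + bond * d / np.linalg.norm(d)
    pos["_attach"] = pos["N1"] + 1.47 * pos["N1"] / np.linalg.norm(pos["N1"])
    pos["_anchor"] = center.copy()
    return pos


def _purine_template(base: str):
    pos = _hexagon()
    center = np.zeros(2)
    c4, c5 = pos["C4"], pos["C5"]
    mid = 0.5 * (c4 + c5)
    out = mid - center
    out /= np.linalg.norm(out)
    apothem = _RING_EDGE / (2.0 * math.tan(math.radians(36.0)))
    pc = mid + apothem * out
    a4 = math.atan2(*(c4 - pc)[::-1])
    a5 = math.atan2(*(c5 - pc)[::-1])
    r5 = np.linalg.norm(c4 - pc)
    # remaining vertices go the long way round from C4 to C5: N9, C8, N7
    delta = (((a5 - a4) % (2 * math.pi)) - 2 * math.pi) / 4.0
    for k, name in enumerate(("N9", "C8", "N7"), start=1):
        ang = a4 + k * delta
        pos[name] = pc + r5 * np.array([math.cos(ang), math.sin(ang)])
    if base in ("G", "DG"):
        pos["O6"] = pos["C6"] + 1.23 * pos["C6"] / np.linalg.norm(pos["C6"])
        pos["N2"] = pos["C2"] + 1.35 * pos["C2"] / np.linalg.norm(pos["C2"])
    else:
        pos["N6"] = pos["C6"] + 1.35 * pos["C6"] / np.linalg.norm(pos["C6"])
    d = pos["N9"] - pc
    pos["_attach"] = pos["N9"] + 1.47 * d / np.linalg.norm(d)
    pos["_anchor"] = pc
    return pos


def _rot2(p, ang):
    c, s = math.cos(ang), math.sin(ang)
    return np.array([c * p[0] - s * p[1], s * p[0] + c * p[1]])


@lru_cache(maxsize=8)
def _pair_template(pu: str, py: str):
    """2D coordinates of a planar WC pair: purine left, pyrimidine right.

    The pyrimidine placement (mirror + rotation) is chosen by a scan
    minimizing deviation of the secondary WC H-bond distances from 2.9 Å
    while keeping the rings apart.
    """
    pur = _purine_template(pu)
    pyr = _pyrimidine_template(py)
    # orient purine so that N1 -> outward is +x
    n1_dir = pur["N1"] / np.linalg.norm(pur["N1"])
    base_rot = -math.atan2(n1_dir[1], n1_dir[0])
    pur = {k: _rot2(v, base_rot) for k, v in pur.items()}
    target_n3 = pur["N1"] + np.array([_PAIR_N1N3, 0.0])

    if pu in ("G", "DG"):
        checks = [("O6", "N4", 2.9), ("N2", "O2", 2.9)]
    else:
        other = "O4"
        checks = [("N6", other, 2.9)]

    best = None
    for mirror in (1.0, -1.0):
        for ang_deg in range(0, 360, 2):
            ang = math.radians(ang_deg)
            cand = {}
            for k, v in pyr.items():
                p = np.array([v[0], mirror * v[1]])
                cand[k] = _rot2(p, ang)
            shift = target_n3 - cand["N3"]
            cand = {k: v + shift for k, v in cand.items()}
            cost = 0.0
            for a, b, d0 in checks:
                if a in pur and b in cand:
                    cost += (np.linalg.norm(pur[a] - cand[b]) - d0) ** 2
            # ring atoms must not collide
            for ka, va in pur.items():
                if ka.startswith("_"):
                    continue
                for kb, vb in cand.items():
                    if kb.startswith("_"):
                        continue
                    d = np.linalg.norm(va - vb)
                    if d < 2.3:
                        cost += (2.3 - d) ** 2 * 50.0
            if best is None or cost < best[0]:
                best = (cost, mirror, ang)
    _, mirror, ang = best
    out = {}
    for k, v in pyr.items():
        p = np.array([v[0], mirror * v[1]])
        out[k] = _rot2(p, ang)
    shift = target_n3 - out["N3"]
    out = {k: v + shift for k, v in out.items()}
    return pur, out


# cumulative (w, t, k) local-frame coordinates of the sugar/phosphate arm,
# measured from the glycosidic attachment point: w radial-outward in the
# base plane, t forward along the helix sweep, k along the axis
_SUGAR_OFFSETS = [
    ("C1'", (0.0, 0.0, 0.0)),
    ("O4'", (0.9, 0.9, 0.4)),
    ("C2'", (1.0, -0.4, -0.5)),
    ("O2'", (2.3, -0.6, -0.8)),
    ("C3'", (1.8, 0.5, 0.3)),
    ("O3'", (2.9, 0.8, 0.6)),
    ("C4'", (1.9, 1.4, 0.1)),
    ("C5'", (2.6, 2.2, 0.7)),
    ("O5'", (3.4, 2.0, 1.3)),
    ("P", (4.3, 2.6, 1.9)),
    ("O1P", (5.5, 2.9, 1.9)),
    ("O2P", (4.2, 2.0, 2.9)),
]

_HELIX_RISE = 2.81
_HELIX_TWIST = math.radians(32.7)
_PAIR_SHIFT = 4.2    # base-pair displacement from the helix axis, applied
                     # perpendicular to the pairing axis (toward the major
                     # groove edge) so both backbones sit at similar radius
_SS_RISE = 5.5
_SS_TWIST = math.radians(55.0)

_DUPLEX_SEQ = "GACUGCAUGACUGCAU"   # strand-1 repeat; complement on strand 2
_SS_SEQ = "GACUAGCUUGCAGUAC"
_WC = {"G": "C", "C": "G", "A": "U", "U": "A"}


def _to_dna(code: str) -> str:
    return {"U": "DT", "A": "DA", "C": "DC", "G": "DG"}[code]


def _base_3d(template2d, twist, rise, shift_sign):
    out = {}
    shift = np.array([0.0, shift_sign * _PAIR_SHIFT])
    for name, v in template2d.items():
        p = _rot2(v + shift, twist)
        out[name] = np.array([p[0], p[1], rise])
    return out


def _sugar_atoms(base3d, is_rna: bool, t_sign: float = 1.0):
    """Sugar + phosphate positions hung off the glycosidic attachment."""
    anchor = base3d["_anchor"]
    attach = base3d["_attach"]
    w = attach - anchor
    w[2] = 0.0
    w /= np.linalg.norm(w)
    k = np.array([0.0, 0.0, 1.0])
    t = t_sign * np.cross(k, w)
    pos = {}
    for name, (cw, ct, ck) in _SUGAR_OFFSETS:
        if name == "O2'" and not is_rna:
            continue
        pos[name] = attach + cw * w + ct * t + ck * k
    return pos


def _nucleic_chains(form: str, length: int, nucleic_type: str):
    """Build nucleic chains: list of (chain_id, [(res_name, {atom: xyz})])."""
    is_rna = nucleic_type == "RNA"
    if form == "a_form_duplex":
        seq = (_DUPLEX_SEQ * ((length // len(_DUPLEX_SEQ)) + 1))[:length]
        strand1, strand2 = [], []
        for i, code in enumerate(seq):
            comp = _WC[code]
            pu, py = (code, comp) if code in "AG" else (comp, code)
            pur2d, pyr2d = _pair_template(pu if is_rna else _to_dna(pu),
                                          py if is_rna else ("DT" if py == "U" else _to_dna(py)))
            # displace the pair away from the helix axis on the side
            # opposite the purine major-groove edge (O6/N6 has +y or -y)
            major_y = pur2d.get("O6", pur2d.get("N6"))[1]
            sign = -1.0 if major_y > 0 else 1.0
            twist, rise = _HELIX_TWIST * i, _HELIX_RISE * i
            pur3d = _base_3d(pur2d, twist, rise, sign)
            pyr3d = _base_3d(pyr2d, twist, rise, sign)
            first3d, second3d = (pur3d, pyr3d) if code in "AG" else (pyr3d, pur3d)
            for target, code_i, b3d, t_sign in (
                    (strand1, code, first3d, 1.0), (strand2, comp, second3d, -1.0)):
                atoms = {n: v for n, v in b3d.items() if not n.startswith("_")}
                atoms.update(_sugar_atoms(b3d, is_rna, t_sign))
                name = code_i if is_rna else ("DT" if code_i == "U" else _to_dna(code_i))
                target.append((name, atoms))
        return [("B", strand1), ("C", strand2[::-1])]
    if form == "single_strand":
        seq = (_SS_SEQ * ((length // len(_SS_SEQ)) + 1))[:length]
        strand = []
        for i, code in enumerate(seq):
            tmpl = _purine_template(code if is_rna else _to_dna(code)) if code in "AG" \
                else _pyrimidine_template(code if is_rna else ("DT" if code == "U" else _to_dna(code)))
            b3d = _base_3d(tmpl, _SS_TWIST * i, _SS_RISE * i, 1.0)
            atoms = {n: v for n, v in b3d.items() if not n.startswith("_")}
            atoms.update(_sugar_atoms(b3d, is_rna, -1.0))
            name = code if is_rna else ("DT" if code == "U" else _to_dna(code))
            strand.append((name, atoms))
        return [("B", strand)]
    raise ValueError(f"unknown rna_form {form!r}")


# ---------------------------------------------------------------------------
# assembly

_ELEMENT = {"N": "N", "C": "C", "O": "O", "P": "P", "S": "S"}


def _element_of(name: str) -> str:
    for c in name:
        if c.isalpha():
            return c.upper()
    return name[0]


_PROT_SEQ_PERIOD = ["ALA", "SER", "ARG", "ALA", "GLY"]


def _protein_chain(form: str, length: int) -> list:
    """[(res_name, {atom: xyz})] with a simple ALA/SER/ARG/GLY sequence.

    Arginine side chains are built as straight outward-pointing arms
    (guanidinium ~6 Å from CA): polar probes that can reach recessed
    nucleic atoms across the interface.
    """
    coords = _protein_coords(form, length)
    out = []
    for i, res in enumerate(coords):
        name = _PROT_SEQ_PERIOD[i % len(_PROT_SEQ_PERIOD)]
        atoms = {"N": res["N"], "CA": res["CA"], "C": res["C"], "O": res["O"]}
        if name != "GLY":
            atoms["CB"] = res["CB"]
        if name == "SER":
            # hydroxyl roughly anti to the backbone N
            d = res["CB"] - res["N"]
            atoms["OG"] = res["CB"] + 1.41 * d / np.linalg.norm(d)
        if name == "ARG":
            d = res["CB"] - res["CA"]
            d /= np.linalg.norm(d)
            perp = np.cross(d, res["C"] - res["N"])
            perp /= np.linalg.norm(perp)
            pos = dict(atoms)
            chain_spec = [("CG", 1.52), ("CD", 1.52), ("NE", 1.47), ("CZ", 1.33)]
            cur = res["CB"]
            for j, (an, bond) in enumerate(chain_spec):
                cur = cur + bond * d + (0.25 if j % 2 == 0 else -0.25) * perp
                atoms[an] = cur
            atoms["NH1"] = atoms["CZ"] + 1.33 * d + 0.55 * perp
            atoms["NH2"] = atoms["CZ"] + 1.33 * d - 0.55 * perp
        out.append((name, atoms))
    return out


def _as_chain(chain_id: str, residues, mol_type: str, serial_start: int):
    ch = ChainModel(chain_id, mol_type)
    serial = serial_start
    for idx, (res_name, atoms) in enumerate(residues, start=1):
        res = Residue(res_name, idx, "")
        for atom_name, xyz in atoms.items():
            serial += 1
            res.atoms.append(AtomRecord(
                serial=serial, name=atom_name, element=_element_of(atom_name),
                alt_loc="", res_name=res_name, chain_id=chain_id, res_seq=idx,
                i_code="", xyz=np.asarray(xyz, dtype=float), occupancy=1.0,
                is_hetero=False))
        ch.residues.append(res)
    return ch, serial


def _center_and_align(residues):
    """Center the coordinate cloud and align its principal axis to z."""
    pts = np.array([xyz for _, atoms in residues for xyz in atoms.values()])
    center = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - center)
    axis = vt[0]
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, zhat)
    c = float(np.dot(axis, zhat))
    if np.linalg.norm(v) < 1e-9:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    out = []
    for res_name, atoms in residues:
        out.append((res_name, {n: rot @ (xyz - center) for n, xyz in atoms.items()}))
    return out


def _translate(residues, shift):
    return [(rn, {n: xyz + shift for n, xyz in atoms.items()}) for rn, atoms in residues]


def _contact_distance(prot_res, nuc_res):
    pa = np.array([xyz for _, atoms in prot_res for xyz in atoms.values()])
    na = np.array([xyz for _, atoms in nuc_res for xyz in atoms.values()])
    from scipy.spatial import cKDTree
    return float(cKDTree(na).query(pa)[0].min())


_CONTACT_GAP = 3.4


def _dock(prot_res, nuc_res, direction):
    """Translate the protein along ``direction`` until the closest
    approach to the nucleic atoms is 3.4 Å."""
    direction = np.asarray(direction, dtype=float)
    lo, hi = -40.0, 80.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        d = _contact_distance(_translate(prot_res, mid * direction), nuc_res)
        if d < _CONTACT_GAP:
            lo = mid
        else:
            hi = mid
    shift = 0.5 * (lo + hi)
    return _translate(prot_res, shift * direction)


# polar atom name sets used for planting (subset of the detection templates)
_PROT_POLAR = {"N", "O", "OG", "NE", "NH1", "NH2"}
_PURINES = {"A", "G", "DA", "DG"}
_PYRIMIDINES = {"C", "U", "DC", "DT"}


def _groove_label(res_name: str, atom_name: str) -> str:
    """Groove membership of a base atom (all duplex bases are paired by
    construction)."""
    if res_name in _PURINES:
        if atom_name in ("N6", "O6", "N7"):
            return "major"
        if atom_name in ("N2", "N3"):
            return "minor"
    elif res_name in _PYRIMIDINES:
        if atom_name in ("O4", "N4"):
            return "major"
        if atom_name == "O2":
            return "minor"
    return "none"
_NUC_POLAR_BACKBONE = {"O1P", "O2P", "O2'", "O3'", "O4'", "O5'"}
_MAJOR = {"N7", "O6", "N6", "O4", "N4"}
_MINOR = {"N2", "O2"}   # N3 excluded: purine N3 placement in the toy rings
                        # sits close to the pair axis; N2/O2 are unambiguous


def _polar_atoms(chains, names=None, polar_only=True):
    out = []
    polar_elements = {"N", "O", "S"}
    for ch in chains:
        for res in ch.residues:
            for a in res.atoms:
                if names is not None and a.name not in names:
                    continue
                if polar_only and a.element not in polar_elements:
                    continue
                out.append(a)
    return out


def _all_coords(model_atoms):
    return np.array([a.xyz for a in model_atoms])


def _circle_points(p, q, r1, r2, n=64):
    """Points at distance r1 from p and r2 from q (the intersection circle)."""
    d = np.linalg.norm(q - p)
    if d >= r1 + r2 or d <= abs(r1 - r2) or d < 1e-9:
        return []
    a = (r1 * r1 - r2 * r2 + d * d) / (2 * d)
    h2 = r1 * r1 - a * a
    if h2 <= 0:
        return []
    h = math.sqrt(h2)
    axis = (q - p) / d
    center = p + a * axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return [center + h * (math.cos(t) * e1 + math.sin(t) * e2)
            for t in np.linspace(0.0, 2 * math.pi, n, endpoint=False)]


_CLASH = 2.2
_SAFE_POLAR = 3.55    # just above the H-bond window: no accidental H-bonds
_HB_PLANT = 2.8


@dataclass
class _Workspace:
    protein_chain: ChainModel
    nucleic_chains: list
    polymer_atoms: list
    polar_all: list
    contact_centroid: np.ndarray
    contact_spread: float
    contact_axis_z: tuple
    contact_pts: np.ndarray = None
    contact_axis: np.ndarray = None     # principal direction of the contact patch
    polymer_xyz: np.ndarray = None
    polar_xyz: np.ndarray = None
    polar_atom_keys: list = None
    prot_xyz: np.ndarray = None
    nuc_xyz: np.ndarray = None

    def finalize(self):
        self.polymer_xyz = np.array([a.xyz for a in self.polymer_atoms])
        self.polar_xyz = np.array([a.xyz for a in self.polar_all])
        self.polar_atom_keys = [a.atom_key for a in self.polar_all]
        self.prot_xyz = np.array([a.xyz for a in self.protein_chain.atoms()])
        self.nuc_xyz = np.array([a.xyz for ch in self.nucleic_chains for a in ch.atoms()])
        prot_keys = {a.atom_key for a in self.protein_chain.atoms()}
        self.prot_polar_xyz = np.array(
            [a.xyz for a in self.polar_all if a.atom_key in prot_keys])
        self.nuc_polar_xyz = np.array(
            [a.xyz for a in self.polar_all if a.atom_key not in prot_keys])
        # contact atoms of each side: within 5.0 Å of the other side, a
        # conservative subset of the ASA-loss interface atoms
        from scipy.spatial import cKDTree
        tn = cKDTree(self.nuc_xyz)
        tp = cKDTree(self.prot_xyz)
        dp = tn.query(self.prot_xyz)[0]
        dn = tp.query(self.nuc_xyz)[0]
        self.prot_contact_xyz = self.prot_xyz[dp < 5.0]
        self.nuc_contact_xyz = self.nuc_xyz[dn < 5.0]
        return self


def _workspace(protein_chain, nucleic_chains):
    polymer = [a for a in protein_chain.atoms()]
    for ch in nucleic_chains:
        polymer.extend(ch.atoms())
    prot = np.array([a.xyz for a in protein_chain.atoms()])
    nuc = np.array([a.xyz for ch in nucleic_chains for a in ch.atoms()])
    from scipy.spatial import cKDTree
    tp, tn = cKDTree(prot), cKDTree(nuc)
    contact_idx_p = tn.query_ball_point(prot, 5.0)
    contact_pts = [prot[i] for i, lst in enumerate(contact_idx_p) if lst]
    contact_idx_n = tp.query_ball_point(nuc, 5.0)
    contact_pts += [nuc[i] for i, lst in enumerate(contact_idx_n) if lst]
    contact_pts = np.array(contact_pts) if contact_pts else np.zeros((1, 3))
    c = contact_pts.mean(axis=0)
    spread = float(np.mean(np.linalg.norm(contact_pts - c, axis=1))) if len(contact_pts) > 1 else 5.0
    zlo = float(contact_pts[:, 2].min())
    zhi = float(contact_pts[:, 2].max())
    if len(contact_pts) > 2:
        _, _, vt = np.linalg.svd(contact_pts - c)
        axis = vt[0]
    else:
        axis = np.array([0.0, 0.0, 1.0])
    polar = _polar_atoms([protein_chain] + list(nucleic_chains))
    return _Workspace(protein_chain, nucleic_chains, polymer, polar, c, spread,
                      (zlo, zhi), contact_pts=contact_pts, contact_axis=axis).finalize()


def _ok_position(pos, ws, waters, partner_keys=(), min_water=_SAFE_POLAR,
                 relaxed=False, free=False):
    """Placement constraints for a candidate water position.

    Strict mode keeps the water out of H-bond range (>= 3.55 Å) of every
    polar atom except its designated partners.  Relaxed mode tolerates
    incidental H-bonds but keeps them comfortably inside the detection
    window (2.45-3.45 Å), avoiding threshold-straddling geometry; the
    ground truth is then read off the constructed distances.  Free mode
    checks only steric clash and water spacing (for waters whose ground
    truth does not involve H-bonds).
    """
    d_all = np.linalg.norm(ws.polymer_xyz - pos, axis=1)
    if d_all.min() < _CLASH:
        return False
    if not free:
        d_pol = np.linalg.norm(ws.polar_xyz - pos, axis=1)
        if relaxed:
            bad = (d_pol < 2.45) | ((d_pol > 3.45) & (d_pol < _SAFE_POLAR))
        else:
            bad = d_pol < _SAFE_POLAR
        if bad.any():
            for idx in np.nonzero(bad)[0]:
                if ws.polar_atom_keys[idx] not in partner_keys:
                    return False
    for w in waters:
        if float(np.linalg.norm(w - pos)) < min_water:
            return False
    return True


def _batch_ok(pts, ws, partner_keys=(), min_water=_SAFE_POLAR, relaxed=False):
    """Vectorized _ok_position over an array of candidate points (without
    the water-spacing check, which depends on already-placed waters)."""
    pts = np.asarray(pts)
    d_all = np.linalg.norm(ws.polymer_xyz[None, :, :] - pts[:, None, :], axis=2)
    ok = d_all.min(axis=1) >= _CLASH
    d_pol = np.linalg.norm(ws.polar_xyz[None, :, :] - pts[:, None, :], axis=2)
    if relaxed:
        bad = (d_pol < 2.45) | ((d_pol > 3.45) & (d_pol < _SAFE_POLAR))
    else:
        bad = d_pol < _SAFE_POLAR
    if partner_keys:
        partner_idx = [i for i, k in enumerate(ws.polar_atom_keys) if k in partner_keys]
        bad[:, partner_idx] = False
    ok &= ~bad.any(axis=1)
    # interface membership for both sides
    dp = np.linalg.norm(ws.prot_contact_xyz[None, :, :] - pts[:, None, :], axis=2).min(axis=1) \
        if len(ws.prot_contact_xyz) else np.full(len(pts), np.inf)
    dn = np.linalg.norm(ws.nuc_contact_xyz[None, :, :] - pts[:, None, :], axis=2).min(axis=1) \
        if len(ws.nuc_contact_xyz) else np.full(len(pts), np.inf)
    ok &= (dp <= 4.4) & (dn <= 4.4)
    return ok


def _hbond_partners(pos, ws):
    """Template-compatible polar atoms within the 2.4-3.5 Å window of a
    planted water: the water's H-bond set by construction."""
    from .hbond import polar_template
    prot, nuc = [], []
    prot_keys = {a.atom_key for a in ws.protein_chain.atoms()}
    for a in ws.polar_all:
        tmpl = polar_template(a.res_name)
        if tmpl is None or (a.name not in tmpl[0] and a.name not in tmpl[1]):
            continue
        d = float(np.linalg.norm(a.xyz - pos))
        if 2.4 <= d <= 3.5:
            (prot if a.atom_key in prot_keys else nuc).append(a)
    return prot, nuc


def _within_both_sides(pos, ws, cutoff=4.4, any_atom=False):
    """Within interface-water range of both sides.

    By default the check runs against the contact atoms (a conservative
    subset of the ASA-loss interface atoms), which guarantees interface
    membership under the default 4.5 Å rule; ``any_atom`` relaxes it to
    the full atom sets (used by the radial modes, whose ground truth is
    wet/dry rather than an exact interface-water count)."""
    if any_atom:
        prot = float(np.linalg.norm(ws.prot_xyz - pos, axis=1).min())
        nuc = float(np.linalg.norm(ws.nuc_xyz - pos, axis=1).min())
        return prot <= cutoff and nuc <= cutoff
    if len(ws.prot_contact_xyz) == 0 or len(ws.nuc_contact_xyz) == 0:
        return False
    prot = float(np.linalg.norm(ws.prot_contact_xyz - pos, axis=1).min())
    nuc = float(np.linalg.norm(ws.nuc_contact_xyz - pos, axis=1).min())
    return prot <= cutoff and nuc <= cutoff


def _bridges_both_sides(pos, ws, limit=_SAFE_POLAR):
    """True when the position is in (or near) H-bond range of polar atoms
    of both partners simultaneously."""
    dp = float(np.linalg.norm(ws.prot_polar_xyz - pos, axis=1).min())
    dn = float(np.linalg.norm(ws.nuc_polar_xyz - pos, axis=1).min())
    return dp < limit and dn < limit


def _plant_bridging(rng, ws, count, groove_major, groove_minor, waters,
                    distinct_protein=False):
    """Place `count` waters, each H-bonded to exactly one protein polar atom
    and one nucleic polar atom; the first groove_major / groove_minor of
    them anchor on major / minor groove atoms of the duplex.

    Partner atoms may be shared between waters (each water still makes
    exactly one H-bond per side); ``distinct_protein`` forbids sharing of
    protein partners, which the bound/unbound pair construction needs so
    that preservation witnesses are unambiguous."""
    placements = []
    used_prot: set = set()
    prot_polar = [a for a in _polar_atoms([ws.protein_chain]) if a.name in _PROT_POLAR]
    groove_specs = ["major"] * groove_major + ["minor"] * groove_minor
    groove_specs += [None] * (count - len(groove_specs))
    # any distance pair in the 2.4-3.5 window is a valid planted H-bond
    radii = [(2.8, 2.8), (3.0, 3.0), (2.8, 3.2), (3.2, 2.8), (3.2, 3.2),
             (2.7, 3.4), (3.4, 2.7), (3.4, 3.4), (3.45, 3.45)]
    for which in groove_specs:
        if which == "major":
            names = _MAJOR
        elif which == "minor":
            names = _MINOR
        else:
            names = None    # any H-bondable nucleic atom
        from .hbond import polar_template
        nuc_polar = []
        for a in _polar_atoms(ws.nucleic_chains):
            if names is not None and a.name not in names:
                continue
            tmpl = polar_template(a.res_name)
            if tmpl and (a.name in tmpl[0] or a.name in tmpl[1]):
                nuc_polar.append(a)
        avail_prot = [pa for pa in prot_polar
                      if not (distinct_protein and pa.atom_key in used_prot)]
        pairs = []
        if avail_prot and nuc_polar:
            from scipy.spatial.distance import cdist
            dmat = cdist(np.array([pa.xyz for pa in avail_prot]),
                         np.array([na.xyz for na in nuc_polar]))
            for i, j in np.argwhere((dmat > 3.6) & (dmat < 6.7)):
                pairs.append((float(dmat[i, j]), avail_prot[i], nuc_polar[j]))
        pairs.sort(key=lambda x: x[0])
        placed = False
        # strict pass first (the planted H-bond set is exactly the two
        # anchors); relaxed pass tolerates incidental extra H-bonds,
        # which the ground truth then includes
        for relaxed in ((False,) if distinct_protein else (False, True)):
            for d, pa, na in pairs:
                for r1, r2 in radii:
                    if d >= r1 + r2:
                        continue
                    pts = _circle_points(pa.xyz, na.xyz, r1, r2, n=96)
                    if not len(pts):
                        continue
                    mask = _batch_ok(pts, ws, partner_keys={pa.atom_key, na.atom_key},
                                     relaxed=relaxed)
                    good = np.nonzero(mask)[0]
                    if not len(good):
                        continue
                    order = rng.permutation(len(good))
                    for idx in order:
                        pos = pts[good[idx]]
                        if all(float(np.linalg.norm(w - pos)) >= 3.0 for w in waters):
                            placements.append((pos, pa, na))
                            waters.append(pos)
                            used_prot.add(pa.atom_key)
                            placed = True
                            break
                    if placed:
                        break
                if placed:
                    break
            if placed:
                break
        if not placed:
            raise GenerationError("could not place a planted bridging water without clashes")
    return placements


_GROOVE_ATOM_NAMES = frozenset({"N6", "O6", "N7", "N2", "N3", "O2", "O4", "N4"})
_FAR_FROM_INTERFACE = 5.6    # beyond any supported interface-water cutoff


def _plant_filler(rng, ws, count, waters, attempts=1000, sides=("protein", "nucleic")):
    """Non-interface bound waters (plus occasional zero-H-bond interface
    shell waters).

    Each filler is first attempted as a zero-H-bond water inside the
    interface (within 4.4 Å of both sides, outside the H-bond shell of
    every polar atom); the contact pocket is usually too polar-dense for
    that, in which case the filler becomes an ordinary surface-bound
    water: anchored 2.6-3.3 Å from a polar atom of one partner on a face
    away from the interface (>= 5.6 Å from the other side, beyond any
    supported interface-water cutoff).  Neither kind can ever bridge the
    interface or touch a groove atom of the contact region, so the
    planted bridging / groove / interface-water ground truths stay exact.

    Returns (position, 'shell'|'protein'|'nucleic') placements.
    """
    from .hbond import polar_template
    prot_keys = {a.atom_key for a in ws.protein_chain.atoms()}

    def surface_anchors(side):
        out = []
        other = ws.nuc_xyz if side == "protein" else ws.prot_xyz
        for a in ws.polar_all:
            in_prot = a.atom_key in prot_keys
            if (side == "protein") != in_prot:
                continue
            tmpl = polar_template(a.res_name)
            if not tmpl or (a.name not in tmpl[0] and a.name not in tmpl[1]):
                continue
            if np.linalg.norm(other - a.xyz, axis=1).min() > _FAR_FROM_INTERFACE + 3.4:
                out.append(a)
        return out

    anchors = {s: surface_anchors(s) for s in sides}
    placements = []
    for k in range(count):
        placed = False
        # strict zero-bond interface shell water first
        for _ in range(60):
            base = ws.contact_pts[rng.integers(len(ws.contact_pts))]
            pos = base + rng.normal(scale=2.5, size=3)
            if _ok_position(pos, ws, waters, min_water=2.9) and _within_both_sides(pos, ws):
                placements.append((pos, "shell"))
                waters.append(pos)
                placed = True
                break
        if placed:
            continue
        side = sides[k % len(sides)]
        for side_try in dict.fromkeys((side,) + tuple(sides)):
            cand = anchors[side_try]
            if not cand:
                continue
            other_xyz = ws.nuc_xyz if side_try == "protein" else ws.prot_xyz
            order = rng.permutation(len(cand))
            for idx in order[:80]:
                a = cand[idx]
                for _ in range(30):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    pos = a.xyz + rng.uniform(2.6, 3.3) * v
                    if not _ok_position(pos, ws, waters, partner_keys={a.atom_key},
                                        min_water=2.9, relaxed=True):
                        continue
                    if np.linalg.norm(other_xyz - pos, axis=1).min() < _FAR_FROM_INTERFACE:
                        continue
                    placements.append((pos, side_try))
                    waters.append(pos)
                    placed = True
                    break
                if placed:
                    break
            if placed:
                break
        if not placed:
            raise GenerationError("could not place a filler water")
    return placements


def _plant_radial(rng, ws, count, radial_scale, waters, attempts=1000):
    """Waters at radial_scale x the contact radial spread from the contact
    centroid (central: inside; peripheral: outside), kept on the interface."""
    out = []
    target = radial_scale * ws.contact_spread
    e1 = ws.contact_axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    for k in range(count):
        placed = False
        for trial in range(attempts):
            # displacement biased along the principal (long) axis of the
            # contact patch, where interface room exists
            a = rng.choice([-1.0, 1.0]) * math.sqrt(0.87)
            b, cc = 0.25 * rng.normal(), 0.25 * rng.normal()
            direction = a * e1 + b * e2 + cc * e3
            direction /= np.linalg.norm(direction)
            # central waters fill the interior; peripheral ones stay on
            # the target shell
            r = target * rng.uniform(0.35, 1.0) if radial_scale <= 1.0 else target
            pos = ws.contact_centroid + r * direction + rng.normal(scale=0.8, size=3)
            # the wet/dry ground truth depends only on positions, so
            # incidental H-bonds are harmless here
            if _ok_position(pos, ws, waters, min_water=2.75, free=True) \
                    and _within_both_sides(pos, ws, any_atom=True):
                out.append(pos)
                waters.append(pos)
                placed = True
                break
        if not placed:
            raise GenerationError("could not place a radial water in 1000 attempts")
    return out


def _water_record(i, pos):
    return AtomRecord(serial=9000 + i, name="O", element="O", alt_loc="",
                      res_name="HOH", chain_id="W", res_seq=i, i_code="",
                      xyz=np.asarray(pos, dtype=float), occupancy=1.0, is_hetero=True)


_POLYMER_CACHE: dict = {}


def _groove_feasibility(prot_res, nuc_res_flat):
    """(n_major, n_minor): groove atoms with a protein polar atom in the
    water-bridgeable 3.6-6.7 Å band."""
    ppolar = np.array([xyz for rn, atoms in prot_res for n, xyz in atoms.items()
                       if n in _PROT_POLAR])
    counts = []
    for names in (_MAJOR, _MINOR):
        pts = np.array([xyz for rn, atoms in nuc_res_flat for n, xyz in atoms.items()
                        if n in names])
        if len(pts) == 0 or len(ppolar) == 0:
            counts.append(0)
            continue
        d = np.linalg.norm(pts[:, None, :] - ppolar[None, :, :], axis=2)
        counts.append(int(np.sum(np.any((d > 3.6) & (d < 6.7), axis=1))))
    return counts[0], counts[1]


def _cap_dock(prot_res, nuc_res_flat):
    """Dock the protein over the duplex end face, scanning roll about its
    long axis and offset along it for the pose that makes the most major-
    and minor-groove atoms reachable by a planted bridging water."""
    ztop = max(xyz[2] for _, atoms in nuc_res_flat for xyz in atoms.values())
    best = None
    for roll_deg in range(0, 360, 45):
        ang = math.radians(roll_deg)
        rotx = np.array([[1.0, 0.0, 0.0],
                         [0.0, math.cos(ang), -math.sin(ang)],
                         [0.0, math.sin(ang), math.cos(ang)]])
        for xoff in (-4.0, 0.0, 4.0):
            cand = [(rn, {n: rotx @ xyz + np.array([xoff, 0.0, ztop + 10.0])
                          for n, xyz in atoms.items()})
                    for rn, atoms in prot_res]
            cand = _dock(cand, nuc_res_flat, np.array([0.0, 0.0, 1.0]))
            n_maj, n_min = _groove_feasibility(cand, nuc_res_flat)
            score = (min(n_maj, n_min), n_maj + n_min)
            if best is None or score > best[0]:
                best = (score, cand)
    return best[1]


def _build_polymers(spec: GeneratorSpec):
    cap_dock = spec.n_major_contacts + spec.n_minor_contacts > 0
    key = (spec.protein_form, spec.protein_length, spec.rna_form,
           spec.rna_length, spec.nucleic_type, cap_dock)
    if key in _POLYMER_CACHE:
        return _POLYMER_CACHE[key]
    nuc = _nucleic_chains(spec.rna_form, spec.rna_length, spec.nucleic_type)
    prot_res = _center_and_align(_protein_chain(spec.protein_form, spec.protein_length))
    nuc_res_flat = [(rn, atoms) for _, strand in nuc for rn, atoms in strand]
    if key[-1]:
        # groove atoms are shielded radially by the sugar-phosphate shell;
        # dock the protein (long axis along x) over the duplex end so the
        # terminal base-pair edges are the contact face
        prot_res = [(rn, {n: np.array([xyz[2], xyz[1], xyz[0]]) for n, xyz in atoms.items()})
                    for rn, atoms in prot_res]        # long axis z -> x
        prot_res = _cap_dock(prot_res, nuc_res_flat)
    else:
        # side docking against the backbone, from +x
        prot_res = _dock(prot_res, nuc_res_flat, np.array([1.0, 0.0, 0.0]))
    serial = 0
    prot_chain, serial = _as_chain("A", prot_res, "protein", serial)
    nuc_chains = []
    for cid, strand in nuc:
        ch, serial = _as_chain(cid, strand, spec.nucleic_type, serial)
        nuc_chains.append(ch)
    _POLYMER_CACHE[key] = (prot_chain, nuc_chains)
    return prot_chain, nuc_chains


def make_complex(spec: GeneratorSpec):
    """Build one synthetic complex.

    Returns ``(pdb_text, ground_truth)`` where ground_truth records the
    planted bridging count, groove contacts, per-water H-bond partners and
    the intended wet/dry outcome (None when the mode does not force one).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    prot_chain, nuc_chains = _build_polymers(spec)
    ws = _workspace(prot_chain, nuc_chains)

    waters_xyz: list = []
    truth = {
        "seed": spec.seed,
        "n_waters": spec.n_waters,
        "n_bridging": 0,
        "n_major_contacts": 0,
        "n_minor_contacts": 0,
        "wet": None,
        "water_partners": [],
    }
    if spec.water_mode == "bridging":
        placements = _plant_bridging(
            rng, ws, spec.n_bridging_planted,
            spec.n_major_contacts, spec.n_minor_contacts, waters_xyz)
        truth["n_bridging"] = len(placements)
        n_major = n_minor = 0
        partners = []
        for pos, _pa, _na in placements:
            prot_p, nuc_p = _hbond_partners(pos, ws)
            partners.append({
                "protein": [list(a.atom_key) for a in prot_p],
                "nucleic": [list(a.atom_key) for a in nuc_p],
            })
            if spec.rna_form == "a_form_duplex":
                for a in nuc_p:
                    g = _groove_label(a.res_name, a.name)
                    if g == "major":
                        n_major += 1
                    elif g == "minor":
                        n_minor += 1
        truth["n_major_contacts"] = n_major
        truth["n_minor_contacts"] = n_minor
        truth["water_partners"] = partners
        fillers = _plant_filler(rng, ws, spec.n_waters - spec.n_bridging_planted, waters_xyz)
        truth["filler_sides"] = [side for _, side in fillers]
        truth["n_interface_waters"] = (
            truth["n_bridging"] + sum(1 for _, s in fillers if s == "shell"))
    elif spec.water_mode in ("central", "peripheral"):
        _plant_radial(rng, ws, spec.n_waters, spec.radial_scale, waters_xyz)
        truth["wet"] = spec.water_mode == "central"
    else:
        _plant_radial(rng, ws, spec.n_waters, 1.0 * spec.radial_scale, waters_xyz)

    model = ComplexModel(
        protein_side=[prot_chain],
        nucleic_side=nuc_chains,
        waters=[_water_record(i + 1, p) for i, p in enumerate(waters_xyz)],
        class_label="C_duplex" if spec.rna_form == "a_form_duplex" else "D_single_stranded",
        source_id=f"SYN{spec.seed:04d}",
    )
    pdb_text = write_pdb(model, remarks=[f"hydrna synthetic generator seed={spec.seed}"])
    return pdb_text, truth


def make_bound_unbound_pair(spec: GeneratorSpec):
    """Bound complex plus an unbound protein retaining the planted
    preserved waters (H-bonded to the same protein atoms in both files).

    Returns ``(bound_pdb, unbound_pdb, ground_truth)``.
    """
    spec.validate()
    if spec.water_mode != "bridging":
        raise ValueError("bound/unbound pairs require water_mode='bridging'")
    n_pres = spec.n_preserved_planted
    n_bridge = max(spec.n_bridging_planted, n_pres)
    base = GeneratorSpec(**{**spec.__dict__, "n_bridging_planted": n_bridge})

    rng = np.random.default_rng(spec.seed)
    prot_chain, nuc_chains = _build_polymers(base)
    ws = _workspace(prot_chain, nuc_chains)
    waters_xyz: list = []
    placements = _plant_bridging(rng, ws, n_bridge,
                                 base.n_major_contacts, base.n_minor_contacts,
                                 waters_xyz, distinct_protein=True)
    # the unbound structure keeps only the first n_pres waters, so the
    # witness set is exactly their protein partners; the remaining
    # interface waters may H-bond freely as long as they avoid those
    # witness atoms
    witness_keys = {pa.atom_key for _, pa, na in placements[:n_pres]}
    witness_xyz = np.array([pa.xyz for _, pa, na in placements[:n_pres]]) \
        if n_pres else None
    for _ in range(base.n_waters - n_bridge):
        placed = False
        for _try in range(3000):
            base_pt = ws.contact_pts[rng.integers(len(ws.contact_pts))]
            pos = base_pt + rng.normal(scale=2.5, size=3)
            # relax the water-water spacing when the pocket gets crowded
            spacing = 2.75 if _try < 1500 else 2.5
            if not (_ok_position(pos, ws, waters_xyz, min_water=spacing, free=True)
                    and _within_both_sides(pos, ws)):
                continue
            if _bridges_both_sides(pos, ws):
                continue
            if witness_xyz is not None and \
                    np.linalg.norm(witness_xyz - pos, axis=1).min() < _SAFE_POLAR:
                continue
            waters_xyz.append(pos)
            placed = True
            break
        if not placed:
            raise GenerationError("could not place a free interface water")

    waters = [_water_record(i + 1, p) for i, p in enumerate(waters_xyz)]
    bound = ComplexModel(
        protein_side=[prot_chain], nucleic_side=nuc_chains, waters=waters,
        class_label="C_duplex" if spec.rna_form == "a_form_duplex" else "D_single_stranded",
        source_id=f"SYN{spec.seed:04d}")
    bound_pdb = write_pdb(bound, remarks=[f"hydrna synthetic generator seed={spec.seed} bound"])

    # unbound: the protein alone, keeping only the first n_pres planted waters
    unbound = ComplexModel(
        protein_side=[prot_chain], nucleic_side=[],
        waters=waters[:n_pres],
        source_id=f"SYN{spec.seed:04d}U")
    unbound_pdb = write_pdb(unbound, remarks=[f"hydrna synthetic generator seed={spec.seed} unbound"])

    truth = {
        "seed": spec.seed,
        "n_waters": spec.n_waters,
        "n_interface_waters": spec.n_waters,
        "n_bridging": n_bridge,
        "n_preserved": n_pres,
        "preserved_partners": [list(pa.atom_key) for _, pa, na in placements[:n_pres]],
    }
    return bound_pdb, unbound_pdb, truth


_SEED_STEP = 7919   # deterministic seed advance on infeasible placements


def make_complex_retry(spec: GeneratorSpec, max_tries: int = 30):
    """Like :func:`make_complex`, but on an infeasible water placement
    advance the seed deterministically and try again (rejection sampling
    over seeds; the emitted PDB still records the seed actually used)."""
    from dataclasses import replace
    last = None
    for t in range(max_tries):
        try:
            return make_complex(replace(spec, seed=(spec.seed + t * _SEED_STEP) % (2**31 - 1)))
        except GenerationError as exc:
            last = exc
    raise last


def make_bound_unbound_pair_retry(spec: GeneratorSpec, max_tries: int = 30):
    """Seed-retrying variant of :func:`make_bound_unbound_pair`."""
    from dataclasses import replace
    last = None
    for t in range(max_tries):
        try:
            return make_bound_unbound_pair(
                replace(spec, seed=(spec.seed + t * _SEED_STEP) % (2**31 - 1)))
        except GenerationError as exc:
            last = exc
    raise last
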