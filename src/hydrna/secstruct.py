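"""Protein secondary structure by the Kabsch-Sander method.

Backbone H-bonds are scored with the electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   kcal/mol

between the C=O of one residue and the N-H of another, with a bond
assigned when E < -0.5 kcal/mol.  Amide hydrogens are reconstructed
geometrically (1.01 Å from N, opposite the previous residue's carbonyl
O->C direction) since X-ray structures usually lack them.  n-turns give
helix labels (G/H/I for 3_10/alpha/pi), bridge patterns give strand
labels (B for isolated bridges, E for ladders), 'T' marks remaining turn
residues, and everything else is coil.

Downstream hydration tables use the three-class collapse: 'helices'
(H, G, I), 'strands' (E, B) and 'other'.  Chain breaks (CA-CA > 4.5 Å)
terminate turn and helix propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResidueSS", "assign_ss", "collapse_class", "SS_CLASSES"]

SS_CLASSES = ("helices", "strands", "other")

_Q = 0.084 * 332.0     # kcal/mol * Å, Kabsch-Sander coupling constant
_E_CUT = -0.5
_NH_LENGTH = 1.01
_BREAK_CA = 4.5


@dataclass(frozen=True)
class ResidueSS:
    """Secondary-structure assignment for one residue."""

    residue: object
    chain_id: str
    dssp_label: str     # H G I E B T or '-' (coil)
    ss_class: str       # helices | strands | other


def collapse_class(label: str) -> str:
    if label in ("H", "G", "I"):
        return "helices"
    if label in ("E", "B"):
        return "strands"
    return "other"


def _backbone(res):
    atoms = {}
    for name in ("N", "CA", "C", "O"):
        a = res.atom(name)
        if a is None:
            return None
        atoms[name] = a.xyz
    return atoms


def _hbond_energy(don, acc, h):
    """Kabsch-Sander energy of N-H (don) ... O=C (acc)."""
    r_on = np.linalg.norm(acc["O"] - don["N"])
    r_ch = np.linalg.norm(acc["C"] - h)
    r_oh = np.linalg.norm(acc["O"] - h)
    r_cn = np.linalg.norm(acc["C"] - don["N"])
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0
    return _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_ss(chain) -> list:
    """Kabsch-Sander labels for one protein chain.

    Residues lacking any backbone atom are labelled coil; chains shorter
    than three assignable residues are entirely coil.
    """
    residues = chain.residues
    n = len(residues)
    bb = [_backbone(r) for r in residues]

    # amide H reconstruction (first residue and post-break residues have none)
    hpos = [None] * n
    breaks = set()
    for i in range(1, n):
        if bb[i] is None or bb[i - 1] is None:
            continue
        if np.linalg.norm(bb[i]["CA"] - bb[i - 1]["CA"]) > _BREAK_CA:
            breaks.add(i)
            continue
        if residues[i].res_name == "PRO":
            continue
        v = bb[i - 1]["C"] - bb[i - 1]["O"]
        hpos[i] = bb[i]["N"] + _NH_LENGTH * v / np.linalg.norm(v)

    def crosses_break(i, j):
        lo, hi = (i, j) if i < j else (j, i)
        return any(lo < b <= hi for b in breaks)

    assignable = sum(b is not None for b in bb)
    labels = ["-"] * n
    if assignable < 3:
        return [ResidueSS(r, chain.chain_id, "-", "other") for r in residues]

    # hb[i][j]: C=O of residue i accepts from N-H of residue j
    hb = [set() for _ in range(n)]
    for i in range(n):
        if bb[i] is None:
            continue
        for j in range(n):
            if abs(i - j) < 2 or bb[j] is None or hpos[j] is None:
                continue
            if _hbond_energy(bb[j], bb[i], hpos[j]) < _E_CUT:
                hb[i].add(j)

    def turn(i, k):
        return (i + k < n and (i + k) in hb[i] and not crosses_break(i, i + k))

    # helices: two consecutive n-turns start a minimal helix (alpha first)
    for k, letter in ((4, "H"), (3, "G"), (5, "I")):
        for i in range(1, n - k):
            if turn(i - 1, k) and turn(i, k):
                for j in range(i, i + k):
                    if labels[j] == "-" or (letter == "H" and labels[j] in ("G", "I", "T")):
                        labels[j] = letter

    # bridges
    def bond(i, j):  # C=O(i) ... N-H(j)
        return 0 <= i < n and 0 <= j < n and j in hb[i]

    bridge = [set() for _ in range(n)]
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (bond(i - 1, j) and bond(j, i + 1)) or (bond(j - 1, i) and bond(i, j + 1))
            anti = (bond(i, j) and bond(j, i)) or (bond(i - 1, j + 1) and bond(j - 1, i + 1))
            if para or anti:
                bridge[i].add(j)
                bridge[j].add(i)

    for i in range(n):
        if not bridge[i]:
            continue
        in_ladder = any(
            (i + 1 < n and any(abs(j2 - j) == 1 for j2 in bridge[i + 1])) or
            (i - 1 >= 0 and any(abs(j2 - j) == 1 for j2 in bridge[i - 1]))
            for j in bridge[i]
        )
        letter = "E" if in_ladder else "B"
        if labels[i] in ("-", "T", "G", "I") or letter == "E" and labels[i] == "B":
            labels[i] = letter

    # turns: residues inside an n-turn not otherwise assigned
    for k in (3, 4, 5):
        for i in range(n):
            if turn(i, k):
                for j in range(i + 1, i + k):
                    if labels[j] == "-":
                        labels[j] = "T"

    return [
        ResidueSS(r, chain.chain_id, lab if bb[i] is not None else "-",
                  collapse_class(lab if bb[i] is not None else "-"))
        for i, (r, lab) in enumerate(zip(residues, labels))
    ]
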