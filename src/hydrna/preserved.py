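"""Waters preserved between bound complexes and unbound partner structures.

An interface water of the bound complex is *preserved* when it H-bonds a
polymer donor/acceptor atom whose counterpart in an unbound structure of
the same partner is H-bonded by any water there.  Counterparts are found
by sequence, not geometry: chains are aligned globally
(Needleman-Wunsch, identity scoring), residues are mapped across
identical aligned positions, and atoms correspond by name within mapped
residues.  No structural superposition is involved, so the criterion is
invariant to rigid-body motion of the unbound structure.

When both partners have unbound forms, a water preserved against either
one counts.  By default one unbound water may witness the preservation
of several bound waters (the criterion is atom-centric); a strict
one-to-one option is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import Align

from .hbond import HBondCriteria, detect_hbonds

__all__ = ["ChainMapping", "AlignmentError", "align_chains", "preserved_waters"]

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
    "A": "a", "C": "c", "G": "g", "U": "u",
    "DA": "a", "DC": "c", "DG": "g", "DT": "t",
}


class AlignmentError(ValueError):
    """Raised when chains cannot be mapped (low identity or coverage)."""


@dataclass
class ChainMapping:
    """Residue correspondence between a bound and an unbound chain."""

    bound_chain_id: str
    unbound_chain_id: str
    residue_pairs: list          # [(bound Residue, unbound Residue), ...]
    percent_identity: float
    alignment_length: int


def _sequence(chain) -> str:
    return "".join(_ONE_LETTER.get(r.res_name, "X") for r in chain.residues)


def align_chains(bound, unbound, min_identity: float = 90.0) -> ChainMapping:
    """Map residues of two chains by global alignment.

    Needleman-Wunsch with identity scoring (+1 match / 0 mismatch, gap
    open -5, extend -1); only identical aligned residues are mapped.
    Raises :class:`AlignmentError` when identity over aligned columns
    falls below ``min_identity`` percent.
    """
    if bound.mol_type != unbound.mol_type:
        raise AlignmentError(
            f"molecule types differ: {bound.mol_type} vs {unbound.mol_type}")
    seq_b, seq_u = _sequence(bound), _sequence(unbound)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_b, seq_u)[0]
    pairs = []
    n_aligned = n_identical = 0
    for (b0, b1), (u0, u1) in zip(*aln.aligned):
        for off in range(b1 - b0):
            i, j = b0 + off, u0 + off
            n_aligned += 1
            if seq_b[i] == seq_u[j]:
                n_identical += 1
                pairs.append((bound.residues[i], unbound.residues[j]))
    identity = 100.0 * n_identical / n_aligned if n_aligned else 0.0
    if identity < min_identity:
        raise AlignmentError(
            f"chains {bound.chain_id}/{unbound.chain_id}: identity "
            f"{identity:.1f}% below the {min_identity:.0f}% threshold")
    return ChainMapping(bound.chain_id, unbound.chain_id, pairs,
                        identity, len(aln[0]))


def _water_bonded_atoms(model, criteria) -> set:
    """Keys of polymer atoms H-bonded by any water in the model."""
    out = set()
    for rec in detect_hbonds(model, criteria):
        atom = rec.polymer_atom()
        if atom is not None:
            out.add(atom.atom_key)
    return out


def preserved_waters(bound_model, interface_waters, bound_hbonds,
                     unbound_models, mappings,
                     criteria: HBondCriteria = HBondCriteria(),
                     one_to_one: bool = False) -> dict:
    """Identify the preserved interface waters of a bound complex.

    ``mappings`` is a list of lists of :class:`ChainMapping`, one list
    per unbound model, pairing bound chains with unbound chains.

    Returns ``{water atom key: [witnessing bound atom keys]}``; a bound
    water appears when at least one polymer atom it H-bonds has a mapped
    counterpart H-bonded by a water in some unbound structure.  With
    ``one_to_one``, each unbound witness atom may certify at most one
    bound water (closest-distance bound water first).
    """
    wkeys = {w.atom_key for w in interface_waters}
    # bound water -> polymer atoms it H-bonds
    bonded: dict = {}
    for rec in bound_hbonds:
        w = rec.water_atom()
        atom = rec.polymer_atom()
        if w is None or atom is None or w.atom_key not in wkeys:
            continue
        bonded.setdefault(w.atom_key, set()).add(atom.atom_key)

    # bound atom key -> mapped unbound atom key, per unbound model
    witnessed: set = set()
    for model, maps in zip(unbound_models, mappings):
        if not model.waters:
            warnings.warn(
                f"unbound structure {model.source_id or '<unnamed>'} has no "
                "waters; it cannot witness any preserved water")
            continue
        unbound_bonded = _water_bonded_atoms(model, criteria)
        for m in maps:
            for res_b, res_u in m.residue_pairs:
                for atom in res_b.atoms:
                    counterpart = (m.unbound_chain_id, res_u.res_seq,
                                   res_u.i_code, atom.name)
                    if counterpart in unbound_bonded:
                        witnessed.add(atom.atom_key)

    out = {}
    used_witnesses: set = set()
    for wkey in sorted(bonded):
        hits = sorted(k for k in bonded[wkey] if k in witnessed)
        if one_to_one:
            hits = [k for k in hits if k not in used_witnesses]
        if hits:
            out[wkey] = hits
            if one_to_one:
                used_witnesses.update(hits)
    return out
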