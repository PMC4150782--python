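"""Fixed-column PDB parsing into a two-sided complex model.

The analysis operates on crystallographic protein–RNA (or protein–DNA)
complexes deposited in PDB v3 format.  This module reads ATOM/HETATM/HOH
records into typed chains, resolves alternate locations, renames modified
residues to their standard parent codes so they are treated as polymer
(the usual curation step for structures that mark modified residues as
HETATM), partitions chains into the protein and nucleic sides of the
interface, and applies minimum chain-length filters (30 amino acids,
5 nucleotides by default).

Only the first MODEL of a multi-model file is used; the structures this
pipeline targets are X-ray structures with a single model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainModel",
    "ComplexModel",
    "ParseError",
    "FilterError",
    "DEFAULT_RESIDUE_MAP",
    "WATER_CODES",
    "STANDARD_AA",
    "RNA_CODES",
    "DNA_CODES",
    "parse_structure",
    "write_pdb",
    "classify_chain",
    "apply_length_filters",
]

#: Common modified residues renamed to their standard parent code at parse
#: time.  User-extensible via the ``residue_map`` argument / config file.
DEFAULT_RESIDUE_MAP = {
    "MSE": "MET",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "PSU": "U",
    "5MC": "C",
    "1MA": "A",
    "OMG": "G",
}

WATER_CODES = frozenset({"HOH", "WAT", "DOD"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
RNA_CODES = frozenset({"A", "C", "G", "U"})
DNA_CODES = frozenset({"DA", "DC", "DG", "DT"})


class ParseError(ValueError):
    """Raised for malformed fixed-column records (carries the line number)."""


class FilterError(ValueError):
    """Raised when chain-length filtering empties one side of the interface."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: the unit of all geometry downstream.

    ``name`` follows the PDB convention (e.g. ``O2'``, ``O1P``); ``res_seq``
    is the author residue number with ``i_code`` the insertion code.
    """

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    xyz: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def res_key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def atom_key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.i_code, self.name)


@dataclass
class Residue:
    """One residue group of atoms."""

    res_name: str
    res_seq: int
    i_code: str
    atoms: list = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.res_seq, self.i_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ChainModel:
    """A polymer chain with its inferred molecule type."""

    chain_id: str
    mol_type: str  # protein | RNA | DNA | other
    residues: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def atoms(self):
        for res in self.residues:
            yield from res.atoms


@dataclass
class ComplexModel:
    """Typed chains partitioned into the two interface sides, plus waters.

    ``waters`` holds the water oxygen atoms only; water hydrogens, when
    deposited, are kept in ``water_hydrogens`` for geometry checks but are
    never counted as waters.
    """

    protein_side: list = field(default_factory=list)
    nucleic_side: list = field(default_factory=list)
    other_chains: list = field(default_factory=list)
    waters: list = field(default_factory=list)
    water_hydrogens: list = field(default_factory=list)
    class_label: str = "unclassified"
    source_id: str = ""

    @property
    def chains(self) -> list:
        return list(self.protein_side) + list(self.nucleic_side) + list(self.other_chains)

    def polymer_atoms(self):
        for ch in self.chains:
            yield from ch.atoms()


def _parse_float(text: str, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"line {lineno}: malformed {what} field {text!r}") from None


def _guess_element(name: str, res_name: str) -> str:
    """Infer the element from the atom-name columns when column 77-78 is blank."""
    stripped = name.strip()
    if res_name in WATER_CODES:
        return "O" if stripped.startswith("O") else "H"
    for c in stripped:
        if c.isalpha():
            return c.upper()
    return stripped[:1].upper()


def parse_structure(
    pdb_text: str,
    residue_map: dict | None = None,
    water_codes=WATER_CODES,
    protein_chains: list | None = None,
    nucleic_chains: list | None = None,
    class_label: str = "unclassified",
    source_id: str = "",
) -> ComplexModel:
    """Parse fixed-column PDB text into a :class:`ComplexModel`.

    Modified residues listed in ``residue_map`` (default
    :data:`DEFAULT_RESIDUE_MAP`) are renamed to their standard code and
    treated as polymer regardless of the HETATM keyword.  Alternate
    locations are resolved to the highest-occupancy copy (ties: first in
    file order).  Only the first MODEL is read.

    Side partitioning defaults to molecule-type classification
    (:func:`classify_chain`); explicit ``protein_chains`` /
    ``nucleic_chains`` chain-id lists override it.

    Raises :class:`ParseError` for malformed coordinate fields, naming the
    offending line.
    """
    rmap = dict(DEFAULT_RESIDUE_MAP)
    if residue_map is not None:
        rmap = dict(residue_map)
    water_codes = frozenset(water_codes)

    atoms: list[AtomRecord] = []
    water_oxygens: list[AtomRecord] = []
    water_hydrogens: list[AtomRecord] = []
    n_models_seen = 0
    in_first_model = True

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            n_models_seen += 1
            if n_models_seen > 1:
                in_first_model = False
        elif rec.startswith("ENDMDL"):
            if n_models_seen >= 1:
                in_first_model = False
        if not in_first_model:
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: record too short for coordinates")
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = 0
        name = line[12:16]
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        try:
            res_seq = int(line[22:26])
        except ValueError:
            raise ParseError(f"line {lineno}: malformed residue number {line[22:26]!r}") from None
        i_code = line[26].strip()
        x = _parse_float(line[30:38], lineno, "x coordinate")
        y = _parse_float(line[38:46], lineno, "y coordinate")
        z = _parse_float(line[46:54], lineno, "z coordinate")
        occ_text = line[54:60].strip()
        occupancy = _parse_float(occ_text, lineno, "occupancy") if occ_text else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name, res_name)
        is_het = rec == "HETATM"

        mapped = rmap.get(res_name, res_name)
        renamed = mapped != res_name
        atom = AtomRecord(
            serial=serial,
            name=name.strip(),
            element=element,
            alt_loc=alt_loc,
            res_name=mapped,
            chain_id=chain_id,
            res_seq=res_seq,
            i_code=i_code,
            xyz=np.array([x, y, z], dtype=float),
            occupancy=occupancy,
            # renamed modified residues become polymer atoms
            is_hetero=is_het and not renamed,
        )
        if not np.all(np.isfinite(atom.xyz)):
            raise ParseError(f"line {lineno}: non-finite coordinates")
        if atom.res_name in water_codes:
            if atom.is_hydrogen:
                water_hydrogens.append(atom)
            else:
                water_oxygens.append(atom)
        elif atom.is_hetero and mapped not in STANDARD_AA | RNA_CODES | DNA_CODES:
            # non-water, non-polymer heteroatoms (ions, ligands): ignored
            continue
        else:
            atoms.append(atom)

    atoms = _resolve_altlocs(atoms)
    water_oxygens = _resolve_altlocs(water_oxygens)

    chains: dict[str, ChainModel] = {}
    for atom in atoms:
        ch = chains.setdefault(atom.chain_id, ChainModel(atom.chain_id, "other"))
        if ch.residues and ch.residues[-1].key == (atom.res_seq, atom.i_code) and ch.residues[-1].res_name == atom.res_name:
            ch.residues[-1].atoms.append(atom)
        else:
            ch.residues.append(Residue(atom.res_name, atom.res_seq, atom.i_code, [atom]))
    for ch in chains.values():
        ch.residues.sort(key=lambda r: (r.res_seq, r.i_code))
        ch.mol_type = classify_chain(ch)

    model = ComplexModel(class_label=class_label, source_id=source_id)
    for cid, ch in chains.items():
        if protein_chains is not None and cid in protein_chains:
            model.protein_side.append(ch)
        elif nucleic_chains is not None and cid in nucleic_chains:
            model.nucleic_side.append(ch)
        elif protein_chains is not None or nucleic_chains is not None:
            model.other_chains.append(ch)
        elif ch.mol_type == "protein":
            model.protein_side.append(ch)
        elif ch.mol_type in ("RNA", "DNA"):
            model.nucleic_side.append(ch)
        else:
            model.other_chains.append(ch)
    model.waters = water_oxygens
    model.water_hydrogens = water_hydrogens
    return model


def _resolve_altlocs(atoms: list) -> list:
    """Keep one atom per (chain, res_seq, i_code, name): highest occupancy,
    ties broken by file order.  Never increases the atom count."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = atom.atom_key
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occupancy > best[key].occupancy:
            best[key] = atom
    return [replace(best[k], alt_loc="") for k in order]


def classify_chain(chain: ChainModel) -> str:
    """Classify a chain as protein / RNA / DNA / other by residue codes.

    Protein if >80% of residues carry standard amino-acid codes; RNA if
    >80% are A/C/G/U or the chain has O2' atoms; DNA if >80% are DA/DC/DG/DT.
    Falls back to ``other``.
    """
    if not chain.residues:
        return "other"
    n = len(chain.residues)
    n_aa = sum(r.res_name in STANDARD_AA for r in chain.residues)
    n_rna = sum(r.res_name in RNA_CODES for r in chain.residues)
    n_dna = sum(r.res_name in DNA_CODES for r in chain.residues)
    has_o2p = any(r.atom("O2'") is not None for r in chain.residues)
    if n_aa / n > 0.8:
        return "protein"
    if n_rna / n > 0.8 or (n_rna + n_dna > 0 and has_o2p):
        return "RNA"
    if n_dna / n > 0.8:
        return "DNA"
    return "other"


def apply_length_filters(model: ComplexModel, min_aa: int = 30, min_nt: int = 5) -> ComplexModel:
    """Drop protein chains shorter than ``min_aa`` residues and nucleic
    chains shorter than ``min_nt`` nucleotides.

    Raises :class:`FilterError` naming the offending side if filtering
    empties either side of the interface.
    """
    kept_prot = [ch for ch in model.protein_side if len(ch) >= min_aa]
    kept_nuc = [ch for ch in model.nucleic_side if len(ch) >= min_nt]
    if model.protein_side and not kept_prot:
        raise FilterError(f"no protein chain of >= {min_aa} residues remains")
    if model.nucleic_side and not kept_nuc:
        raise FilterError(f"no nucleic chain of >= {min_nt} nucleotides remains")
    return ComplexModel(
        protein_side=kept_prot,
        nucleic_side=kept_nuc,
        other_chains=list(model.other_chains),
        waters=list(model.waters),
        water_hydrogens=list(model.water_hydrogens),
        class_label=model.class_label,
        source_id=model.source_id,
    )


def _format_atom(atom: AtomRecord, serial: int, hetero: bool) -> str:
    rec = "HETATM" if hetero else "ATOM  "
    name = atom.name
    # PDB alignment: 1-3 char names of 1-char elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    name = name.ljust(4)
    res = atom.res_name.rjust(3)
    x, y, z = atom.xyz
    return (
        f"{rec}{serial:5d} {name}{atom.alt_loc or ' '}{res} {atom.chain_id}"
        f"{atom.res_seq:4d}{atom.i_code or ' '}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element.rjust(2)}"
    )


def write_pdb(model: ComplexModel, remarks: list | None = None) -> str:
    """Serialize a model back to fixed-column PDB text (ATOM/TER/HETATM/END)."""
    lines = [f"REMARK 999 {r}" for r in (remarks or [])]
    serial = 0
    for ch in model.chains:
        for res in ch.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom(atom, serial, hetero=False))
        serial += 1
        lines.append(f"TER   {serial:5d}")
    for atom in list(model.waters) + list(model.water_hydrogens):
        serial += 1
        lines.append(_format_atom(atom, serial, hetero=True))
    lines.append("END")
    return "\n".join(lines) + "\n"
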