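"""Solvent accessible surface area by the Lee–Richards slice method.

The accessible surface is traced by the center of a spherical probe
(default radius 1.4 Å, a water molecule) rolling over the van der Waals
spheres of the heavy atoms.  Each probe-expanded sphere is cut into thin
z-slices; on every slice the arcs occluded by neighbouring spheres are
removed and the remaining arc length integrates to the accessible area
(the band area between two planes of a sphere depends only on the slice
thickness, so each slice contributes ``R * accessible_angle * dz``).

The interface area B of a complex is the accessible area buried on
association::

    B = ASA(side 1 alone) + ASA(side 2 alone) - ASA(complex)

and equals the summed per-atom ASA loss over both sides.  Atoms losing
accessible area are the interface atoms; the non-polar fraction f_np of a
side is the share of its area loss contributed by carbon atoms (the
carbon-containing groups under a group-radii scheme).  Hydrogens are
excluded throughout, as in heavy-atom crystallographic practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

__all__ = [
    "AsaResult",
    "InterfaceModel",
    "RadiusError",
    "load_radii",
    "assign_radii",
    "atom_asa",
    "interface_area",
    "nonpolar_fraction",
]


class RadiusError(ValueError):
    """Raised when an atom has no assignable radius and no fallback is given."""


_RADII_CACHE: dict | None = None


def load_radii() -> dict:
    """Load the packaged group-radii table.

    Returns ``{"name": {atom_name: r}, "element": {symbol: r}}``.
    """
    global _RADII_CACHE
    if _RADII_CACHE is None:
        table = {"name": {}, "element": {}}
        text = resources.files("hydrna").joinpath("data/radii.tsv").read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, key, radius = line.split("\t")
            table[kind][key] = float(radius)
        _RADII_CACHE = table
    return _RADII_CACHE


def assign_radii(atoms, radii: dict | None = None, fallback: float | None = None) -> np.ndarray:
    """Assign a van der Waals radius to every atom.

    Atom-name entries take precedence over element entries; an atom
    matching neither raises :class:`RadiusError` unless ``fallback`` is
    given.
    """
    table = radii if radii is not None else load_radii()
    out = np.empty(len(atoms))
    for i, atom in enumerate(atoms):
        r = table["name"].get(atom.name)
        if r is None:
            r = table["element"].get(atom.element)
        if r is None:
            r = fallback
        if r is None:
            raise RadiusError(
                f"no radius for atom {atom.name} ({atom.element}) in residue "
                f"{atom.res_name} {atom.chain_id}{atom.res_seq}"
            )
        out[i] = r
    return out


@dataclass
class AsaResult:
    """Per-atom accessible areas (Å²) and their total."""

    atoms: list
    per_atom: np.ndarray

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def by_key(self) -> dict:
        return {a.atom_key: float(v) for a, v in zip(self.atoms, self.per_atom)}


@njit(cache=True)
def _lr_slices(coords, radii, indptr, indices, dz):  # pragma: no cover - jitted
    n = coords.shape[0]
    areas = np.zeros(n)
    two_pi = 2.0 * np.pi
    for i in range(n):
        ri = radii[i]
        zi = coords[i, 2]
        nbr = indices[indptr[i]:indptr[i + 1]]
        m = nbr.shape[0]
        # slice planes through the sphere, offset by dz/2 from the pole
        nsl = int(np.ceil(2.0 * ri / dz))
        starts = np.empty(2 * m + 2)
        ends = np.empty(2 * m + 2)
        # two-point Gauss-Legendre sampling within each slice
        for ks in range(2 * nsl):
            k = ks // 2
            g = -0.2886751345948129 if ks % 2 == 0 else 0.2886751345948129
            z = zi - ri + (k + 0.5 + g) * dz
            h = z - zi
            sq = ri * ri - h * h
            if sq <= 0.0:
                continue
            r_slice = np.sqrt(sq)
            nint = 0
            buried = False
            for jj in range(m):
                j = nbr[jj]
                hj = z - coords[j, 2]
                sqj = radii[j] * radii[j] - hj * hj
                if sqj <= 0.0:
                    continue
                rj_slice = np.sqrt(sqj)
                dx = coords[j, 0] - coords[i, 0]
                dy = coords[j, 1] - coords[i, 1]
                d = np.sqrt(dx * dx + dy * dy)
                if d >= r_slice + rj_slice:
                    continue
                if d + r_slice <= rj_slice:
                    buried = True
                    break
                if d + rj_slice <= r_slice:
                    continue
                cosa = (d * d + r_slice * r_slice - rj_slice * rj_slice) / (2.0 * d * r_slice)
                if cosa > 1.0:
                    cosa = 1.0
                elif cosa < -1.0:
                    cosa = -1.0
                alpha = np.arccos(cosa)
                beta = np.arctan2(dy, dx)
                lo = beta - alpha
                hi = beta + alpha
                # normalize to [0, 2pi), splitting wrapped intervals
                while lo < 0.0:
                    lo += two_pi
                    hi += two_pi
                if hi > two_pi:
                    starts[nint] = lo
                    ends[nint] = two_pi
                    nint += 1
                    starts[nint] = 0.0
                    ends[nint] = hi - two_pi
                    nint += 1
                else:
                    starts[nint] = lo
                    ends[nint] = hi
                    nint += 1
            if buried:
                continue
            if nint == 0:
                areas[i] += 0.5 * ri * two_pi * dz
                continue
            order = np.argsort(starts[:nint])
            covered = 0.0
            cur_lo = starts[order[0]]
            cur_hi = ends[order[0]]
            for q in range(1, nint):
                s = starts[order[q]]
                e = ends[order[q]]
                if s > cur_hi:
                    covered += cur_hi - cur_lo
                    cur_lo = s
                    cur_hi = e
                elif e > cur_hi:
                    cur_hi = e
            covered += cur_hi - cur_lo
            acc = two_pi - covered
            if acc < 0.0:
                acc = 0.0
            areas[i] += 0.5 * ri * acc * dz
    return areas


def atom_asa(atoms, probe: float = 1.4, radii: dict | None = None,
             slice_spacing: float = 0.05, fallback_radius: float | None = None) -> AsaResult:
    """Per-atom accessible surface area of a set of heavy atoms.

    Hydrogens in ``atoms`` are ignored (assigned zero area).  ``radii``
    overrides the packaged group-radii table; ``slice_spacing`` is the
    z-slice thickness in Å.
    """
    heavy = [a for a in atoms if not a.is_hydrogen]
    per_atom_all = np.zeros(len(atoms))
    if heavy:
        coords = np.array([a.xyz for a in heavy], dtype=float)
        vdw = assign_radii(heavy, radii, fallback_radius)
        expanded = vdw + probe
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=2.0 * float(expanded.max()), output_type="ndarray")
        # keep only pairs whose expanded spheres intersect
        if len(pairs):
            d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            pairs = pairs[d < expanded[pairs[:, 0]] + expanded[pairs[:, 1]]]
        indptr, indices = _to_csr(len(heavy), pairs)
        per_heavy = _lr_slices(coords, expanded, indptr, indices, float(slice_spacing))
        j = 0
        for i, a in enumerate(atoms):
            if not a.is_hydrogen:
                per_atom_all[i] = per_heavy[j]
                j += 1
    return AsaResult(list(atoms), per_atom_all)


def _to_csr(n: int, pairs: np.ndarray):
    counts = np.zeros(n, dtype=np.int64)
    if len(pairs):
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)
    cursor = indptr[:-1].copy()
    for i, j in pairs:
        indices[cursor[i]] = j
        cursor[i] += 1
        indices[cursor[j]] = i
        cursor[j] += 1
    return indptr, indices


@dataclass
class InterfaceModel:
    """The buried interface: area, interface atoms, polarity, centroid.

    ``per_atom_loss`` maps atom keys of both sides to their ASA loss on
    complexation; interface atoms are those losing more than
    ``loss_threshold`` Å² (default 0.01, suppressing floating-point noise).
    The centroid is the unweighted mean of interface-atom coordinates.
    """

    B: float
    protein_interface_atoms: list
    nucleic_interface_atoms: list
    f_np_protein: float | None
    f_np_nucleic: float | None
    centroid: np.ndarray | None
    per_atom_loss: dict = field(default_factory=dict)
    loss_threshold: float = 0.01

    @property
    def interface_atoms(self) -> list:
        return list(self.protein_interface_atoms) + list(self.nucleic_interface_atoms)


def interface_area(model, probe: float = 1.4, radii: dict | None = None,
                   slice_spacing: float = 0.05, loss_threshold: float = 0.01,
                   mass_weighted_centroid: bool = False) -> InterfaceModel:
    """Interface area B by ASA subtraction, with interface atom sets.

    B = ASA(protein side alone) + ASA(nucleic side alone) − ASA(complex).
    Waters and hydrogens are excluded from all three calculations.
    """
    prot_atoms = [a for ch in model.protein_side for a in ch.atoms() if not a.is_hydrogen]
    nuc_atoms = [a for ch in model.nucleic_side for a in ch.atoms() if not a.is_hydrogen]
    if not prot_atoms or not nuc_atoms:
        raise ValueError("interface_area requires non-empty protein and nucleic sides")

    kwargs = dict(probe=probe, radii=radii, slice_spacing=slice_spacing)
    asa_prot = atom_asa(prot_atoms, **kwargs)
    asa_nuc = atom_asa(nuc_atoms, **kwargs)
    asa_cplx = atom_asa(prot_atoms + nuc_atoms, **kwargs)

    n_p = len(prot_atoms)
    loss_prot = asa_prot.per_atom - asa_cplx.per_atom[:n_p]
    loss_nuc = asa_nuc.per_atom - asa_cplx.per_atom[n_p:]
    B = float(loss_prot.sum() + loss_nuc.sum())

    iface_p = [a for a, l in zip(prot_atoms, loss_prot) if l > loss_threshold]
    iface_n = [a for a, l in zip(nuc_atoms, loss_nuc) if l > loss_threshold]
    per_atom_loss = {a.atom_key: float(l) for a, l in zip(prot_atoms, loss_prot)}
    per_atom_loss.update({a.atom_key: float(l) for a, l in zip(nuc_atoms, loss_nuc)})

    f_np_p = nonpolar_fraction(prot_atoms, dict(zip((a.atom_key for a in prot_atoms), loss_prot)))
    f_np_n = nonpolar_fraction(nuc_atoms, dict(zip((a.atom_key for a in nuc_atoms), loss_nuc)))

    iface_all = iface_p + iface_n
    if iface_all:
        coords = np.array([a.xyz for a in iface_all])
        if mass_weighted_centroid:
            masses = np.array([_MASS.get(a.element, 12.0) for a in iface_all])
            centroid = (coords * masses[:, None]).sum(axis=0) / masses.sum()
        else:
            centroid = coords.mean(axis=0)
    else:
        centroid = None
    return InterfaceModel(
        B=B,
        protein_interface_atoms=iface_p,
        nucleic_interface_atoms=iface_n,
        f_np_protein=f_np_p,
        f_np_nucleic=f_np_n,
        centroid=centroid,
        per_atom_loss=per_atom_loss,
        loss_threshold=loss_threshold,
    )


_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "S": 32.06, "SE": 78.97}


def nonpolar_fraction(side_atoms, asa_loss: dict) -> float | None:
    """Fraction of a side's buried area contributed by carbon atoms.

    Returns ``None`` when the side buries no area.
    """
    total = 0.0
    carbon = 0.0
    for a in side_atoms:
        l = float(asa_loss.get(a.atom_key, 0.0))
        if l <= 0.0:
            continue
        total += l
        if a.element == "C":
            carbon += l
    if total <= 0.0:
        return None
    return carbon / total
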