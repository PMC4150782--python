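"""Interface-water statistics: the analytical core of the pipeline.

Definitions (all configurable):

* **interface water** — a crystallographic water whose oxygen lies within
  the cutoff (default 4.5 Å) of at least one interface atom of *each*
  partner (an ``any-atom`` variant relaxes "interface atom" to "atom").
* **water-mediated H-bond** — an H-bond between an interface water and a
  polar atom of either partner; water-water H-bonds are tallied
  separately.
* **direct H-bond** — a protein-nucleic H-bond between interface atoms.
* **bridging water** — an interface water with >= 1 H-bond to polar
  groups of both partners.
* **d_r** — mean distance of the interface waters from the interface
  centroid divided by the mean distance of the interface atoms from the
  same centroid; an interface is *wet* when d_r <= 1 (waters concentrated
  inside the interface disc) and *dry* otherwise (waters pushed to the
  periphery).

Densities are reported per 1000 Å² of the interface area B.  The module
also provides the chemical-group, 2'OH, secondary-structure and groove
breakdowns of the H-bond inventory, and the one-way ANOVA / pooled
two-sample t-test used for class comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .hbond import DEFAULT_SCHEMA, GroupSchema, classify_endpoint, groove_of
from .secstruct import SS_CLASSES

__all__ = [
    "WaterProfile",
    "HydrationSummary",
    "select_interface_waters",
    "build_water_profiles",
    "compute_dr",
    "hydration_summary",
    "chemistry_table",
    "hydroxyl_stats",
    "ss_hydration",
    "groove_hydration",
    "one_way_anova",
    "two_tailed_ttest",
    "density_per_1000",
]


def density_per_1000(count: float, B: float) -> float | None:
    """Count per 1000 Å² of interface area; None when B is not positive."""
    if B is None or B <= 0:
        return None
    return 1000.0 * count / B


@dataclass
class WaterProfile:
    """Per-water H-bond bookkeeping."""

    water: object
    n_hb_protein: int = 0
    n_hb_nucleic: int = 0
    n_hb_water: int = 0
    is_interface: bool = True
    is_bridging: bool = False
    dist_to_centroid: float | None = None

    @property
    def n_hb_polymer(self) -> int:
        return self.n_hb_protein + self.n_hb_nucleic


def select_interface_waters(model, iface, cutoff: float = 4.5,
                            rule: str = "interface_atoms") -> list:
    """Interface waters: within ``cutoff`` of >= 1 atom of each partner.

    ``rule='interface_atoms'`` measures against the interface-atom sets
    (atoms losing accessible area); ``rule='any_atom'`` measures against
    all atoms of each partner.
    """
    if rule == "interface_atoms":
        prot_ref = [a.xyz for a in iface.protein_interface_atoms]
        nuc_ref = [a.xyz for a in iface.nucleic_interface_atoms]
    elif rule == "any_atom":
        prot_ref = [a.xyz for ch in model.protein_side for a in ch.atoms() if not a.is_hydrogen]
        nuc_ref = [a.xyz for ch in model.nucleic_side for a in ch.atoms() if not a.is_hydrogen]
    else:
        raise ValueError(f"unknown water-selection rule {rule!r}")
    if not prot_ref or not nuc_ref:
        return []
    prot_ref = np.array(prot_ref)
    nuc_ref = np.array(nuc_ref)
    out = []
    for w in model.waters:
        dp = np.min(np.linalg.norm(prot_ref - w.xyz, axis=1))
        dn = np.min(np.linalg.norm(nuc_ref - w.xyz, axis=1))
        if dp <= cutoff and dn <= cutoff:
            out.append(w)
    return out


def build_water_profiles(interface_waters, hbonds, centroid=None) -> list:
    """H-bond counts per interface water, with the bridging flag.

    Counts of >= 4 bonds to a partner are capped only in histogram output
    (:func:`multiplicity_histogram`); the raw counts are kept here.
    """
    keys = {w.atom_key: WaterProfile(w) for w in interface_waters}
    water_key_set = set(keys)
    for rec in hbonds:
        for me, other_atom, other_kind in (
                (rec.donor, rec.acceptor, rec.acceptor_kind),
                (rec.acceptor, rec.donor, rec.donor_kind)):
            prof = keys.get(me.atom_key)
            if prof is None or me.atom_key not in water_key_set:
                continue
            if rec.donor_kind == "water" and rec.acceptor_kind == "water":
                prof.n_hb_water += 1
            elif other_kind == "protein":
                prof.n_hb_protein += 1
            elif other_kind == "nucleic":
                prof.n_hb_nucleic += 1
    for prof in keys.values():
        prof.is_bridging = prof.n_hb_protein >= 1 and prof.n_hb_nucleic >= 1
        if centroid is not None:
            prof.dist_to_centroid = float(np.linalg.norm(prof.water.xyz - centroid))
    return list(keys.values())


def multiplicity_histogram(profiles, side: str, cap: int = 4) -> dict:
    """Histogram of per-water H-bond counts to one partner (capped at 4).

    The zero bin counts waters with no H-bond to this partner but at
    least one to the other partner.
    """
    attr = "n_hb_protein" if side == "protein" else "n_hb_nucleic"
    other = "n_hb_nucleic" if side == "protein" else "n_hb_protein"
    hist = {k: 0 for k in range(cap + 1)}
    for p in profiles:
        n = getattr(p, attr)
        if n == 0:
            if getattr(p, other) > 0:
                hist[0] += 1
            continue
        hist[min(n, cap)] += 1
    return hist


def compute_dr(interface_waters, iface):
    """The wet/dry statistic d_r and the wet flag.

    d_r = mean ||w - c|| / mean ||a - c|| over interface waters w and
    interface atoms a, with c the interface centroid.  Returns
    ``(None, None)`` when there are no interface waters.
    """
    atoms = iface.interface_atoms
    if not atoms:
        raise ValueError("interface has no interface atoms")
    if not interface_waters:
        return None, None
    c = iface.centroid
    mean_w = float(np.mean([np.linalg.norm(w.xyz - c) for w in interface_waters]))
    mean_a = float(np.mean([np.linalg.norm(a.xyz - c) for a in atoms]))
    d_r = mean_w / mean_a
    return d_r, d_r <= 1.0


def _is_direct(rec, iface_keys) -> bool:
    return (rec.kinds == frozenset({"protein", "nucleic"})
            and rec.donor.atom_key in iface_keys
            and rec.acceptor.atom_key in iface_keys)


def split_hbonds(hbonds, interface_waters, iface):
    """Partition the H-bond inventory for one complex.

    Returns ``(water_mediated, direct, water_water)`` where water-mediated
    bonds involve an interface water and a polymer atom, direct bonds join
    interface atoms of the two partners, and water_water bonds join two
    waters of which at least one is an interface water.
    """
    wkeys = {w.atom_key for w in interface_waters}
    iface_keys = {a.atom_key for a in iface.interface_atoms}
    wm, direct, ww = [], [], []
    for rec in hbonds:
        kinds = rec.kinds
        if kinds == frozenset({"water"}):
            if rec.donor.atom_key in wkeys or rec.acceptor.atom_key in wkeys:
                ww.append(rec)
        elif "water" in kinds:
            w = rec.water_atom()
            if w.atom_key in wkeys:
                wm.append(rec)
        elif _is_direct(rec, iface_keys):
            direct.append(rec)
    return wm, direct, ww


@dataclass
class HydrationSummary:
    """One summary row for one complex."""

    source_id: str
    class_label: str
    B: float
    f_np_protein: float | None
    f_np_nucleic: float | None
    n_bound_waters: int
    n_interface_waters: int
    n_wm_hbonds: int
    n_direct_hbonds: int
    n_bridging: int
    water_density: float | None
    wm_hbond_density: float | None
    bridging_density: float | None
    d_r: float | None
    wet: bool | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def hydration_summary(model, iface, profiles, hbonds) -> HydrationSummary:
    """Assemble the per-complex hydration summary row."""
    interface_waters = [p.water for p in profiles if p.is_interface]
    wm, direct, _ = split_hbonds(hbonds, interface_waters, iface)
    n_bridging = sum(p.is_bridging for p in profiles)
    d_r, wet = compute_dr(interface_waters, iface) if iface.interface_atoms else (None, None)
    B = iface.B
    return HydrationSummary(
        source_id=model.source_id,
        class_label=model.class_label,
        B=B,
        f_np_protein=iface.f_np_protein,
        f_np_nucleic=iface.f_np_nucleic,
        n_bound_waters=len(model.waters),
        n_interface_waters=len(interface_waters),
        n_wm_hbonds=len(wm),
        n_direct_hbonds=len(direct),
        n_bridging=n_bridging,
        water_density=density_per_1000(len(interface_waters), B),
        wm_hbond_density=density_per_1000(len(wm), B),
        bridging_density=density_per_1000(n_bridging, B),
        d_r=d_r,
        wet=wet,
    )


_PROTEIN_GROUPS = ("main_chain_O", "main_chain_N", "charged_side", "neutral_side")
_NUCLEIC_GROUPS = ("phosphate", "sugar", "base")
_BASE_IDENTITY = {"G": "guanine", "DG": "guanine", "A": "adenine", "DA": "adenine",
                  "C": "cytosine", "DC": "cytosine", "U": "uracil_thymine", "DT": "uracil_thymine"}


def _polymer_endpoints(rec):
    """(atom, kind) for each non-water endpoint of an H-bond."""
    out = []
    if rec.donor_kind != "water":
        out.append((rec.donor, rec.donor_kind, "donor"))
    if rec.acceptor_kind != "water":
        out.append((rec.acceptor, rec.acceptor_kind, "acceptor"))
    return out


def chemistry_table(wm_hbonds, direct_hbonds, schema: GroupSchema = DEFAULT_SCHEMA) -> dict:
    """Chemical-group composition of the H-bond inventory.

    For each of the two H-bond sets: total counts, counts with each
    partner, percentage by protein group and by nucleic group (plus
    per-base identity), and the donor/acceptor role split per group
    (role counts skip bonds whose direction is ambiguous without
    hydrogens).
    """
    out = {}
    for label, bonds in (("water_mediated", wm_hbonds), ("direct", direct_hbonds)):
        prot_counts = {g: 0 for g in _PROTEIN_GROUPS}
        nuc_counts = {g: 0 for g in _NUCLEIC_GROUPS}
        base_counts = {b: 0 for b in ("guanine", "adenine", "cytosine", "uracil_thymine")}
        roles = {}
        n_prot = n_nuc = 0
        for rec in bonds:
            for atom, kind, role in _polymer_endpoints(rec):
                group = classify_endpoint(atom, schema)
                if kind == "protein":
                    n_prot += 1
                    if group in prot_counts:
                        prot_counts[group] += 1
                else:
                    n_nuc += 1
                    if group in nuc_counts:
                        nuc_counts[group] += 1
                    if group == "base":
                        ident = _BASE_IDENTITY.get(atom.res_name)
                        if ident:
                            base_counts[ident] += 1
                if rec.donor_is_certain:
                    roles.setdefault((kind, group, role), 0)
                    roles[(kind, group, role)] += 1
        total = len(bonds)
        entry = {
            "total": total,
            "with_protein": n_prot,
            "with_nucleic": n_nuc,
            "protein_group_counts": prot_counts,
            "nucleic_group_counts": nuc_counts,
            "base_identity_counts": base_counts,
            "protein_group_pct": _pct(prot_counts, n_prot),
            "nucleic_group_pct": _pct(nuc_counts, n_nuc),
            "base_identity_pct": _pct(base_counts, n_nuc),
            "role_counts": {f"{k[0]}:{k[1]}:{k[2]}": v for k, v in sorted(roles.items())},
        }
        out[label] = entry
    return out


def _pct(counts: dict, denom: int) -> dict:
    if denom <= 0:
        return {k: 0.0 for k in counts}
    return {k: 100.0 * v / denom for k, v in counts.items()}


def hydroxyl_stats(wm_hbonds, direct_hbonds, schema: GroupSchema = DEFAULT_SCHEMA) -> dict:
    """2'OH contribution to the H-bond inventory.

    For water-mediated and direct H-bonds on the nucleic side: the overall
    count, the count with ribose-sugar oxygens, the count with the 2'OH
    itself, and the two derived percentages (with respect to all bonds on
    the nucleic side, and within the sugar moiety).
    """
    out = {}
    for label, bonds in (("water_mediated", wm_hbonds), ("direct", direct_hbonds)):
        overall = ribose = o2p = 0
        for rec in bonds:
            for atom, kind, _role in _polymer_endpoints(rec):
                if kind != "nucleic":
                    continue
                overall += 1
                group = classify_endpoint(atom, schema)
                if group == "sugar":
                    ribose += 1
                    if atom.name == "O2'":
                        o2p += 1
        out[label] = {
            "overall": overall,
            "with_ribose": ribose,
            "with_2OH": o2p,
            "pct_of_all": 100.0 * o2p / overall if overall else 0.0,
            "pct_within_sugar": 100.0 * o2p / ribose if ribose else 0.0,
        }
    return out


def ss_hydration(wm_hbonds, direct_hbonds, residue_ss, iface) -> dict:
    """H-bond density per 1000 Å² of B contributed by each protein
    secondary-structure class.

    The B contribution of a class is the summed ASA loss of its interface
    residues; its density is 1000 x (H-bonds whose protein endpoint lies
    in residues of that class) / that contribution.  A class burying no
    area has an absent (None) density.
    """
    ss_by_res = {(r.chain_id, r.residue.res_seq, r.residue.i_code): r.ss_class
                 for r in residue_ss}
    b_contrib = {c: 0.0 for c in SS_CLASSES}
    for a in iface.protein_interface_atoms:
        loss = iface.per_atom_loss.get(a.atom_key, 0.0)
        cls = ss_by_res.get(a.res_key, "other")
        b_contrib[cls] += loss

    def counts(bonds):
        c = {cls: 0 for cls in SS_CLASSES}
        for rec in bonds:
            for atom, kind, _role in _polymer_endpoints(rec):
                if kind == "protein":
                    c[ss_by_res.get(atom.res_key, "other")] += 1
        return c

    out = {"B_contribution": b_contrib}
    for label, bonds in (("water_mediated", wm_hbonds), ("direct", direct_hbonds)):
        n = counts(bonds)
        out[label] = {
            cls: (density_per_1000(n[cls], b_contrib[cls]) if b_contrib[cls] > 0 else None)
            for cls in SS_CLASSES
        }
        out[f"{label}_counts"] = n
    return out


def groove_hydration(wm_hbonds, pairs, schema: GroupSchema = DEFAULT_SCHEMA) -> dict:
    """Major/minor groove split of the water-mediated H-bonds.

    Among water-mediated H-bonds to groove-labelled atoms of
    Watson-Crick-paired bases, the percentage to major- vs minor-groove
    atoms.  Both absent when there are no groove H-bonds.
    """
    n_major = n_minor = 0
    for rec in wm_hbonds:
        for atom, kind, _role in _polymer_endpoints(rec):
            if kind != "nucleic":
                continue
            g = groove_of(atom, pairs, schema)
            if g == "major":
                n_major += 1
            elif g == "minor":
                n_minor += 1
    total = n_major + n_minor
    if total == 0:
        return {"n_major": 0, "n_minor": 0, "major_pct": None, "minor_pct": None}
    return {
        "n_major": n_major,
        "n_minor": n_minor,
        "major_pct": 100.0 * n_major / total,
        "minor_pct": 100.0 * n_minor / total,
    }


# ---------------------------------------------------------------------------
# significance tests (classic decompositions; scipy only for the
# reference distributions)

def one_way_anova(groups) -> tuple:
    """One-way fixed-effects ANOVA: (F, p).

    Classic between/within sum-of-squares decomposition; p from the F
    distribution.  Zero within-group variance with equal means gives
    F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA requires >= 2 groups with >= 2 observations each")
    all_obs = np.concatenate(groups)
    grand = all_obs.mean()
    n_total = len(all_obs)
    k = len(groups)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(_scipy_stats.f.sf(F, df_between, df_within))
    return float(F), p


def two_tailed_ttest(a, b) -> tuple:
    """Two-sample Student t-test with pooled variance: (t, p two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test requires >= 2 observations per sample")
    na, nb = len(a), len(b)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), na + nb - 2))
    return float(t), p
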