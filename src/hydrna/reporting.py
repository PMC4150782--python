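"""Pipeline orchestration, configuration and report generation.

``RunConfig`` is the single home of every tunable constant (cutoffs,
probe and slice parameters, residue map, water residue codes, chain-side
assignments, class labels).  ``analyze_complex`` executes the full stage
sequence — parse, SASA/interface, H-bonds, secondary structure,
hydration statistics — and returns a report bundle; ``run_batch``
aggregates many complexes into class-stratified tables with ANOVA and
t-test results.

Report formatting follows crystallographic-table convention: densities
to one decimal, percentages to integers, B to integer Å²; the JSON
bundles keep full precision.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import structure_io, sasa, hbond, secstruct, interface_hydration as ih

__all__ = ["RunConfig", "AnalysisBundle", "analyze_complex", "analyze_file",
           "run_batch", "cutoff_sweep", "annotate_waters_pdb"]


@dataclass
class RunConfig:
    """Every configurable constant of the pipeline, with its default."""

    water_cutoff: float = 4.5            # interface-water distance cutoff (Å)
    water_rule: str = "interface_atoms"  # or "any_atom"
    probe_radius: float = 1.4            # SASA probe (Å)
    slice_spacing: float = 0.05          # Lee-Richards z-slice (Å)
    interface_loss_threshold: float = 0.01   # Å² ASA loss for interface atoms
    hb_d_min: float = 2.4
    hb_d_max: float = 3.5
    hb_da_max_with_h: float = 3.9
    hb_ha_max: float = 2.5
    hb_dha_min_deg: float = 90.0
    wc_window: tuple = (2.5, 3.5)
    include_wobble: bool = False
    mass_weighted_centroid: bool = False
    min_aa: int = 30
    min_nt: int = 5
    apply_length_filters: bool = True
    residue_map: dict | None = None      # None -> packaged defaults
    water_codes: tuple = tuple(sorted(structure_io.WATER_CODES))
    protein_chains: list | None = None   # explicit side assignment
    nucleic_chains: list | None = None
    class_label: str = "unclassified"
    auto_class_label: bool = False       # duplex/single-strand heuristic
    radii: dict | None = None            # None -> packaged table
    fallback_radius: float | None = None

    def hb_criteria(self) -> hbond.HBondCriteria:
        return hbond.HBondCriteria(
            d_min=self.hb_d_min, d_max=self.hb_d_max,
            da_max_with_h=self.hb_da_max_with_h, ha_max=self.hb_ha_max,
            dha_min_deg=self.hb_dha_min_deg)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        import yaml
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "wc_window" in data:
            data["wc_window"] = tuple(data["wc_window"])
        return cls(**data)


@dataclass
class AnalysisBundle:
    """Everything computed for one complex."""

    model: object
    iface: object
    hbonds: list
    wm_hbonds: list
    direct_hbonds: list
    water_water_hbonds: list
    profiles: list
    interface_waters: list
    residue_ss: list
    wc_pairs: list
    summary: object
    chemistry: dict
    hydroxyl: dict
    ss_table: dict
    groove: dict

    def to_json(self) -> str:
        return json.dumps({
            "summary": self.summary.as_dict(),
            "chemistry": self.chemistry,
            "hydroxyl": self.hydroxyl,
            "secondary_structure": self.ss_table,
            "groove": self.groove,
            "n_hbonds_total": len(self.hbonds),
            "n_water_water_hbonds": len(self.water_water_hbonds),
            "n_wc_pairs": len(self.wc_pairs),
        }, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def analyze_complex(model, config: RunConfig = RunConfig()) -> AnalysisBundle:
    """Run the full hydration analysis on a parsed complex."""
    if config.apply_length_filters:
        model = structure_io.apply_length_filters(model, config.min_aa, config.min_nt)
    if not model.protein_side or not model.nucleic_side:
        raise ValueError("analysis requires both a protein side and a nucleic side")
    if config.auto_class_label and model.class_label == "unclassified":
        model.class_label = _heuristic_class(model, config)

    iface = sasa.interface_area(
        model, probe=config.probe_radius, radii=config.radii,
        slice_spacing=config.slice_spacing,
        loss_threshold=config.interface_loss_threshold,
        mass_weighted_centroid=config.mass_weighted_centroid)
    hbonds = hbond.detect_hbonds(model, config.hb_criteria())
    interface_waters = ih.select_interface_waters(
        model, iface, cutoff=config.water_cutoff, rule=config.water_rule)
    wm, direct, ww = ih.split_hbonds(hbonds, interface_waters, iface)
    profiles = ih.build_water_profiles(interface_waters, hbonds, iface.centroid)
    residue_ss = []
    for ch in model.protein_side:
        residue_ss.extend(secstruct.assign_ss(ch))
    wc_pairs = hbond.detect_wc_pairs(
        model.nucleic_side, d_window=config.wc_window,
        include_wobble=config.include_wobble)
    summary = ih.hydration_summary(model, iface, profiles, hbonds)
    bundle = AnalysisBundle(
        model=model, iface=iface, hbonds=hbonds,
        wm_hbonds=wm, direct_hbonds=direct, water_water_hbonds=ww,
        profiles=profiles, interface_waters=interface_waters,
        residue_ss=residue_ss, wc_pairs=wc_pairs, summary=summary,
        chemistry=ih.chemistry_table(wm, direct),
        hydroxyl=ih.hydroxyl_stats(wm, direct),
        ss_table=ih.ss_hydration(wm, direct, residue_ss, iface),
        groove=ih.groove_hydration(wm, wc_pairs),
    )
    return bundle


def analyze_file(path, config: RunConfig = RunConfig()) -> AnalysisBundle:
    with open(path) as fh:
        text = fh.read()
    model = structure_io.parse_structure(
        text,
        residue_map=config.residue_map,
        water_codes=frozenset(config.water_codes),
        protein_chains=config.protein_chains,
        nucleic_chains=config.nucleic_chains,
        class_label=config.class_label,
        source_id=str(path),
    )
    return analyze_complex(model, config)


def _heuristic_class(model, config) -> str:
    """Label C_duplex when >= 50% of nucleotides are WC-paired, else
    D_single_stranded.  Never overrides an explicit label."""
    pairs = hbond.detect_wc_pairs(model.nucleic_side, d_window=config.wc_window)
    n_nt = sum(len(ch) for ch in model.nucleic_side)
    if n_nt == 0:
        return "unclassified"
    return "C_duplex" if 2 * len(pairs) / n_nt >= 0.5 else "D_single_stranded"


# ---------------------------------------------------------------------------
# batch aggregation

def run_batch(bundles) -> dict:
    """Class-stratified aggregation over many analyzed complexes.

    Emits per-class means ± SD and dataset densities (computed both as
    ratio of totals and as mean of per-complex ratios), ANOVA across
    classes for interface waters / water-mediated H-bonds / bridging
    waters, and the wet-vs-dry t-test on d_r split at 1.0.
    """
    if len(bundles) < 2:
        raise ValueError("batch aggregation requires >= 2 complexes; use analyze for one")
    rows = [b.summary for b in bundles]
    classes = sorted({r.class_label for r in rows})
    by_class = {c: [r for r in rows if r.class_label == c] for c in classes}

    def agg(rs):
        B = [r.B for r in rs]
        nw = [r.n_interface_waters for r in rs]
        nh = [r.n_wm_hbonds for r in rs]
        nb = [r.n_bridging for r in rs]
        dr = [r.d_r for r in rs if r.d_r is not None]
        tot_B = sum(B)
        return {
            "n_complexes": len(rs),
            "B_mean": float(np.mean(B)), "B_sd": float(np.std(B, ddof=1)) if len(rs) > 1 else 0.0,
            "interface_waters_mean": float(np.mean(nw)),
            "interface_waters_sd": float(np.std(nw, ddof=1)) if len(rs) > 1 else 0.0,
            "wm_hbonds_mean": float(np.mean(nh)),
            "bridging_mean": float(np.mean(nb)),
            "water_density_ratio_of_totals": ih.density_per_1000(sum(nw), tot_B),
            "water_density_mean_of_ratios": float(np.mean(
                [ih.density_per_1000(a, b) for a, b in zip(nw, B) if b > 0])),
            "wm_hbond_density_ratio_of_totals": ih.density_per_1000(sum(nh), tot_B),
            "bridging_density_ratio_of_totals": ih.density_per_1000(sum(nb), tot_B),
            "d_r_mean": float(np.mean(dr)) if dr else None,
            "d_r_sd": float(np.std(dr, ddof=1)) if len(dr) > 1 else None,
            "n_wet": sum(1 for r in rs if r.wet),
        }

    report = {"classes": {c: agg(rs) for c, rs in by_class.items()},
              "all": agg(rows), "anova": {}, "ttest": {}, "warnings": []}

    eligible = {c: rs for c, rs in by_class.items() if len(rs) >= 2}
    skipped = sorted(set(by_class) - set(eligible))
    if skipped:
        report["warnings"].append(
            f"classes excluded from ANOVA (fewer than 2 members): {skipped}")
    if len(eligible) >= 2:
        for key, attr in (("interface_waters", "n_interface_waters"),
                          ("wm_hbonds", "n_wm_hbonds"),
                          ("bridging", "n_bridging")):
            F, p = ih.one_way_anova([[getattr(r, attr) for r in rs]
                                     for rs in eligible.values()])
            report["anova"][key] = {"F": F, "p": p}
    wet = [r.d_r for r in rows if r.d_r is not None and r.d_r <= 1.0]
    dry = [r.d_r for r in rows if r.d_r is not None and r.d_r > 1.0]
    if len(wet) >= 2 and len(dry) >= 2:
        t, p = ih.two_tailed_ttest(wet, dry)
        report["ttest"]["d_r_wet_vs_dry"] = {"t": t, "p": p}
    return report


def cutoff_sweep(model, config: RunConfig, cutoffs=None) -> list:
    """Interface-water counts over a range of selection cutoffs (Å)."""
    if cutoffs is None:
        cutoffs = [3.0, 3.5, 4.0, 4.5, 5.0]
    base = analyze_complex(model, config)
    out = []
    for c in cutoffs:
        waters = ih.select_interface_waters(
            base.model, base.iface, cutoff=c, rule=config.water_rule)
        out.append({"cutoff": float(c), "n_interface_waters": len(waters)})
    return out


# ---------------------------------------------------------------------------
# formatted output

def format_summary_tsv(summaries) -> str:
    """Paper-style TSV: B integer, densities 1 decimal, d_r 2 decimals."""
    cols = ["source_id", "class_label", "B", "f_np_protein", "f_np_nucleic",
            "n_bound_waters", "n_interface_waters", "n_wm_hbonds",
            "n_direct_hbonds", "n_bridging", "water_density",
            "wm_hbond_density", "bridging_density", "d_r", "wet"]
    buf = io.StringIO()
    buf.write("\t".join(cols) + "\n")
    for s in summaries:
        row = []
        for c in cols:
            v = getattr(s, c)
            if v is None:
                row.append("NA")
            elif c == "B":
                row.append(str(int(round(v))))
            elif c.startswith("f_np"):
                row.append(str(int(round(100 * v))))
            elif c.endswith("density"):
                row.append(f"{v:.1f}")
            elif c == "d_r":
                row.append(f"{v:.2f}")
            elif c == "wet":
                row.append("wet" if v else "dry")
            else:
                row.append(str(v))
        buf.write("\t".join(row) + "\n")
    return buf.getvalue()


def format_hbonds_tsv(hbonds) -> str:
    buf = io.StringIO()
    buf.write("donor_chain\tdonor_res\tdonor_atom\tacceptor_chain\tacceptor_res\t"
              "acceptor_atom\tdistance\tdonor_kind\tacceptor_kind\tcertain\n")
    for r in hbonds:
        buf.write(f"{r.donor.chain_id}\t{r.donor.res_seq}{r.donor.i_code}\t{r.donor.name}\t"
                  f"{r.acceptor.chain_id}\t{r.acceptor.res_seq}{r.acceptor.i_code}\t"
                  f"{r.acceptor.name}\t{r.da_distance:.2f}\t{r.donor_kind}\t"
                  f"{r.acceptor_kind}\t{int(r.donor_is_certain)}\n")
    return buf.getvalue()


def format_asa_tsv(asa_result) -> str:
    buf = io.StringIO()
    buf.write("chain\tresseq\tatom\tasa\n")
    for a, v in zip(asa_result.atoms, asa_result.per_atom):
        buf.write(f"{a.chain_id}\t{a.res_seq}{a.i_code}\t{a.name}\t{v:.3f}\n")
    return buf.getvalue()


def format_asa_loss_tsv(bundle) -> str:
    """Per-atom ASA loss on complexation (both sides, file order)."""
    buf = io.StringIO()
    buf.write("chain\tresseq\tatom\tasa_loss\tinterface\n")
    iface_keys = {a.atom_key for a in bundle.iface.interface_atoms}
    for a in bundle.model.polymer_atoms():
        loss = bundle.iface.per_atom_loss.get(a.atom_key)
        if loss is None:
            continue
        buf.write(f"{a.chain_id}\t{a.res_seq}{a.i_code}\t{a.name}\t{loss:.3f}\t"
                  f"{int(a.atom_key in iface_keys)}\n")
    return buf.getvalue()


def format_ss_tsv(residue_ss) -> str:
    buf = io.StringIO()
    buf.write("chain\tresseq\tdssp_label\tss_class\n")
    for r in residue_ss:
        buf.write(f"{r.chain_id}\t{r.residue.res_seq}{r.residue.i_code}\t"
                  f"{r.dssp_label}\t{r.ss_class}\n")
    return buf.getvalue()


def annotate_waters_pdb(bundle) -> str:
    """PDB passthrough with the waters' B-factor column recoded:
    bridging = 2, other interface water = 1, else 0."""
    bridging = {p.water.atom_key for p in bundle.profiles if p.is_bridging}
    interface = {w.atom_key for w in bundle.interface_waters}
    lines = []
    serial = 0
    for ch in bundle.model.chains:
        for res in ch.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(structure_io._format_atom(atom, serial, hetero=False))
    for w in bundle.model.waters:
        serial += 1
        line = structure_io._format_atom(w, serial, hetero=True)
        code = 2.0 if w.atom_key in bridging else (1.0 if w.atom_key in interface else 0.0)
        lines.append(line[:60] + f"{code:6.2f}" + line[66:])
    lines.append("END")
    return "\n".join(lines) + "\n"
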