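# hydrna — hydration analysis of protein–RNA recognition sites

Crystallographic water molecules are active participants in protein–RNA
recognition: they bridge the two partners through hydrogen bonds, fill
interface cavities, and a subset survives complex formation in place.
`hydrna` quantifies this from PDB-format structures, for structural
biologists studying protein–RNA (or protein–DNA) interfaces and for
method developers who need hydration statistics with known ground truth.

## What it computes

For a complex with a protein side and a nucleic side:

* **Interface area** `B = ASA(protein) + ASA(RNA) − ASA(complex)`, with
  per-atom solvent accessible surface areas from an authored
  Lee–Richards z-slice integrator (probe 1.4 Å, NACCESS-style group
  radii, slice 0.05 Å). Atoms losing area are the *interface atoms*;
  the non-polar fraction *f*<sub>np</sub> is the carbon share of the loss.
* **Interface waters**: water oxygens within 4.5 Å (configurable
  3.0–5.0 Å) of interface atoms of *both* partners.
* **Hydrogen bonds** by geometric criteria (donor/acceptor heavy-atom
  pair at 2.4–3.5 Å without hydrogens; D–A ≤ 3.9 Å, H–A ≤ 2.5 Å,
  D–H–A ≥ 90° with explicit hydrogens), classified by endpoint
  chemistry: protein main-chain O/N, charged and neutral side chains;
  nucleic phosphate {P, O1P, O2P}, sugar {O2′, O3′, O4′, O5′}, base —
  plus the 2′OH contribution and the major/minor-groove split over
  Watson–Crick-paired bases.
* **Bridging waters** (≥ 1 H-bond to polar groups of each partner),
  per-water H-bond multiplicity histograms, and densities per
  1000 Å² of B.
* **The wet/dry statistic**
  *d*<sub>r</sub> = ⟨‖w − c‖⟩ / ⟨‖a − c‖⟩ over interface waters *w* and
  interface atoms *a*, with *c* the interface centroid; an interface is
  *wet* when *d*<sub>r</sub> ≤ 1 (waters spread through the interface)
  and *dry* otherwise (waters pushed to the periphery).
* **Preserved waters** between a bound complex and unbound partner
  structures: a bound interface water is preserved when a polymer atom
  it H-bonds has a sequence-mapped counterpart (Needleman–Wunsch global
  alignment, ≥ 90% identity) that is H-bonded by a water in the unbound
  structure.
* Protein secondary structure by the Kabsch–Sander method, collapsed to
  helices (H/G/I), strands (E/B) and other, with per-class
  water-mediated H-bond densities.
* Batch aggregation with class-stratified tables, one-way ANOVA across
  classes and the wet-vs-dry two-sample t-test.

A first-class synthetic-structure generator (`hydrna.synthetic`) builds
ideal-geometry toy complexes with *planted* hydration ground truth —
bridging waters with known partners, groove contacts, wet/dry water
layouts, and bound/unbound pairs with known preserved waters — so every
statistic the pipeline reports can be checked exactly.

## Worked example

```
$ hydrna generate --seed 1 --out demo --n-waters 12 --n-bridging 5
wrote synthetic structure(s) to demo
$ hydrna analyze demo/complex.pdb --out demo_report
wrote report bundle to demo_report
$ hydrna sweep demo/complex.pdb --out demo_sweep
cutoff 3.0 A: 2 interface waters
cutoff 3.5 A: 5 interface waters
cutoff 4.0 A: 5 interface waters
cutoff 4.5 A: 5 interface waters
cutoff 5.0 A: 5 interface waters
```

The report bundle contains `summary.tsv` (one row per complex; this run
prints `B 61 Å², 5 interface waters, 5 bridging, 14 water-mediated and 1
direct H-bond, d_r 1.25 → dry`), per-H-bond and per-residue detail
tables, and an annotated PDB whose water B-factor column encodes
bridging (2), interface (1) or other (0) for visualization. The five
interface waters are exactly the five planted bridging waters recorded
in `demo/ground_truth.json`.

The numbered scripts under `analysis/` run the same machinery over a
24-complex synthetic cohort (duplex large/small, single-stranded, and
wet/dry reference classes) and write class-stratified hydration tables,
chemical-group and 2′OH composition, secondary-structure densities,
groove splits, preserved-water contrasts and the cutoff sweep to
`results/`. On this cohort the class ANOVA for interface-water counts
gives p ≈ 1e-6, preserved waters average 2.0 polymer H-bonds against
1.3 for the other interface waters, and strands carry the highest
water-mediated H-bond density per unit buried area.

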