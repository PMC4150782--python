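# Methods

This note records the models, conventions and numerical choices behind
`hydrna`, and what its synthetic-data tests do and do not establish
about real crystal structures.

## Structure model

PDB v3 fixed-column text is parsed into typed chains. Modified residues
named in the residue map (defaults: MSE→MET, SEP→SER, TPO→THR, PTR→TYR,
PSU→U, 5MC→C, 1MA→A, OMG→G; user-extensible) are renamed to their parent
code and treated as polymer regardless of the HETATM keyword. Alternate
locations resolve to the highest-occupancy copy, ties to the first in
file order; only the first MODEL of a multi-model file is read. Waters
(HOH/WAT/DOD) are represented by their oxygen; deposited water hydrogens
are retained for angle checks but never counted. Chains classify as
protein / RNA / DNA when > 80% of residues carry the corresponding
standard codes (an O2′ atom also marks RNA); chain-length filters
(≥ 30 aa, ≥ 5 nt) drop fragments before analysis. Non-water, non-polymer
heteroatoms (ions, ligands) are ignored. Symmetry mates are not
reconstructed: the analysis sees exactly the deposited asymmetric-unit
copy the user supplies.

## Accessible surface and interface area

Per-atom ASA uses the Lee–Richards construction: each heavy atom's
radius is expanded by the probe (default 1.4 Å), the sphere is cut into
z-slices (default 0.05 Å), and on each slice the arcs occluded by
neighbouring expanded spheres are removed by exact interval merging;
two-point Gauss–Legendre sampling inside every slice makes the totals
stable to < 0.1% between 0.2 Å and 0.05 Å spacings. Radii are
NACCESS-style group radii (C 1.87, carbonyl C 1.76, N 1.65, O 1.40,
S 1.85, P 1.90 Å), shipped as a text resource and overridable; an atom
with no radius is an error unless a fallback is configured. Hydrogens
are excluded throughout.

Interface area B is the ASA buried on association,
`ASA(side1) + ASA(side2) − ASA(complex)`, computed with waters removed.
Atoms losing more than 0.01 Å² (a float-noise threshold; the field's
definitions leave it unstated) form the interface-atom sets. The interface
centroid is the unweighted mean of interface-atom coordinates — the
"center of mass" language of the field is ambiguous, and the unweighted
choice keeps waters and heavy atoms on a common geometric footing; a
mass-weighted switch exists in the API. The non-polar fraction is the
carbon share of each side's ASA loss, following the group-radii
convention in which carbon-bonded hydrogens are absorbed into carbon.

## Hydrogen bonds

Donor/acceptor heavy atoms come from per-residue templates (protein
main-chain N/O, side-chain donors and acceptors including His N as
both, Ser/Thr/Tyr hydroxyls as both, Cys/Met sulfurs; nucleic phosphate
oxygens, sugar oxygens with O2′ as both donor and acceptor, and base
edge atoms). Without hydrogens — the usual crystallographic situation,
and always the case for waters — an H-bond is a donor/acceptor pair at
2.4–3.5 Å. With an explicit donor hydrogen the criteria become
D–A ≤ 3.9 Å, H–A ≤ 2.5 Å, D–H–A ≥ 90°. One H-bond is recorded per atom
pair; when both atoms could play either role the recorded direction is
flagged uncertain and excluded from donor/acceptor role tallies.
Residues without a template are skipped with a warning. Protonation
states are not modelled; water–water H-bonds use the same window and
are tallied separately from water–polymer ("water-mediated") bonds.

Watson–Crick pairs are complementary purine/pyrimidine pairs (G–C, A–U,
A–T; wobble G–U excluded by default, available behind a flag) whose
N1–N3 distance lies in [2.5, 3.5] Å, accepted greedily by shortest
distance with each base in at most one pair. Groove labels apply only
to paired bases: major groove N6/O6 and N7 of purines, O4/N4 of
pyrimidines; minor groove N2/N3 of purines, O2 of pyrimidines.

## Interface waters and derived statistics

An interface water lies within the cutoff (default 4.5 Å, supported
3.0–5.0 Å) of at least one *interface atom* of each partner. The
alternative any-atom reading of the selection rule is available as a
config switch; the interface-atom form is the default because it is the
more specific statement of the two the field uses. Water-mediated
H-bonds are interface-water–polymer bonds; direct H-bonds join
interface atoms of the two partners. A bridging water has ≥ 1 bond to
each side. Multiplicity histograms cap at 4 bonds per partner for
display; raw counts are retained. Densities are `1000 × count / B`.
Dataset-level densities can be computed as ratio of totals (default) or
mean of per-complex ratios; both are reported by the batch aggregator
since the field's tables do not say which convention they use.

d_r divides the mean interface-water distance from the interface
centroid by the mean interface-atom distance; d_r ≤ 1 is wet. The
statistic is scale-invariant and undefined (reported absent) for an
interface without waters.

Secondary structure follows Kabsch–Sander: backbone H-bond energy
`E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with a
bond below −0.5; amide hydrogens are rebuilt 1.01 Å from N opposite the
preceding carbonyl; n-turns give G/H/I helices (alpha first at
overlaps), bridge patterns give B/E, remaining turn residues T, and
chain breaks (CA–CA > 4.5 Å) stop pattern propagation. The hydration
tables use the three-class collapse (helices = H/G/I, strands = E/B,
other). Full DSSP bend/chirality refinements are out of scope; labels
at helix termini may differ from other implementations by a residue,
which is why an external label-import option exists. Per-class H-bond
densities divide the bonds whose protein endpoint lies in a class by
that class's summed interface-residue ASA loss.

Preserved waters: bound and unbound chains are aligned globally
(identity scoring +1/0, gap open −5, extend −1, via Biopython's
PairwiseAligner; mappings below 90% identity are rejected), residues map
across identical aligned positions, atoms by name. A bound interface
water is preserved when one of its H-bonded polymer atoms has a mapped
counterpart H-bonded by any water of an unbound structure; with both
partners unbound, the union counts. The criterion is exactly the
H-bond-partner identity — no distance tolerance on the unbound water
position and no superposition — so it is invariant to rigid motion of
the unbound structure. One unbound water may witness several bound
waters (the rule is atom-centric); a strict one-to-one option exists.
Resolution parity between bound and unbound structures is the user's
responsibility (headers are often absent, so it is not enforced).

## Significance tests

One-way ANOVA is the classic between/within sum-of-squares
decomposition with p from the F distribution; the two-sample t-test
uses the pooled variance with a two-sided p. Degenerate inputs (zero
within-group variance with equal means) return F = 0 / t = 0 with
p = 1. Both are cross-checked against scipy in the tests; classes with
fewer than two members are excluded from batch ANOVA with a warning.

## Synthetic data: what it emulates and what it does not

The generator builds ideal-geometry polymers: an α-helix (φ −57°,
ψ −47°), a two-strand sheet, or an extended coil, with a simple
ALA/SER/ARG/GLY sequence whose arginine side chains are straight
outward probes; and a duplex of planar Watson–Crick pairs (regular
polygon rings, N1–N3 2.9 Å, rise 2.81 Å, twist 32.7°) or a single
strand. The sheet form is a *parallel* two-strand ladder: exhaustive
rigid-placement scans of an ideal twisted strand against transformed
copies of itself register at most isolated bridges in antiparallel
arrangements (real antiparallel registration requires coupled strand
twist), while the parallel screw copy registers a clean ladder that
both the package and reference DSSP label E.

Water planting modes define the study conditions:

* **bridging** — each planted water is placed on the intersection
  circle 2.4–3.5 Å from one protein and one nucleic polar atom and kept
  ≥ 3.55 Å from every other polar atom, so its H-bond set is exactly
  the intended one; when the pocket is too dense, a relaxed placement
  admits extra bonds kept well inside the window (2.45–3.45 Å) and the
  ground truth is read off the constructed distances. Remaining waters
  become surface-bound waters ≥ 5.6 Å from the other partner (outside
  every supported cutoff), or occasional zero-bond interface shell
  waters where space allows. Groove-anchored specs dock the protein
  over the duplex end face (side docking buries groove atoms under the
  sugar-phosphate shell) with a cached pose scan maximizing groove-atom
  reachability.
* **central / peripheral / uniform** — waters at `radial_scale` times
  the contact patch's radial spread along its principal axis, forcing
  d_r below/above 1; study conditions use 40-aa/20-nt side-docked
  complexes (scale 0.8 wet, 1.6 dry), whose elongated two-patch
  interface leaves interior room that small point contacts lack.
* **bound/unbound pairs** — the unbound file is the protein alone
  retaining the first *k* planted waters; witness-atom exclusion keeps
  the preserved count exactly *k*.

Placement is rejection sampling; an infeasible spec raises a clean
generation error, and the `*_retry` helpers advance the seed
deterministically (step 7919) — the acceptance script and recovery
analyses use those. Identical spec and seed give byte-identical PDB
output; the seed is recorded in a REMARK.

Passing the planted-recovery tests shows the pipeline's bookkeeping is
exact under controlled geometry. It does not validate the physics of
real hydration: the toy bases are regular polygons, sugars are
schematic arms, solvation is unrefined, and interfaces are far smaller
(B of tens to hundreds of Å²) than real protein–RNA interfaces
(~2500 Å²). The worked-example checks complement this by verifying the
aggregation arithmetic against a published dataset's printed totals.

## Problem sizes

The default test run analyzes ~130 small synthetic complexes
(30–40 residue proteins, 10–20 nt strands, ≤ 24 waters); the
planted-recovery acceptance test covers 100 seeded specifications
(45 bridging, 25 groove, 20 wet/dry, 10 bound/unbound pairs) and
completes in about two minutes on one CPU. The acceptance script uses
8 bridging, 6 groove, 6 wet/dry seeds and one 24-water preserved
vignette (~30 s). These sizes are the package's chosen study
conditions; all of them scale up by passing larger `GeneratorSpec`
values.

## Known limitations

* No mmCIF input, no NMR ensembles, no symmetry-mate water handling.
* H-bond detection is geometric only (no energies, no C–H···O).
* Donor/acceptor role splits are undefined for hydrogen-free
  structures when both endpoints are amphoteric; such bonds are
  excluded from role tallies.
* The d_r centroid convention (unweighted) can differ from
  mass-weighted variants by a few percent on strongly asymmetric
  interfaces.
* DNA support covers chemistry and groove tables; fiber-accurate B-form
  geometry is not attempted by the generator.
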