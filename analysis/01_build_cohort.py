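#!/usr/bin/env python
"""Generate the synthetic study cohort.

Builds a class-stratified set of toy protein-RNA complexes: duplex-RNA
complexes of two sizes (standing in for the large-interface and
small-interface duplex classes) and single-stranded-RNA complexes, each
with planted bridging waters, plus wet/dry reference complexes.  PDB
files go to scratch/cohort/ (regenerable, not part of the deliverable);
the manifest with the planted ground truth goes to results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from hydrna.synthetic import GeneratorSpec, make_complex_retry  # noqa: E402

COHORT = []
# duplex-RNA classes: larger and smaller interfaces, bridging waters planted
for seed in range(1, 7):
    COHORT.append((GeneratorSpec(seed=seed, n_waters=14, n_bridging_planted=6,
                                 rna_length=20, protein_length=40), "C_duplex"))
for seed in range(7, 13):
    COHORT.append((GeneratorSpec(seed=seed, n_waters=8, n_bridging_planted=3,
                                 protein_form="beta_hairpin"),
                   "C_duplex_small"))
# single-stranded class
for seed in range(13, 19):
    COHORT.append((GeneratorSpec(seed=seed, n_waters=6, n_bridging_planted=3,
                                 protein_form="coil",
                                 rna_form="single_strand", rna_length=12),
                   "D_single_stranded"))
# wet / dry reference complexes for the d_r analysis
for k, seed in enumerate(range(19, 25)):
    mode, scale = (("central", 0.8) if k % 2 == 0 else ("peripheral", 1.6))
    COHORT.append((GeneratorSpec(seed=seed, n_waters=8, water_mode=mode,
                                 radial_scale=scale, rna_length=20,
                                 protein_length=40),
                   "wet_reference" if mode == "central" else "dry_reference"))


def main():
    out_dir = ROOT / "scratch" / "cohort"
    out_dir.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    manifest = []
    for spec, label in COHORT:
        pdb, truth = make_complex_retry(spec)
        name = f"{label}_{spec.seed:03d}.pdb"
        (out_dir / name).write_text(pdb)
        manifest.append({"file": str(Path("scratch/cohort") / name),
                         "class_label": label, "truth": truth,
                         "spec": spec.__dict__})
    (results / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"built {len(manifest)} complexes -> {out_dir}")
    print(f"manifest -> {results/'cohort_manifest.json'}")


if __name__ == "__main__":
    main()
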