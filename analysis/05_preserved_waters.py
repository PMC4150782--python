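#!/usr/bin/env python
"""Preserved interface waters across bound/unbound pairs.

Generates seeded bound/unbound pairs with planted preserved waters, maps
chains by global alignment, applies the same-partner-atom criterion, and
contrasts the H-bond multiplicity of preserved vs other interface waters.
"""

import json
import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from hydrna.preserved import align_chains, preserved_waters  # noqa: E402
from hydrna.reporting import analyze_complex  # noqa: E402
from hydrna.structure_io import parse_structure  # noqa: E402
from hydrna.synthetic import GeneratorSpec, make_bound_unbound_pair_retry  # noqa: E402


def main():
    rows = []
    pres_mult, other_mult = [], []
    for seed in range(1, 9):
        spec = GeneratorSpec(seed=seed, n_waters=16, n_bridging_planted=8,
                             n_preserved_planted=4, rna_length=20, protein_length=40)
        bound_pdb, unbound_pdb, truth = make_bound_unbound_pair_retry(spec)
        bm = parse_structure(bound_pdb)
        um = parse_structure(unbound_pdb)
        bundle = analyze_complex(bm)
        maps = [align_chains(bc, uc)
                for bc, uc in zip(bm.protein_side, um.protein_side)]
        pres = preserved_waters(bm, bundle.interface_waters, bundle.hbonds,
                                [um], [maps])
        by_key = {p.water.atom_key: p for p in bundle.profiles}
        pres_mult += [by_key[k].n_hb_polymer for k in pres]
        other_mult += [p.n_hb_polymer for p in bundle.profiles
                       if p.water.atom_key not in pres]
        rows.append({"seed": seed, "n_interface": len(bundle.interface_waters),
                     "n_preserved": len(pres), "planted": truth["n_preserved"],
                     "identity_pct": maps[0].percent_identity})
    out = {"pairs": rows,
           "preserved_mean_hbonds": float(np.mean(pres_mult)),
           "other_mean_hbonds": float(np.mean(other_mult))}
    (ROOT / "results" / "preserved_waters.json").write_text(json.dumps(out, indent=2))
    exact = sum(r["n_preserved"] == r["planted"] for r in rows)
    print(f"{exact}/{len(rows)} pairs recover the planted preserved count exactly")
    print(f"preserved waters make {out['preserved_mean_hbonds']:.1f} H-bonds on average "
          f"vs {out['other_mean_hbonds']:.1f} for the other interface waters")


if __name__ == "__main__":
    main()
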