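#!/usr/bin/env python
"""Chemical-group and 2'OH composition of the cohort's H-bond inventory.

Aggregates water-mediated and direct H-bonds over the cohort, tabulates
the protein (main chain O/N, charged, neutral) and nucleic (phosphate /
sugar / base) group shares, and the 2'OH contribution overall and within
the sugar moiety.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from hydrna.interface_hydration import chemistry_table, hydroxyl_stats  # noqa: E402
from hydrna.reporting import RunConfig, analyze_file  # noqa: E402


def main():
    manifest = json.loads((ROOT / "results" / "cohort_manifest.json").read_text())
    wm, direct = [], []
    for entry in manifest:
        bundle = analyze_file(ROOT / entry["file"], RunConfig(class_label=entry["class_label"]))
        wm.extend(bundle.wm_hbonds)
        direct.extend(bundle.direct_hbonds)
    chem = chemistry_table(wm, direct)
    oh = hydroxyl_stats(wm, direct)
    out = {"chemistry": chem, "hydroxyl": oh}
    (ROOT / "results" / "cohort_chemistry.json").write_text(
        json.dumps(out, indent=2, default=float))
    w = chem["water_mediated"]
    print(f"water-mediated H-bonds: {w['total']} "
          f"({w['with_nucleic']} nucleic-side, {w['with_protein']} protein-side)")
    print(f"  nucleic split (%): phosphate {w['nucleic_group_pct']['phosphate']:.0f}, "
          f"sugar {w['nucleic_group_pct']['sugar']:.0f}, base {w['nucleic_group_pct']['base']:.0f}")
    print(f"  2'OH: {oh['water_mediated']['pct_of_all']:.0f}% of water-RNA H-bonds, "
          f"{oh['water_mediated']['pct_within_sugar']:.0f}% within the sugar moiety")


if __name__ == "__main__":
    main()
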