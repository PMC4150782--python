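#!/usr/bin/env python
"""Secondary-structure hydration densities and groove preferences.

For the cohort: H-bonds per 1000 A^2 of buried area contributed by
helices / strands / non-regular structure, aggregated over complexes;
and the major/minor groove split of water-mediated H-bonds on
groove-planted duplex complexes.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from hydrna.reporting import RunConfig, analyze_file  # noqa: E402
from hydrna.structure_io import parse_structure  # noqa: E402
from hydrna.reporting import analyze_complex  # noqa: E402
from hydrna.secstruct import SS_CLASSES  # noqa: E402
from hydrna.synthetic import GeneratorSpec, make_complex_retry  # noqa: E402


def main():
    manifest = json.loads((ROOT / "results" / "cohort_manifest.json").read_text())
    b_contrib = {c: 0.0 for c in SS_CLASSES}
    wm_counts = {c: 0 for c in SS_CLASSES}
    direct_counts = {c: 0 for c in SS_CLASSES}
    for entry in manifest:
        bundle = analyze_file(ROOT / entry["file"], RunConfig(class_label=entry["class_label"]))
        ss = bundle.ss_table
        for c in SS_CLASSES:
            b_contrib[c] += ss["B_contribution"][c]
            wm_counts[c] += ss["water_mediated_counts"][c]
            direct_counts[c] += ss["direct_counts"][c]
    ss_out = {c: {"B": b_contrib[c],
                  "wm_density": 1000 * wm_counts[c] / b_contrib[c] if b_contrib[c] else None,
                  "direct_density": 1000 * direct_counts[c] / b_contrib[c] if b_contrib[c] else None}
              for c in SS_CLASSES}

    # groove split on end-cap docked duplex complexes with planted contacts
    groove_total = {"n_major": 0, "n_minor": 0}
    truth_total = {"n_major": 0, "n_minor": 0}
    for seed in (101, 102, 103, 104):
        pdb, truth = make_complex_retry(GeneratorSpec(
            seed=seed, n_waters=5, n_bridging_planted=5,
            n_major_contacts=2, n_minor_contacts=1))
        bundle = analyze_complex(parse_structure(pdb))
        groove_total["n_major"] += bundle.groove["n_major"]
        groove_total["n_minor"] += bundle.groove["n_minor"]
        truth_total["n_major"] += truth["n_major_contacts"]
        truth_total["n_minor"] += truth["n_minor_contacts"]

    out = {"secondary_structure": ss_out,
           "groove": groove_total, "groove_truth": truth_total}
    (ROOT / "results" / "cohort_ss_groove.json").write_text(
        json.dumps(out, indent=2, default=float))
    for c in SS_CLASSES:
        d = ss_out[c]["wm_density"]
        print(f"  {c:>8s}: B={b_contrib[c]:.0f} A^2, "
              f"wm density={'n/a' if d is None else f'{d:.1f}'} per 1000 A^2")
    tot = groove_total["n_major"] + groove_total["n_minor"]
    print(f"  groove split: {100*groove_total['n_major']/tot:.0f}% major / "
          f"{100*groove_total['n_minor']/tot:.0f}% minor "
          f"(planted {truth_total['n_major']}/{truth_total['n_minor']})")


if __name__ == "__main__":
    main()
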