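"""Quantify the simulated sedimentation assays through the Bradford path.

Calibrates the A594/A466 standard line, converts every total/supernatant
ratio to a concentration, computes the level 1 - [s]/[t] per replicate,
averages per condition, and reports each variant's relative change versus
the wild-type reference — the designed truth is 20% less sedimentation
for GQQ and 50% less for GEE.
"""

import json
import sys
from pathlib import Path

from galphase import (AssayMeasurement, calibrate, compare_levels,
                      ratio_to_conc)
from galphase.assay_quant import aggregate_replicates

FIXTURES = Path(__file__).resolve().parent.parent / "scratch" / "fixtures"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    std_rows = (FIXTURES / "standards.tsv").read_text().splitlines()[1:]
    line = calibrate([(float(a), float(b))
                      for a, b in (r.split("\t") for r in std_rows)])
    print(f"calibration: ratio = {line.slope:.4f} x conc + "
          f"{line.intercept:.4f} (r^2 = {line.r_squared:.5f})")

    rows = (FIXTURES / "assay.tsv").read_text().splitlines()[1:]
    by_label: dict[str, tuple[list, list]] = {}
    for r in rows:
        label, _rep, tr, sr = r.split("\t")
        by_label.setdefault(label, ([], []))
        by_label[label][0].append(ratio_to_conc(line, float(tr)))
        by_label[label][1].append(ratio_to_conc(line, float(sr)))

    levels = {}
    for label, (ts, ss) in by_label.items():
        mean, sd, n = aggregate_replicates(label, ts, ss)
        levels[label] = {"mean": mean, "sd": sd, "n": n}
        print(f"{label}: level {mean:.3f} +/- {sd:.3f} (n={n})")

    ms = [AssayMeasurement(lab, 1.0, 1.0 - v["mean"])
          for lab, v in levels.items()]
    rel = dict(compare_levels(ms, "WT"))
    for lab, change in sorted(rel.items()):
        print(f"{lab}: {100 * change:.1f}% less sedimentation than WT")

    truth = json.loads((FIXTURES / "assay_truth.json").read_text())
    (OUT / "assay_levels.json").write_text(json.dumps({
        "calibration": {"slope": line.slope, "intercept": line.intercept,
                        "r_squared": line.r_squared},
        "levels": levels,
        "relative_change_vs_WT": rel,
        "truth": truth,
    }, indent=2) + "\n")


if __name__ == "__main__":
    sys.exit(main())
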