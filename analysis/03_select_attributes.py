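#!/usr/bin/env python
"""Attribute-importance ranking by repeated correlation-based selection.

Restricts the simulated angle table to the angles that passed the
dimorphism filter, runs CFS + best-first subset search on the training side
of each of 10 x 5 stratified partitions, and writes per-angle selection
frequencies (attribute importance) and the thresholded subsets to
results/attribute_importance.csv / .json.  Frontal and upper-midface angles
(n-g-m, n-m-FH, fmo-n-fmo, nm-rhi-nm) dominate the top of the ranking on
reference-calibrated data.
"""

import argparse
import json
from pathlib import Path

from cranangles.dimorphism import dimorphism_report
from cranangles.geometry import AngleTable
from cranangles.selection import repeated_selection

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="input_path",
                        default=ROOT / "results" / "data" / "angles.csv")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    table = AngleTable.from_csv(args.input_path)
    significant = dimorphism_report(table).significant_codes()
    ai = repeated_selection(table.frame[significant], table.sex, seed=args.seed)

    out_dir = ROOT / "results"
    ai.to_frame().sort_values("frequency", ascending=False).to_csv(
        out_dir / "attribute_importance.csv")
    (out_dir / "attribute_importance.json").write_text(json.dumps(
        {"total_runs": ai.total_runs, "subsets": ai.subsets}, indent=1),
        encoding="utf-8")
    top = ai.frequencies.sort_values(ascending=False).head(6)
    print(f"selection over {ai.total_runs} runs on {len(significant)} "
          f"significant angles; top attributes:")
    for code, freq in top.items():
        print(f"  {code:16s} AI = {freq:.2f}")


if __name__ == "__main__":
    main()
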