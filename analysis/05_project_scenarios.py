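#!/usr/bin/env python
"""Stage 5 — 2040 scenario projection and range-shift summary.

Applies the shared climate signal (annual precipitation -10%, annual mean
temperature +1.5 degC) plus four scenario-specific synthetic landcover
trends (Eucalyptus held constant), re-maps favourability at the training
prevalence, and summarizes the shift: percentage of favourable cells per
scenario, the chi-squared homogeneity test across scenarios, and counts of
highly favourable cells (F > 0.75) in the southern third of the grid.
"""

import argparse
import json
import pickle
from pathlib import Path

import numpy as np

from racbrt import apply_scenario, make_map, project, summarize_shift
from racbrt.io import read_cell_table
from racbrt.run import default_scenarios


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cells", type=Path, default=Path("scratch/analysis/cells.csv"))
    ap.add_argument("--model", type=Path, default=Path("scratch/analysis/best_model.pkl"))
    ap.add_argument("--out", type=Path, default=Path("scratch/analysis"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cells = read_cell_table(args.cells)
    with open(args.model, "rb") as fh:
        result = pickle.load(fh)
    sampled = cells[cells["sampled"].astype(bool)]
    n1 = int(sampled["presence"].sum())
    n0 = len(sampled) - n1

    baseline = make_map(result, cells, n1, n0, model_id="baseline")
    maps = {}
    for scn in default_scenarios():
        maps[scn.name] = project(result, apply_scenario(cells, scn), n1, n0,
                                 model_id=scn.name)

    south = cells.index[cells["row"] > cells["row"].max() * 2 // 3]
    shift = summarize_shift(baseline, maps, region_mask=south)
    (args.out / "scenario_shift.json").write_text(
        json.dumps(shift.__dict__, indent=2, default=float) + "\n"
    )

    print(f"baseline: {shift.pct_favourable_baseline:.2f}% of cells favourable (F >= 0.5)")
    for name, pct in shift.pct_favourable_per_scenario.items():
        print(f"  {name}: {pct:.2f}%")
    print(f"mean change: {shift.mean_increase:+.2f} percentage points "
          f"(chi2 = {shift.chi2:.3f}, df = {shift.chi2_df}, p = {shift.p:.3f})")
    print("highly favourable cells (F > 0.75) in the southern third:")
    for name, count in shift.region_counts_F075.items():
        print(f"  {name}: {count}")
    print(f"wrote {args.out / 'scenario_shift.json'}")


if __name__ == "__main__":
    main()
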