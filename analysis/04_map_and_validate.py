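#!/usr/bin/env python
"""Stage 4 — grid-wide predictability and favourability maps, plus
validation against an independent presence set.

The best RAC-BRT model predicts every cell of the grid (non-sampled cells
receive the mean RAC of the sampled cells); predictions are transformed to
favourability at the training prevalence (n1 presences, n0 absences).
Validation draws an independent set of occupied, unsurveyed cells from the
synthetic truth and reports the favourable and near-threshold percentages.
"""

import argparse
import pickle
from pathlib import Path

import numpy as np

from racbrt import classify_favourable, make_map, validate_independent
from racbrt.io import export_raster, read_cell_table
from racbrt.run import stage_seed


def _grid_from_cells(cells, cell_size_km=5.0):
    from racbrt import generate_grid

    n_rows = int(cells["row"].max()) + 1
    n_cols = int(cells["col"].max()) + 1
    mask = np.zeros((n_rows, n_cols), bool)
    mask[cells["row"].to_numpy(int), cells["col"].to_numpy(int)] = True
    return generate_grid(n_rows, n_cols, cell_size_km, mask)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cells", type=Path, default=Path("scratch/analysis/cells.csv"))
    ap.add_argument("--model", type=Path, default=Path("scratch/analysis/best_model.pkl"))
    ap.add_argument("--out", type=Path, default=Path("scratch/analysis"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-validation", type=int, default=68)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cells = read_cell_table(args.cells)
    with open(args.model, "rb") as fh:
        result = pickle.load(fh)
    sampled = cells[cells["sampled"].astype(bool)]
    n1 = int(sampled["presence"].sum())
    n0 = len(sampled) - n1

    fmap = make_map(result, cells, n1, n0, model_id=result.hypothesis.name)
    fmap.to_frame().rename_axis("cell_id").to_csv(args.out / "favourability.csv")
    grid = _grid_from_cells(cells)
    export_raster(grid, fmap.P, args.out / "predictability.tif")
    export_raster(grid, fmap.F, args.out / "favourability.tif")

    counts = classify_favourable(fmap.F)
    print(f"model {result.hypothesis.name}: prevalence {n1}/{n1 + n0} "
          f"({n1 / (n1 + n0):.1%})")
    for thr, rec in sorted(counts.items()):
        print(f"  cells with F >= {thr:.2f}: {rec['count']} "
              f"({rec['count'] / len(fmap.F):.1%} of the grid)")

    rng = np.random.default_rng(stage_seed(args.seed, "validation"))
    pool = cells.index[(cells["occupied"] == 1) & ~cells["sampled"].astype(bool)]
    test = rng.choice(pool, size=min(args.n_validation, len(pool)), replace=False)
    rep = validate_independent(fmap, test)
    print(f"independent validation on {rep.n_test_cells} occupied unsurveyed cells:")
    print(f"  favourable (F >= 0.50): {rep.n_favourable} ({rep.pct_favourable:.1f}%)")
    print(f"  near threshold (0.45 <= F < 0.50): {rep.n_near_threshold} "
          f"(cumulative {rep.pct_with_near:.1f}%)")
    print(f"  false negatives: {rep.false_negative_pct:.1f}%")


if __name__ == "__main__":
    main()
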