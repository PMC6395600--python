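"""End-to-end orchestration: simulate -> screen -> fit H1..H5 -> map ->
validate -> project, with a machine-readable manifest.

One global seed fans out to per-stage seeds by stable hashing of stage
names, so stages are reproducible independently and the whole run is
bit-for-bit deterministic at the serialization level.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .brt import BRTConfig
from .favour import make_map, validate_independent
from .grids import generate_grid, portugal_like_mask
from .pipeline import (
    HypothesisSpec,
    PipelineConfig,
    RAC_NAME,
    compare_hypotheses,
    desk_scale_config,
    fit_hypothesis,
    select_hybrid_variables,
)
from .registry import HYPOTHESIS_GROUPS, default_covariate_specs
from .scenarios import Scenario, apply_scenario, climate_2040_rules, project, summarize_shift
from .spatial import build_weights
from .synth import default_response_spec, design_survey, simulate_covariates, simulate_presence

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "default_scenarios"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Settings of one synthetic end-to-end run."""

    seed: int = 0
    out_dir: str = "scratch/run"
    n_rows_10km: int = 33
    n_cols_10km: int = 30
    mask: str = "portugal_like"  # or "none"
    n_blocks: int | None = 136
    covariates: list | None = None  # CovariateSpec list; default registry
    hypotheses: dict | None = None  # name -> variable list; default registry
    pipeline: PipelineConfig | None = None
    weights_scheme: str = "queen"
    n_validation_cells: int = 68
    scenarios: list | None = None  # Scenario list; default 2040 set

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pipe = raw.pop("pipeline", None)
        fixed = None
        if pipe and "fixed_config" in pipe:
            fixed = BRTConfig(**pipe.pop("fixed_config"))
        cfg = cls(**raw)
        if pipe is not None:
            cfg.pipeline = PipelineConfig(
                **{**pipe, "fixed_config": fixed,
                   **({"seed": cfg.seed} if "seed" not in pipe else {})}
            )
        return cfg


def default_scenarios() -> list[Scenario]:
    """Four named 2040 scenarios: one shared climate signal (precipitation
    -10%, temperature +1.5 degC) plus scenario-specific synthetic landcover
    trends in shrubland and herbaceous cover; Eucalyptus frozen."""
    trends = {
        "A1_2040": {"Shrublands": 0.90, "Herbaceous": 1.10},
        "A2_2040": {"Shrublands": 1.05, "Herbaceous": 0.95},
        "B1_2040": {"Shrublands": 1.10, "Herbaceous": 1.05},
        "B2_2040": {"Shrublands": 1.15, "Herbaceous": 1.10},
    }
    out = []
    for name, t in trends.items():
        lc = {var: (lambda col, f=f: (col * f).clip(upper=100)) for var, f in t.items()}
        out.append(Scenario(name, climate_rules=climate_2040_rules(), landcover_rules=lc))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Writes the cell table, VIF log, per-hypothesis influence tables, the
    hypothesis ranking, predictability/favourability maps (CSV + TIFF), the
    independent-validation report, the scenario shift summary, a stage-timing
    log, and ``manifest.json`` hashing every artifact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: list[Path] = []

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    # --- simulate -----------------------------------------------------
    with stage("simulate"):
        mask = portugal_like_mask(config.n_rows_10km, config.n_cols_10km) \
            if config.mask == "portugal_like" else None
        grid10 = generate_grid(config.n_rows_10km, config.n_cols_10km, 10.0, mask)
        design, grid5 = design_survey(
            grid10, seed=stage_seed(config.seed, "survey"), n_blocks=config.n_blocks
        )
        specs = config.covariates or default_covariate_specs()
        cov = simulate_covariates(grid5, specs, seed=stage_seed(config.seed, "covariates"))
        response = default_response_spec()
        have = set(cov.columns)
        response = type(response)(
            effects={k: v for k, v in response.effects.items() if k in have},
            intercept=response.intercept,
            target_prevalence=response.target_prevalence,
            spatial_noise_sd=response.spatial_noise_sd,
            spatial_noise_range_cells=response.spatial_noise_range_cells,
            detection_prob_per_transect=response.detection_prob_per_transect,
        )
        pres, info = simulate_presence(
            grid5, cov, response, design, seed=stage_seed(config.seed, "presence")
        )
        cells = cov.join(pres)
        artifacts.append(rio.write_cell_table(cells.rename_axis("cell_id"), out / "cells.csv"))

    # --- fit hypotheses ----------------------------------------------
    with stage("fit"):
        weights = build_weights(grid5, scheme=config.weights_scheme)
        pipe = config.pipeline or desk_scale_config(seed=config.seed)
        groups = config.hypotheses or {
            h: [v for v in vs if v in cells.columns]
            for h, vs in HYPOTHESIS_GROUPS.items()
        }
        groups = {h: vs for h, vs in groups.items() if vs}
        results = {}
        for name, vars_ in groups.items():
            results[name] = fit_hypothesis(
                HypothesisSpec(name, tuple(vars_)), cells, weights, pipe
            )
        hybrid = select_hybrid_variables(results)
        results["H5"] = fit_hypothesis(
            HypothesisSpec("H5", tuple(hybrid), "hybrid"), cells, weights, pipe
        )
        vif_log = pd.concat(
            [r.vif_report.to_frame().assign(hypothesis=h) for h, r in results.items()],
            ignore_index=True,
        )
        vif_path = out / "vif_log.csv"
        vif_log.to_csv(vif_path, index=False)
        artifacts.append(vif_path)
        for name, res in results.items():
            p = out / f"influences_{name}.csv"
            res.final_model.relative_influence.rename("influence_pct").to_csv(p)
            artifacts.append(p)
        ranking = compare_hypotheses(results)
        moran_cols = []
        for name in ranking["hypothesis"]:
            m = results[name].residual_moran
            moran_cols.append(m.p_value if m else np.nan)
        ranking["residual_moran_p"] = moran_cols
        rank_path = out / "hypotheses.csv"
        ranking.to_csv(rank_path, index=False)
        artifacts.append(rank_path)
        best_name = ranking.loc[0, "hypothesis"]
        best = results[best_name]

    # --- map ----------------------------------------------------------
    with stage("map"):
        sampled = cells.loc[cells["sampled"]]
        n1 = int(sampled["presence"].sum())
        n0 = int(len(sampled) - n1)
        fmap = make_map(best, cells, n1, n0, model_id=best_name)
        map_path = out / "favourability.csv"
        fmap.to_frame().rename_axis("cell_id").pipe(
            lambda t: t.assign(row=cells["row"], col=cells["col"])
        ).to_csv(map_path)
        artifacts.append(map_path)
        artifacts.append(rio.export_raster(grid5, fmap.P, out / "predictability.tif"))
        artifacts.append(rio.export_raster(grid5, fmap.F, out / "favourability.tif"))

    # --- validate -----------------------------------------------------
    with stage("validate"):
        rng = np.random.default_rng(stage_seed(config.seed, "validation"))
        occupied = cells.index[(cells["occupied"] == 1) & ~cells["sampled"]]
        n_test = min(config.n_validation_cells, len(occupied))
        test_cells = rng.choice(occupied, size=n_test, replace=False)
        report = validate_independent(fmap, test_cells)
        val_path = out / "validation.json"
        val_path.write_text(json.dumps(report.__dict__, indent=2) + "\n")
        artifacts.append(val_path)

    # --- project ------------------------------------------------------
    with stage("project"):
        scenario_maps = {}
        for scn in config.scenarios or default_scenarios():
            cov2 = apply_scenario(cells, scn)
            scenario_maps[scn.name] = project(best, cov2, n1, n0, model_id=scn.name)
        south = cells.index[cells["row"] > grid5.n_rows * 2 // 3]
        shift = summarize_shift(fmap, scenario_maps, region_mask=south)
        shift_path = out / "scenario_shift.json"
        shift_path.write_text(
            json.dumps(
                {k: v for k, v in shift.__dict__.items()}, indent=2, default=float
            )
            + "\n"
        )
        artifacts.append(shift_path)

    # --- report -------------------------------------------------------
    with stage("report"):
        (out / "run.log").write_text(
            "".join(f"{k}: {v:.3f}s\n" for k, v in timings.items())
        )
        manifest = {
            "seed": config.seed,
            "prevalence_observed": info["observed_prevalence"],
            "n_sampled_cells": int(cells["sampled"].sum()),
            "best_hypothesis": str(best_name),
            "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
            "timings": timings,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
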