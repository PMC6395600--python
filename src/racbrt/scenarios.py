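"""Scenario projection: perturb covariates, re-map favourability, and
summarize the range shift.

Climate rules are cell-wise multiplicative or additive deltas (the default
2040 climate signal is -10% annual precipitation and +1.5 degC annual mean
temperature); landcover rules replace a column outright (e.g. with a
regrouped external scenario layer) or remap it through a callable. Frozen
variables (Eucalyptus by default: its cover is legally capped) are asserted
untouched. Projection always reuses the training prevalence (n1, n0), so
favourability shifts reflect changed conditions, not a changed baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .favour import FavourabilityMap, make_map
from .pipeline import RACBRTResult

__all__ = [
    "Scenario",
    "ShiftSummary",
    "climate_2040_rules",
    "apply_scenario",
    "project",
    "summarize_shift",
]


def climate_2040_rules() -> dict:
    """Default 2040 climate deltas: precipitation -10%, temperature +1.5 degC."""
    return {"Ann_Prec": ("mul", 0.90), "Ann_Temp": ("add", 1.5)}


@dataclass(frozen=True)
class Scenario:
    """A named set of covariate-change rules.

    ``climate_rules``: variable -> ("mul"|"add", delta).
    ``landcover_rules``: variable -> replacement Series (cell_id-indexed) or
    a callable applied to the existing column.
    ``frozen_variables`` must not appear in any rule and are left bit-identical.
    """

    name: str
    climate_rules: dict = field(default_factory=dict)
    landcover_rules: dict = field(default_factory=dict)
    frozen_variables: tuple = ("Eucalyptus",)

    def __post_init__(self) -> None:
        ruled = list(self.climate_rules) + list(self.landcover_rules)
        if len(ruled) != len(set(ruled)):
            raise ValueError(f"{self.name}: a variable appears in more than one rule")
        clash = set(ruled) & set(self.frozen_variables)
        if clash:
            raise ValueError(f"{self.name}: frozen variables have rules: {sorted(clash)}")


def apply_scenario(covariates: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Return a modified copy of the covariate table under the scenario."""
    for var in list(scenario.climate_rules) + list(scenario.landcover_rules):
        if var not in covariates.columns:
            raise KeyError(f"{scenario.name}: rule for unknown variable {var!r}")
    out = covariates.copy()
    for var, (kind, delta) in scenario.climate_rules.items():
        if kind == "mul":
            out[var] = out[var] * delta
        elif kind == "add":
            out[var] = out[var] + delta
        else:
            raise ValueError(f"{scenario.name}: unknown rule kind {kind!r}")
    for var, rule in scenario.landcover_rules.items():
        if callable(rule):
            out[var] = rule(out[var])
        else:
            out[var] = pd.Series(rule).reindex(out.index)
    for var in scenario.frozen_variables:
        if var in covariates.columns and not out[var].equals(covariates[var]):
            raise AssertionError(f"{scenario.name}: frozen variable {var!r} changed")
    return out


def project(
    result: RACBRTResult,
    scenario_covariates: pd.DataFrame,
    n1: int,
    n0: int,
    rac_policy: str = "mean",
    model_id: str = "",
) -> FavourabilityMap:
    """Favourability map under scenario covariates, at training prevalence."""
    return make_map(result, scenario_covariates, n1, n0, model_id, rac_policy)


@dataclass
class ShiftSummary:
    pct_favourable_baseline: float
    pct_favourable_per_scenario: dict
    mean_increase: float  # percentage points vs baseline
    chi2: float
    chi2_df: int
    p: float
    region_counts_F075: dict | None = None  # baseline + per-scenario counts
    region_mean_F: dict | None = None


def summarize_shift(
    baseline_map: FavourabilityMap,
    scenario_maps: dict[str, FavourabilityMap],
    region_mask=None,
    favourable_threshold: float = 0.5,
    high_threshold: float = 0.75,
) -> ShiftSummary:
    """Before/after favourability statistics.

    Reports the percentage of cells at F >= 0.5 for the baseline and each
    scenario, the mean increase over scenarios (percentage points), and a
    chi-squared homogeneity test of favourable/unfavourable counts across
    the scenario maps (df = n_scenarios - 1). With ``region_mask`` (an
    index/list of cell ids) also reports counts at F > 0.75 and mean F
    inside the region, baseline included.
    """
    base_ids = baseline_map.F.index
    for name, m in scenario_maps.items():
        if not m.F.index.equals(base_ids):
            raise ValueError(f"scenario {name!r} map is not grid-aligned with baseline")

    def pct_fav(m):
        return 100 * float((m.F >= favourable_threshold).mean())

    base_pct = pct_fav(baseline_map)
    per_scn = {name: pct_fav(m) for name, m in scenario_maps.items()}
    mean_increase = float(np.mean(list(per_scn.values())) - base_pct)

    counts = np.array(
        [
            [
                int((m.F >= favourable_threshold).sum()),
                int((m.F < favourable_threshold).sum()),
            ]
            for m in scenario_maps.values()
        ]
    )
    if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0 or len(counts) < 2:
        chi2, p, df = 0.0, 1.0, max(len(counts) - 1, 0)
    else:
        chi2, p, df, _ = stats.chi2_contingency(counts)
    region_counts = region_means = None
    if region_mask is not None:
        ids = pd.Index(region_mask)
        region_counts = {"baseline": int((baseline_map.F.loc[ids] > high_threshold).sum())}
        region_means = {"baseline": float(baseline_map.F.loc[ids].mean())}
        for name, m in scenario_maps.items():
            region_counts[name] = int((m.F.loc[ids] > high_threshold).sum())
            region_means[name] = float(m.F.loc[ids].mean())
    return ShiftSummary(
        base_pct, per_scn, mean_increase, float(chi2), int(df), float(p),
        region_counts, region_means,
    )
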