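"""Grid-wide prediction, the favourability transform, and validation.

Predicted probability P depends on the prevalence of the training data; the
favourability transform removes that dependence by expressing each cell's
odds relative to the overall presence/absence odds n1/n0:

    F = (P / (1 - P)) / (n1/n0 + P / (1 - P))

so F = 0.5 exactly where P equals the prevalence n1/(n1+n0), making cells
comparable across models and time slices. Favourable cells are F >= 0.50
(the boundary is included by convention throughout this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import RAC_NAME, RACBRTResult

__all__ = [
    "FavourabilityMap",
    "ValidationReport",
    "predict_grid",
    "make_map",
    "favourability",
    "classify_favourable",
    "validate_independent",
]


@dataclass
class FavourabilityMap:
    P: pd.Series  # predicted probability per cell_id
    F: pd.Series  # favourability per cell_id
    n1: int
    n0: int
    model_id: str = ""

    @property
    def prevalence(self) -> float:
        return self.n1 / (self.n1 + self.n0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"P": self.P, "F": self.F})


def predict_grid(
    result: RACBRTResult,
    covariates_all_cells: pd.DataFrame,
    rac_policy: str = "mean",
) -> pd.Series:
    """Predicted probability for every cell of the grid.

    Sampled cells use their own RAC value; non-sampled cells get the mean
    RAC over sampled cells (``mean`` policy, the default: residuals of a
    calibrated model average out near zero) or their neighbourhood RAC as
    computed from sampled neighbours (``neighbourhood``).
    """
    model = result.final_model
    needed = [v for v in model.variables if v != RAC_NAME]
    missing = [v for v in needed if v not in covariates_all_cells.columns]
    if missing:
        raise KeyError(f"missing covariate columns: {missing}")
    X = covariates_all_cells.copy()
    if RAC_NAME in model.variables:
        rac_all = result.rac.values  # neighbourhood RAC for every grid cell
        sampled = X.index.intersection(result.training_index)
        unsampled = X.index.difference(sampled)
        rac_col = pd.Series(np.nan, index=X.index, dtype=float)
        rac_col.loc[sampled] = rac_all.reindex(sampled)
        if rac_policy == "mean":
            rac_col.loc[unsampled] = rac_all.reindex(sampled).mean()
        elif rac_policy == "neighbourhood":
            rac_col.loc[unsampled] = rac_all.reindex(unsampled)
        else:
            raise ValueError(f"unknown rac_policy {rac_policy!r}")
        X[RAC_NAME] = rac_col.fillna(rac_all.mean())
    p = pd.Series(model.predict_proba(X), index=X.index, name="P")
    return p.clip(0.0, 1.0)


def make_map(
    result: RACBRTResult,
    covariates_all_cells: pd.DataFrame,
    n1: int,
    n0: int,
    model_id: str = "",
    rac_policy: str = "mean",
) -> FavourabilityMap:
    """Predict the grid and wrap P and F into a :class:`FavourabilityMap`."""
    P = predict_grid(result, covariates_all_cells, rac_policy=rac_policy)
    F = pd.Series(favourability(P.to_numpy(), n1, n0), index=P.index, name="F")
    return FavourabilityMap(P, F, n1, n0, model_id)


def favourability(P, n1: int, n0: int):
    """Prevalence-corrected favourability of predicted probability P."""
    if n1 <= 0 or n0 <= 0:
        raise ValueError("need at least one presence and one absence")
    P = np.asarray(P, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("P must lie in [0, 1]")
    ratio = n1 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = P / (1 - P)
        F = np.where(P >= 1.0, 1.0, odds / (ratio + odds))
    return F if F.ndim else float(F)


def classify_favourable(F: pd.Series, thresholds=(0.5, 0.75, 0.45)) -> dict:
    """Boolean layer and count per threshold (favourable means F >= t)."""
    out = {}
    for t in thresholds:
        layer = F >= t
        out[t] = {"layer": layer, "count": int(layer.sum())}
    return out


@dataclass(frozen=True)
class ValidationReport:
    n_test_cells: int
    n_favourable: int  # F >= 0.50
    n_near_threshold: int  # 0.45 <= F < 0.50
    pct_favourable: float
    pct_with_near: float
    false_negative_pct: float


def validate_independent(fav_map: FavourabilityMap, presence_cells) -> ValidationReport:
    """Score the map against an independent set of confirmed-presence cells.

    Counts test cells at F >= 0.50 (favourable) and in the near-threshold
    band 0.45 <= F < 0.50; the false-negative percentage is the complement
    of the favourable percentage.
    """
    ids = pd.Index(np.unique(np.asarray(list(presence_cells))))
    if len(ids) == 0:
        raise ValueError("empty presence set")
    F = fav_map.F.reindex(ids).dropna()
    n = len(F)
    n_fav = int((F >= 0.50).sum())
    n_near = int(((F >= 0.45) & (F < 0.50)).sum())
    pct_fav = 100 * n_fav / n
    pct_with_near = 100 * (n_fav + n_near) / n
    return ValidationReport(n, n_fav, n_near, pct_fav, pct_with_near, 100 - pct_fav)
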