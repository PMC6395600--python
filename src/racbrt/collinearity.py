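"""Iterative variance-inflation-factor (VIF) screening.

VIF(x_k) = 1 / (1 - R^2) from the least-squares regression of x_k on the
remaining covariates (with intercept). Screening removes the single worst
offender per round and recomputes until every retained variable satisfies
VIF <= threshold (default 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VIFReport", "vif", "iterative_vif_filter"]

_R2_PERFECT = 1 - 1e-12


@dataclass
class VIFReport:
    rounds: list = field(default_factory=list)  # list of {variable: vif}
    removed: list = field(default_factory=list)  # removal order
    retained: list = field(default_factory=list)
    threshold: float = 5.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format log: round, variable, vif, action."""
        rows = []
        for k, rnd in enumerate(self.rounds):
            worst = self.removed[k] if k < len(self.removed) else None
            for var, v in rnd.items():
                action = "removed" if var == worst else "kept"
                rows.append({"round": k, "variable": var, "vif": v, "action": action})
        return pd.DataFrame(rows)


def vif(table: pd.DataFrame, variable: str) -> float:
    """VIF of ``variable`` against all other columns of ``table``.

    Perfect collinearity returns ``inf``. A constant variable is an error
    (its VIF is undefined: zero variance to inflate).
    """
    if variable not in table.columns:
        raise KeyError(variable)
    if table.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if table.shape[0] <= table.shape[1]:
        raise ValueError("need more rows than variables")
    y = table[variable].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"variable {variable!r} is constant")
    X = table.drop(columns=[variable]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - resid @ resid / ss_tot
    if r2 >= _R2_PERFECT:
        return float("inf")
    return float(1.0 / (1.0 - r2))


def iterative_vif_filter(
    table: pd.DataFrame,
    threshold: float = 5.0,
    groups: dict[str, list[str]] | None = None,
) -> VIFReport:
    """Screen covariates until max VIF <= threshold.

    Each round removes the single highest-VIF variable (ties broken by
    column order). With ``groups`` (hypothesis name -> variable list) the
    screen runs independently within each group and the reports are merged,
    which is the default mode of the hypothesis pipeline.
    """
    if groups is not None:
        merged = VIFReport(threshold=threshold)
        for name in groups:
            rep = iterative_vif_filter(table[groups[name]], threshold=threshold)
            merged.rounds.extend(rep.rounds)
            merged.removed.extend(rep.removed)
            merged.retained.extend(rep.retained)
        return merged

    cols = list(table.columns)
    report = VIFReport(threshold=threshold)
    while True:
        if len(cols) < 2:
            warnings.warn("fewer than 2 variables remain; stopping VIF screen", stacklevel=2)
            break
        vifs = {c: vif(table[cols], c) for c in cols}
        report.rounds.append(vifs)
        worst = max(cols, key=lambda c: vifs[c])  # first max wins ties
        if vifs[worst] <= threshold:
            break
        report.removed.append(worst)
        cols.remove(worst)
    report.retained = cols
    return report
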