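"""Lattice spatial statistics: neighbour weights, Moran's I, and the
residuals autocovariate (RAC).

The RAC is the spatial-correction device of the pipeline: model residuals on
the sampled cells are summarised into a per-cell focal mean over the cell's
neighbourhood and fed back into the model as one extra predictor, absorbing
residual spatial autocorrelation without altering the learner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "RACLayer",
    "build_weights",
    "morans_i",
    "residual_autocovariate",
]


@dataclass(frozen=True)
class SpatialWeights:
    """Sparse neighbour structure over a set of cell ids.

    ``neighbors[i]`` lists neighbour cell ids of cell i, ``weights[i]`` the
    matching non-negative weights. No cell is its own neighbour.
    """

    scheme: str
    ids: np.ndarray
    neighbors: dict = field(repr=False)
    weights: dict = field(repr=False)
    row_standardized: bool = False

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, keep_ids) -> "SpatialWeights":
        """Restrict to ``keep_ids``; weights are renormalized over surviving
        neighbours when the parent was row-standardized."""
        keep = set(int(i) for i in np.asarray(keep_ids).ravel())
        nbrs, wts = {}, {}
        for i in keep:
            js = self.neighbors.get(i, [])
            ws = self.weights.get(i, [])
            pairs = [(j, w) for j, w in zip(js, ws) if j in keep]
            nbrs[i] = [j for j, _ in pairs]
            wts[i] = [w for _, w in pairs]
            if self.row_standardized and wts[i]:
                s = sum(wts[i])
                wts[i] = [w / s for w in wts[i]]
        ids = np.array(sorted(keep))
        return SpatialWeights(self.scheme, ids, nbrs, wts, self.row_standardized)

    def to_matrix(self) -> np.ndarray:
        """Dense weight matrix in the order of ``ids`` (small grids only)."""
        pos = {int(i): k for k, i in enumerate(self.ids)}
        W = np.zeros((self.n, self.n))
        for i in self.ids:
            for j, w in zip(self.neighbors[int(i)], self.weights[int(i)]):
                W[pos[int(i)], pos[int(j)]] = w
        return W


def build_weights(
    grid,
    scheme: str = "queen",
    row_standardize: bool = True,
    cutoff_km: float | None = None,
) -> SpatialWeights:
    """Neighbour weights for the unmasked cells of a grid.

    rook/queen use lattice contiguity (weight 1 before standardization);
    ``inverse_distance`` weights every pair within ``cutoff_km`` (no cutoff:
    all pairs) by 1/centroid distance.
    """
    cells = grid.cells()
    if len(cells) == 0:
        raise ValueError("grid has no unmasked cells")
    ids = cells["cell_id"].to_numpy()
    neighbors: dict[int, list] = {int(i): [] for i in ids}
    weights: dict[int, list] = {int(i): [] for i in ids}

    if scheme in ("rook", "queen"):
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        inside = {(int(r), int(c)) for r, c in zip(cells["row"], cells["col"])}
        for r, c, i in zip(cells["row"], cells["col"], ids):
            for dr, dc in steps:
                if (r + dr, c + dc) in inside:
                    neighbors[int(i)].append(int(grid.cell_id(r + dr, c + dc)))
                    weights[int(i)].append(1.0)
    elif scheme == "inverse_distance":
        xy = cells[["x_km", "y_km"]].to_numpy()
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        for a, i in enumerate(ids):
            for b, j in enumerate(ids):
                if a == b:
                    continue
                if cutoff_km is not None and d[a, b] > cutoff_km:
                    continue
                neighbors[int(i)].append(int(j))
                weights[int(i)].append(1.0 / d[a, b])
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")

    isolated = [i for i in ids if not neighbors[int(i)]]
    if isolated:
        warnings.warn(f"{len(isolated)} cell(s) have no neighbours", stacklevel=2)
    if row_standardize:
        for i in ids:
            s = sum(weights[int(i)])
            if s > 0:
                weights[int(i)] = [w / s for w in weights[int(i)]]
    return SpatialWeights(scheme, np.sort(ids), neighbors, weights, row_standardize)


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    variance: float
    z: float
    p_value: float
    n_used: int


def _moran_statistic(z: np.ndarray, pairs, S0: float) -> float:
    num = sum(w * z[a] * z[b] for a, b, w in pairs)
    return len(z) / S0 * num / (z @ z)


def morans_i(
    values: pd.Series,
    weights: SpatialWeights,
    p_method: str = "normal",
    alternative: str = "two-sided",
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Moran's I with p-value by randomization normal approximation or
    permutation.

    ``values`` is indexed by cell_id; cells absent from the weights (or with
    no neighbour among the valued cells) are dropped and ``n_used`` reports
    the count actually entering the statistic.
    """
    values = values.dropna()
    w = weights.subset(values.index.to_numpy())
    ids = [int(i) for i in w.ids if w.neighbors[int(i)]]
    if len(ids) < 3:
        raise ValueError("need at least 3 connected cells")
    x = values.loc[ids].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant input: Moran's I undefined")
    n = len(ids)
    pos = {i: k for k, i in enumerate(ids)}
    pairs = []
    for i in ids:
        for j, wij in zip(w.neighbors[i], w.weights[i]):
            pairs.append((pos[i], pos[j], wij))
    S0 = sum(p[2] for p in pairs)

    z = x - x.mean()
    I = _moran_statistic(z, pairs, S0)
    EI = -1.0 / (n - 1)

    # randomization variance (standard closed form)
    Wm = np.zeros((n, n))
    for a, b, wij in pairs:
        Wm[a, b] = wij
    S1 = 0.5 * ((Wm + Wm.T) ** 2).sum()
    S2 = ((Wm.sum(1) + Wm.sum(0)) ** 2).sum()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * S0**2
    var = num / den - EI**2
    zscore = (I - EI) / np.sqrt(var)

    if p_method == "normal":
        if alternative == "two-sided":
            p = 2 * stats.norm.sf(abs(zscore))
        elif alternative == "greater":
            p = stats.norm.sf(zscore)
        elif alternative == "less":
            p = stats.norm.cdf(zscore)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        stat = np.empty(n_perm)
        for k in range(n_perm):
            zp = rng.permutation(z)
            stat[k] = _moran_statistic(zp, pairs, S0)
        if alternative == "two-sided":
            extreme = np.abs(stat - EI) >= abs(I - EI) - 1e-15
        elif alternative == "greater":
            extreme = stat >= I - 1e-15
        elif alternative == "less":
            extreme = stat <= I + 1e-15
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        p = (1 + extreme.sum()) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return MoranResult(float(I), float(EI), float(var), float(zscore), float(p), n)


@dataclass(frozen=True)
class RACLayer:
    """Per-cell residual autocovariate: focal mean of neighbouring sampled
    cells' residuals; cells without any sampled neighbour carry the global
    mean residual."""

    values: pd.Series
    neighborhood: str
    source: str = ""


def residual_autocovariate(
    residuals: pd.Series,
    weights: SpatialWeights,
    target_ids=None,
    source: str = "",
) -> RACLayer:
    """Compute the RAC from residuals on sampled cells.

    ``residuals`` is indexed by sampled cell_id. ``target_ids`` defaults to
    every cell in ``weights`` (so unsampled cells get a value too, for
    grid-wide prediction). Weights over unsampled neighbours are dropped and
    the remainder renormalized; a cell with no sampled neighbour gets the
    global mean residual.
    """
    residuals = residuals.dropna()
    if len(residuals) == 0:
        raise ValueError("empty residual set")
    sampled = {int(i): float(v) for i, v in residuals.items()}
    if target_ids is None:
        target_ids = weights.ids
    fallback = residuals.mean()
    out = {}
    for i in np.asarray(target_ids).ravel():
        i = int(i)
        js = weights.neighbors.get(i, [])
        ws = weights.weights.get(i, [])
        num = den = 0.0
        for j, wij in zip(js, ws):
            if j in sampled:
                num += wij * sampled[j]
                den += wij
        out[i] = num / den if den > 0 else fallback
    vals = pd.Series(out, name="rac").sort_index()
    return RACLayer(vals, weights.scheme, source)
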