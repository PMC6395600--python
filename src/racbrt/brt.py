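"""Boosted regression trees for presence/absence, with the ecological
modelling workflow built around them: k-fold cross-validated selection of
the ensemble size, the "largest learning rate / smallest tree complexity
reaching a minimum tree count" tuning rule, backward simplification by
relative influence, and partial-dependence curves.

The booster itself is scikit-learn's ``GradientBoostingClassifier``
(stage-wise trees on Bernoulli deviance). Tree complexity ``tc`` is the
number of splits per tree, mapped to ``max_leaf_nodes = tc + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "BRTConfig",
    "BRTModel",
    "fit_brt",
    "tune_lr_tc",
    "simplify_brt",
    "relative_influence",
    "partial_dependence",
]

_EPS = 1e-12


@dataclass(frozen=True)
class BRTConfig:
    """Booster hyperparameters. ``tc`` is splits per tree (interaction depth)."""

    lr: float = 0.01
    tc: int = 2
    bag_fraction: float = 0.5
    n_folds: int = 10
    max_trees: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr <= 1:
            raise ValueError("learning rate must be in (0, 1]")
        if self.tc < 1:
            raise ValueError("tree complexity must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag fraction must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class BRTModel:
    """A fitted, CV-evaluated boosted-tree model."""

    config: BRTConfig
    n_trees: int
    variables: list
    relative_influence: pd.Series  # % per variable, sums to 100
    cv_auc: float
    cv_auc_se: float
    deviance_explained_pct: float
    estimator: GradientBoostingClassifier = field(repr=False)
    drop_log: list = field(default_factory=list, repr=False)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(X[self.variables].to_numpy())[:, 1]

    def decision(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.decision_function(X[self.variables].to_numpy())


def _bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-2 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _make_estimator(config: BRTConfig, n_trees: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        n_estimators=n_trees,
        learning_rate=config.lr,
        max_leaf_nodes=config.tc + 1,
        max_depth=None,
        subsample=config.bag_fraction,
        random_state=config.seed,
    )


def fit_brt(X: pd.DataFrame, y, config: BRTConfig) -> BRTModel:
    """Fit a BRT with CV-selected ensemble size.

    The number of trees is the minimizer of the mean held-out Bernoulli
    deviance across stratified k folds; cv_auc is the mean held-out AUC at
    that size (SE = sd / sqrt(k)); deviance explained is
    100 * (1 - CV deviance / null deviance), both on held-out predictions.
    The returned estimator is refit on the full data at the selected size.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if len(y) < config.n_folds:
        raise ValueError("fewer observations than CV folds")
    Xa = X.to_numpy(dtype=float)

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    staged_dev = np.zeros((config.n_folds, config.max_trees))
    fold_links = []  # (test_idx, staged decision matrix)
    null_devs = []
    for k, (tr, te) in enumerate(skf.split(Xa, y)):
        est = _make_estimator(config, config.max_trees).fit(Xa[tr], y[tr])
        links = np.vstack([np.ravel(d) for d in est.staged_decision_function(Xa[te])])
        probs = expit(links)
        staged_dev[k] = [_bernoulli_deviance(y[te], probs[s]) for s in range(config.max_trees)]
        fold_links.append((te, links))
        null_devs.append(_bernoulli_deviance(y[te], np.full(len(te), y[tr].mean())))

    mean_dev = staged_dev.mean(axis=0)
    n_trees = int(np.argmin(mean_dev)) + 1
    aucs = []
    for te, links in fold_links:
        if len(np.unique(y[te])) == 2:
            aucs.append(roc_auc_score(y[te], links[n_trees - 1]))
    aucs = np.asarray(aucs)
    cv_auc = float(aucs.mean())
    cv_auc_se = float(aucs.std(ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0
    dev_expl = float(100 * (1 - mean_dev[n_trees - 1] / np.mean(null_devs)))

    final = _make_estimator(config, n_trees).fit(Xa, y)
    infl = pd.Series(final.feature_importances_ * 100, index=list(X.columns))
    total = infl.sum()
    infl = infl * 100 / total if total > 0 else infl
    return BRTModel(
        config=config,
        n_trees=n_trees,
        variables=list(X.columns),
        relative_influence=infl.sort_values(ascending=False),
        cv_auc=cv_auc,
        cv_auc_se=cv_auc_se,
        deviance_explained_pct=dev_expl,
        estimator=final,
    )


def tune_lr_tc(
    X: pd.DataFrame,
    y,
    lr_grid=(0.1, 0.05, 0.01, 0.005, 0.001),
    tc_grid=(1, 2, 3, 5),
    min_trees: int = 1000,
    base_config: BRTConfig | None = None,
) -> BRTConfig:
    """Smallest tc, then largest lr, whose CV-selected size reaches
    ``min_trees``.

    Shrinkage controls how many trees the ensemble needs: a large learning
    rate converges (and overfits) in few trees, so the rule walks down the
    grid until the held-out deviance minimum lands at or beyond the floor.
    Falls back to (smallest lr, largest tc) with a warning if nothing does.
    """
    if not len(lr_grid) or not len(tc_grid):
        raise ValueError("empty tuning grid")
    lr_grid = sorted(lr_grid, reverse=True)
    tc_grid = sorted(tc_grid)
    base = base_config or BRTConfig()
    for tc in tc_grid:
        for lr in lr_grid:
            cfg = replace(base, lr=lr, tc=tc)
            model = fit_brt(X, y, cfg)
            if model.n_trees >= min_trees:
                return cfg
    warnings.warn(
        f"no (lr, tc) combination reached {min_trees} trees; "
        "falling back to smallest lr / largest tc",
        stacklevel=2,
    )
    return replace(base, lr=lr_grid[-1], tc=tc_grid[-1])


def simplify_brt(
    model: BRTModel,
    X: pd.DataFrame,
    y,
    tol_auc: float = 0.005,
    tol_dev: float = 0.5,
    protected: tuple = (),
) -> BRTModel:
    """Backward variable elimination by relative influence.

    Repeatedly drop the lowest-influence unprotected variable and refit;
    a drop is kept only while neither cv_auc falls by more than ``tol_auc``
    nor deviance explained by more than ``tol_dev`` percentage points
    relative to the model before the drop. ``protected`` variables (e.g.
    the RAC term) are never candidates.
    """
    current = model
    log = list(model.drop_log)
    while True:
        droppable = [v for v in current.variables if v not in protected]
        if len(current.variables) < 2 or not droppable:
            break
        if protected and len(droppable) < 2:
            break  # a protected correction term alone is not a model
        worst = min(droppable, key=lambda v: current.relative_influence[v])
        keep = [v for v in current.variables if v != worst]
        if not keep:
            break
        trial = fit_brt(X[keep], y, current.config)
        d_auc = current.cv_auc - trial.cv_auc
        d_dev = current.deviance_explained_pct - trial.deviance_explained_pct
        if d_auc <= tol_auc and d_dev <= tol_dev:
            log.append(
                {"dropped": worst, "cv_auc": trial.cv_auc,
                 "deviance_explained_pct": trial.deviance_explained_pct}
            )
            current = trial
        else:
            break
    current.drop_log = log
    return current


def relative_influence(model: BRTModel) -> pd.Series:
    """Per-variable split-improvement importance, rescaled to sum 100."""
    return model.relative_influence


def partial_dependence(
    model: BRTModel,
    X: pd.DataFrame,
    variable: str,
    grid_points: int | np.ndarray = 50,
    scale: str = "link",
) -> pd.DataFrame:
    """Mean prediction with ``variable`` clamped to each grid value.

    Returns a DataFrame with columns (value, effect); ``scale`` is ``link``
    (log-odds, the default) or ``probability``.
    """
    if variable not in model.variables:
        raise KeyError(variable)
    if np.isscalar(grid_points):
        col = X[variable].to_numpy(dtype=float)
        grid = np.linspace(col.min(), col.max(), int(grid_points))
    else:
        grid = np.asarray(grid_points, dtype=float)
    Xw = X[model.variables].copy()
    effect = np.empty(len(grid))
    for k, g in enumerate(grid):
        Xw[variable] = g
        if scale == "link":
            effect[k] = model.decision(Xw).mean()
        elif scale == "probability":
            effect[k] = model.predict_proba(Xw).mean()
        else:
            raise ValueError(f"unknown scale {scale!r}")
    return pd.DataFrame({"value": grid, "effect": effect})
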