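"""Boosted-tree fitting, tuning rule, simplification, influence and
partial dependence."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from racbrt import BRTConfig, fit_brt, partial_dependence, simplify_brt, tune_lr_tc


def toy_data(n=200, seed=0, n_noise=2):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 1 + n_noise)),
        columns=["signal"] + [f"noise{i}" for i in range(n_noise)],
    )
    p = 1 / (1 + np.exp(-2.5 * X["signal"]))
    y = (rng.random(n) < p).astype(int)
    return X, y


class TestFitBrt:
    def test_perfect_binary_separator(self, small_brt_config):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 300)
        X = pd.DataFrame({"flag": x.astype(float)})
        y = x
        model = fit_brt(X, y, small_brt_config)
        train_auc = roc_auc_score(y, model.decision(X))
        assert train_auc == 1.0
        assert model.relative_influence["flag"] == pytest.approx(100.0)

    def test_influences_sum_to_100(self, small_brt_config):
        X, y = toy_data(seed=1)
        model = fit_brt(X, y, small_brt_config)
        assert model.relative_influence.sum() == pytest.approx(100.0, abs=1e-6)
        assert model.n_trees >= 1

    def test_pure_noise_gives_chance_level_auc(self, small_brt_config):
        # mean CV AUC over seeds stays within 2 SE of 0.5
        aucs, ses = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
            y = rng.integers(0, 2, 120)
            m = fit_brt(X, y, small_brt_config)
            aucs.append(m.cv_auc)
            ses.append(m.cv_auc_se)
        assert abs(np.mean(aucs) - 0.5) < 2 * np.mean(ses)

    def test_single_class_rejected(self, small_brt_config):
        X, _ = toy_data(50)
        with pytest.raises(ValueError, match="both classes"):
            fit_brt(X, np.ones(50, int), small_brt_config)

    def test_seeded_determinism(self, small_brt_config):
        X, y = toy_data(seed=2)
        m1 = fit_brt(X, y, small_brt_config)
        m2 = fit_brt(X, y, small_brt_config)
        assert m1.n_trees == m2.n_trees
        pd.testing.assert_series_equal(m1.relative_influence, m2.relative_influence)
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_duplicated_informative_predictor_splits_influence(self, small_brt_config):
        X, y = toy_data(n=400, seed=3, n_noise=1)
        X["signal2"] = X["signal"] + 1e-9  # tie-broken duplicate
        m = fit_brt(X, y, small_brt_config)
        a = m.relative_influence["signal"]
        b = m.relative_influence["signal2"]
        assert max(a, b) / max(min(a, b), 1e-9) < 2.0


class TestTuneLrTc:
    def test_min_trees_one_returns_greediest_config(self):
        X, y = toy_data(150, seed=4)
        cfg = tune_lr_tc(X, y, lr_grid=(0.1, 0.01), tc_grid=(1, 3), min_trees=1,
                         base_config=BRTConfig(n_folds=4, max_trees=60))
        assert cfg.lr == 0.1 and cfg.tc == 1

    def test_small_learning_rate_needed_for_many_trees(self):
        # lr 0.1 converges early; only the small lr reaches the tree floor
        X, y = toy_data(250, seed=5)
        cfg = tune_lr_tc(
            X, y, lr_grid=(0.1, 0.005), tc_grid=(2,), min_trees=120,
            base_config=BRTConfig(n_folds=4, max_trees=200),
        )
        assert cfg.lr == 0.005

    def test_unreachable_floor_falls_back_with_warning(self):
        X, y = toy_data(120, seed=6)
        with pytest.warns(UserWarning, match="falling back"):
            cfg = tune_lr_tc(
                X, y, lr_grid=(0.5, 0.3), tc_grid=(1, 2), min_trees=10_000,
                base_config=BRTConfig(n_folds=4, max_trees=50),
            )
        assert cfg.lr == 0.3 and cfg.tc == 2

    def test_empty_grid_rejected(self):
        X, y = toy_data(60)
        with pytest.raises(ValueError):
            tune_lr_tc(X, y, lr_grid=(), tc_grid=(1,))


class TestSimplify:
    def test_noise_variable_dropped(self, small_brt_config):
        hits = 0
        for seed in range(5):
            X, y = toy_data(n=300, seed=seed, n_noise=2)
            m = fit_brt(X, y, small_brt_config)
            s = simplify_brt(m, X, y)
            hits += "signal" in s.variables and len(s.variables) < 3
        assert hits >= 4

    def test_infinite_tolerance_leaves_single_variable(self, small_brt_config):
        X, y = toy_data(150, seed=7)
        m = fit_brt(X, y, small_brt_config)
        s = simplify_brt(m, X, y, tol_auc=np.inf, tol_dev=np.inf)
        assert len(s.variables) == 1
        assert len(s.drop_log) == X.shape[1] - 1

    def test_zero_tolerance_keeps_helpful_variables(self, small_brt_config):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        logitp = 2.0 * X["a"] + 2.0 * X["b"]
        y = (rng.random(400) < 1 / (1 + np.exp(-logitp))).astype(int)
        m = fit_brt(X, y, small_brt_config)
        s = simplify_brt(m, X, y, tol_auc=0.0, tol_dev=0.0)
        assert set(s.variables) == {"a", "b"}

    def test_protected_variable_never_dropped(self, small_brt_config):
        X, y = toy_data(200, seed=9, n_noise=2)
        m = fit_brt(X, y, small_brt_config)
        s = simplify_brt(m, X, y, tol_auc=np.inf, tol_dev=np.inf, protected=("noise0",))
        assert "noise0" in s.variables


class TestPartialDependence:
    def test_unused_variable_gives_flat_curve(self, small_brt_config):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"flag": rng.integers(0, 2, 200).astype(float),
                          "unused": np.zeros(200)})
        y = X["flag"].astype(int)
        m = fit_brt(X, y, small_brt_config)
        curve = partial_dependence(m, X.assign(unused=rng.normal(size=200)), "unused", 11)
        assert np.ptp(curve["effect"]) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_effect_recovered(self, small_brt_config):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"x": rng.uniform(-2, 2, 500)})
        y = ((X["x"] > 0).astype(int).to_numpy() ^ (rng.random(500) < 0.05)).astype(int)
        m = fit_brt(X, y, small_brt_config)
        curve = partial_dependence(m, X, "x", 21)
        # monotone up to tree-step wiggles: strongly increasing overall
        assert curve["effect"].iloc[-1] - curve["effect"].iloc[0] > 2.0
        from scipy.stats import spearmanr

        rho = spearmanr(curve["value"], curve["effect"]).statistic
        assert rho > 0.8

    def test_probability_scale_bounded(self, small_brt_config):
        X, y = toy_data(150, seed=12)
        m = fit_brt(X, y, small_brt_config)
        curve = partial_dependence(m, X, "signal", 15, scale="probability")
        assert curve["effect"].between(0, 1).all()

    def test_unknown_variable_rejected(self, small_brt_config):
        X, y = toy_data(80, seed=13)
        m = fit_brt(X, y, small_brt_config)
        with pytest.raises(KeyError):
            partial_dependence(m, X, "ghost")
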