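"""Scenario application, projection, and range-shift summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from racbrt import FavourabilityMap, Scenario, apply_scenario, climate_2040_rules, summarize_shift


@pytest.fixture
def cov_table():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "Ann_Prec": rng.uniform(600, 1400, 50),
            "Ann_Temp": rng.uniform(10, 17, 50),
            "Eucalyptus": rng.uniform(0, 40, 50),
            "Shrublands": rng.uniform(0, 60, 50),
        },
        index=pd.RangeIndex(50, name="cell_id"),
    )


class TestApplyScenario:
    def test_null_scenario_is_identity(self, cov_table):
        out = apply_scenario(cov_table, Scenario("null"))
        pd.testing.assert_frame_equal(out, cov_table)

    def test_default_climate_deltas_arithmetic(self, cov_table):
        cov = cov_table.copy()
        cov.loc[0, ["Ann_Prec", "Ann_Temp"]] = [1000.0, 14.13]
        out = apply_scenario(cov, Scenario("A1B", climate_rules=climate_2040_rules()))
        assert out.loc[0, "Ann_Prec"] == pytest.approx(900.0)
        assert out.loc[0, "Ann_Temp"] == pytest.approx(15.63)

    def test_eucalyptus_frozen_bit_identical(self, cov_table):
        out = apply_scenario(
            cov_table,
            Scenario("A1B", climate_rules=climate_2040_rules(),
                     landcover_rules={"Shrublands": lambda c: c * 1.1}),
        )
        assert out["Eucalyptus"].equals(cov_table["Eucalyptus"])

    def test_pure_delta_rules_invert_exactly(self, cov_table):
        fwd = Scenario("fwd", climate_rules={"Ann_Prec": ("mul", 0.9), "Ann_Temp": ("add", 1.5)})
        inv = Scenario("inv", climate_rules={"Ann_Prec": ("mul", 1 / 0.9), "Ann_Temp": ("add", -1.5)})
        back = apply_scenario(apply_scenario(cov_table, fwd), inv)
        assert np.allclose(back.to_numpy(), cov_table.to_numpy(), atol=1e-12)

    def test_rule_for_unknown_variable_rejected(self, cov_table):
        with pytest.raises(KeyError):
            apply_scenario(cov_table, Scenario("bad", climate_rules={"Snow": ("add", 1)}))

    def test_variable_in_two_rules_rejected(self):
        with pytest.raises(ValueError):
            Scenario("bad", climate_rules={"Shrublands": ("mul", 1.1)},
                     landcover_rules={"Shrublands": lambda c: c})

    def test_frozen_variable_with_rule_rejected(self):
        with pytest.raises(ValueError):
            Scenario("bad", climate_rules={"Eucalyptus": ("mul", 1.1)})


def _map(F, n1=95, n0=177):
    F = pd.Series(np.asarray(F, float))
    return FavourabilityMap(P=F.copy(), F=F, n1=n1, n0=n0)


class TestSummarizeShift:
    def test_printed_percentages_give_mean_increase_275(self):
        # baseline 22.73% favourable vs scenario maps at 24.71/25.17/
        # 25.86/26.19% -> mean increase 2.75 percentage points
        n = 10_000

        def frac_map(pct):
            k = round(n * pct / 100)
            return _map(np.r_[np.full(k, 0.9), np.full(n - k, 0.1)])

        base = frac_map(22.73)
        scn = {name: frac_map(p) for name, p in
               [("A1_2040", 24.71), ("A2_2040", 25.17), ("B1_2040", 25.86), ("B2_2040", 26.19)]}
        shift = summarize_shift(base, scn)
        assert shift.pct_favourable_baseline == pytest.approx(22.73)
        assert shift.mean_increase == pytest.approx(2.7525, abs=0.005)
        assert shift.chi2_df == 3

    def test_identical_scenarios_give_zero_chi2(self):
        m = _map(np.linspace(0, 1, 40))
        shift = summarize_shift(m, {f"S{k}": m for k in range(4)})
        assert shift.chi2 == pytest.approx(0.0)
        assert shift.p == pytest.approx(1.0)
        assert shift.mean_increase == pytest.approx(0.0)

    def test_printed_chi2_pair_consistent_with_df3(self):
        # the reported test statistic and p-value imply 3 degrees of
        # freedom: chi2_sf(1.392, 3) = 0.707
        assert stats.chi2.sf(1.392, 3) == pytest.approx(0.707, abs=5e-4)

    def test_region_counts_match_hand_fixture(self):
        # region of 40 cells; baseline 35 above 0.75, scenarios 16/15/17/18
        def region_map(k):
            return _map(np.r_[np.full(k, 0.9), np.full(40 - k, 0.3)])

        base = region_map(35)
        scn = {name: region_map(k) for name, k in
               [("A1_2040", 16), ("A2_2040", 15), ("B1_2040", 17), ("B2_2040", 18)]}
        shift = summarize_shift(base, scn, region_mask=range(40))
        assert shift.region_counts_F075["baseline"] == 35
        scn_counts = [v for k, v in shift.region_counts_F075.items() if k != "baseline"]
        assert np.mean(scn_counts) == pytest.approx(16.5)

    def test_misaligned_maps_rejected(self):
        a = _map(np.linspace(0, 1, 10))
        b = FavourabilityMap(
            P=pd.Series(0.5, index=range(5, 15)),
            F=pd.Series(0.5, index=range(5, 15)), n1=1, n0=1,
        )
        with pytest.raises(ValueError, match="aligned"):
            summarize_shift(a, {"S": b})


class TestProjection:
    def test_null_scenario_reproduces_baseline_map_exactly(self, cells12, weights12):
        from racbrt import (
            BRTConfig, HypothesisSpec, PipelineConfig, fit_hypothesis, make_map, project,
        )

        pipe = PipelineConfig(tune=False, simplify=False,
                              fixed_config=BRTConfig(lr=0.05, tc=2, n_folds=5, max_trees=120, seed=0))
        res = fit_hypothesis(
            HypothesisSpec("H1", ("Herbaceous", "Eucalyptus")), cells12, weights12, pipe
        )
        sampled = cells12[cells12["sampled"]]
        n1 = int(sampled["presence"].sum())
        n0 = len(sampled) - n1
        base = make_map(res, cells12, n1, n0)
        null = project(res, apply_scenario(cells12, Scenario("null")), n1, n0)
        assert base.P.equals(null.P)
        assert base.F.equals(null.F)

    def test_shifting_into_optimum_does_not_reduce_mean_favourability(self, cells12, weights12):
        # single-variable model; move every cell's precipitation toward the
        # generating optimum band (800-1000 mm)
        from racbrt import (
            BRTConfig, HypothesisSpec, PipelineConfig, fit_hypothesis, make_map, project,
        )

        pipe = PipelineConfig(tune=False, simplify=False,
                              fixed_config=BRTConfig(lr=0.05, tc=2, n_folds=5, max_trees=120, seed=0))
        res = fit_hypothesis(
            HypothesisSpec("H4", ("Ann_Prec",)), cells12, weights12, pipe
        )
        sampled = cells12[cells12["sampled"]]
        n1 = int(sampled["presence"].sum())
        n0 = len(sampled) - n1
        base = make_map(res, cells12, n1, n0)
        to_optimum = cells12.copy()
        to_optimum["Ann_Prec"] = 900.0
        best_cell = base.F.idxmax()
        if 800 <= cells12.loc[best_cell, "Ann_Prec"] <= 1000:
            fut = project(res, to_optimum, n1, n0)
            assert fut.F.mean() >= base.F.mean() - 1e-9

    def test_default_scenarios_produce_finite_maps(self, cells12, weights12):
        from racbrt import BRTConfig, HypothesisSpec, PipelineConfig, fit_hypothesis, project
        from racbrt.run import default_scenarios

        pipe = PipelineConfig(tune=False, simplify=False,
                              fixed_config=BRTConfig(lr=0.05, tc=2, n_folds=5, max_trees=120, seed=0))
        res = fit_hypothesis(
            HypothesisSpec("H5", ("Herbaceous", "Shrublands", "Ann_Prec", "Ann_Temp")),
            cells12, weights12, pipe,
        )
        for scn in default_scenarios():
            fmap = project(res, apply_scenario(cells12, scn), 30, 70)
            assert fmap.P.notna().all() and fmap.F.notna().all()
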