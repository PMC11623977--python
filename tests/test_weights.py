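"""Inverse-probability weight estimation: IPCW, IPTW, truncation, classic."""

import numpy as np
import pandas as pd
import pytest

import ccw
from ccw.pipeline import compute_weighted_table
from ccw.simulate import fixture_strategies
from ccw.weights import (
    PositivityError,
    WeightModelSpec,
    compute_ipcw,
    compute_iptw,
    fit_uncensored_model,
    truncate_weights,
)


@pytest.fixture(scope="module")
def lung5_table(lung5_bundle, lung5_strategies, lung5_clones):
    return ccw.expand_person_time(lung5_clones, lung5_bundle,
                                  strategies=lung5_strategies)


NONPAR = WeightModelSpec(implementation="nonparametric")


class TestUncensoredModel:
    def test_empirical_probabilities_match_hand_counts(self, lung5_table, lung5_bundle):
        m_b = fit_uncensored_model(lung5_table, NONPAR, "no_surgery", lung5_bundle.grid)
        rows_b = lung5_table[
            (lung5_table.strategy_id == "no_surgery") & (lung5_table.interval_end == 90)
        ]
        # day 90 in the abstention arm: 5 at risk, 1 censored
        np.testing.assert_allclose(m_b.predict_event_probability(rows_b), 1 / 5)
        m_a = fit_uncensored_model(lung5_table, NONPAR, "surgery", lung5_bundle.grid)
        rows_a = lung5_table[
            (lung5_table.strategy_id == "surgery") & (lung5_table.interval_end == 182)
        ]
        # day 182 in the initiation arm: 4 at risk (one died day 112), 3 censored
        assert len(rows_a) == 4
        np.testing.assert_allclose(m_a.predict_event_probability(rows_a), 3 / 4)

    def test_arm_without_censoring_gets_probability_one(self, sim_small):
        # forbid window of length 0 at day 0: nobody can deviate
        strat = [
            ccw.StrategySpec(
                id="all", kind="initiation",
                components=(ccw.ComponentRule("treatment", "require", (0, 365)),),
            ),
            ccw.StrategySpec(
                id="none", kind="abstention",
                components=(ccw.ComponentRule("treatment", "forbid", (0, 365)),),
            ),
        ]
        clones = ccw.censor_clones(ccw.make_clones(sim_small, strat), sim_small, strat)
        table = ccw.expand_person_time(clones, sim_small, strategies=strat)
        rows_all = table[table.strategy_id == "all"]
        assert rows_all["artificial_censor_this_interval"].sum() == 0
        spec = WeightModelSpec(implementation="nonparametric")
        m = fit_uncensored_model(table, spec, "all", sim_small.grid)
        at_risk = rows_all[rows_all.at_censor_risk == 1]
        assert np.all(m.predict_event_probability(at_risk) == 0)
        wt = compute_ipcw(
            table, {"all": m,
                    "none": fit_uncensored_model(table, spec, "none", sim_small.grid)},
            spec,
        )
        np.testing.assert_allclose(
            wt.loc[wt.strategy_id == "all", "weight"], 1.0
        )


class TestComputeIPCW:
    def test_fixture_weights(self, lung5_table, lung5_bundle, lung5_strategies):
        models = {
            s.id: fit_uncensored_model(lung5_table, NONPAR, s.id, lung5_bundle.grid)
            for s in lung5_strategies
        }
        wt = compute_ipcw(lung5_table, models, NONPAR)
        b_surv = wt[(wt.strategy_id == "no_surgery") & (wt.interval_end > 90)
                    & (wt.weight > 0)]
        np.testing.assert_allclose(b_surv["weight"], 5 / 4)
        p1 = wt[(wt.strategy_id == "surgery") & (wt.patient_id == "P1")]
        np.testing.assert_allclose(p1[p1.interval_end >= 182]["weight"], 4.0)
        np.testing.assert_allclose(p1[p1.interval_end < 182]["weight"], 1.0)

    def test_censored_rows_weight_zero(self, lung5_table, lung5_bundle, lung5_strategies):
        models = {
            s.id: fit_uncensored_model(lung5_table, NONPAR, s.id, lung5_bundle.grid)
            for s in lung5_strategies
        }
        wt = compute_ipcw(lung5_table, models, NONPAR)
        assert (wt.loc[wt.artificial_censor_this_interval == 1, "weight"] == 0).all()

    def test_self_stabilization_gives_unit_weights(self, sim_small, sim_strategies):
        # numerator model == denominator model -> all ratios 1
        spec = WeightModelSpec(
            implementation="nonparametric",
            denominator_covariates=("z",),
            numerator_covariates=("z",),
        )
        table, _, _ = compute_weighted_table(sim_small, sim_strategies, spec)
        pos = table[table.weight > 0]
        np.testing.assert_allclose(pos["weight"], 1.0)

    def test_stabilized_weight_mean_near_one(self, sim_small, sim_strategies):
        spec = WeightModelSpec(
            implementation="nonparametric",
            denominator_covariates=("z",),
            stabilized=True,  # marginal (time-only) numerator
        )
        table, _, _ = compute_weighted_table(sim_small, sim_strategies, spec)
        for arm in ("initiate", "never"):
            w = table.loc[(table.strategy_id == arm) & (table.weight > 0), "weight"]
            assert abs(w.mean() - 1) < 0.05

    def test_structural_positivity_violation_raises(self):
        # everyone initiates on day 1: the abstention arm empties
        pts = pd.DataFrame(
            {"id": ["a", "b"], "followup_end": [50, 50], "event": [0, 0],
             "classic_censor_reason": ["administrative"] * 2}
        )
        trt = pd.DataFrame({"id": ["a", "b"], "day": [1, 1], "component": ["t", "t"]})
        b = ccw.make_bundle(pts, trt, None, ccw.TimeGrid(horizon=50))
        strats = fixture_strategies(grace_period=30, component="t")
        with pytest.raises(PositivityError):
            compute_weighted_table(b, strats, NONPAR)


class TestTruncation:
    def test_outlier_capped_to_sample_percentile(self):
        table = pd.DataFrame(
            {"weight": [1.0, 1.0, 1.0, 1.0, 100.0],
             "strategy_id": "a", "patient_id": list("vwxyz"), "interval_index": 0}
        )
        out, n = truncate_weights(table, 80)
        np.testing.assert_allclose(out["weight"], 1.0)
        assert n == 1

    def test_percentile_100_is_identity(self):
        table = pd.DataFrame(
            {"weight": [1.0, 2.0, 5.0], "strategy_id": "a",
             "patient_id": list("xyz"), "interval_index": 0}
        )
        out, n = truncate_weights(table, 100)
        np.testing.assert_allclose(out["weight"], table["weight"])
        assert n == 0

    def test_degenerate_distribution_identity_at_any_percentile(self):
        table = pd.DataFrame(
            {"weight": [2.0] * 6, "strategy_id": "a",
             "patient_id": list("uvwxyz"), "interval_index": 0}
        )
        for q in (1, 50, 99):
            out, n = truncate_weights(table, q)
            np.testing.assert_allclose(out["weight"], 2.0)
            assert n == 0

    def test_invalid_percentile_rejected(self):
        table = pd.DataFrame({"weight": [1.0], "strategy_id": "a",
                              "patient_id": ["x"], "interval_index": 0})
        for q in (0, -5, 101):
            with pytest.raises(ValueError):
                truncate_weights(table, q)

    def test_cap_bounds_reported_max(self, sim_small, sim_strategies, z_weight_spec):
        import dataclasses

        spec = dataclasses.replace(z_weight_spec, truncation_percentile=99.0)
        table, _, _ = compute_weighted_table(sim_small, sim_strategies, spec)
        from ccw.diagnostics import weight_summary

        summary = weight_summary(table)
        for arm in summary:
            assert summary[arm]["max"] <= summary[arm]["p99"] + 1e-12


class TestClassicWeights:
    def test_no_loss_to_followup_is_identity(self, lung5_bundle, lung5_strategies):
        table, _, _ = compute_weighted_table(
            lung5_bundle, lung5_strategies, NONPAR, classic=False
        )
        table2, _, _ = compute_weighted_table(
            lung5_bundle, lung5_strategies, NONPAR, classic=True
        )
        np.testing.assert_allclose(table["weight"], table2["weight"])

    def test_multiplicativity(self):
        from ccw.weights import combine_classic_weights

        table = pd.DataFrame(
            {
                "strategy_id": ["a", "a"],
                "patient_id": ["p", "p"],
                "interval_index": [0, 1],
                "weight": [2.0, 2.0],
                "classic_censor_this_interval": [0, 0],
                "end_reason": ["event", "event"],
            }
        )

        class Half:
            covariates = ()

            def predict_event_probability(self, rows):
                return np.full(len(rows), 0.5)

        out = combine_classic_weights(table, {"a": Half()})
        np.testing.assert_allclose(out["weight"], [4.0, 8.0])

    def test_informative_dropout_corrected(self, sim_strategies, z_weight_spec):
        """With Z-driven loss to follow-up, classic-censoring weights pull the
        per-arm survival estimates back toward the counterfactual truth."""
        params = ccw.SimulationParams(
            n=3000, seed=21, effect_logodds=0.0, dropout_prob=(0.0005, 0.004)
        )
        truth = ccw.oracle_truth(params, 300_000)
        b = ccw.simulate_cohort(params)
        t_plain, _, _ = compute_weighted_table(b, sim_strategies, z_weight_spec)
        t_cls, _, _ = compute_weighted_table(b, sim_strategies, z_weight_spec,
                                             classic=True)
        err_plain = abs(
            ccw.weighted_km(t_plain, "never").survival_at(365) - truth.survival_never
        )
        err_cls = abs(
            ccw.weighted_km(t_cls, "never").survival_at(365) - truth.survival_never
        )
        assert err_cls < err_plain
        assert err_cls < 0.04


class TestIPTW:
    def test_agrees_exactly_with_ipcw_for_empirical_models(self):
        b = ccw.simulate_cohort(ccw.SimulationParams(n=250, seed=5))
        strats = fixture_strategies(grace_period=182, component="treatment")
        spec_c = WeightModelSpec(implementation="nonparametric",
                                 denominator_covariates=("z",))
        spec_t = WeightModelSpec(implementation="iptw", estimator="empirical",
                                 denominator_covariates=("z",))
        tab_c, _, _ = compute_weighted_table(b, strats, spec_c)
        tab_t, _, _ = compute_weighted_table(b, strats, spec_t)
        for arm in ("treatment", "no_treatment"):
            sc = ccw.weighted_km(tab_c, arm)
            st_ = ccw.weighted_km(tab_t, arm)
            np.testing.assert_allclose(sc.survival, st_.survival, atol=1e-12)

    def test_pooled_logistic_iptw_close_to_ipcw(self):
        b = ccw.simulate_cohort(ccw.SimulationParams(n=1500, seed=6))
        grid = ccw.TimeGrid(horizon=360, interval_length=30)
        b = ccw.make_bundle(b.patients.copy(), b.treatments, None, grid)
        strats = fixture_strategies(grace_period=180, component="treatment")
        spec_c = WeightModelSpec(implementation="nonparametric",
                                 denominator_covariates=("z",))
        spec_t = WeightModelSpec(implementation="iptw", estimator="pooled-logistic",
                                 denominator_covariates=("z",), time_form="categorical")
        tab_c, _, _ = compute_weighted_table(b, strats, spec_c)
        tab_t, _, _ = compute_weighted_table(b, strats, spec_t)
        arms = ("treatment", "no_treatment")
        rd_c = ccw.contrast({a: ccw.weighted_km(tab_c, a) for a in arms},
                            "risk_difference", 360, arms).point
        rd_t = ccw.contrast({a: ccw.weighted_km(tab_t, a) for a in arms},
                            "risk_difference", 360, arms).point
        assert abs(rd_c - rd_t) < 0.02

    def test_rejected_for_non_initiation_designs(self, lung5_bundle):
        strats = [
            ccw.StrategySpec(
                id="seq", kind="sequential",
                components=(
                    ccw.ComponentRule("radiation", "require", (0, 7)),
                    ccw.ComponentRule("surgery", "require", (0, 182),
                                      anchor="completion-of-previous-component"),
                ),
            ),
            fixture_strategies()[1],
        ]
        spec = WeightModelSpec(implementation="iptw")
        with pytest.raises(NotImplementedError):
            compute_weighted_table(lung5_bundle, strats, spec)
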