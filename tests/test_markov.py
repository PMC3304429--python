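"""Cohort engine: schedules, accounting, and an independent enumeration oracle.

The oracle re-derives expected outcomes by exact dynamic programming over
(conceptual state, had-local-recurrence, had-axillary-recurrence) triples,
written directly from the model rules.  It shares no code or state layout
with the engine (flags here versus expanded layers there), so agreement is
evidence both encode the same process.
"""

from collections import defaultdict

import numpy as np
import pytest

from slnb_cea.markov import (
    HealthState,
    InfeasibleParametersError,
    build_schedule,
    compare,
    halving_factor,
    run_cohort,
    run_comparison,
    run_strategy,
)
from slnb_cea.parameters import CostSet, ModelSettings, ParameterSet
from slnb_cea.staging import NodalStatus, Pathway, StratumSpec, StrategyId, build_strata


def make_stratum(fn_elevated=False, nodal=NodalStatus.POSITIVE, p_lymph=0.2,
                 upfront=1000.0):
    pathway = (
        Pathway.SLNB_FALSE_NEGATIVE if fn_elevated else Pathway.ALND_DIRECT
    )
    strategy = StrategyId.SLNB if fn_elevated else StrategyId.ALND
    return StratumSpec(strategy, nodal, pathway, 1.0, upfront, p_lymph, fn_elevated)


# ---------------------------------------------------------------------------
# Independent oracle: exact DP over (state, had_local, had_ax)
# ---------------------------------------------------------------------------


def enumerate_stratum(stratum, params, costs, settings):
    """Expected per-1000 outcomes by brute-force distribution propagation."""
    positive = stratum.nodal_status is NodalStatus.POSITIVE
    dm_first = params.p_dm_first_node_pos if positive else params.p_dm_first_node_neg
    dm_local = params.p_dm_after_local_pos if positive else params.p_dm_after_local_neg
    dm_ax = (
        params.p_dm_after_axillary_pos if positive else params.p_dm_after_axillary_neg
    )

    def transitions(state, hl, ha, t):
        h = halving_factor(t)
        q = params.q_other(settings.start_age + t - 1)
        if state == "DF":
            p_dm = dm_ax if ha else (dm_local if hl else dm_first)
            p_lr = h * params.p_local_recur_first
            p_ax = h * (
                params.p_axillary_recur_given_fn
                if (stratum.fn_elevated and not ha)
                else params.p_axillary_recur_first
            )
            stay = 1.0 - p_dm - p_lr - p_ax - q
            return [
                (("DM", hl, ha), p_dm),
                (("LR", True, ha), p_lr),
                (("AX", hl, True), p_ax),
                (("DO", hl, ha), q),
                (("DF", hl, ha), stay),
            ]
        if state == "LR":
            p_dm = dm_ax if ha else dm_local
            return [
                (("DM", hl, ha), p_dm),
                (("DO", hl, ha), q),
                (("DF", hl, ha), 1.0 - p_dm - q),
            ]
        if state == "AX":
            return [
                (("DM", hl, ha), dm_ax),
                (("DO", hl, ha), q),
                (("DF", hl, ha), 1.0 - dm_ax - q),
            ]
        if state == "DM":
            p = params.p_death_after_dm
            return [
                (("DC", hl, ha), p),
                (("DO", hl, ha), q),
                (("DM", hl, ha), 1.0 - p - q),
            ]
        return [((state, hl, ha), 1.0)]

    util = {
        "DF": params.u_disease_free,
        "LR": params.u_recurrence,
        "AX": params.u_recurrence,
        "DM": params.u_dm,
        "DC": 0.0,
        "DO": 0.0,
    }
    annual_cost = {
        "DF": costs.c_followup_annual,
        "LR": costs.c_followup_annual,
        "AX": costs.c_followup_annual,
        "DM": costs.c_dm_annual,
        "DC": 0.0,
        "DO": 0.0,
    }

    dist = {("DF", False, False): 1.0}
    out = {
        "qalys_discounted": 0.0,
        "qalys_undiscounted": 0.0,
        "cost_discounted": stratum.upfront_cost,
        "cost_undiscounted": stratum.upfront_cost,
        "life_years": 0.0,
        "years_disease_free": 0.0,
        "axillary_recurrences": 0.0,
        "distant_metastases": 0.0,
    }

    def marginal(d):
        m = defaultdict(float)
        for (state, _, _), pr in d.items():
            m[state] += pr
        return m

    for t in range(1, settings.horizon + 1):
        new = defaultdict(float)
        flows = defaultdict(float)
        for key, pr in dist.items():
            state, hl, ha = key
            for nkey, tp in transitions(state, hl, ha, t):
                new[nkey] += pr * tp
                nstate = nkey[0]
                if nstate != state and nstate in ("LR", "AX", "DM", "DC", "DO"):
                    flows[nstate] += pr * tp
                if state == "DF" and nstate == "AX" and not ha:
                    flows["first_ax"] += pr * tp
        prev_m, new_m = marginal(dist), marginal(new)
        hcc = {
            s: (0.5 * (prev_m[s] + new_m[s]) if settings.half_cycle_correction
                else new_m[s])
            for s in util
        }
        alive = sum(hcc[s] for s in ("DF", "LR", "AX", "DM"))
        qaly = (
            sum(hcc[s] * util[s] for s in util)
            - stratum.p_lymphoedema * params.lymphoedema_disutility * alive
        )
        cost = (
            sum(hcc[s] * annual_cost[s] for s in util)
            + stratum.p_lymphoedema * alive * costs.c_lymph_annual
            + flows["LR"] * costs.c_local_recur_event
            + flows["AX"] * costs.c_axillary_recur_event
            + flows["DC"] * costs.c_death_cancer
            + flows["DO"] * costs.c_death_other
        )
        disc = settings.discount_factor(t)
        out["qalys_discounted"] += qaly * disc
        out["qalys_undiscounted"] += qaly
        out["cost_discounted"] += cost * disc
        out["cost_undiscounted"] += cost
        out["life_years"] += alive
        out["years_disease_free"] += hcc["DF"]
        out["axillary_recurrences"] += flows["first_ax"]
        out["distant_metastases"] += flows["DM"]
        dist = new
    return {k: 1000.0 * v for k, v in out.items()} | {
        "cost_discounted": 1000.0 * out["cost_discounted"],
        "cost_undiscounted": 1000.0 * out["cost_undiscounted"],
    }


TOY_PARAMS = dict(
    p_local_recur_first=0.10,
    p_axillary_recur_first=0.05,
    p_axillary_recur_given_fn=0.20,
    p_dm_first_node_pos=0.15,
    p_dm_after_local_pos=0.30,
    p_dm_after_axillary_pos=0.40,
    p_death_after_dm=0.50,
    other_cause_mortality=np.full(21, 0.01),
)


class TestEnumerationOracle:
    @pytest.mark.parametrize("fn_elevated", [False, True])
    @pytest.mark.parametrize("hcc", [True, False])
    def test_engine_matches_exact_enumeration(self, fn_elevated, hcc):
        params = ParameterSet(**TOY_PARAMS)
        costs = CostSet()
        settings = ModelSettings(horizon=4, half_cycle_correction=hcc)
        stratum = make_stratum(fn_elevated=fn_elevated)
        expected = enumerate_stratum(stratum, params, costs, settings)
        got = run_cohort([stratum], params, costs, settings).at(4)
        for key, ref in expected.items():
            assert got[key] == pytest.approx(ref, rel=1e-12), key

    def test_engine_matches_enumeration_at_base_case(self, base_params, base_costs):
        settings = ModelSettings()
        stratum = make_stratum(fn_elevated=True, p_lymph=0.119)
        expected = enumerate_stratum(stratum, base_params, base_costs, settings)
        got = run_cohort([stratum], base_params, base_costs, settings).at(20)
        for key, ref in expected.items():
            assert got[key] == pytest.approx(ref, rel=1e-12), key

    def test_two_cycle_toy_frozen_value(self):
        # frozen from the enumeration oracle above (independent DP), guarding
        # against the oracle and engine drifting together
        params = ParameterSet(**TOY_PARAMS)
        settings = ModelSettings(horizon=2)
        stratum = make_stratum(fn_elevated=True)
        got = run_cohort([stratum], params, CostSet(), settings).at(2)
        assert got["qalys_undiscounted"] == pytest.approx(1825.334400, abs=1e-5)
        assert got["qalys_discounted"] == pytest.approx(1698.802630, abs=1e-5)


class TestScheduleConstruction:
    def test_halving_rule_applied_to_first_event_recurrences(
        self, base_params, base_settings
    ):
        sched = build_schedule(make_stratum(), base_params, base_settings)
        m = sched.matrices
        # local recurrence from disease free: 0.0055, then halved twice
        assert m[0, 0, 1] == pytest.approx(0.0055)
        assert m[5, 0, 1] == pytest.approx(0.00275)  # cycle 6
        assert m[10, 0, 1] == pytest.approx(0.001375)  # cycle 11
        # distant metastases as first event is not halved
        assert m[0, 0, 7] == m[19, 0, 7] == pytest.approx(0.0126)

    def test_fn_elevation_applies_before_first_axillary_recurrence_only(
        self, base_params, base_settings
    ):
        sched = build_schedule(
            make_stratum(fn_elevated=True), base_params, base_settings
        )
        m = sched.matrices[0]
        assert m[0, 4] == pytest.approx(0.016)  # naive disease free -> axillary
        assert m[5, 4] == pytest.approx(0.0008)  # post-axillary disease free

    def test_rows_are_stochastic_and_dead_states_absorbing(
        self, base_params, base_settings
    ):
        for fn in (False, True):
            sched = build_schedule(make_stratum(fn_elevated=fn), base_params,
                                   base_settings)
            np.testing.assert_allclose(sched.matrices.sum(axis=2), 1.0, atol=1e-12)
            assert np.all(sched.matrices >= 0)
            for t in range(base_settings.horizon):
                assert sched.matrices[t, 8, 8] == 1.0
                assert sched.matrices[t, 9, 9] == 1.0

    def test_infeasible_competing_probabilities_named(self, base_settings):
        params = ParameterSet(p_dm_after_axillary_pos=0.999)
        with pytest.raises(InfeasibleParametersError) as exc:
            build_schedule(make_stratum(), params, base_settings)
        assert exc.value.cycle == 1
        assert exc.value.state in (
            HealthState.DISEASE_FREE,  # post-axillary layer hits the cap first
            HealthState.AXILLARY_RECURRENCE,
        )

    def test_mortality_follows_age_as_cohort_ages(self, base_params, base_settings):
        sched = build_schedule(make_stratum(), base_params, base_settings)
        q = [sched.matrices[t, 0, 9] for t in range(20)]
        np.testing.assert_allclose(q, base_params.other_cause_mortality[:20])


class TestCohortAccounting:
    def test_mass_conservation_every_cycle_every_stratum(
        self, base_params, base_costs, base_settings
    ):
        for strategy in StrategyId:
            strata = build_strata(strategy, base_params, base_costs)
            res = run_cohort(strata, base_params, base_costs, base_settings,
                             collect_trace=True)
            for occ in res.trace.occupancy.values():
                np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)

    def test_counters_non_decreasing_and_bounded(self, base_params, base_costs,
                                                 base_settings):
        res = run_strategy(StrategyId.SLNB, base_params, base_costs, base_settings)
        for name in ("axillary_recurrences", "distant_metastases", "cancer_deaths",
                     "other_deaths"):
            s = res.series[name]
            assert np.all(np.diff(s) >= 0)
            assert s[-1] <= 1000.0
        assert res.at(5)["axillary_recurrences"] <= res.at(20)["axillary_recurrences"]

    def test_zero_discount_makes_discounted_equal_undiscounted(
        self, base_params, base_costs
    ):
        settings = ModelSettings(discount_rate=0.0)
        res = run_strategy(StrategyId.ALND, base_params, base_costs, settings)
        final = res.at(20)
        assert final["qalys_discounted"] == pytest.approx(
            final["qalys_undiscounted"], rel=1e-14
        )
        assert final["cost_discounted"] == pytest.approx(
            final["cost_undiscounted"], rel=1e-14
        )

    def test_positive_discount_shrinks_qalys(self, base_params, base_costs,
                                             base_settings):
        final = run_strategy(
            StrategyId.ALND, base_params, base_costs, base_settings
        ).at(20)
        assert final["qalys_discounted"] < final["qalys_undiscounted"]

    def test_symmetry_null_is_exact(self, symmetric_inputs):
        params, costs, settings = symmetric_inputs
        slnb = run_strategy(StrategyId.SLNB, params, costs, settings)
        alnd = run_strategy(StrategyId.ALND, params, costs, settings)
        diff = compare(slnb, alnd).difference(20)
        for key, value in diff.items():
            assert value == pytest.approx(0.0, abs=1e-9), key

    def test_trace_exports_tidy_csv(self, base_params, base_costs, base_settings,
                                    tmp_path):
        res = run_strategy(StrategyId.ALND, base_params, base_costs, base_settings,
                           collect_trace=True)
        df = res.trace.to_frame()
        assert set(df.columns) == {"strategy", "stratum", "cycle", "state",
                                   "occupancy"}
        assert set(df["state"]) == {s.value for s in HealthState}
        path = tmp_path / "trace.csv"
        res.trace.to_csv(path)
        assert path.exists()


class TestComparison:
    def test_identical_arms_give_zero_differences(self, base_params, base_costs,
                                                  base_settings):
        res = run_strategy(StrategyId.ALND, base_params, base_costs, base_settings)
        cmp = compare(res, res)
        assert all(v == 0.0 for v in cmp.difference(20).values())

    def test_base_case_classification_favours_slnb(self):
        cmp = run_comparison()
        assert cmp.classification(20, discounted=True) == "SLNB dominant"
        assert cmp.classification(20, discounted=False) == "SLNB dominant"

    def test_icer_reported_when_more_effective_and_more_costly(self, base_params,
                                                               base_settings):
        # make every SLNB pathway far more expensive than ALND
        costs = CostSet(
            c_slnb_neg=30000.0, c_slnb_pos_then_alnd=30000.0,
            c_slnb_fail_then_alnd=30000.0,
        )
        cmp = run_comparison(base_params, costs, base_settings)
        diff = cmp.difference(20)
        assert diff["qalys_discounted"] > 0 and diff["cost_discounted"] > 0
        label = cmp.classification(20)
        assert label.startswith("ICER = ")
        assert float(label.split("=")[1].split("per")[0]) > 0

    def test_mismatched_settings_rejected(self, base_params, base_costs):
        a = run_strategy(StrategyId.ALND, base_params, base_costs, ModelSettings())
        b = run_strategy(
            StrategyId.SLNB, base_params, base_costs,
            ModelSettings(discount_rate=0.0),
        )
        with pytest.raises(ValueError, match="settings"):
            compare(b, a)

    def test_short_horizon_table_has_single_column_block(self, base_params,
                                                         base_costs):
        settings = ModelSettings(horizon=5)
        cmp = run_comparison(base_params, base_costs, settings)
        table = cmp.to_table()
        assert "SLNB_5y" in table.columns
        assert not any(c.endswith("_20y") for c in table.columns)
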