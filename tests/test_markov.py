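"""Markov cohort engine: strategy application, trace propagation against a
matrix-power oracle, closed-form accrual checks, ICER conventions and the
sensitivity analyses."""

import numpy as np
import pytest

from ckdcare.errors import ValidationError
from ckdcare.markov import (
    CohortTrace,
    MarkovSpec,
    StrategyConfig,
    accumulate,
    apply_strategy,
    default_markov_spec,
    icer,
    null_strategy,
    one_way_analysis,
    psa,
    run_cea,
    run_cohort,
    scenario_analysis,
    threshold_analysis,
)


def two_state_spec(p_die=0.2, discount=0.0, **kw):
    """Toy chain: alive -> dead with constant hazard."""
    return MarkovSpec(
        states=("alive", "dead"),
        transitions=np.array([[1 - p_die, p_die], [0.0, 1.0]]),
        state_costs=np.array(kw.pop("state_costs", [0.0, 0.0])),
        utilities=np.array([1.0, 0.0]),
        discount_rate=discount,
        stage_edges={},
        **kw,
    )


@pytest.fixture(scope="module")
def ckd_spec():
    return default_markov_spec()


class TestSpecValidation:
    def test_row_sums_checked(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            MarkovSpec(
                states=("a", "dead"),
                transitions=np.array([[0.7, 0.2], [0.0, 1.0]]),
                state_costs=np.zeros(2),
                utilities=np.array([1.0, 0.0]),
            )

    def test_dead_must_be_absorbing(self):
        with pytest.raises(ValidationError, match="absorbing"):
            MarkovSpec(
                states=("a", "dead"),
                transitions=np.array([[0.8, 0.2], [0.1, 0.9]]),
                state_costs=np.zeros(2),
                utilities=np.array([1.0, 0.0]),
            )

    def test_dead_utility_must_be_zero(self):
        with pytest.raises(ValidationError, match="utility"):
            MarkovSpec(
                states=("a", "dead"),
                transitions=np.array([[0.8, 0.2], [0.0, 1.0]]),
                state_costs=np.zeros(2),
                utilities=np.array([1.0, 0.1]),
            )


class TestApplyStrategy:
    def test_relative_risk_moves_mass_to_diagonal(self, ckd_spec):
        spec, _ = ckd_spec
        strat = StrategyConfig(rr_stage3_to_4=0.8, rr_stage4_to_5=1.0, rr_complications=1.0)
        i, j = spec.index("CKD3"), spec.index("CKD4")
        base, eff = spec.transitions, apply_strategy(spec, strat, 0)
        assert eff[i, j] == pytest.approx(base[i, j] * 0.8)
        assert eff[i, i] == pytest.approx(base[i, i] + base[i, j] * 0.2)
        assert np.allclose(eff.sum(axis=1), 1.0, atol=1e-12)

    def test_effect_expires_after_duration(self, ckd_spec):
        spec, strat = ckd_spec
        assert apply_strategy(spec, strat, 5) is spec.transitions
        assert not np.allclose(apply_strategy(spec, strat, 4), spec.transitions)

    def test_null_strategy_leaves_matrix_unchanged(self, ckd_spec):
        spec, _ = ckd_spec
        assert np.array_equal(apply_strategy(spec, null_strategy(), 0), spec.transitions)


class TestRunCohort:
    def test_geometric_decay_toy_chain(self):
        trace = run_cohort(two_state_spec())
        alive = trace.occupancy[:, 0]
        assert np.allclose(alive, 0.8 ** np.arange(len(alive)), atol=1e-12)

    def test_mass_conserved_and_death_monotone(self, ckd_spec):
        spec, strat = ckd_spec
        for s in (None, strat):
            trace = run_cohort(spec, s)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            dead = trace.occupancy[:, spec.index("dead")]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_matches_matrix_power_oracle_for_static_chain(self, ckd_spec):
        spec, _ = ckd_spec
        trace = run_cohort(spec, None)
        for t in (1, 3, 10, trace.n_cycles):
            expected = spec.start_distribution @ np.linalg.matrix_power(spec.transitions, t)
            assert np.allclose(trace.occupancy[t], expected, atol=1e-12)

    def test_lifetime_stops_by_age_100(self):
        spec = two_state_spec(p_die=0.001, start_age=60.0)
        trace = run_cohort(spec)
        assert trace.n_cycles == 40

    def test_numeric_horizon(self):
        spec = two_state_spec(horizon=7)
        assert run_cohort(spec).n_cycles == 7


class TestAccumulate:
    def test_undiscounted_qalys_geometric_series(self):
        spec = two_state_spec(p_die=0.2, discount=0.0, start_age=0.0)
        trace = run_cohort(spec)
        _, qalys = accumulate(trace, spec)
        assert qalys == pytest.approx(5.0, abs=1e-4)

    def test_discounted_qalys_closed_form(self):
        spec = two_state_spec(p_die=0.2, discount=0.03, start_age=0.0)
        _, qalys = accumulate(run_cohort(spec), spec)
        assert qalys == pytest.approx(1.0 / (1.0 - 0.8 / 1.03), abs=1e-4)

    def test_zero_costs_everywhere(self):
        spec = two_state_spec()
        cost, _ = accumulate(run_cohort(spec), spec)
        assert cost == 0.0

    def test_program_cost_charged_to_living_only_within_duration(self):
        spec = two_state_spec(p_die=0.5, discount=0.0, horizon=4, start_age=0.0)
        strat = StrategyConfig(annual_program_cost=100.0, rr_stage3_to_4=1.0,
                               rr_stage4_to_5=1.0, rr_complications=1.0, effect_duration=2.0)
        cost, _ = accumulate(run_cohort(spec, strat), spec, strat)
        assert cost == pytest.approx(100.0 * (1.0 + 0.5))  # cycles 0 and 1 only

    def test_event_cost_charged_on_incident_transitions(self):
        spec = MarkovSpec(
            states=("well", "sick", "dead"),
            transitions=np.array([[0.7, 0.2, 0.1], [0.0, 0.9, 0.1], [0.0, 0.0, 1.0]]),
            state_costs=np.zeros(3),
            utilities=np.array([1.0, 0.5, 0.0]),
            event_costs={"sick": 1000.0},
            event_states=("sick",),
            discount_rate=0.0,
            horizon=1,
            stage_edges={},
        )
        cost, _ = accumulate(run_cohort(spec), spec)
        assert cost == pytest.approx(0.2 * 1000.0)

    def test_cost_doubling_is_linear(self, ckd_spec):
        spec, strat = ckd_spec
        res = run_cea(spec, strat)
        doubled = MarkovSpec(
            **{
                **{f: getattr(spec, f) for f in (
                    "states", "event_states", "dead_state", "stage_edges",
                    "discount_rate", "cycle_length", "start_age", "horizon",
                    "half_cycle_correction", "utilities", "transitions",
                    "start_distribution",
                )},
                "state_costs": spec.state_costs * 2,
                "event_costs": {k: 2 * v for k, v in spec.event_costs.items()},
            }
        )
        strat2 = StrategyConfig(**{**strat.__dict__, "annual_program_cost": 2 * strat.annual_program_cost})
        res2 = run_cea(doubled, strat2)
        assert res2.incremental.delta_cost == pytest.approx(2 * res.incremental.delta_cost)
        assert res2.incremental.delta_qalys == pytest.approx(res.incremental.delta_qalys)

    def test_totals_non_increasing_in_discount_rate(self, ckd_spec):
        spec, strat = ckd_spec
        prev_cost, prev_q = np.inf, np.inf
        for rate in (0.0, 0.03, 0.06):
            s = MarkovSpec(**{**_spec_kwargs(spec), "discount_rate": rate})
            cost, q = accumulate(run_cohort(s, strat), s, strat)
            assert cost <= prev_cost and q <= prev_q
            prev_cost, prev_q = cost, q

    def test_half_cycle_correction_brackets_start_of_cycle(self):
        base = two_state_spec(p_die=0.2, discount=0.0, start_age=0.0)
        hcc = two_state_spec(p_die=0.2, discount=0.0, start_age=0.0, half_cycle_correction=True)
        _, q0 = accumulate(run_cohort(base), base)
        _, q1 = accumulate(run_cohort(hcc), hcc)
        assert q1 < q0  # mid-cycle accrual averages in the post-transition mass


def _spec_kwargs(spec):
    return {f: getattr(spec, f) for f in (
        "states", "transitions", "state_costs", "utilities", "event_costs",
        "event_states", "dead_state", "stage_edges", "discount_rate",
        "cycle_length", "start_distribution", "start_age", "horizon",
        "half_cycle_correction",
    )}


class TestIcer:
    def test_ratio_on_rounded_published_style_totals(self):
        # 7,512 Baht over 0.4 QALYs -> 18,780 Baht/QALY
        res = icer(486898.0, 11.22, 479386.0, 10.82)
        assert res.delta_cost == pytest.approx(7512.0)
        assert res.delta_qalys == pytest.approx(0.4)
        assert res.icer == pytest.approx(18780.0)
        assert res.label == "icer"

    def test_identical_strategies_undefined(self):
        res = icer(100.0, 2.0, 100.0, 2.0)
        assert res.icer is None and res.label == "undefined"

    def test_dominance_labels(self):
        assert icer(99.0, 2.1, 100.0, 2.0).label == "dominant"
        assert icer(101.0, 1.9, 100.0, 2.0).label == "dominated"


class TestStrategiesAndSensitivity:
    def test_null_strategy_recovers_comparator_exactly(self, ckd_spec):
        spec, _ = ckd_spec
        res = run_cea(spec, null_strategy("a"), null_strategy("b"))
        assert res.incremental.delta_cost == 0.0
        assert res.incremental.delta_qalys == 0.0

    def test_stronger_effect_never_reduces_qalys(self, ckd_spec):
        spec, strat = ckd_spec
        base_q = run_cea(spec, strat).qalys_intervention
        for field in ("rr_stage3_to_4", "rr_stage4_to_5", "rr_complications"):
            stronger = StrategyConfig(**{**strat.__dict__, field: getattr(strat, field) * 0.5})
            assert run_cea(spec, stronger).qalys_intervention >= base_q - 1e-12

    def test_icer_non_decreasing_in_program_cost(self, ckd_spec):
        spec, strat = ckd_spec
        table, best = threshold_analysis(spec, strat, [1000, 3000, 6000, 15000], 160000.0)
        icers = table["icer_baht_per_qaly"].to_numpy()
        assert np.all(np.diff(icers) > 0)
        assert best is not None and best in table["annual_program_cost"].values

    def test_free_effective_program_dominates(self, ckd_spec):
        spec, strat = ckd_spec
        free = StrategyConfig(**{**strat.__dict__, "annual_program_cost": 0.0})
        res = run_cea(spec, free)
        assert res.incremental.delta_qalys > 0
        assert res.incremental.delta_cost < run_cea(spec, strat).incremental.delta_cost

    def test_scenario_empty_overrides_is_base_case(self, ckd_spec):
        spec, strat = ckd_spec
        table = scenario_analysis(spec, strat, {"base": {}})
        base = run_cea(spec, strat)
        assert table.loc[0, "icer_baht_per_qaly"] == pytest.approx(base.incremental.icer)

    def test_scenario_unknown_parameter_rejected(self, ckd_spec):
        spec, strat = ckd_spec
        with pytest.raises(ValidationError, match="unknown parameter"):
            scenario_analysis(spec, strat, {"bad": {"no_such_knob": 1.0}})

    def test_one_way_table_is_tornado_ordered(self, ckd_spec):
        spec, strat = ckd_spec
        table = one_way_analysis(spec, strat, rel=0.2)
        swings = table["swing"].to_numpy()
        assert np.all(np.diff(swings[~np.isnan(swings)]) <= 1e-9)

    def test_psa_hook_runs_user_distributions(self, ckd_spec):
        spec, strat = ckd_spec

        def sampler(rng):
            return {"annual_program_cost": float(rng.uniform(500, 2000))}

        table = psa(spec, strat, sampler, n=5, seed=1)
        assert len(table) == 5
        assert table["icer_baht_per_qaly"].notna().all()
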