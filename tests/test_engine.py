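"""Daily engine: satisfaction rules, probability updates, full runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from ugsim.city import CityLayout, GreenSpace, Zone
from ugsim.engine import (
    DISSATISFIED,
    NEUTRAL,
    P_FLOOR,
    SATISFIED,
    EngineError,
    SimParams,
    Simulation,
    daily_visit_probability,
    evaluate_satisfaction,
    reorder_park_list,
    run_simulation,
    social_influence_update,
    update_probability,
)
from ugsim.population import DemogConfig, generate_population


def _uniform_layout(n_parks=1, sunshine=1.0, quality="medium"):
    zone = Zone(id="z0", geometry=box(0, 0, 1000, 1000), resident_count=100,
                ses_shares=np.array([0.25, 0.25, 0.25, 0.25]), walkability_quartile=3)
    parks = [
        GreenSpace(f"p{i}", (200.0 + 300 * i, 500.0), 10.0, quality=quality,
                   catchment_radius_m=3000.0)
        for i in range(n_parks)
    ]
    return CityLayout(name="u", zones=[zone], green_spaces=parks, sunshine_factor=sunshine)


def _pop(layout, n_override=None, seed=0, params=None, demog=None):
    demog = demog or DemogConfig(scale=1.0, seed=seed,
                                 dog_rate_by_ses={g: 0.0 for g in ("AB", "C1", "C2", "DE")})
    params = params or SimParams(seed=seed)
    if n_override is not None:
        layout.zones[0].resident_count = n_override
    return generate_population(layout, demog, params)


class TestDailyVisitProbability:
    def test_product_of_factors(self):
        params = SimParams(scenario="walkability", sunshine_factor=0.88)
        assert daily_visit_probability(0.07, 2.0, params) == pytest.approx(0.1232)

    def test_social_only_forces_unit_walkability(self):
        params = SimParams(scenario="social_only", sunshine_factor=1.0)
        assert daily_visit_probability(0.07, 2.0, params) == pytest.approx(0.07)

    def test_capped_at_one(self):
        params = SimParams(scenario="walkability", sunshine_factor=1.0)
        assert daily_visit_probability(0.9, 2.0, params) == 1.0


class TestEvaluateSatisfaction:
    def test_homophilic_dissatisfied_above_threshold(self):
        # high-SES focal, 6 of 10 co-visitors in the low pair
        tally = np.array([2, 2, 3, 3])
        assert evaluate_satisfaction(True, False, 0.5, tally) == DISSATISFIED

    def test_homophilic_boundary_is_strict(self):
        tally = np.array([3, 2, 3, 2])  # exactly half other-group
        assert evaluate_satisfaction(True, False, 0.5, tally) == SATISFIED

    def test_heterophilic_minimum_is_inclusive(self):
        tally = np.array([3, 2, 3, 2])  # half high-SES meets ht = 0.5
        assert evaluate_satisfaction(False, True, 0.5, tally) == SATISFIED

    def test_heterophilic_below_minimum_dissatisfied(self):
        tally = np.array([1, 0, 4, 5])
        assert evaluate_satisfaction(False, True, 0.5, tally) == DISSATISFIED

    def test_low_homophilic_other_group_is_high(self):
        tally = np.array([5, 2, 1, 2])  # 70% high
        assert evaluate_satisfaction(False, False, 0.5, tally) == DISSATISFIED

    def test_empty_park_neutral(self):
        assert evaluate_satisfaction(True, False, 0.5, np.zeros(4)) == NEUTRAL

    def test_subsampling_used_for_big_rosters(self, rng):
        tally = np.array([500, 0, 500, 0])
        outcomes = {
            evaluate_satisfaction(True, False, 0.5, tally, rng=rng, sample_max=30)
            for _ in range(50)
        }
        assert outcomes <= {SATISFIED, DISSATISFIED} and len(outcomes) == 2


class TestUpdateProbability:
    def test_satisfied_grows(self):
        assert update_probability(0.2, SATISFIED, 0.25, False) == pytest.approx(0.25)

    def test_dissatisfied_shrinks(self):
        assert update_probability(0.2, DISSATISFIED, 0.25, False) == pytest.approx(0.15)

    def test_dog_floor_dominates(self):
        assert update_probability(0.3, DISSATISFIED, 0.25, True, floor=0.33) == 0.33

    def test_cap_and_floor(self):
        assert update_probability(0.9, SATISFIED, 0.25, False) == 1.0
        assert update_probability(1e-4, DISSATISFIED, 0.25, False) == P_FLOOR

    @settings(deadline=None, derandomize=True)
    @given(
        p=st.floats(1e-4, 1.0),
        a=st.floats(0.0, 0.99),
        outcome=st.sampled_from([SATISFIED, DISSATISFIED, NEUTRAL]),
        dog=st.booleans(),
    )
    def test_update_stays_in_bounds(self, p, a, outcome, dog):
        new = update_probability(p, outcome, a, dog)
        assert P_FLOOR <= new <= 1.0
        if dog:
            assert new >= 0.33


class TestReorderParkList:
    def test_dissatisfied_moves_to_tail(self):
        assert reorder_park_list(["A", "B", "C"], "A", DISSATISFIED) == ["B", "C", "A"]

    def test_satisfied_stays_or_moves_to_head(self):
        assert reorder_park_list(["A", "B", "C"], "A", SATISFIED) == ["A", "B", "C"]
        assert reorder_park_list(["A", "B", "C"], "B", SATISFIED) == ["B", "A", "C"]

    def test_singleton_unchanged(self):
        assert reorder_park_list(["A"], "A", DISSATISFIED) == ["A"]

    def test_unknown_park_errors(self):
        with pytest.raises(EngineError):
            reorder_park_list(["A"], "Z", SATISFIED)

    @settings(deadline=None, derandomize=True)
    @given(
        lst=st.lists(st.integers(0, 20), min_size=1, max_size=8, unique=True),
        pos=st.integers(0, 7),
        outcome=st.sampled_from([SATISFIED, DISSATISFIED, NEUTRAL]),
    )
    def test_reorder_is_a_permutation(self, lst, pos, outcome):
        park = lst[pos % len(lst)]
        new = reorder_park_list(lst, park, outcome)
        assert sorted(new) == sorted(lst)
        if outcome == DISSATISFIED:
            assert new[-1] == park
        elif outcome == SATISFIED:
            assert new[0] == park
        else:
            assert new == lst


class TestSocialInfluence:
    def test_inside_band_unchanged(self):
        assert social_influence_update(0.05, 0.2, 0.2, 0.1) == 0.05

    def test_zero_nudge_disabled(self):
        assert social_influence_update(0.05, 0.0, 0.2, 0.0) == 0.05

    def test_nudge_toward_group_norm(self):
        assert social_influence_update(0.05, 0.0, 0.2, 0.1) == pytest.approx(0.065)


class TestSelectPark:
    def _sim(self, quality_scenario, park_quality, avoid):
        layout = _uniform_layout(n_parks=1, quality=park_quality)
        params = SimParams(
            scenario="quality" if quality_scenario else "social_only",
            avoid_low_quality_prob_by_ses={"AB": avoid, "C1": avoid, "C2": avoid, "DE": avoid},
            seed=1,
        )
        pop = _pop(layout, n_override=10, params=params)
        return Simulation(layout, pop, params)

    def test_medium_park_always_selected(self):
        sim = self._sim(True, "medium", 1.0)
        sel, col = sim._select_parks(np.arange(10))
        assert (sel == 0).all() and (col == 0).all()

    def test_quality_rule_disabled_outside_scenario(self):
        sim = self._sim(False, "low", 1.0)
        sel, _ = sim._select_parks(np.arange(10))
        assert (sel == 0).all()

    def test_certain_avoidance_yields_no_visit(self):
        sim = self._sim(True, "low", 1.0)
        sel, _ = sim._select_parks(np.arange(10))
        assert (sel == -1).all()


class TestStepAndRun:
    def test_zero_probability_no_visits(self):
        layout = _uniform_layout()
        params = SimParams(days=5, seed=0)
        pop = _pop(layout, n_override=20, params=params)
        pop.p0[:] = 0.0
        log = run_simulation(layout, pop, params)
        assert log.total_visits == 0 and (log.daily_totals == 0).all()

    def test_lone_visitor_is_neutral(self):
        layout = _uniform_layout()
        params = SimParams(days=30, a=0.25, social_influence_nudge=0.0, seed=0)
        pop = _pop(layout, n_override=1, params=params)
        pop.p0[:] = 1.0
        log = run_simulation(layout, pop, params)
        # neutral outcomes leave p unchanged, so the lone agent visits daily
        assert log.visits[0] == 30
        assert (log.roster.sum(axis=(1, 2)) == 1).all()

    def test_fixed_seed_reproducible(self, small_layout):
        params = SimParams(days=30, seed=4)
        demog = DemogConfig(seed=4)
        pops = [generate_population(small_layout, demog, params) for _ in range(2)]
        logs = [run_simulation(small_layout, p, params) for p in pops]
        assert np.array_equal(logs[0].visits, logs[1].visits)
        assert np.array_equal(logs[0].roster, logs[1].roster)

    def test_zero_days(self, small_layout, small_pop):
        log = run_simulation(small_layout, small_pop, SimParams(days=0))
        assert log.total_visits == 0 and log.roster.shape[0] == 0

    def test_visits_bounded_by_days(self, small_layout):
        params = SimParams(days=50, seed=2)
        pop = generate_population(small_layout, DemogConfig(seed=2), params)
        log = run_simulation(small_layout, pop, params)
        assert (log.visits <= 50).all()

    def test_roster_conservation(self, small_layout):
        params = SimParams(days=60, seed=3)
        pop = generate_population(small_layout, DemogConfig(seed=3), params)
        log = run_simulation(small_layout, pop, params)
        assert (log.roster.sum(axis=(1, 2)) == log.daily_totals).all()
        assert log.daily_totals.sum() == log.total_visits

    def test_propensity_stays_in_bounds(self, small_layout):
        params = SimParams(days=120, seed=5)
        pop = generate_population(small_layout, DemogConfig(seed=5), params)
        sim = Simulation(small_layout, pop, params)
        for _ in range(120):
            sim.step_day()
            assert (sim.p >= P_FLOOR).all() and (sim.p <= 1.0).all()

    def test_single_binomial_agent_oracle(self):
        # a = 0 and a single agent: visits ~ Binomial(1460, 0.1)
        layout = _uniform_layout()
        params = SimParams(days=1460, a=0.0, social_influence_nudge=0.0, seed=8)
        pop = _pop(layout, n_override=1, params=params)
        pop.p0[:] = 0.1
        log = run_simulation(layout, pop, params)
        assert abs(log.visits[0] - 146) <= 34  # 3 SD of Binomial(1460, 0.1)

    def test_single_ses_population_never_dissatisfied(self):
        layout = _uniform_layout()
        layout.zones[0].ses_shares = np.array([1.0, 0.0, 0.0, 0.0])
        params = SimParams(days=40, social_influence_nudge=0.0, seed=6)
        pop = _pop(layout, n_override=50, params=params)
        sim = Simulation(layout, pop, params)
        p_prev = sim.p.copy()
        for _ in range(40):
            sim.step_day()
            assert (sim.p >= p_prev - 1e-12).all()
            p_prev = sim.p.copy()
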