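"""NPV discounting, scenario comparison and the break-even solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from careernpv import (
    BASELINE,
    EARLY,
    NO_PROMOTION,
    STALLED,
    TRAJECTORIES,
    BreakevenUnreachableError,
    EconomicParams,
    GeneratorConfig,
    Rank,
    SpecialtyRecord,
    breakeven_additional_years,
    compare_to_baseline,
    generate_compensation_table,
    make_career_plan,
    npv,
    salary_stream,
    scenario_npv,
    scenario_npv_closed_form,
)
from careernpv.compensation import PERCENTILES
from _oracles import brute_breakeven, brute_npv, brute_scenario_npv


def toy_record(s_assistant=100.0, s_associate=120.0, s_full=150.0, T=20, name="toy"):
    salaries = {}
    for rank, s in zip(Rank, (s_assistant, s_associate, s_full)):
        for j, pct in enumerate(PERCENTILES):
            salaries[(rank, pct)] = s * (1.1**j)
    return SpecialtyRecord(name, T, salaries)


class TestNPV:
    def test_zero_discount_is_plain_sum(self):
        assert npv(np.array([100.0, 100.0, 100.0]), 0.0) == 300.0

    def test_single_period_beginning_convention_undiscounted(self):
        assert npv(np.array([100.0]), 0.37) == 100.0

    def test_end_convention_is_beginning_over_one_plus_r(self):
        stream = np.array([100.0, 103.0, 106.09, 150.0])
        r = 0.04
        assert npv(stream, r, "end_of_year") == npv(stream, r, "beginning_of_year") / (1 + r)

    def test_growth_equals_discount_collapses_to_s_times_t(self, alpha):
        # (1+g)/(1+r) = 1: every discounted year contributes the starting salary
        plan = make_career_plan("standard", 10)
        p = EconomicParams(wage_growth=0.04, discount_rate=0.04)
        stream = salary_stream(alpha, 50, NO_PROMOTION, plan, p)
        value = npv(stream, p.discount_rate)
        assert value == pytest.approx(100_000.0 * 10, rel=1e-12)
        assert value == pytest.approx(brute_npv([100_000.0] * 10, [1.0] * 10, 0.04, 0.04), rel=1e-12)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            npv(np.array([]), 0.04)

    def test_zero_rate_equals_undiscounted_sum(self, alpha, std_plan, default_params):
        stream = salary_stream(alpha, 50, BASELINE, std_plan, default_params)
        assert npv(stream, 0.0) == pytest.approx(stream.sum(), rel=1e-14)


class TestScenarioNPV:
    def test_undiscounted_no_promotion_is_salary_times_t(self, alpha):
        plan = make_career_plan("standard", 35)
        p = EconomicParams(wage_growth=0.0, discount_rate=0.0)
        assert scenario_npv(alpha, 50, NO_PROMOTION, plan, p).npv == pytest.approx(3_500_000.0)

    def test_defaults_applied_when_params_omitted(self, alpha, std_plan):
        implicit = scenario_npv(alpha, 50, BASELINE, std_plan)
        explicit = scenario_npv(alpha, 50, BASELINE, std_plan, EconomicParams(0.03, 0.04))
        assert implicit.npv == explicit.npv

    @pytest.mark.parametrize("trajectory", list(TRAJECTORIES.values()), ids=lambda t: t.name)
    @pytest.mark.parametrize("convention", ["beginning_of_year", "end_of_year"])
    def test_matches_brute_force_and_closed_form(self, alpha, trajectory, convention):
        plan = make_career_plan("standard", alpha.career_years)
        p = EconomicParams(0.03, 0.04, convention)
        value = scenario_npv(alpha, 50, trajectory, plan, p).npv
        brute = brute_scenario_npv(alpha, 50, trajectory, plan, 0.03, 0.04, convention)
        closed = scenario_npv_closed_form(alpha, 50, trajectory, plan, p)
        assert value == pytest.approx(brute, rel=1e-9)
        assert value == pytest.approx(closed, rel=1e-9)

    def test_part_time_plan_agrees_with_oracles(self, beta):
        plan = make_career_plan("part_time", beta.career_years)
        p = EconomicParams()
        for traj in TRAJECTORIES.values():
            value = scenario_npv(beta, 75, traj, plan, p).npv
            assert value == pytest.approx(
                brute_scenario_npv(beta, 75, traj, plan, 0.03, 0.04), rel=1e-9
            )
            assert value == pytest.approx(
                scenario_npv_closed_form(beta, 75, traj, plan, p), rel=1e-9
            )

    def test_npv_monotone_in_salaries_growth_discount_and_length(self, alpha):
        plan = make_career_plan("standard", 35)
        base = scenario_npv(alpha, 50, BASELINE, plan).npv
        assert scenario_npv(alpha, 75, BASELINE, plan).npv > base  # higher ladder
        assert (
            scenario_npv(alpha, 50, BASELINE, plan, EconomicParams(wage_growth=0.04)).npv > base
        )
        assert (
            scenario_npv(alpha, 50, BASELINE, plan, EconomicParams(discount_rate=0.05)).npv < base
        )
        longer = make_career_plan("standard", 36)
        assert scenario_npv(alpha, 50, BASELINE, longer).npv > base


class TestScenarioDeltas:
    def test_baseline_delta_is_exactly_zero(self, alpha, std_plan):
        d = compare_to_baseline(alpha, 50, BASELINE, std_plan)
        assert d.delta_vs_baseline == 0.0

    def test_early_positive_none_negative_on_monotone_record(self, alpha, std_plan):
        assert compare_to_baseline(alpha, 50, EARLY, std_plan).delta_vs_baseline > 0
        assert compare_to_baseline(alpha, 50, STALLED, std_plan).delta_vs_baseline < 0
        assert compare_to_baseline(alpha, 50, NO_PROMOTION, std_plan).delta_vs_baseline < 0

    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        pct=st.sampled_from(PERCENTILES),
        variant=st.sampled_from(["standard", "part_time", "early_retirement"]),
    )
    def test_scenario_ordering_on_generated_schedules(self, seed, pct, variant):
        sched = generate_compensation_table(GeneratorConfig(n_specialties=2, seed=seed))
        for rec in sched:
            plan = make_career_plan(variant, rec.career_years)
            values = [
                scenario_npv(rec, pct, t, plan).npv
                for t in (EARLY, BASELINE, STALLED, NO_PROMOTION)
            ]
            assert values == sorted(values, reverse=True)


class TestBreakeven:
    def test_identical_trajectories_need_zero_years(self, alpha, std_plan):
        res = breakeven_additional_years(alpha, 50, BASELINE, BASELINE, std_plan)
        assert res.years == 0
        assert res.years_fractional == 0.0

    def test_toy_record_matches_exhaustive_scan(self):
        rec = toy_record(100.0, 120.0, 150.0, T=20)
        plan = make_career_plan("standard", 20)
        p = EconomicParams(wage_growth=0.0, discount_rate=0.0)
        res = breakeven_additional_years(rec, 25, NO_PROMOTION, BASELINE, plan, p)
        expected = brute_breakeven(rec, 25, NO_PROMOTION, BASELINE, plan, 0.0, 0.0)
        assert res.years == expected
        # undiscounted arithmetic: baseline earns 7*100 + 7*120 + 6*150 = 2440
        # vs 20*100 = 2000; each extra year adds 100, so 5 years close the gap
        assert res.years == 5

    def test_fractional_refinement_brackets_the_integer(self, alpha, std_plan):
        res = breakeven_additional_years(alpha, 50, NO_PROMOTION, BASELINE, std_plan)
        assert res.years - 1 < res.years_fractional <= res.years
        assert res.extended_npv >= res.reference_npv

    def test_unreachable_under_heavy_discounting(self):
        rec = toy_record(100.0, 120.0, 150.0, T=20)
        plan = make_career_plan("standard", 20)
        p = EconomicParams(wage_growth=0.0, discount_rate=0.60)
        with pytest.raises(BreakevenUnreachableError) as exc:
            breakeven_additional_years(rec, 50, NO_PROMOTION, BASELINE, plan, p, max_extra=40)
        assert exc.value.residual_gap > 0

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        pct=st.sampled_from(PERCENTILES),
        deficit=st.sampled_from(["stalled", "none"]),
    )
    def test_solver_equals_scan_oracle_on_generated_schedules(self, seed, pct, deficit):
        sched = generate_compensation_table(GeneratorConfig(n_specialties=1, seed=seed))
        rec = sched.records[0]
        plan = make_career_plan("standard", rec.career_years)
        try:
            years = breakeven_additional_years(
                rec, pct, TRAJECTORIES[deficit], BASELINE, plan, max_extra=40
            ).years
        except BreakevenUnreachableError:
            years = None
        assert years == brute_breakeven(
            rec, pct, TRAJECTORIES[deficit], BASELINE, plan, 0.03, 0.04, max_extra=40
        )

    def test_breakeven_grows_with_rank_salary_gap(self):
        plan = make_career_plan("standard", 35)
        years = []
        for uplift in (1.1, 1.3, 1.5):
            rec = toy_record(100_000.0, 100_000.0 * uplift, 100_000.0 * uplift**2, T=35,
                             name=f"uplift_{uplift}")
            res = breakeven_additional_years(
                rec, 50, NO_PROMOTION, BASELINE, plan, max_extra=300
            )
            years.append(res.years)
        assert years[0] > 0
        assert years == sorted(years)
        assert years[-1] > years[0]
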