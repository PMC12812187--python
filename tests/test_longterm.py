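import numpy as np
import pytest

from strokecea import longterm
from strokecea.parameters import WEEKS_PER_YEAR, draws_from_means
from strokecea.strategies import DEATH

from _oracles import lifetable_survival, microsim_undisc_qalys


def _no_recurrence(params):
    """Push the Weibull scale out so recurrence is numerically zero."""
    p = params.copy()
    p.weibull_log_scale = 60.0
    return p


def _no_mortality(params):
    p = params.copy()
    p.mortality_rate_age80 = 0.0
    p.mortality_rate_age99 = 0.0
    return p


class TestRecurrenceHazard:
    def test_normalization_is_identity_for_unit_hazard_ratios(self, params):
        p = params.copy()
        p.recurrence_hr = np.array([1.0, 1.0, 1.0])
        model = longterm.RecurrenceModel.from_draws(draws_from_means(p))
        assert model.normalization[0] == pytest.approx(1.0)

    def test_exponential_limit_constant_in_time(self, params):
        p = params.copy()
        p.weibull_log_shape = 0.0  # shape 1: constant hazard
        model = longterm.RecurrenceModel.from_draws(draws_from_means(p))
        early = longterm.recurrence_weekly_prob(0.0, 3, model)
        late = longterm.recurrence_weekly_prob(520.0, 3, model)
        assert early == pytest.approx(late, rel=1e-12)
        lam = model.scale_weeks[0]
        expected = 1 - np.exp(-model.normalization[0] * model.hr_by_state[0, 3] / lam)
        assert early == pytest.approx(expected, rel=1e-12)

    def test_hazard_decreases_over_time(self, params):
        model = longterm.RecurrenceModel.from_draws(draws_from_means(params))
        p52 = longterm.recurrence_weekly_prob(52.0, 3, model)
        p104 = longterm.recurrence_weekly_prob(104.0, 3, model)
        assert p104 < p52

    def test_dead_patients_cannot_recur(self, params):
        model = longterm.RecurrenceModel.from_draws(draws_from_means(params))
        with pytest.raises(ValueError):
            longterm.recurrence_weekly_prob(10.0, 6, model)


class TestRedistribution:
    def test_state0_gets_full_soc_vector(self, params):
        soc = params.mrs["SoC"]
        np.testing.assert_allclose(
            longterm.redistribute_on_recurrence(0, soc), soc
        )

    def test_state5_two_state_truncation(self, params):
        soc = params.mrs["SoC"]
        out = longterm.redistribute_on_recurrence(5, soc)
        np.testing.assert_allclose(out[:5], 0.0)
        np.testing.assert_allclose(
            out[5:], soc[5:] / soc[5:].sum()
        )

    def test_state3_matches_printed_ratios(self, params):
        out = longterm.redistribute_on_recurrence(3, params.mrs["SoC"])
        expected_tail = np.array([0.21, 0.19, 0.12, 0.24])
        np.testing.assert_allclose(
            out[3:], expected_tail / expected_tail.sum(), rtol=1e-12
        )

    def test_death_cannot_redistribute(self, params):
        with pytest.raises(ValueError):
            longterm.redistribute_on_recurrence(6, params.mrs["SoC"])


class TestTransitionMatrix:
    def test_rows_are_stochastic_every_sampled_cycle(self, params):
        draws = draws_from_means(params)
        for cycle in (0, 1, 52, 500, params.settings.n_cycles - 1):
            T = longterm.transition_matrix(cycle, draws)
            np.testing.assert_allclose(T.sum(axis=2), 1.0, atol=1e-12)

    def test_death_row_is_absorbing(self, params):
        draws = draws_from_means(params)
        T = longterm.transition_matrix(100, draws)
        expected = np.zeros(7)
        expected[DEATH] = 1.0
        np.testing.assert_array_equal(T[0, DEATH], expected)

    def test_identity_without_hazards(self, params):
        p = _no_mortality(_no_recurrence(params))
        T = longterm.transition_matrix(0, draws_from_means(p))
        np.testing.assert_allclose(T[0], np.eye(7), atol=1e-12)

    def test_death_probability_closed_form(self, params):
        # entry exactly at age 80 so cycle 0 uses the age-80 baseline rate
        p = _no_recurrence(params)
        p.settings.start_age = 80 - 90 / 365.25
        T = longterm.transition_matrix(0, draws_from_means(p))
        expected = 1 - np.exp(-0.001 * 6.91)
        assert T[0, 5, DEATH] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.00689, abs=5e-5)

    def test_cycle_outside_horizon_rejected(self, params):
        draws = draws_from_means(params)
        with pytest.raises(longterm.ModelError):
            longterm.transition_matrix(params.settings.n_cycles, draws)


class TestCohortRun:
    def test_dead_cohort_accrues_nothing(self, params):
        init = np.zeros(7)
        init[DEATH] = 1.0
        trace = longterm.run_cohort(init, params=params)
        assert trace.total_disc_cost == 0.0
        assert trace.total_disc_qalys == 0.0
        assert trace.total_undisc_qalys == 0.0

    def test_zero_hazard_zero_discount_closed_form(self, params):
        p = _no_mortality(_no_recurrence(params))
        p.settings.cost_discount_rate = 0.0
        p.settings.qaly_discount_rate = 0.0
        init = np.zeros(7)
        init[2] = 1.0  # utility 0.78
        trace = longterm.run_cohort(init, params=p)
        years = p.settings.n_cycles / WEEKS_PER_YEAR
        assert trace.total_undisc_qalys == pytest.approx(0.78 * years, rel=1e-12)
        assert trace.total_disc_qalys == pytest.approx(0.78 * years, rel=1e-12)

    def test_occupancy_conserved_and_death_monotone(self, params):
        trace = longterm.run_cohort(None, "SoC", params)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        death = trace.occupancy[:, DEATH]
        assert np.all(np.diff(death) >= -1e-12)

    def test_discounting_reduces_totals(self, params):
        trace = longterm.run_cohort(None, "SoC", params)
        assert trace.total_disc_qalys < trace.total_undisc_qalys

    def test_invalid_simplex_rejected(self, params):
        with pytest.raises(longterm.ModelError):
            longterm.run_cohort(np.full(7, 0.5), params=params)

    def test_lifetable_reproduced_without_excess_hazards(self, params):
        p = _no_recurrence(params)
        p.mortality_hr = np.ones(6)
        trace = longterm.run_cohort(None, "SoC", p)
        survival = 1.0 - trace.occupancy[1:, DEATH]
        alive0 = 1.0 - params.mrs["SoC"][DEATH]
        expected = alive0 * lifetable_survival(p, p.settings.n_cycles)
        np.testing.assert_allclose(survival, expected, rtol=1e-9)

    def test_recurrence_event_cost_accrues(self, params):
        p = params.copy()
        p.recurrence_acute_cost = 10_000.0
        with_cost = longterm.run_cohort(None, "SoC", p)
        without = longterm.run_cohort(None, "SoC", params)
        assert with_cost.total_disc_cost > without.total_disc_cost

    def test_trace_export(self, params):
        trace = longterm.run_cohort(None, "SoC", params)
        frame = trace.to_frame()
        assert {"cycle", "age", "mrs0", "mrs6", "disc_cost"} <= set(frame.columns)
        assert len(frame) == params.settings.n_cycles


def test_cohort_agrees_with_microsimulation(params):
    """Cohort expectations match a 10,000-walker microsimulation oracle."""
    trace = longterm.run_cohort(None, "SoC", params)
    mean, se = microsim_undisc_qalys(
        params, params.mrs["SoC"], n_walkers=10_000, seed=11
    )
    assert abs(trace.total_undisc_qalys - mean) < 3 * se


def test_survival_curve_export(params):
    frame = longterm.survival_curves(params)
    assert set(frame["initial_mrs"]) == set(range(6))
    # worse initial states never outlive better ones at the end of follow-up
    final = frame.groupby("initial_mrs")["survival"].last()
    assert np.all(np.diff(final.to_numpy()) <= 1e-12)
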