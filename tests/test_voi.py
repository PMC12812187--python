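import numpy as np
import pytest

from strokecea import voi
from strokecea.voi import (
    EvsiCurve,
    PopulationModel,
    TrialDesign,
    enbs,
    evpi,
    evppi,
    evsi_mrs_trial,
    interpolate_evsi,
    parameter_groups,
    population_evsi,
)

from _oracles import toy_evsi_enumeration, toy_evsi_regression


class TestEvpi:
    def test_identical_strategies_worthless(self):
        nmb = np.tile(np.array([[1.0, 1.0]]), (10, 1))
        assert evpi(nmb) == 0.0

    def test_two_by_two_enumeration(self):
        nmb = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert evpi(nmb) == pytest.approx(0.5)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            evpi(np.ones((1, 3)))
        with pytest.raises(ValueError):
            evpi(np.ones(5))

    def test_nonnegative_on_model_output(self, psa_small):
        assert evpi(psa_small.nmb_matrix(50_000)) >= 0.0


class TestEvppi:
    def test_pure_noise_group_is_worthless(self, psa_small, rng):
        nmb = psa_small.nmb_matrix(50_000)
        noise = rng.normal(size=(psa_small.n, 4))
        value = evppi(nmb, noise, seed=0)
        # regression floor at 1,500 draws: a few percent of the EVPI
        assert value <= 0.03 * evpi(nmb)

    def test_saturated_regression_recovers_evpi(self, psa_small):
        """Regressing NMB on a sufficient statistic of the per-draw optimum
        (the NMB matrix itself) reproduces the two-term EVPI within 1%."""
        nmb = psa_small.nmb_matrix(50_000)
        value = evppi(nmb, nmb, seed=0)
        assert value == pytest.approx(evpi(nmb), rel=0.01)

    def test_bounded_by_evpi(self, psa_small):
        nmb = psa_small.nmb_matrix(50_000)
        groups = parameter_groups(psa_small.draws)
        total = evpi(nmb)
        for name in ("mrs_Met-Cef-Par", "utilities", "recurrence"):
            assert -1e-9 <= evppi(nmb, groups[name], seed=0) <= total * 1.02

    def test_misaligned_rows_rejected(self, psa_small):
        nmb = psa_small.nmb_matrix(50_000)
        with pytest.raises(ValueError):
            evppi(nmb, np.ones((3, 2)))

    def test_group_table_contains_all_mrs_groups(self, psa_small):
        groups = parameter_groups(psa_small.draws)
        mrs_groups = [g for g in groups if g.startswith("mrs_")]
        assert len(mrs_groups) == 8

    def test_gam_regressor_agrees_on_linear_signal(self, psa_small):
        """Tree and spline regressors agree on a group whose effect on NMB
        is exactly linear (a single arm's mRS vector)."""
        nmb = psa_small.nmb_matrix(50_000)
        X = parameter_groups(psa_small.draws)["mrs_Met-Cef-Par"]
        tree = evppi(nmb, X, regressor="tree", seed=0)
        gam = evppi(nmb, X, regressor="gam", seed=0)
        assert tree == pytest.approx(gam, rel=0.35)

    def test_unknown_regressor_rejected(self, psa_small):
        nmb = psa_small.nmb_matrix(50_000)
        with pytest.raises(ValueError):
            evppi(nmb, nmb[:, :1], regressor="loess")


class TestEvsi:
    def test_zero_sample_size_worthless(self, psa_small):
        assert evsi_mrs_trial(psa_small, 50_000, 0) == 0.0

    def test_sample_size_below_arms_rejected(self, psa_small):
        with pytest.raises(ValueError):
            evsi_mrs_trial(psa_small, 50_000, 4)

    def test_large_trial_approaches_mrs_evppi(self, psa_small):
        """With an enormous trial the mRS vectors are learned exactly, so
        EVSI approaches the joint EVPPI of the 8 mRS groups."""
        nmb = psa_small.nmb_matrix(50_000)
        joint_mrs = psa_small.draws.mrs.reshape(psa_small.n, -1)
        target = evppi(nmb, joint_mrs, seed=0)
        value = evsi_mrs_trial(psa_small, 50_000, 1_000_000, seed=0)
        assert value == pytest.approx(target, rel=0.25, abs=0.05 * evpi(nmb))

    def test_value_bounded_by_evpi(self, psa_small):
        value = evsi_mrs_trial(psa_small, 50_000, 800, seed=0)
        assert 0.0 <= value <= evpi(psa_small.nmb_matrix(50_000)) * 1.02

    def test_oversampling_warns(self, psa_small):
        with pytest.warns(UserWarning, match="resampling"):
            evsi_mrs_trial(
                psa_small, 50_000, 160, n_datasets=psa_small.n + 1, seed=0
            )

    def test_matches_exhaustive_enumeration_on_toy_model(self):
        """Regression EVSI against exact enumeration on a conjugate
        2-strategy binary-outcome model."""
        exact = toy_evsi_enumeration(
            prior_a=12, prior_b=18, p_ref=0.42, n_trial=30, wtp=10_000
        )
        estimated = toy_evsi_regression(
            prior_a=12, prior_b=18, p_ref=0.42, n_trial=30, wtp=10_000,
            n_draws=8_000, seed=3,
        )
        assert exact > 0
        assert estimated == pytest.approx(exact, rel=0.15)


class TestTrialDesign:
    def test_even_allocation_largest_remainder(self):
        design = TrialDesign()
        alloc = design.allocate(161)
        assert alloc.sum() == 161
        assert set(alloc) == {20, 21}

    def test_duration_and_cost(self):
        design = TrialDesign()
        assert design.duration_months(800) == 800 / 80 + 3 + 6
        assert design.cost(800) == 4.6e6 + 500 * 800

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            TrialDesign(strategy_subset=())


class TestInterpolation:
    def test_recovers_exact_curve(self):
        n = np.array([160, 320, 800, 4_000])
        truth_a, truth_c = 7_000.0, 1 / 700.0
        values = truth_a * (1 - np.exp(-truth_c * n))
        curve = interpolate_evsi(n, values)
        assert curve.asymptote == pytest.approx(truth_a, rel=1e-4)
        assert curve.rate == pytest.approx(truth_c, rel=1e-4)
        assert curve(0) == 0.0

    def test_flat_input_gives_flat_curve(self):
        curve = interpolate_evsi([100, 200, 300], [5_000.0, 5_000.0, 5_000.0])
        assert curve(50) == pytest.approx(5_000.0)
        assert curve(5_000) == pytest.approx(5_000.0)

    def test_fit_passes_near_inputs(self):
        n = [160, 320, 800, 4_000]
        values = [1_697.0, 2_800.0, 4_600.0, 7_549.0]
        curve = interpolate_evsi(n, values)
        np.testing.assert_allclose(curve(np.array(n)), values, rtol=0.25)

    def test_nonmonotone_inputs_warn(self):
        with pytest.warns(UserWarning, match="monotone"):
            interpolate_evsi([100, 200, 300], [5.0, 3.0, 6.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            interpolate_evsi([100, 200], [1.0, 2.0])


class TestPopulationScaling:
    def test_default_monthly_incidence(self):
        pop = PopulationModel()
        assert pop.monthly_incidence == pytest.approx(41_300 * 0.75 * 0.50 / 12)
        assert round(pop.monthly_incidence) == 1_291

    def test_zero_discount_closed_form(self):
        pop = PopulationModel(
            monthly_incidence=100.0, horizon_months=120, annual_discount_rate=0.0
        )
        design = TrialDesign()
        duration = design.duration_months(800)  # 19 months
        value = population_evsi(1.0, pop, design, 800)
        assert value == pytest.approx(100.0 * (120 - duration))

    def test_zero_per_person_value(self):
        assert population_evsi(0.0, PopulationModel(), TrialDesign(), 800) == 0.0

    def test_trial_longer_than_horizon_warns(self):
        pop = PopulationModel(horizon_months=12)
        with pytest.warns(UserWarning, match="horizon"):
            assert population_evsi(1.0, pop, TrialDesign(), 4_000) == 0.0


class TestEnbs:
    def test_worthless_information_costs_only(self):
        curve = EvsiCurve(0.0, 1.0, np.array([0.0]), np.array([0.0]))
        design = TrialDesign()
        result = enbs(design, PopulationModel(), curve, n_grid=[50, 100, 500])
        np.testing.assert_allclose(
            result.enbs, -(4.6e6 + 500 * np.array([50, 100, 500]))
        )
        assert result.optimal_n == 50
        assert result.optimal_enbs < 0

    def test_constant_value_erodes_with_trial_duration(self):
        curve = EvsiCurve(5_000.0, np.inf, np.array([0.0]), np.array([0.0]))
        design = TrialDesign(fixed_cost=0.0, cost_per_patient=0.0)
        result = enbs(
            design, PopulationModel(), curve, n_grid=[80, 800, 2_400]
        )
        assert np.all(np.diff(result.enbs) < 0)


def test_voi_invariant_ordering(psa_small):
    """EVSI(n) <= joint mRS EVPPI <= EVPI within regression tolerance."""
    nmb = psa_small.nmb_matrix(50_000)
    total = evpi(nmb)
    joint_mrs = psa_small.draws.mrs.reshape(psa_small.n, -1)
    joint = evppi(nmb, joint_mrs, seed=0)
    small = evsi_mrs_trial(psa_small, 50_000, 800, seed=0)
    slack = 0.05 * total
    assert small <= joint + slack
    assert joint <= total + slack
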