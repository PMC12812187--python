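import numpy as np
import pandas as pd
import pytest

from strokecea.strategies import STRATEGIES
from strokecea.synthetic_trial import (
    DAY_COLUMNS,
    DEFAULT_MISSINGNESS,
    TrialTable,
    estimate_parameters,
    generate_trial,
    impute_missing,
)

NO_MISSING = {k: 0.0 for k in DEFAULT_MISSINGNESS}


class TestGeneration:
    def test_arm_sizes_match_request(self, params):
        table = generate_trial(params, n_per_arm=50, missingness=NO_MISSING, seed=0)
        assert table.data["arm"].value_counts().eq(50).all()

    def test_no_missingness_leaves_table_complete(self, params):
        table = generate_trial(params, n_per_arm=100, missingness=NO_MISSING, seed=0)
        assert not table.data.isna().any().any()

    def test_mrs_frequencies_recover_truth(self, params):
        table = generate_trial(
            params, n_per_arm=10_000, missingness=NO_MISSING, seed=3
        )
        for arm in ("SoC", "Cef"):
            sub = table.data[table.data["arm"] == arm]
            freq = (
                sub["mrs"].value_counts(normalize=True)
                .reindex(range(7), fill_value=0.0)
                .to_numpy()
            )
            truth = params.mrs[arm]
            se = np.sqrt(truth * (1 - truth) / len(sub))
            # 4 SE: 14 simultaneous comparisons need a Bonferroni-style bound
            assert np.all(np.abs(freq - truth) < 4 * np.maximum(se, 1e-4))

    def test_default_utility_missingness_rate(self, params):
        table = generate_trial(params, n_per_arm=3_000, seed=5)
        rate = table.data["utility"].isna().mean()
        n = len(table.data)
        se = np.sqrt(0.255 * 0.745 / n)
        assert abs(rate - 0.255) < 3 * se

    def test_durations_respect_followup_window(self, params):
        table = generate_trial(params, n_per_arm=500, missingness=NO_MISSING, seed=1)
        totals = table.data[list(DAY_COLUMNS)].sum(axis=1)
        assert (totals <= 90 + 1e-9).all()

    def test_mar_mechanism_targets_severe_states(self, params):
        table = generate_trial(
            params, n_per_arm=5_000, seed=2, mechanism="mar_mrs",
            missingness={"mrs": 0.0, "utility": 0.2, "procedures": 0.0, "los": 0.0},
        )
        df = table.data
        severe = df["mrs"] >= 4
        assert (
            df.loc[severe, "utility"].isna().mean()
            > df.loc[~severe, "utility"].isna().mean()
        )

    def test_invalid_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            generate_trial(params, n_per_arm=0)
        with pytest.raises(ValueError):
            generate_trial(params, missingness={"mrs": 1.5})
        with pytest.raises(ValueError):
            generate_trial(params, mechanism="mnar")


class TestImputation:
    def test_complete_table_returned_unchanged(self, params):
        table = generate_trial(params, n_per_arm=200, missingness=NO_MISSING, seed=0)
        imputed = impute_missing(table, seed=1)
        pd.testing.assert_frame_equal(imputed.data, table.data)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            impute_missing(TrialTable(data=pd.DataFrame()))

    def test_all_fields_filled(self, params):
        table = generate_trial(params, n_per_arm=400, seed=4)
        imputed = impute_missing(table, seed=4)
        assert not imputed.data.isna().any().any()

    def test_imputed_values_within_observed_support(self, params):
        table = generate_trial(params, n_per_arm=400, seed=4)
        imputed = impute_missing(table, seed=4)
        df = imputed.data
        assert df["mrs"].between(0, 6).all()
        assert df["utility"].between(-0.446, 1).all()
        assert df["ivt"].isin([0.0, 1.0]).all()
        assert (df[list(DAY_COLUMNS)].sum(axis=1) <= 90 + 1e-9).all()

    def test_mcar_utility_imputation_unbiased(self, params):
        """With fully observed mRS and 25% MCAR-missing utilities, imputed
        per-state means match the complete-data means."""
        table = generate_trial(
            params, n_per_arm=1_250, missingness=NO_MISSING, seed=9
        )
        complete = table.data.copy()
        rng = np.random.default_rng(10)
        mask = rng.random(len(complete)) < 0.25
        amputed = complete.copy()
        amputed.loc[mask, "utility"] = np.nan
        imputed = impute_missing(TrialTable(data=amputed), seed=11).data
        for s in range(6):
            obs = complete.loc[complete["mrs"] == s, "utility"]
            imp = imputed.loc[imputed["mrs"] == s, "utility"]
            se = obs.std(ddof=1) / np.sqrt(len(obs))
            assert abs(imp.mean() - obs.mean()) < 3 * max(se, 1e-4)


class TestEstimation:
    def test_requires_complete_table(self, params):
        table = generate_trial(params, n_per_arm=100, seed=0)
        with pytest.raises(ValueError, match="impute"):
            estimate_parameters(table, params)

    def test_empty_arm_rejected(self, params):
        table = generate_trial(params, n_per_arm=20, missingness=NO_MISSING, seed=0)
        dropped = TrialTable(data=table.data[table.data["arm"] != "Cef"])
        with pytest.raises(ValueError, match="Cef"):
            estimate_parameters(dropped, params)

    def test_degenerate_single_state_arm(self, params):
        table = generate_trial(params, n_per_arm=30, missingness=NO_MISSING, seed=0)
        df = table.data.copy()
        df.loc[df["arm"] == "SoC", "mrs"] = 2
        est = estimate_parameters(TrialTable(data=df), params)
        np.testing.assert_allclose(
            est.mrs["SoC"], [0, 0, 1, 0, 0, 0, 0], atol=1e-12
        )

    def test_constant_utility_stratum_recovered_exactly(self, params):
        table = generate_trial(params, n_per_arm=30, missingness=NO_MISSING, seed=0)
        df = table.data.copy()
        df.loc[df["mrs"] == 2, "utility"] = 0.85
        est = estimate_parameters(TrialTable(data=df), params)
        assert est.utilities[2] == pytest.approx(0.85)

    def test_non_trial_fields_pass_through(self, params):
        table = generate_trial(params, n_per_arm=50, missingness=NO_MISSING, seed=0)
        est = estimate_parameters(table, params)
        assert est.weibull_log_scale == params.weibull_log_scale
        assert est.unit_costs == params.unit_costs
        np.testing.assert_array_equal(est.mortality_hr, params.mortality_hr)


def test_headline_parameter_recovery(params):
    """generate -> impute -> estimate recovers the truth at large n.

    This is the module's headline consistency check: with 50,000 patients
    per arm
    and the default missingness rates, the estimated mRS vectors,
    utilities, lengths of stay, and procedure rates must all converge to
    the generating values within Monte-Carlo tolerance.
    """
    table = generate_trial(params, n_per_arm=50_000, seed=13)
    imputed = impute_missing(table, seed=14)
    est = estimate_parameters(imputed, params)
    for arm in STRATEGIES:
        np.testing.assert_allclose(est.mrs[arm], params.mrs[arm], atol=0.01)
    np.testing.assert_allclose(est.utilities[:6], params.utilities[:6], atol=0.02)
    for loc in params.los:
        np.testing.assert_allclose(est.los[loc], params.los[loc], rtol=0.06, atol=0.3)
    np.testing.assert_allclose(est.p_ivt, params.p_ivt, atol=0.02)
    np.testing.assert_allclose(est.p_evt, params.p_evt, atol=0.02)


def test_csv_roundtrip(params, tmp_path):
    table = generate_trial(params, n_per_arm=50, seed=1)
    path = tmp_path / "trial.csv"
    table.to_csv(path)
    back = TrialTable.from_csv(path)
    pd.testing.assert_frame_equal(back.data, table.data)
    assert back.missingness_realized.keys() == table.missingness_realized.keys()
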