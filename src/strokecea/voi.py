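"""Value-of-information analysis: EVPI, EVPPI, EVSI, and ENBS.

All quantities are expressed in net monetary benefit (euros per person)
at a fixed willingness-to-pay threshold, computed from a PSA's per-draw
NMB matrix:

* EVPI — mean over draws of the per-draw best NMB, minus the best
  per-strategy mean NMB (the value of resolving all uncertainty).
* EVPPI — the same two-term contrast applied to fitted values from a
  flexible regression of each strategy's NMB on the draws of a parameter
  group (the value of resolving only that group).
* EVSI — the contrast applied to regressions on summary statistics of
  simulated trial datasets (per-arm conjugate Dirichlet posterior means
  of the mRS probabilities), giving the value of a finite new study
  before it is run.
* ENBS — population-scaled EVSI (incident patients from trial end to the
  decision horizon, discounted monthly) minus the fixed and per-patient
  trial costs, maximized over the sample size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import RidgeCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer

from .parameters import ParameterDraws
from .psa import PsaDraws
from .strategies import STRATEGIES, strategy_index

# ---------------------------------------------------------------------------
# EVPI
# ---------------------------------------------------------------------------


def evpi(nmb_matrix: np.ndarray) -> float:
    """Expected value of perfect information from a per-draw NMB matrix."""
    nmb_matrix = np.asarray(nmb_matrix, float)
    if nmb_matrix.ndim != 2 or nmb_matrix.shape[0] < 2 or nmb_matrix.shape[1] < 2:
        raise ValueError("NMB matrix must be (draws >= 2) x (strategies >= 2)")
    return float(nmb_matrix.max(axis=1).mean() - nmb_matrix.mean(axis=0).max())


# ---------------------------------------------------------------------------
# flexible regressors for EVPPI / EVSI
# ---------------------------------------------------------------------------


def _make_regressor(kind: str, seed: int | None = None):
    """A flexible conditional-mean estimator.

    ``tree``: gradient-boosted additive tree ensemble;
    ``gam``: smooth additive model (per-feature cubic splines + ridge).
    """
    if kind == "tree":
        # validation-based early stopping keeps the fitted values from
        # chasing Monte-Carlo noise, which would otherwise inflate the
        # max-of-fitted-values contrast that EVPPI and EVSI are built on
        return HistGradientBoostingRegressor(
            max_iter=500, learning_rate=0.1, max_leaf_nodes=15,
            l2_regularization=1e-3, early_stopping=True,
            validation_fraction=0.2, n_iter_no_change=15,
            random_state=seed if seed is not None else 0,
        )
    if kind == "gam":
        return make_pipeline(
            SplineTransformer(n_knots=8, degree=3),
            RidgeCV(alphas=np.logspace(-4, 3, 15)),
        )
    raise ValueError(f"unknown regressor {kind!r}; expected 'tree' or 'gam'")


def _fitted_value_contrast(
    nmb_matrix: np.ndarray, features: np.ndarray, regressor: str, seed: int | None
) -> float:
    """mean(max_s fitted_s) - max_s(mean fitted_s) over regression fits."""
    n = nmb_matrix.shape[0]
    fitted = np.empty_like(nmb_matrix)
    for j in range(nmb_matrix.shape[1]):
        model = _make_regressor(regressor, seed)
        model.fit(features, nmb_matrix[:, j])
        fitted[:, j] = model.predict(features)
    value = float(fitted.max(axis=1).mean() - fitted.mean(axis=0).max())
    return max(value, 0.0)


def evppi(
    nmb_matrix: np.ndarray,
    group_draws: np.ndarray,
    regressor: str = "tree",
    seed: int | None = None,
) -> float:
    """EVPPI of a parameter group by nonparametric regression.

    ``group_draws`` holds the sampled values of the group, one row per PSA
    draw (aligned with ``nmb_matrix`` rows).
    """
    nmb_matrix = np.asarray(nmb_matrix, float)
    group_draws = np.asarray(group_draws, float)
    if group_draws.ndim == 1:
        group_draws = group_draws[:, None]
    if group_draws.shape[0] != nmb_matrix.shape[0]:
        raise ValueError("group draws are not aligned with the NMB matrix rows")
    return _fitted_value_contrast(nmb_matrix, group_draws, regressor, seed)


def parameter_groups(draws: ParameterDraws) -> dict[str, np.ndarray]:
    """Named parameter groups for the EVPPI screen.

    One group per arm's 7-component mRS vector, plus utilities, acute care
    (lengths of stay and unit costs), long-term care costs, stroke
    recurrence (Weibull + hazard ratios), and mortality hazard ratios.
    """
    groups: dict[str, np.ndarray] = {}
    for j, s in enumerate(STRATEGIES):
        groups[f"mrs_{s}"] = draws.mrs[:, j, :]
    groups["utilities"] = draws.utilities[:, :6]
    groups["acute_care"] = np.column_stack(
        [
            draws.los.reshape(draws.n, -1),
            draws.unit_costs,
            draws.p_ivt,
            draws.p_evt,
            draws.p_carotid[:, None],
        ]
    )
    groups["long_term_care_costs"] = draws.ltc_weekly
    groups["recurrence"] = np.column_stack(
        [draws.weibull_log_shape, draws.weibull_log_scale, draws.recurrence_hr[:, 1:]]
    )
    groups["mortality"] = draws.mortality_hr
    return groups


def evppi_table(
    psa: PsaDraws,
    threshold: float,
    groups: dict[str, np.ndarray] | None = None,
    regressor: str = "tree",
    seed: int | None = None,
) -> pd.DataFrame:
    """EVPPI for every parameter group, sorted by value (descending)."""
    if psa.draws is None:
        raise ValueError("PsaDraws must retain the parameter draws for EVPPI")
    if groups is None:
        groups = parameter_groups(psa.draws)
    nmb_matrix = psa.nmb_matrix(threshold)
    rows = [
        {"group": name, "evppi": evppi(nmb_matrix, X, regressor, seed)}
        for name, X in groups.items()
    ]
    return (
        pd.DataFrame(rows).sort_values("evppi", ascending=False).reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# EVSI for a new multi-arm mRS trial
# ---------------------------------------------------------------------------


@dataclass
class TrialDesign:
    """Design and cost structure of the hypothetical new mRS trial."""

    strategy_subset: tuple[str, ...] = STRATEGIES
    enrollment_per_month: float = 80.0
    followup_months: float = 3.0
    reporting_months: float = 6.0
    fixed_cost: float = 4.6e6
    cost_per_patient: float = 500.0

    def __post_init__(self):
        if not self.strategy_subset:
            raise ValueError("strategy subset must be non-empty")

    def allocate(self, n_total: int) -> np.ndarray:
        """Even allocation with largest-remainder rounding."""
        arms = len(self.strategy_subset)
        base = np.full(arms, n_total // arms)
        remainder = n_total - base.sum()
        base[:remainder] += 1
        return base

    def duration_months(self, n_total: int) -> float:
        """Enrollment + follow-up + analysis/reporting, in months."""
        return (
            math.ceil(n_total / self.enrollment_per_month)
            + self.followup_months
            + self.reporting_months
        )

    def cost(self, n_total: int) -> float:
        return self.fixed_cost + self.cost_per_patient * n_total


def evsi_mrs_trial(
    psa: PsaDraws,
    threshold: float,
    n_total: int,
    design: TrialDesign | None = None,
    n_datasets: int | None = None,
    prior_ess: float = 1493 / 8,
    regressor: str = "tree",
    seed: int | None = None,
) -> float:
    """EVSI of a new trial collecting 90-day mRS scores in each arm.

    For each retained PSA draw, one trial dataset is simulated by drawing
    per-arm multinomial mRS counts from that draw's probabilities. The
    dataset is summarized by the conjugate Dirichlet posterior-mean
    vectors (prior concentration = point estimate x ``prior_ess``), which
    are sufficient for the multinomial likelihood, and each strategy's NMB
    is regressed on these summaries.
    """
    if design is None:
        design = TrialDesign()
    if n_total == 0:
        return 0.0
    arms = len(design.strategy_subset)
    if n_total < arms:
        raise ValueError("sample size must cover at least 1 patient per arm")
    if psa.draws is None:
        raise ValueError("PsaDraws must retain the parameter draws for EVSI")

    rng = np.random.default_rng(seed)
    n_psa = psa.n
    if n_datasets is None or n_datasets == n_psa:
        idx = np.arange(n_psa)
    elif n_datasets < n_psa:
        idx = rng.choice(n_psa, size=n_datasets, replace=False)
    else:
        warnings.warn(
            "requested more simulated datasets than PSA draws; "
            "resampling draws with replacement",
            stacklevel=2,
        )
        idx = rng.choice(n_psa, size=n_datasets, replace=True)

    alloc = design.allocate(n_total)
    features = []
    for a, strategy in enumerate(design.strategy_subset):
        probs = psa.draws.mrs[idx, strategy_index(strategy), :]
        counts = rng.multinomial(int(alloc[a]), probs)
        prior = psa.draws.params.mrs[strategy] * prior_ess  # point-estimate prior
        posterior_mean = (prior + counts) / (prior.sum() + alloc[a])
        features.append(posterior_mean)
    X = np.column_stack(features)
    nmb_matrix = psa.nmb_matrix(threshold)[idx]
    return _fitted_value_contrast(nmb_matrix, X, regressor, seed)


# ---------------------------------------------------------------------------
# EVSI interpolation, population scaling, ENBS
# ---------------------------------------------------------------------------


def _asymptotic(n, a, c):
    return a * (1.0 - np.exp(-c * np.asarray(n, float)))


@dataclass
class EvsiCurve:
    """Fitted asymptotic-regression curve EVSI(n) = a (1 - exp(-c n))."""

    asymptote: float
    rate: float
    sample_sizes: np.ndarray
    values: np.ndarray

    def __call__(self, n) -> np.ndarray | float:
        out = _asymptotic(n, self.asymptote, self.rate)
        return float(out) if np.ndim(out) == 0 else out


def interpolate_evsi(sample_sizes, evsi_values) -> EvsiCurve:
    """Fit the diminishing-returns curve through EVSI estimates.

    The curve passes through the origin (no data, no value) and its
    asymptote is constrained to at least the largest observed EVSI.
    """
    sample_sizes = np.asarray(sample_sizes, float)
    evsi_values = np.asarray(evsi_values, float)
    if sample_sizes.size < 3:
        raise ValueError("need at least 3 EVSI points to fit the curve")
    if np.any(np.diff(evsi_values[np.argsort(sample_sizes)]) < -1e-9):
        warnings.warn(
            "EVSI estimates are not monotone in sample size; fitting anyway",
            stacklevel=2,
        )
    vmax = float(evsi_values.max())
    if vmax <= 0:
        return EvsiCurve(0.0, 1.0, sample_sizes, evsi_values)
    if np.ptp(evsi_values) < 1e-12 * max(1.0, vmax):
        # degenerate: flat input -> flat curve at the common value
        return EvsiCurve(vmax, np.inf, sample_sizes, evsi_values)
    c0 = 1.0 / np.median(sample_sizes)
    (a, c), _ = curve_fit(
        _asymptotic,
        sample_sizes,
        evsi_values,
        p0=(vmax * 1.05, c0),
        bounds=([vmax, 1e-12], [np.inf, 1.0]),
        maxfev=20_000,
    )
    return EvsiCurve(float(a), float(c), sample_sizes, evsi_values)


@dataclass
class PopulationModel:
    """Beneficiary population for scaling per-person value to the country.

    The default monthly incidence reproduces the eligible-patient
    calculation: 41,300 strokes/year x 75% (age) x 50% (severity) / 12.
    """

    monthly_incidence: float = 41_300 * 0.75 * 0.50 / 12.0
    horizon_months: float = 120.0
    annual_discount_rate: float = 0.03

    def __post_init__(self):
        if self.monthly_incidence <= 0:
            raise ValueError("monthly incidence must be positive")


def population_evsi(
    per_person: float,
    pop: PopulationModel,
    design: TrialDesign,
    n_total: int,
) -> float:
    """Scale per-person EVSI to the population that can still benefit.

    Beneficiaries accrue monthly from the end of the trial (enrollment +
    follow-up + reporting) to the decision horizon, each month's cohort
    discounted back at the annual rate with monthly compounding.
    """
    duration = design.duration_months(n_total)
    if duration >= pop.horizon_months:
        warnings.warn(
            "trial duration reaches the decision horizon; no one benefits",
            stacklevel=2,
        )
        return 0.0
    months = np.arange(duration, pop.horizon_months)
    factor = (1.0 + pop.annual_discount_rate) ** (-months / 12.0)
    return float(per_person * pop.monthly_incidence * factor.sum())


@dataclass
class EnbsResult:
    """ENBS over the sample-size grid for one decision horizon."""

    horizon_months: float
    sample_sizes: np.ndarray
    population_evsi: np.ndarray
    trial_cost: np.ndarray
    enbs: np.ndarray
    optimal_n: int
    optimal_enbs: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "horizon_months": self.horizon_months,
                "n": self.sample_sizes,
                "population_evsi": self.population_evsi,
                "trial_cost": self.trial_cost,
                "enbs": self.enbs,
            }
        )


def enbs(
    design: TrialDesign,
    pop: PopulationModel,
    evsi_curve,
    n_grid=None,
) -> EnbsResult:
    """Expected net benefit of sampling over a sample-size grid."""
    if n_grid is None:
        n_grid = np.arange(50, 5_001)
    n_grid = np.asarray(n_grid, int)
    pop_evsi = np.array(
        [
            population_evsi(float(evsi_curve(n)), pop, design, int(n))
            for n in n_grid
        ]
    )
    cost = np.array([design.cost(int(n)) for n in n_grid])
    values = pop_evsi - cost
    best = int(np.argmax(values))
    return EnbsResult(
        horizon_months=pop.horizon_months,
        sample_sizes=n_grid,
        population_evsi=pop_evsi,
        trial_cost=cost,
        enbs=values,
        optimal_n=int(n_grid[best]),
        optimal_enbs=float(values[best]),
    )


# ---------------------------------------------------------------------------
# full VOI pipeline
# ---------------------------------------------------------------------------


@dataclass
class VOIResult:
    threshold: float
    evpi: float
    evppi: pd.DataFrame
    evsi_by_n: pd.DataFrame
    evsi_curve: EvsiCurve | None
    enbs_by_horizon: dict[float, EnbsResult] = field(default_factory=dict)


def run_voi(
    psa: PsaDraws,
    threshold: float = 50_000.0,
    design: TrialDesign | None = None,
    sample_sizes=(160, 320, 800, 4_000),
    horizons_months=(60.0, 120.0, 180.0, 240.0),
    n_datasets: int | None = None,
    regressor: str = "tree",
    seed: int | None = None,
    monthly_incidence: float | None = None,
) -> VOIResult:
    """EVPI, per-group EVPPI, EVSI-by-n, and ENBS curves in one pass."""
    if design is None:
        design = TrialDesign()
    nmb_matrix = psa.nmb_matrix(threshold)
    total_evpi = evpi(nmb_matrix)
    evppi_df = evppi_table(psa, threshold, regressor=regressor, seed=seed)
    evsi_values = [
        evsi_mrs_trial(
            psa,
            threshold,
            int(n),
            design=design,
            n_datasets=n_datasets,
            regressor=regressor,
            seed=None if seed is None else seed + i,
        )
        for i, n in enumerate(sample_sizes)
    ]
    evsi_df = pd.DataFrame({"n": list(sample_sizes), "evsi": evsi_values})
    curve = interpolate_evsi(evsi_df["n"], evsi_df["evsi"])
    result = VOIResult(
        threshold=threshold,
        evpi=total_evpi,
        evppi=evppi_df,
        evsi_by_n=evsi_df,
        evsi_curve=curve,
    )
    for horizon in horizons_months:
        pop = PopulationModel(horizon_months=float(horizon))
        if monthly_incidence is not None:
            pop.monthly_incidence = monthly_incidence
        result.enbs_by_horizon[float(horizon)] = enbs(design, pop, curve)
    return result
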