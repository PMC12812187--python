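"""Model inputs: loading, validation, and probabilistic sampling.

All inputs of the decision model live in a :class:`ParameterSet`: the 90-day
mRS outcome distribution of each treatment arm, the Weibull recurrent-stroke
model, other-cause mortality and its mRS-specific hazard ratios, utility
weights, acute-phase resource use and unit costs, long-term and indirect
weekly costs, and the economic settings (discount rates, thresholds,
horizon). A bundled YAML file carries the default values (2024 euros,
Dutch payer perspective); any field can be overridden from a user config.

For probabilistic analysis, :func:`build_sampler` attaches a parametric
uncertainty distribution to each parameter group (Dirichlet for the mRS
simplexes, gamma for costs and lengths of stay, beta for utilities,
lognormal for hazard ratios, normal for the Weibull log-parameters) and
draws joint parameter vectors that are bit-reproducible given a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from .strategies import DEATH, N_STATES, N_STRATEGIES, STRATEGIES

WEEKS_PER_YEAR = 365.25 / 7.0
ACUTE_DAYS = 90.0
ACUTE_YEARS = ACUTE_DAYS / 365.25

#: Locations of acute-phase stay, in the order used by LOS arrays.
LOS_LOCATIONS = ("hospital", "rehabilitation", "nursing_home", "home")

#: Unit-cost keys in canonical order (column order of draw matrices).
UNIT_COST_KEYS = (
    "hospital_per_day",
    "rehabilitation_per_day",
    "nursing_home_per_day",
    "visits_per_patient",
    "diagnostics_per_patient",
    "allied_health_per_patient",
    "carotid_endarterectomy",
    "intravenous_thrombolysis",
    "endovascular_thrombectomy",
    "intravenous_infusion",
)

_TIME_UNIT_WEEKS = {
    "weeks": 1.0,
    "days": 1.0 / 7.0,
    "months": WEEKS_PER_YEAR / 12.0,
    "years": WEEKS_PER_YEAR,
}

#: Tolerated deviation of a printed mRS vector from the unit simplex.
SIMPLEX_TOLERANCE = 0.02


class ParameterError(ValueError):
    """A model input failed validation."""


# ---------------------------------------------------------------------------
# economic settings
# ---------------------------------------------------------------------------


@dataclass
class EconomicSettings:
    """Discounting, thresholds, and time-structure settings."""

    cost_discount_rate: float = 0.03
    qaly_discount_rate: float = 0.015
    thresholds: tuple[float, ...] = (20_000.0, 50_000.0, 80_000.0)
    horizon_years: float = 20.0
    cycle_length_weeks: float = 1.0
    start_age: float = 80.0
    max_age: float = 100.0

    def validate(self) -> None:
        for name in ("cost_discount_rate", "qaly_discount_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ParameterError(f"{name} must be in [0, 1), got {r}")
        if self.horizon_years <= 0:
            raise ParameterError("horizon_years must be positive")
        if self.cycle_length_weeks <= 0:
            raise ParameterError("cycle_length_weeks must be positive")
        if any(t < 0 for t in self.thresholds):
            raise ParameterError("thresholds must be non-negative")

    @property
    def n_cycles(self) -> int:
        """Number of weekly cycles in the long-term phase.

        The horizon is truncated so that no one is modelled past
        ``max_age``; the long-term phase starts 90 days after the stroke.
        """
        entry_age = self.start_age + ACUTE_YEARS
        years = min(self.horizon_years, self.max_age - entry_age)
        return int(np.floor(years * WEEKS_PER_YEAR / self.cycle_length_weeks))


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """A complete, validated set of model inputs.

    ``mrs`` holds the renormalized per-arm 90-day mRS probability vectors;
    ``mrs_raw`` keeps the vectors as configured (printed values may sum to
    0.99-1.01) for reconstructing Dirichlet sample sizes.
    """

    mrs: dict[str, np.ndarray]
    mrs_raw: dict[str, np.ndarray]
    weibull_log_shape: float
    weibull_log_scale: float
    weibull_time_unit: str
    recurrence_hr: np.ndarray  # (3,) for mRS groups {0, 1-2, 3+}
    recurrence_acute_cost: float
    mortality_rate_age80: float
    mortality_rate_age99: float
    mortality_hr: np.ndarray  # (6,) for mRS 0..5
    utilities: np.ndarray  # (7,)
    los: dict[str, np.ndarray]  # location -> (7,) days
    p_ivt: np.ndarray  # (7,)
    p_evt: np.ndarray  # (7,)
    p_carotid: float
    unit_costs: dict[str, float]
    drug_costs: dict[str, float]
    infusion_rule: str  # "cef_only" | "all" | "none"
    ltc_weekly: np.ndarray  # (6,) euro/week for mRS 0..5
    indirect_enabled: bool
    indirect_age80: float
    indirect_age99: float
    genpop_qale: float
    settings: EconomicSettings = field(default_factory=EconomicSettings)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        self.settings.validate()
        if set(self.mrs) != set(STRATEGIES):
            missing = set(STRATEGIES) - set(self.mrs)
            extra = set(self.mrs) - set(STRATEGIES)
            raise ParameterError(
                f"mrs_probabilities must cover exactly the 8 strategies; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        for arm, p in self.mrs.items():
            if p.shape != (N_STATES,):
                raise ParameterError(f"mRS vector for {arm} must have 7 entries")
            if np.any(p < 0):
                raise ParameterError(f"mRS vector for {arm} has negative entries")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ParameterError(f"mRS vector for {arm} is not normalized")
        if not np.all(np.isfinite(self.recurrence_hr)) or np.any(
            self.recurrence_hr <= 0
        ):
            raise ParameterError("recurrence hazard ratios must be positive")
        if self.weibull_time_unit not in _TIME_UNIT_WEEKS:
            raise ParameterError(
                f"weibull_time_unit must be one of {sorted(_TIME_UNIT_WEEKS)}"
            )
        for name, r in (
            ("mortality_rate_age80", self.mortality_rate_age80),
            ("mortality_rate_age99", self.mortality_rate_age99),
        ):
            if not 0 <= r < 1:
                raise ParameterError(f"{name} must be a weekly rate in [0, 1)")
        if np.any(self.mortality_hr <= 0):
            raise ParameterError("mortality hazard ratios must be positive")
        if np.any(self.utilities < -0.446) or np.any(self.utilities > 1.0):
            raise ParameterError("utilities must lie in [-0.446, 1]")
        if self.utilities[DEATH] != 0.0:
            raise ParameterError("utility of mRS 6 (death) must be 0")
        for loc in LOS_LOCATIONS:
            if loc not in self.los:
                raise ParameterError(f"missing length-of-stay entry for {loc}")
            if np.any(self.los[loc] < 0):
                raise ParameterError(f"negative length of stay for {loc}")
        total_los = sum(self.los[loc] for loc in LOS_LOCATIONS)
        # printed per-location means can overshoot the window by rounding;
        # rescale mildly overfull states, reject anything worse
        if np.any(total_los > ACUTE_DAYS + 1.0):
            raise ParameterError(
                "total acute length of stay exceeds the 90-day window for "
                f"mRS state(s) {np.nonzero(total_los > ACUTE_DAYS)[0].tolist()}"
            )
        over = total_los > ACUTE_DAYS
        if np.any(over):
            factor = np.where(over, ACUTE_DAYS / total_los, 1.0)
            for loc in LOS_LOCATIONS:
                self.los[loc] = self.los[loc] * factor
        for vec, name in ((self.p_ivt, "ivt"), (self.p_evt, "evt")):
            if np.any(vec < 0) or np.any(vec > 1):
                raise ParameterError(f"{name} proportions must lie in [0, 1]")
        if not 0 <= self.p_carotid <= 1:
            raise ParameterError("carotid endarterectomy proportion not in [0, 1]")
        for key, value in {**self.unit_costs, **self.drug_costs}.items():
            if value < 0:
                raise ParameterError(f"cost {key} must be non-negative, got {value}")
        if np.any(self.ltc_weekly < 0):
            raise ParameterError("long-term care costs must be non-negative")
        if self.infusion_rule not in ("cef_only", "all", "none"):
            raise ParameterError("infusion_rule must be cef_only, all, or none")
        if self.genpop_qale <= 0:
            raise ParameterError("general_population_qale must be positive")

    # -- convenience -------------------------------------------------------

    @property
    def mrs_matrix(self) -> np.ndarray:
        """(8, 7) matrix of renormalized mRS vectors in canonical order."""
        return np.stack([self.mrs[s] for s in STRATEGIES])

    @property
    def los_matrix(self) -> np.ndarray:
        """(4, 7) lengths of stay, rows ordered as :data:`LOS_LOCATIONS`."""
        return np.stack([self.los[loc] for loc in LOS_LOCATIONS])

    @property
    def unit_cost_vector(self) -> np.ndarray:
        return np.array([self.unit_costs[k] for k in UNIT_COST_KEYS], float)

    @property
    def recurrence_hr_by_state(self) -> np.ndarray:
        """(6,) recurrence hazard ratios expanded to mRS 0..5."""
        g = self.recurrence_hr
        return np.array([g[0], g[1], g[1], g[2], g[2], g[2]], float)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "mrs_probabilities": {
                s: [float(x) for x in self.mrs_raw[s]] for s in STRATEGIES
            },
            "recurrence": {
                "weibull_log_shape": float(self.weibull_log_shape),
                "weibull_log_scale": float(self.weibull_log_scale),
                "weibull_time_unit": self.weibull_time_unit,
                "hazard_ratios": [float(x) for x in self.recurrence_hr],
                "acute_cost_per_event": float(self.recurrence_acute_cost),
            },
            "mortality": {
                "weekly_rate_age80": float(self.mortality_rate_age80),
                "weekly_rate_age99": float(self.mortality_rate_age99),
                "hazard_ratio_mrs0": float(self.mortality_hr[0]),
                "hazard_ratios_mrs1_5": [float(x) for x in self.mortality_hr[1:]],
            },
            "utilities": {"mrs0_6": [float(x) for x in self.utilities]},
            "length_of_stay_days": {
                loc: [float(x) for x in self.los[loc]] for loc in LOS_LOCATIONS
            },
            "procedures": {
                "ivt_proportion_mrs0_6": [float(x) for x in self.p_ivt],
                "evt_proportion_mrs0_6": [float(x) for x in self.p_evt],
                "carotid_endarterectomy_proportion": float(self.p_carotid),
            },
            "unit_costs": {k: float(v) for k, v in self.unit_costs.items()},
            "drug_costs_per_patient": {
                k: float(v) for k, v in self.drug_costs.items()
            },
            "infusion_rule": self.infusion_rule,
            "long_term_care": {
                "weekly_cost_mrs0_5": [float(x) for x in self.ltc_weekly]
            },
            "indirect_costs": {
                "enabled": bool(self.indirect_enabled),
                "weekly_at_age80": float(self.indirect_age80),
                "weekly_at_age99": float(self.indirect_age99),
            },
            "economics": {
                "cost_discount_rate": self.settings.cost_discount_rate,
                "qaly_discount_rate": self.settings.qaly_discount_rate,
                "thresholds": [float(t) for t in self.settings.thresholds],
                "horizon_years": self.settings.horizon_years,
                "cycle_length_weeks": self.settings.cycle_length_weeks,
                "start_age": self.settings.start_age,
                "max_age": self.settings.max_age,
            },
            "population": {"general_population_qale": float(self.genpop_qale)},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row table of every scalar input (CSV export)."""
        flat: dict[str, float] = {}
        for s in STRATEGIES:
            for k in range(N_STATES):
                flat[f"mrs[{s}][{k}]"] = self.mrs[s][k]
        flat["weibull_log_shape"] = self.weibull_log_shape
        flat["weibull_log_scale"] = self.weibull_log_scale
        for i, g in enumerate(("0", "1-2", "3+")):
            flat[f"recurrence_hr[{g}]"] = self.recurrence_hr[i]
        for k in range(6):
            flat[f"mortality_hr[{k}]"] = self.mortality_hr[k]
        for k in range(N_STATES):
            flat[f"utility[{k}]"] = self.utilities[k]
        for loc in LOS_LOCATIONS:
            for k in range(N_STATES):
                flat[f"los[{loc}][{k}]"] = self.los[loc][k]
        for k in range(N_STATES):
            flat[f"p_ivt[{k}]"] = self.p_ivt[k]
            flat[f"p_evt[{k}]"] = self.p_evt[k]
        flat["p_carotid"] = self.p_carotid
        for k in UNIT_COST_KEYS:
            flat[f"unit_cost[{k}]"] = self.unit_costs[k]
        for k, v in self.drug_costs.items():
            flat[f"drug_cost[{k}]"] = v
        for k in range(6):
            flat[f"ltc_weekly[{k}]"] = self.ltc_weekly[k]
        return pd.DataFrame([flat])

    def copy(self) -> "ParameterSet":
        new = dataclasses.replace(self)
        new.mrs = {k: v.copy() for k, v in self.mrs.items()}
        new.mrs_raw = {k: v.copy() for k, v in self.mrs_raw.items()}
        new.los = {k: v.copy() for k, v in self.los.items()}
        new.unit_costs = dict(self.unit_costs)
        new.drug_costs = dict(self.drug_costs)
        for name in ("recurrence_hr", "mortality_hr", "utilities", "p_ivt",
                     "p_evt", "ltc_weekly"):
            setattr(new, name, getattr(self, name).copy())
        new.settings = dataclasses.replace(self.settings)
        return new


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _require(cfg: dict, *keys):
    node: Any = cfg
    path = []
    for key in keys:
        path.append(key)
        if not isinstance(node, dict) or key not in node:
            raise ParameterError(f"missing config field: {'.'.join(path)}")
        node = node[key]
    return node


def default_config() -> dict[str, Any]:
    """The bundled default configuration as a plain dict."""
    text = (
        resources.files("strokecea").joinpath("data/default_params.yaml").read_text()
    )
    return yaml.safe_load(text)


def _params_from_config(cfg: dict[str, Any]) -> ParameterSet:
    mrs_cfg = _require(cfg, "mrs_probabilities")
    mrs_raw: dict[str, np.ndarray] = {}
    mrs: dict[str, np.ndarray] = {}
    for arm in STRATEGIES:
        if arm not in mrs_cfg:
            raise ParameterError(f"missing mRS vector for strategy {arm}")
        raw = np.asarray(mrs_cfg[arm], float)
        if raw.shape != (N_STATES,):
            raise ParameterError(f"mRS vector for {arm} must have 7 entries")
        if np.any(raw < 0):
            raise ParameterError(f"mRS vector for {arm} has negative entries")
        if abs(raw.sum() - 1.0) > SIMPLEX_TOLERANCE:
            raise ParameterError(
                f"mRS vector for {arm} sums to {raw.sum():.4f}; deviation from 1 "
                f"exceeds the rounding tolerance {SIMPLEX_TOLERANCE}"
            )
        mrs_raw[arm] = raw
        mrs[arm] = raw / raw.sum()

    rec = _require(cfg, "recurrence")
    mort = _require(cfg, "mortality")
    econ = _require(cfg, "economics")
    settings = EconomicSettings(
        cost_discount_rate=float(econ["cost_discount_rate"]),
        qaly_discount_rate=float(econ["qaly_discount_rate"]),
        thresholds=tuple(float(t) for t in econ["thresholds"]),
        horizon_years=float(econ["horizon_years"]),
        cycle_length_weeks=float(econ.get("cycle_length_weeks", 1.0)),
        start_age=float(econ["start_age"]),
        max_age=float(econ["max_age"]),
    )
    params = ParameterSet(
        mrs=mrs,
        mrs_raw=mrs_raw,
        weibull_log_shape=float(rec["weibull_log_shape"]),
        weibull_log_scale=float(rec["weibull_log_scale"]),
        weibull_time_unit=str(rec.get("weibull_time_unit", "years")),
        recurrence_hr=np.asarray(rec["hazard_ratios"], float),
        recurrence_acute_cost=float(rec.get("acute_cost_per_event", 0.0)),
        mortality_rate_age80=float(mort["weekly_rate_age80"]),
        mortality_rate_age99=float(mort["weekly_rate_age99"]),
        mortality_hr=np.concatenate(
            [[float(mort["hazard_ratio_mrs0"])],
             np.asarray(mort["hazard_ratios_mrs1_5"], float)]
        ),
        utilities=np.asarray(_require(cfg, "utilities", "mrs0_6"), float),
        los={
            loc: np.asarray(_require(cfg, "length_of_stay_days", loc), float)
            for loc in LOS_LOCATIONS
        },
        p_ivt=np.asarray(_require(cfg, "procedures", "ivt_proportion_mrs0_6"), float),
        p_evt=np.asarray(_require(cfg, "procedures", "evt_proportion_mrs0_6"), float),
        p_carotid=float(
            _require(cfg, "procedures", "carotid_endarterectomy_proportion")
        ),
        unit_costs={k: float(v) for k, v in _require(cfg, "unit_costs").items()},
        drug_costs={
            k: float(v) for k, v in _require(cfg, "drug_costs_per_patient").items()
        },
        infusion_rule=str(cfg.get("infusion_rule", "cef_only")),
        ltc_weekly=np.asarray(
            _require(cfg, "long_term_care", "weekly_cost_mrs0_5"), float
        ),
        indirect_enabled=bool(_require(cfg, "indirect_costs", "enabled")),
        indirect_age80=float(_require(cfg, "indirect_costs", "weekly_at_age80")),
        indirect_age99=float(_require(cfg, "indirect_costs", "weekly_at_age99")),
        genpop_qale=float(_require(cfg, "population", "general_population_qale")),
        settings=settings,
    )
    missing_costs = set(UNIT_COST_KEYS) - set(params.unit_costs)
    if missing_costs:
        raise ParameterError(f"missing unit costs: {sorted(missing_costs)}")
    params.validate()
    return params


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def load_parameters(config: str | None = None) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML config file.

    ``config`` may be ``None`` (bundled defaults), a path to a full config,
    or a path to a partial config whose fields override the defaults.
    """
    cfg = default_config()
    if config is not None:
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ParameterError("config file must contain a YAML mapping")
        cfg = _deep_update(cfg, user)
    return _params_from_config(cfg)


def load_uncertainty(config: str | None = None) -> "UncertaintySpec":
    """Load the PSA uncertainty specification (defaults + overrides)."""
    cfg = default_config()
    if config is not None:
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_update(cfg, user)
    unc = cfg.get("uncertainty", {})
    spec = UncertaintySpec(
        dirichlet_ess=float(unc.get("dirichlet_ess", 1493 / 8)),
        gamma_cv=float(unc.get("gamma_cv", 0.2)),
        beta_se=float(unc.get("beta_se", 0.02)),
        lognormal_cv=float(unc.get("lognormal_cv", 0.1)),
        normal_se_log_weibull=float(unc.get("normal_se_log_weibull", 0.1)),
    )
    if "families" in unc:
        spec.families = {**spec.families, **unc["families"]}
    return spec


# ---------------------------------------------------------------------------
# mortality / indirect-cost schedules
# ---------------------------------------------------------------------------


def baseline_weekly_mortality(
    age, rate_age80: float = 0.001, rate_age99: float = 0.008
):
    """Baseline weekly other-cause mortality rate at a given age.

    Log-linearly interpolates between the configured anchor rates at ages 80
    and 99 (a Gompertz-type schedule); ages above 99 are clamped to the
    age-99 value. Accepts scalars or arrays.
    """
    age = np.asarray(age, float)
    if np.any(age < 80.0):
        raise ParameterError("baseline mortality is defined for ages >= 80")
    frac = np.clip((age - 80.0) / 19.0, 0.0, 1.0)
    if rate_age80 <= 0.0 or rate_age99 <= 0.0:
        # degenerate anchors (e.g. a mortality-free scenario): fall back to
        # linear interpolation, which passes through zero cleanly
        rate = rate_age80 + frac * (rate_age99 - rate_age80)
    else:
        rate = np.exp(
            (1.0 - frac) * np.log(rate_age80) + frac * np.log(rate_age99)
        )
    return float(rate) if rate.ndim == 0 else rate


def indirect_weekly_cost(age, params: ParameterSet):
    """Age-dependent indirect medical cost per week for alive states.

    Linear between the configured anchors at ages 80 and 99, clamped above
    99; zero when the indirect-cost component is disabled.
    """
    if not params.indirect_enabled:
        return 0.0 if np.isscalar(age) else np.zeros_like(np.asarray(age, float))
    age = np.asarray(age, float)
    frac = np.clip((age - 80.0) / 19.0, 0.0, 1.0)
    cost = params.indirect_age80 + frac * (params.indirect_age99 - params.indirect_age80)
    return float(cost) if cost.ndim == 0 else cost


# ---------------------------------------------------------------------------
# uncertainty specification and sampling
# ---------------------------------------------------------------------------

_DEFAULT_FAMILIES = {
    "mrs": "dirichlet",
    "weibull": "normal",
    "recurrence_hr": "lognormal",
    "mortality_hr": "lognormal",
    "utilities": "beta",
    "los": "gamma",
    "procedures": "gamma",
    "carotid": "beta",
    "unit_costs": "gamma",
    "ltc": "gamma",
}

_ALLOWED_FAMILIES = {
    "mrs": {"dirichlet", "constant"},
    "weibull": {"normal", "constant"},
    "recurrence_hr": {"lognormal", "constant"},
    "mortality_hr": {"lognormal", "constant"},
    "utilities": {"beta", "constant"},
    "los": {"gamma", "constant"},
    "procedures": {"gamma", "beta", "constant"},
    "carotid": {"beta", "constant"},
    "unit_costs": {"gamma", "constant"},
    "ltc": {"gamma", "constant"},
}


@dataclass
class UncertaintySpec:
    """Distribution families and hyperparameters for the PSA.

    The Dirichlet effective sample size reconstructs per-arm mRS counts
    (trial total split evenly over the 8 arms); the remaining
    hyperparameters are documented stand-ins for the unavailable source
    values and are meant to be overridden from the config where better
    information exists.
    """

    dirichlet_ess: float = 1493 / 8
    gamma_cv: float = 0.2
    beta_se: float = 0.02
    lognormal_cv: float = 0.1
    normal_se_log_weibull: float = 0.1
    families: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_FAMILIES)
    )

    def validate(self) -> None:
        if self.dirichlet_ess <= 0:
            raise ParameterError("dirichlet_ess must be positive")
        for group, fam in self.families.items():
            if group not in _ALLOWED_FAMILIES:
                raise ParameterError(f"unknown parameter group {group!r}")
            if fam not in _ALLOWED_FAMILIES[group]:
                raise ParameterError(
                    f"unknown family {fam!r} for group {group!r}; "
                    f"allowed: {sorted(_ALLOWED_FAMILIES[group])}"
                )

    @classmethod
    def all_constant(cls) -> "UncertaintySpec":
        """A degenerate spec in which nothing is sampled."""
        spec = cls()
        spec.families = {g: "constant" for g in _DEFAULT_FAMILIES}
        return spec


@dataclass
class ParameterDraws:
    """A matrix of sampled parameter vectors (one row per PSA draw).

    Array shapes: ``mrs`` (n, 8, 7) in canonical strategy order;
    ``los`` (n, 4, 7) ordered as :data:`LOS_LOCATIONS`;
    ``unit_costs`` (n, 10) ordered as :data:`UNIT_COST_KEYS`.
    """

    n: int
    seed: int | None
    params: ParameterSet
    mrs: np.ndarray
    weibull_log_shape: np.ndarray
    weibull_log_scale: np.ndarray
    recurrence_hr: np.ndarray  # (n, 3)
    mortality_hr: np.ndarray  # (n, 6)
    utilities: np.ndarray  # (n, 7)
    los: np.ndarray  # (n, 4, 7)
    p_ivt: np.ndarray  # (n, 7)
    p_evt: np.ndarray  # (n, 7)
    p_carotid: np.ndarray  # (n,)
    unit_costs: np.ndarray  # (n, 10)
    ltc_weekly: np.ndarray  # (n, 6)

    def mrs_arm(self, strategy: str) -> np.ndarray:
        from .strategies import strategy_index

        return self.mrs[:, strategy_index(strategy), :]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for j, s in enumerate(STRATEGIES):
            for k in range(N_STATES):
                cols[f"mrs[{s}][{k}]"] = self.mrs[:, j, k]
        cols["weibull_log_shape"] = self.weibull_log_shape
        cols["weibull_log_scale"] = self.weibull_log_scale
        for i, g in enumerate(("0", "1-2", "3+")):
            cols[f"recurrence_hr[{g}]"] = self.recurrence_hr[:, i]
        for k in range(6):
            cols[f"mortality_hr[{k}]"] = self.mortality_hr[:, k]
        for k in range(N_STATES):
            cols[f"utility[{k}]"] = self.utilities[:, k]
        for i, loc in enumerate(LOS_LOCATIONS):
            for k in range(N_STATES):
                cols[f"los[{loc}][{k}]"] = self.los[:, i, k]
        for k in range(N_STATES):
            cols[f"p_ivt[{k}]"] = self.p_ivt[:, k]
            cols[f"p_evt[{k}]"] = self.p_evt[:, k]
        cols["p_carotid"] = self.p_carotid
        for i, k in enumerate(UNIT_COST_KEYS):
            cols[f"unit_cost[{k}]"] = self.unit_costs[:, i]
        for k in range(6):
            cols[f"ltc_weekly[{k}]"] = self.ltc_weekly[:, k]
        return pd.DataFrame(cols)


def _sample_gamma(rng, mean: np.ndarray, cv: float, n: int) -> np.ndarray:
    """Gamma draws moment-matched to (mean, cv * mean); zero mean stays 0."""
    mean = np.asarray(mean, float)
    out = np.tile(mean, (n,) + (1,) * mean.ndim).astype(float)
    if cv <= 0:
        return out
    pos = mean > 0
    shape = 1.0 / cv**2
    scale = mean * cv**2
    draws = rng.gamma(shape, np.where(pos, scale, 1.0), size=(n,) + mean.shape)
    out[..., pos] = draws[..., pos]
    return out


def _sample_lognormal(rng, mean: np.ndarray, cv: float, n: int) -> np.ndarray:
    mean = np.asarray(mean, float)
    if cv <= 0:
        return np.tile(mean, (n,) + (1,) * mean.ndim).astype(float)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=(n,) + mean.shape)


def _sample_beta(rng, mean: np.ndarray, se: float, n: int) -> np.ndarray:
    """Beta draws moment-matched to (mean, se); means outside (0, 1) or
    infeasible variances fall back to constants."""
    mean = np.atleast_1d(np.asarray(mean, float))
    out = np.tile(mean, (n, 1)).astype(float)
    if se <= 0:
        return out
    var = se**2
    ok = (mean > 0) & (mean < 1) & (var < mean * (1 - mean))
    if np.any(ok):
        m = mean[ok]
        k = m * (1 - m) / var - 1.0
        out[:, ok] = rng.beta(m * k, (1 - m) * k, size=(n, ok.sum()))
    return out


class ParameterSampler:
    """Seeded joint sampler over all uncertain model parameters."""

    def __init__(self, params: ParameterSet, unc: UncertaintySpec):
        unc.validate()
        params.validate()
        self.params = params
        self.unc = unc

    def dirichlet_concentrations(self, strategy: str) -> np.ndarray:
        """Per-arm Dirichlet concentration vector.

        Uses the renormalized mRS probabilities scaled by the effective
        per-arm sample size, so the Dirichlet mean reproduces the point
        estimate exactly.
        """
        p = self.params.mrs[strategy]
        return np.maximum(p * self.unc.dirichlet_ess, 1e-9)

    def sample(self, n_draws: int, seed: int | None = None) -> ParameterDraws:
        if n_draws < 1:
            raise ParameterError("n_draws must be at least 1")
        p, unc = self.params, self.unc
        rng = np.random.default_rng(seed)
        fam = unc.families

        mrs = np.empty((n_draws, N_STRATEGIES, N_STATES))
        for j, s in enumerate(STRATEGIES):
            if fam["mrs"] == "dirichlet":
                mrs[:, j, :] = rng.dirichlet(
                    self.dirichlet_concentrations(s), size=n_draws
                )
            else:
                mrs[:, j, :] = p.mrs[s]
        # guard against floating-point drift off the simplex
        mrs /= mrs.sum(axis=2, keepdims=True)

        if fam["weibull"] == "normal":
            w_shape = rng.normal(p.weibull_log_shape, unc.normal_se_log_weibull, n_draws)
            w_scale = rng.normal(p.weibull_log_scale, unc.normal_se_log_weibull, n_draws)
        else:
            w_shape = np.full(n_draws, p.weibull_log_shape)
            w_scale = np.full(n_draws, p.weibull_log_scale)

        rec_hr = np.tile(p.recurrence_hr, (n_draws, 1)).astype(float)
        if fam["recurrence_hr"] == "lognormal":
            # the reference group (mRS 0, HR = 1) stays fixed
            rec_hr[:, 1:] = _sample_lognormal(
                rng, p.recurrence_hr[1:], unc.lognormal_cv, n_draws
            )

        if fam["mortality_hr"] == "lognormal":
            mort_hr = _sample_lognormal(rng, p.mortality_hr, unc.lognormal_cv, n_draws)
        else:
            mort_hr = np.tile(p.mortality_hr, (n_draws, 1)).astype(float)

        util = np.zeros((n_draws, N_STATES))
        if fam["utilities"] == "beta":
            util[:, :DEATH] = _sample_beta(
                rng, p.utilities[:DEATH], unc.beta_se, n_draws
            )
        else:
            util[:, :DEATH] = p.utilities[:DEATH]

        if fam["los"] == "gamma":
            los = _sample_gamma(rng, p.los_matrix, unc.gamma_cv, n_draws)
            # keep each state's total stay inside the 90-day window
            total = los.sum(axis=1, keepdims=True)
            factor = np.minimum(1.0, ACUTE_DAYS / np.maximum(total, 1e-12))
            los = los * factor
        else:
            los = np.tile(p.los_matrix, (n_draws, 1, 1)).astype(float)

        if fam["procedures"] == "gamma":
            p_ivt = np.clip(_sample_gamma(rng, p.p_ivt, unc.gamma_cv, n_draws), 0, 1)
            p_evt = np.clip(_sample_gamma(rng, p.p_evt, unc.gamma_cv, n_draws), 0, 1)
        elif fam["procedures"] == "beta":
            p_ivt = _sample_beta(rng, p.p_ivt, unc.beta_se, n_draws)
            p_evt = _sample_beta(rng, p.p_evt, unc.beta_se, n_draws)
        else:
            p_ivt = np.tile(p.p_ivt, (n_draws, 1)).astype(float)
            p_evt = np.tile(p.p_evt, (n_draws, 1)).astype(float)

        if fam["carotid"] == "beta":
            p_car = _sample_beta(rng, p.p_carotid, unc.beta_se, n_draws)[:, 0]
        else:
            p_car = np.full(n_draws, p.p_carotid)

        if fam["unit_costs"] == "gamma":
            unit = _sample_gamma(rng, p.unit_cost_vector, unc.gamma_cv, n_draws)
        else:
            unit = np.tile(p.unit_cost_vector, (n_draws, 1)).astype(float)

        if fam["ltc"] == "gamma":
            ltc = _sample_gamma(rng, p.ltc_weekly, unc.gamma_cv, n_draws)
        else:
            ltc = np.tile(p.ltc_weekly, (n_draws, 1)).astype(float)

        return ParameterDraws(
            n=n_draws,
            seed=seed,
            params=p,
            mrs=mrs,
            weibull_log_shape=w_shape,
            weibull_log_scale=w_scale,
            recurrence_hr=rec_hr,
            mortality_hr=mort_hr,
            utilities=util,
            los=los,
            p_ivt=p_ivt,
            p_evt=p_evt,
            p_carotid=p_car,
            unit_costs=unit,
            ltc_weekly=ltc,
        )


def build_sampler(params: ParameterSet, unc: UncertaintySpec | None = None):
    """Construct a seeded PSA sampler over all uncertain parameters."""
    return ParameterSampler(params, unc if unc is not None else UncertaintySpec())


def sample_parameters(
    sampler: ParameterSampler, n_draws: int, seed: int | None = None
) -> ParameterDraws:
    """Draw ``n_draws`` joint parameter vectors (bit-identical given seed)."""
    return sampler.sample(n_draws, seed)


def draws_from_means(params: ParameterSet) -> ParameterDraws:
    """A single 'draw' equal to the parameter means (deterministic run)."""
    return ParameterSampler(params, UncertaintySpec.all_constant()).sample(1, 0)


def weibull_scale_weeks(log_scale, time_unit: str):
    """Convert the Weibull scale from its configured time unit to weeks."""
    try:
        factor = _TIME_UNIT_WEEKS[time_unit]
    except KeyError:
        raise ParameterError(
            f"weibull_time_unit must be one of {sorted(_TIME_UNIT_WEEKS)}"
        ) from None
    return np.exp(np.asarray(log_scale, float)) * factor
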