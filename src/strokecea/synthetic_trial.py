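"""Patient-level trial emulation and parameter re-estimation.

The model's trial-informed inputs (per-arm 90-day mRS distributions,
per-state utilities, lengths of stay, procedure rates) are point estimates
from patient-level follow-up data. This module generates synthetic
patient tables with the same statistical structure — mRS drawn from the
arm's outcome distribution, utility and location-day values centred on
the state-specific means, procedure flags Bernoulli — imposes
missing-completely-at-random gaps at the observed completeness rates,
fills them with a single-pass chained imputation (multinomial regression
for categorical fields, predictive-mean matching within mRS stratum for
continuous ones), and re-estimates the trial-informed parameters from the
completed table.

Columns of the trial table: ``patient_id, arm, mrs, utility,
days_hospital, days_rehabilitation, days_nursing_home, days_home, ivt,
evt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .parameters import ACUTE_DAYS, LOS_LOCATIONS, ParameterSet
from .strategies import DEATH, N_STATES, STRATEGIES

DAY_COLUMNS = (
    "days_hospital",
    "days_rehabilitation",
    "days_nursing_home",
    "days_home",
)

#: Observed per-field completeness translated into missingness rates.
DEFAULT_MISSINGNESS = {
    "mrs": 0.014,
    "utility": 0.255,
    "procedures": 0.135,
    "los": 0.121,
}

#: Dispersion of individual-level values around the state means.
UTILITY_SD = 0.15
#: Gamma shape per mean day of stay; the four locations partition the
#: 90-day window, so patient-level days are a normalized gamma
#: composition whose shares average the true length-of-stay fractions.
LOS_CONCENTRATION = 0.1


@dataclass
class TrialTable:
    """A synthetic patient-level table plus realized missingness rates."""

    data: pd.DataFrame
    missingness_realized: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialTable":
        df = pd.read_csv(path)
        table = cls(data=df)
        table.missingness_realized = _realized_missingness(df)
        return table


def _realized_missingness(df: pd.DataFrame) -> dict[str, float]:
    rates = {
        "mrs": df["mrs"].isna().mean(),
        "utility": float(df.loc[df["mrs"] != DEATH, "utility"].isna().mean()),
        "procedures": df["ivt"].isna().mean(),
        "los": df[list(DAY_COLUMNS)].isna().any(axis=1).mean(),
    }
    return {k: float(v) for k, v in rates.items()}


def _beta_around(rng, mean: np.ndarray, sd: float) -> np.ndarray:
    """Individual beta values centred on per-patient means (clipped to a
    feasible variance)."""
    m = np.clip(mean, 1e-3, 1 - 1e-3)
    var = np.minimum(sd**2, 0.95 * m * (1 - m))
    k = m * (1 - m) / var - 1.0
    return rng.beta(m * k, (1 - m) * k)


def generate_trial(
    truth: ParameterSet,
    n_per_arm: int = 187,
    missingness: dict[str, float] | None = None,
    seed: int | None = None,
    mechanism: str = "mcar",
) -> TrialTable:
    """Simulate a factorial trial table from the true parameter values.

    ``mechanism`` is ``"mcar"`` (default) or ``"mar_mrs"``, under which
    the per-field missingness probability doubles for mRS >= 4 relative
    to mRS <= 3 while preserving the overall rate.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be at least 1")
    if mechanism not in ("mcar", "mar_mrs"):
        raise ValueError("mechanism must be 'mcar' or 'mar_mrs'")
    rates = dict(DEFAULT_MISSINGNESS)
    if missingness is not None:
        rates.update(missingness)
    for key, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {key} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    for arm in STRATEGIES:
        p = truth.mrs[arm]
        mrs = rng.choice(N_STATES, size=n_per_arm, p=p)
        rows.append(pd.DataFrame({"arm": arm, "mrs": mrs}))
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "patient_id", np.arange(len(df)))
    mrs = df["mrs"].to_numpy()

    utility = _beta_around(rng, truth.utilities[mrs], UTILITY_SD)
    utility[mrs == DEATH] = 0.0
    df["utility"] = utility

    # gamma draws per location, jointly rescaled to fill the 90-day window
    # (normalized gammas form a Dirichlet composition, so per-location
    # means reproduce the configured lengths of stay)
    los = np.zeros((len(df), 4))
    for i, loc in enumerate(LOS_LOCATIONS):
        means = truth.los[loc][mrs]
        pos = means > 0
        draw = np.zeros(len(df))
        draw[pos] = rng.gamma(means[pos] * LOS_CONCENTRATION, 1.0)
        los[:, i] = draw
    # each state's composition fills that state's true total stay (at most
    # 90 days; decedents occupy locations only until death)
    target_total = sum(truth.los[loc] for loc in LOS_LOCATIONS)[mrs]
    total = los.sum(axis=1)
    scale = np.divide(target_total, total, out=np.zeros_like(total),
                      where=total > 0)
    los *= scale[:, None]
    for i, col in enumerate(DAY_COLUMNS):
        df[col] = los[:, i]

    df["ivt"] = (rng.random(len(df)) < truth.p_ivt[mrs]).astype(float)
    df["evt"] = (rng.random(len(df)) < truth.p_evt[mrs]).astype(float)

    # impose missingness
    def _mask(rate: float) -> np.ndarray:
        if rate <= 0:
            return np.zeros(len(df), bool)
        if mechanism == "mcar":
            return rng.random(len(df)) < rate
        weight = np.where(mrs >= 4, 2.0, 1.0)
        prob = np.clip(rate * weight / weight.mean(), 0.0, 1.0)
        return rng.random(len(df)) < prob

    df.loc[_mask(rates["mrs"]), "mrs"] = np.nan
    df.loc[_mask(rates["utility"]), "utility"] = np.nan
    df.loc[_mask(rates["procedures"]), ["ivt", "evt"]] = np.nan
    df.loc[_mask(rates["los"]), list(DAY_COLUMNS)] = np.nan

    table = TrialTable(data=df)
    table.missingness_realized = _realized_missingness(df)
    return table


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _pmm_impute(
    rng, values: np.ndarray, missing: np.ndarray, strata: np.ndarray, k: int = 5
) -> np.ndarray:
    """Predictive-mean matching within mRS stratum.

    Each missing value receives the value of one of the ``k`` observed
    donors closest to the stratum mean; strata with no observed donors
    fall back to the global observed pool.
    """
    out = values.copy()
    observed = ~missing
    global_pool = values[observed]
    if global_pool.size == 0:
        raise ValueError("cannot impute a column with no observed values")
    for stratum in np.unique(strata[missing]):
        idx = np.flatnonzero(missing & (strata == stratum))
        pool = values[observed & (strata == stratum)]
        if pool.size == 0:
            pool = global_pool
        center = pool.mean()
        donors = pool[np.argsort(np.abs(pool - center))[: max(k, 1)]]
        out[idx] = rng.choice(donors, size=idx.size)
    return out


def impute_missing(table: TrialTable, seed: int | None = None) -> TrialTable:
    """Single-pass chained imputation of all missing fields.

    Order: mRS (multinomial regression on arm and observed continuous
    fields), then procedure flags (logistic regression on arm and mRS),
    then utility and location days (predictive-mean matching within the
    imputed mRS stratum). Imputed durations are rescaled to respect the
    90-day follow-up window; utilities of imputed deaths are set to 0.
    """
    df = table.data.copy()
    if len(df) == 0:
        raise ValueError("cannot impute an empty table")
    rng = np.random.default_rng(seed)
    if not df.isna().any().any():
        return TrialTable(data=df, missingness_realized=_realized_missingness(df))

    arm_dummies = pd.get_dummies(df["arm"]).to_numpy(float)

    # --- mRS: multinomial regression on arm + mean-filled continuous fields
    mrs_missing = df["mrs"].isna().to_numpy()
    if mrs_missing.any():
        cont = df[["utility", *DAY_COLUMNS]].to_numpy(float)
        col_means = np.nanmean(cont, axis=0)
        cont = np.where(np.isnan(cont), col_means, cont)
        X = np.column_stack([arm_dummies, cont])
        y = df["mrs"].to_numpy(float)
        clf = LogisticRegression(max_iter=2000)
        clf.fit(X[~mrs_missing], y[~mrs_missing].astype(int))
        proba = clf.predict_proba(X[mrs_missing])
        classes = clf.classes_
        cum = proba.cumsum(axis=1)
        u = rng.random(len(proba))[:, None]
        picks = classes[(u > cum).sum(axis=1)]
        y[mrs_missing] = picks
        df["mrs"] = y
    mrs = df["mrs"].to_numpy(int)

    # --- procedure flags: logistic regression on arm + mRS
    for col in ("ivt", "evt"):
        miss = df[col].isna().to_numpy()
        if not miss.any():
            continue
        X = np.column_stack([arm_dummies, mrs])
        y = df[col].to_numpy(float)
        observed = y[~miss]
        if np.unique(observed).size < 2:
            y[miss] = observed[0] if observed.size else 0.0
        else:
            clf = LogisticRegression(max_iter=2000)
            clf.fit(X[~miss], observed.astype(int))
            p1 = clf.predict_proba(X[miss])[:, clf.classes_.tolist().index(1)]
            y[miss] = (rng.random(miss.sum()) < p1).astype(float)
        df[col] = y

    # --- continuous fields: PMM within mRS stratum
    util = df["utility"].to_numpy(float)
    miss = np.isnan(util)
    if miss.any():
        util = _pmm_impute(rng, util, miss, mrs)
        df["utility"] = util
    df.loc[df["mrs"] == DEATH, "utility"] = 0.0

    day_values = df[list(DAY_COLUMNS)].to_numpy(float)
    for i in range(4):
        col = day_values[:, i]
        miss = np.isnan(col)
        if miss.any():
            day_values[:, i] = _pmm_impute(rng, col, miss, mrs)
    total = day_values.sum(axis=1)
    over = total > ACUTE_DAYS
    day_values[over] *= (ACUTE_DAYS / total[over])[:, None]
    df[list(DAY_COLUMNS)] = day_values

    return TrialTable(data=df, missingness_realized=_realized_missingness(df))


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def estimate_parameters(table: TrialTable, template: ParameterSet) -> ParameterSet:
    """Re-estimate the trial-informed fields from a completed table.

    Per-arm mRS proportions, per-state mean utility, mean days per
    location, and procedure proportions replace the template's values;
    everything else (recurrence, mortality, unit costs, settings) passes
    through unchanged. States never observed keep the template values.
    """
    df = table.data
    if df.isna().any().any():
        raise ValueError("table contains missing values; impute first")
    est = template.copy()

    for arm in STRATEGIES:
        sub = df[df["arm"] == arm]
        if len(sub) == 0:
            raise ValueError(f"arm {arm} has no patients")
        counts = np.bincount(sub["mrs"].astype(int), minlength=N_STATES).astype(float)
        est.mrs_raw[arm] = counts / counts.sum()
        est.mrs[arm] = est.mrs_raw[arm]

    mrs = df["mrs"].to_numpy(int)
    for s in range(DEATH):
        mask = mrs == s
        if mask.any():
            est.utilities[s] = df.loc[mask, "utility"].mean()
            for loc, col in zip(LOS_LOCATIONS, DAY_COLUMNS):
                est.los[loc][s] = df.loc[mask, col].mean()
            est.p_ivt[s] = df.loc[mask, "ivt"].mean()
            est.p_evt[s] = df.loc[mask, "evt"].mean()
    dead = mrs == DEATH
    if dead.any():
        for loc, col in zip(LOS_LOCATIONS, DAY_COLUMNS):
            est.los[loc][DEATH] = df.loc[dead, col].mean()
        est.p_ivt[DEATH] = df.loc[dead, "ivt"].mean()
        est.p_evt[DEATH] = df.loc[dead, "evt"].mean()
    est.utilities[DEATH] = 0.0
    est.validate()
    return est
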