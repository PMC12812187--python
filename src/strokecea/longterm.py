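"""Weekly-cycle cohort state-transition model for long-term outcomes.

Survivors of the 90-day acute phase occupy mRS states 0-5 (6 = death,
absorbing) and are followed in weekly cycles for up to 20 years, truncated
at age 100. Each cycle a patient can:

* die from other causes — baseline weekly mortality (log-linear in age
  between the configured anchors) multiplied by an mRS-specific hazard
  ratio;
* suffer a recurrent stroke — a Weibull baseline hazard (decreasing over
  time, shape < 1) scaled by mRS-group hazard ratios that are normalized
  on the standard-of-care case mix, with the new state drawn from the
  standard-of-care 90-day distribution truncated to same-or-worse states
  (death included);
* otherwise remain in the current state.

Mortality and recurrence compete as exponential rates within the cycle:
the total event probability is computed from the summed rates and split
proportionally, which avoids order-of-application artefacts at weekly
resolution. Costs (weekly long-term care by state plus age-dependent
indirect costs) and QALYs (state utility per week) accrue on the occupancy
at the start of each cycle and are discounted continuously from the time
of the stroke; no half-cycle correction is applied.

The engine is vectorized over PSA draws: all occupancy and transition
arrays carry a leading draw axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    ACUTE_YEARS,
    WEEKS_PER_YEAR,
    ParameterDraws,
    ParameterSet,
    baseline_weekly_mortality,
    draws_from_means,
    indirect_weekly_cost,
    weibull_scale_weeks,
)
from .strategies import DEATH, N_STATES, STRATEGIES, strategy_index


class ModelError(RuntimeError):
    """Internal inconsistency detected while running the cohort model."""


# ---------------------------------------------------------------------------
# hazard components
# ---------------------------------------------------------------------------


@dataclass
class RecurrenceModel:
    """Weibull recurrent-stroke hazard with mRS-group adjustment.

    ``shape`` and ``scale_weeks`` are per-draw arrays; ``hr_by_state`` is
    (n, 6); ``normalization`` rescales the state-specific hazards so the
    standard-of-care survivor mix has an average hazard ratio of exactly 1
    (the calibrated baseline risk is not inflated by the adjustment).
    """

    shape: np.ndarray
    scale_weeks: np.ndarray
    hr_by_state: np.ndarray
    normalization: np.ndarray

    @classmethod
    def from_draws(cls, draws: ParameterDraws) -> "RecurrenceModel":
        shape = np.exp(draws.weibull_log_shape)
        scale = weibull_scale_weeks(
            draws.weibull_log_scale, draws.params.weibull_time_unit
        )
        g = draws.recurrence_hr
        hr = np.stack(
            [g[:, 0], g[:, 1], g[:, 1], g[:, 2], g[:, 2], g[:, 2]], axis=1
        )
        soc = draws.mrs[:, strategy_index("SoC"), :]
        alive = soc[:, :DEATH] / soc[:, :DEATH].sum(axis=1, keepdims=True)
        norm = 1.0 / np.einsum("ns,ns->n", alive, hr)
        return cls(shape=shape, scale_weeks=scale, hr_by_state=hr, normalization=norm)

    def cumulative_hazard(self, t) -> np.ndarray:
        """Baseline cumulative hazard H(t) = (t / scale)^shape, t in weeks."""
        t = np.asarray(t, float)
        return (t / self.scale_weeks) ** self.shape

    def hazard_increment(self, t) -> np.ndarray:
        """H(t+1) - H(t) for one weekly cycle starting at t weeks."""
        return self.cumulative_hazard(t + 1.0) - self.cumulative_hazard(t)


def recurrence_weekly_prob(t, mrs: int, model: RecurrenceModel) -> np.ndarray:
    """Probability of a recurrent stroke during week [t, t+1) in state ``mrs``.

    ``t`` counts weeks since the end of the 90-day acute phase.
    """
    if not 0 <= mrs < DEATH:
        raise ValueError("recurrence is defined for alive states (mRS 0-5)")
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    dh = model.hazard_increment(t)
    rate = model.normalization * model.hr_by_state[:, mrs] * dh
    out = -np.expm1(-rate)
    return out if out.ndim else float(out)


def redistribute_on_recurrence(current: int, soc_mrs: np.ndarray) -> np.ndarray:
    """Post-recurrence state distribution over {current, ..., 6}.

    A recurrent stroke is assumed to look like the index stroke under
    standard of care, conditional on not improving: the SoC 90-day vector
    is truncated at the current state and renormalized (death included).
    """
    if not 0 <= current < DEATH:
        raise ValueError("current state must be an alive state (mRS 0-5)")
    soc_mrs = np.asarray(soc_mrs, float)
    out = soc_mrs.copy()
    out[..., :current] = 0.0
    return out / out.sum(axis=-1, keepdims=True)


def _redistribution_tensor(soc: np.ndarray) -> np.ndarray:
    """(n, 6, 7) stack of post-recurrence distributions for each origin state."""
    n = soc.shape[0]
    R = np.empty((n, DEATH, N_STATES))
    for s in range(DEATH):
        R[:, s, :] = redistribute_on_recurrence(s, soc)
    return R


# ---------------------------------------------------------------------------
# transition matrix
# ---------------------------------------------------------------------------


def transition_matrix(
    cycle: int, draws: ParameterDraws, recurrence: RecurrenceModel | None = None
) -> np.ndarray:
    """Row-stochastic (n, 7, 7) transition matrix for a given weekly cycle.

    Row ``s`` (alive): competing other-cause death and recurrence rates are
    converted jointly to probabilities; the recurrence mass is spread over
    same-or-worse states. Row 6 is absorbing.
    """
    params = draws.params
    if recurrence is None:
        recurrence = RecurrenceModel.from_draws(draws)
    settings = params.settings
    if not 0 <= cycle < settings.n_cycles:
        raise ModelError(f"cycle {cycle} outside the model horizon")
    age = settings.start_age + ACUTE_YEARS + cycle / WEEKS_PER_YEAR
    base = baseline_weekly_mortality(
        age, params.mortality_rate_age80, params.mortality_rate_age99
    )
    m = base * draws.mortality_hr  # (n, 6)
    dh = recurrence.hazard_increment(float(cycle))
    r = recurrence.normalization[:, None] * recurrence.hr_by_state * dh[:, None]
    total = m + r
    p_event = -np.expm1(-total)
    with np.errstate(invalid="ignore"):
        frac_death = np.where(total > 0, m / np.maximum(total, 1e-300), 0.0)
    p_death = p_event * frac_death
    p_recur = p_event - p_death

    soc = draws.mrs[:, strategy_index("SoC"), :]
    R = _redistribution_tensor(soc)

    T = np.zeros((draws.n, N_STATES, N_STATES))
    idx = np.arange(DEATH)
    T[:, idx, idx] = 1.0 - p_event
    T[:, :DEATH, :] += p_recur[:, :, None] * R
    T[:, :DEATH, DEATH] += p_death
    T[:, DEATH, DEATH] = 1.0
    rowsum = T.sum(axis=2)
    if np.any(np.abs(rowsum - 1.0) > 1e-10):
        raise ModelError("transition matrix rows do not sum to 1")
    return T


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortTrace:
    """Per-cycle record of a single cohort run (one parameter vector)."""

    occupancy: np.ndarray  # (cycles + 1, 7), entry distribution first
    ages: np.ndarray  # (cycles,) age at the start of each cycle
    disc_cost: np.ndarray  # (cycles,) discounted cost increments
    disc_qalys: np.ndarray  # (cycles,)
    undisc_qalys: np.ndarray  # (cycles,)
    total_disc_cost: float
    total_disc_qalys: float
    total_undisc_qalys: float
    total_undisc_life_years: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy[:-1], columns=[f"mrs{k}" for k in range(N_STATES)]
        )
        df.insert(0, "cycle", np.arange(len(self.ages)))
        df.insert(1, "age", self.ages)
        df["disc_cost"] = self.disc_cost
        df["disc_qalys"] = self.disc_qalys
        df["undisc_qalys"] = self.undisc_qalys
        return df


def run_longterm(
    draws: ParameterDraws,
    initial: np.ndarray,
    collect_trace: bool = False,
):
    """Run the weekly cohort model for one or more initial distributions.

    Parameters
    ----------
    draws:
        Parameter draws; all arrays carry the draw axis ``n``.
    initial:
        Initial occupancy, shape (n, m, 7) for ``m`` cohorts per draw
        (typically the 8 strategy mRS vectors) or (n, 7).
    collect_trace:
        Record per-cycle occupancy (only supported for n = 1, m = 1).

    Returns
    -------
    dict of arrays shaped like ``initial`` without the state axis:
    ``disc_cost``, ``disc_qalys``, ``undisc_qalys``, ``undisc_life_years``;
    plus ``trace`` (a :class:`CohortTrace`) when requested.
    """
    params = draws.params
    settings = params.settings
    initial = np.asarray(initial, float)
    squeeze = initial.ndim == 2
    if squeeze:
        initial = initial[:, None, :]
    n, m, _ = initial.shape
    if n != draws.n:
        raise ModelError("initial occupancy draw axis does not match draws")
    sums = initial.sum(axis=2)
    if np.any(np.abs(sums - 1.0) > 1e-8):
        raise ModelError("initial occupancy must lie on the unit simplex")
    if collect_trace and (n != 1 or m != 1):
        raise ModelError("traces are recorded for single-cohort runs only")

    recurrence = RecurrenceModel.from_draws(draws)
    soc = draws.mrs[:, strategy_index("SoC"), :]
    R = _redistribution_tensor(soc)  # (n, 6, 7)

    n_cycles = settings.n_cycles
    entry_age = settings.start_age + ACUTE_YEARS
    cycles = np.arange(n_cycles)
    ages = entry_age + cycles / WEEKS_PER_YEAR
    t_years = ACUTE_YEARS + cycles / WEEKS_PER_YEAR
    disc_c = (1.0 + settings.cost_discount_rate) ** (-t_years)
    disc_q = (1.0 + settings.qaly_discount_rate) ** (-t_years)
    base_mort = baseline_weekly_mortality(
        ages, params.mortality_rate_age80, params.mortality_rate_age99
    )
    indirect = indirect_weekly_cost(ages, params)
    if np.isscalar(indirect):
        indirect = np.full(n_cycles, float(indirect))

    # per-draw weekly accrual weights
    util_w = draws.utilities[:, :DEATH] / WEEKS_PER_YEAR  # (n, 6)
    ltc_w = draws.ltc_weekly  # (n, 6)

    occ = initial.copy()
    out_dc = np.zeros((n, m))
    out_dq = np.zeros((n, m))
    out_uq = np.zeros((n, m))
    out_ly = np.zeros((n, m))
    trace_occ = np.empty((n_cycles + 1, N_STATES)) if collect_trace else None
    trace_dc = np.empty(n_cycles) if collect_trace else None
    trace_dq = np.empty(n_cycles) if collect_trace else None
    trace_uq = np.empty(n_cycles) if collect_trace else None
    if collect_trace:
        trace_occ[0] = occ[0, 0]

    recur_cost = params.recurrence_acute_cost

    for t in range(n_cycles):
        alive = occ[:, :, :DEATH]  # (n, m, 6)
        alive_mass = alive.sum(axis=2)
        uq = np.einsum("nms,ns->nm", alive, util_w)
        cost = np.einsum("nms,ns->nm", alive, ltc_w) + alive_mass * indirect[t]
        out_uq += uq
        out_ly += alive_mass / WEEKS_PER_YEAR
        out_dq += uq * disc_q[t]

        # competing transition rates for this cycle
        mort = base_mort[t] * draws.mortality_hr  # (n, 6)
        dh = recurrence.hazard_increment(float(t))  # (n,)
        rec = recurrence.normalization[:, None] * recurrence.hr_by_state * dh[:, None]
        total = mort + rec
        p_event = -np.expm1(-total)
        frac_death = mort / np.maximum(total, 1e-300)
        p_death = p_event * frac_death
        p_recur = p_event - p_death

        recur_mass = alive * p_recur[:, None, :]  # (n, m, 6)
        if recur_cost:
            cost = cost + recur_mass.sum(axis=2) * recur_cost
        out_dc += cost * disc_c[t]

        new = np.zeros_like(occ)
        new[:, :, :DEATH] = alive * (1.0 - p_event)[:, None, :]
        new[:, :, :] += np.einsum("nms,nsk->nmk", recur_mass, R)
        new[:, :, DEATH] += occ[:, :, DEATH] + np.einsum(
            "nms,ns->nm", alive, p_death
        )
        occ = new
        if np.any(np.abs(occ.sum(axis=2) - 1.0) > 1e-10):
            raise ModelError(f"occupancy not conserved at cycle {t}")
        if collect_trace:
            trace_occ[t + 1] = occ[0, 0]
            trace_dc[t] = cost[0, 0] * disc_c[t]
            trace_dq[t] = uq[0, 0] * disc_q[t]
            trace_uq[t] = uq[0, 0]

    result = {
        "disc_cost": out_dc[:, 0] if squeeze else out_dc,
        "disc_qalys": out_dq[:, 0] if squeeze else out_dq,
        "undisc_qalys": out_uq[:, 0] if squeeze else out_uq,
        "undisc_life_years": out_ly[:, 0] if squeeze else out_ly,
    }
    if collect_trace:
        result["trace"] = CohortTrace(
            occupancy=trace_occ,
            ages=ages,
            disc_cost=trace_dc,
            disc_qalys=trace_dq,
            undisc_qalys=trace_uq,
            total_disc_cost=float(out_dc[0, 0]),
            total_disc_qalys=float(out_dq[0, 0]),
            total_undisc_qalys=float(out_uq[0, 0]),
            total_undisc_life_years=float(out_ly[0, 0]),
        )
    return result


def run_cohort(
    initial, strategy: str | None = None, params: ParameterSet | None = None
) -> CohortTrace:
    """Run a single deterministic cohort and return its full trace.

    ``initial`` may be an explicit 7-vector on the simplex or ``None`` to
    use the 90-day mRS distribution of ``strategy``.
    """
    if params is None:
        raise ValueError("params is required")
    draws = draws_from_means(params)
    if initial is None:
        if strategy is None:
            raise ValueError("either an initial vector or a strategy is required")
        initial = params.mrs[strategy]
    initial = np.asarray(initial, float)[None, :]
    if np.abs(initial.sum() - 1.0) > 1e-8 or np.any(initial < 0):
        raise ModelError("initial occupancy must lie on the unit simplex")
    return run_longterm(draws, initial, collect_trace=True)["trace"]


def survival_curves(params: ParameterSet) -> pd.DataFrame:
    """Survival by initial mRS state over the model horizon (plot data)."""
    frames = []
    for s in range(DEATH):
        init = np.zeros(N_STATES)
        init[s] = 1.0
        trace = run_cohort(init, params=params)
        surv = 1.0 - trace.occupancy[:-1, DEATH]
        frames.append(
            pd.DataFrame(
                {"initial_mrs": s, "age": trace.ages, "survival": surv}
            )
        )
    return pd.concat(frames, ignore_index=True)
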