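"""Decision-tree component: expected costs and QALYs over the first 90 days.

Treatment effects act entirely through the 90-day mRS distribution of each
arm. Conditional on the mRS state reached, the acute phase accrues
location costs (hospital / rehabilitation centre / nursing home days at
their per-day costs, home days at the weekly long-term care cost of the
state), procedure costs (thrombolysis, thrombectomy, carotid
endarterectomy), per-patient follow-up costs, and the per-course drug plus
administration cost of the strategy. Acute QALYs are the 90-day interval
weighted by the state utility; decedents (mRS 6) accrue the location and
procedure costs observed for that state but no follow-up costs or QALYs.

All functions accept either a single :class:`~strokecea.parameters.ParameterSet`
(via its mean 'draws') or a :class:`~strokecea.parameters.ParameterDraws`
matrix, and are vectorized over draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import (
    ACUTE_YEARS,
    ParameterDraws,
    ParameterSet,
    UNIT_COST_KEYS,
    draws_from_means,
)
from .strategies import COMPONENTS, DEATH, N_STATES, STRATEGIES, strategy_index

_UC = {k: i for i, k in enumerate(UNIT_COST_KEYS)}


def _as_draws(params) -> ParameterDraws:
    if isinstance(params, ParameterDraws):
        return params
    if isinstance(params, ParameterSet):
        return draws_from_means(params)
    raise TypeError("expected ParameterSet or ParameterDraws")


def acute_cost_by_mrs(params) -> np.ndarray:
    """Expected acute-phase cost per mRS state, (n, 7) euros.

    Per-patient follow-up costs (visits, diagnostics, allied health) and
    the carotid-endarterectomy component apply to survivors only; the
    death state keeps its (truncated-stay) location and procedure costs.
    """
    d = _as_draws(params)
    uc = d.unit_costs
    per_day = np.stack(
        [
            uc[:, _UC["hospital_per_day"]],
            uc[:, _UC["rehabilitation_per_day"]],
            uc[:, _UC["nursing_home_per_day"]],
        ],
        axis=1,
    )  # (n, 3)
    cost = np.einsum("nl,nls->ns", per_day, d.los[:, :3, :])
    # home days are costed at the state's weekly long-term care rate
    home_daily = np.zeros((d.n, N_STATES))
    home_daily[:, :DEATH] = d.ltc_weekly / 7.0
    cost = cost + d.los[:, 3, :] * home_daily
    cost = cost + d.p_ivt * uc[:, [_UC["intravenous_thrombolysis"]]]
    cost = cost + d.p_evt * uc[:, [_UC["endovascular_thrombectomy"]]]
    survivors_only = (
        uc[:, _UC["visits_per_patient"]]
        + uc[:, _UC["diagnostics_per_patient"]]
        + uc[:, _UC["allied_health_per_patient"]]
        + d.p_carotid * uc[:, _UC["carotid_endarterectomy"]]
    )
    cost[:, :DEATH] += survivors_only[:, None]
    return cost


def drug_cost(strategy: str, params) -> np.ndarray:
    """Per-course drug plus administration cost of a strategy, (n,) euros.

    Sums the component drug prices; one intravenous-infusion course is
    added for ceftriaxone-containing strategies (ceftriaxone is IV-only)
    under the default ``cef_only`` rule, for every active arm under
    ``all``, and never under ``none``.
    """
    d = _as_draws(params)
    components = COMPONENTS[strategy]  # raises KeyError for unknown labels
    base = sum(d.params.drug_costs[c] for c in components)
    cost = np.full(d.n, float(base))
    rule = d.params.infusion_rule
    add_infusion = (rule == "all" and components) or (
        rule == "cef_only" and "Cef" in components
    )
    if add_infusion:
        cost = cost + d.unit_costs[:, _UC["intravenous_infusion"]]
    return cost


def acute_qalys_by_mrs(params) -> np.ndarray:
    """Acute-phase QALYs per mRS state, (n, 7): 90 days at the state utility."""
    d = _as_draws(params)
    return ACUTE_YEARS * d.utilities


def expected_acute_outcomes(strategy: str, params) -> tuple[np.ndarray, np.ndarray]:
    """Probability-weighted acute (cost, QALYs) for one strategy, each (n,)."""
    d = _as_draws(params)
    p = d.mrs[:, strategy_index(strategy), :]
    cost = np.einsum("ns,ns->n", p, acute_cost_by_mrs(d)) + drug_cost(strategy, d)
    qalys = np.einsum("ns,ns->n", p, acute_qalys_by_mrs(d))
    return cost, qalys


def acute_outcomes_all(params) -> tuple[np.ndarray, np.ndarray]:
    """Acute (cost, QALYs) for all 8 strategies, each (n, 8)."""
    d = _as_draws(params)
    cost_s = acute_cost_by_mrs(d)
    qaly_s = acute_qalys_by_mrs(d)
    cost = np.einsum("njs,ns->nj", d.mrs, cost_s)
    qalys = np.einsum("njs,ns->nj", d.mrs, qaly_s)
    for j, s in enumerate(STRATEGIES):
        cost[:, j] += drug_cost(s, d)
    return cost, qalys


def decomposition_table(params: ParameterSet) -> pd.DataFrame:
    """Per-strategy, per-state acute cost/QALY decomposition (CSV export)."""
    d = draws_from_means(params)
    cost_s = acute_cost_by_mrs(d)[0]
    qaly_s = acute_qalys_by_mrs(d)[0]
    rows = []
    for s in STRATEGIES:
        p = params.mrs[s]
        dc = float(drug_cost(s, d)[0])
        for k in range(N_STATES):
            rows.append(
                {
                    "strategy": s,
                    "mrs": k,
                    "probability": p[k],
                    "acute_cost": cost_s[k],
                    "acute_qalys": qaly_s[k],
                    "drug_cost": dc,
                }
            )
    return pd.DataFrame(rows)
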