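"""Independent oracles shared between the unit and acceptance suites.

Each routine recomputes a quantity by a route unrelated to the production
implementation: patient-level random walks instead of cohort matrix
algebra, and exhaustive dataset enumeration instead of regression-based
EVSI.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import betabinom

from strokecea import longterm
from strokecea.parameters import WEEKS_PER_YEAR, draws_from_means
from strokecea.strategies import DEATH, N_STATES


def microsim_undisc_qalys(params, initial, n_walkers=10_000, seed=0):
    """Monte-Carlo microsimulation of the weekly-cycle model.

    Walks individual patients through the same per-cycle transition
    matrices the cohort engine uses and accrues undiscounted QALYs on the
    state at the start of each cycle. Returns (mean, standard error).
    """
    rng = np.random.default_rng(seed)
    draws = draws_from_means(params)
    recurrence = longterm.RecurrenceModel.from_draws(draws)
    n_cycles = params.settings.n_cycles
    util_w = draws.utilities[0] / WEEKS_PER_YEAR

    states = rng.choice(N_STATES, size=n_walkers, p=np.asarray(initial, float))
    qalys = np.zeros(n_walkers)
    for t in range(n_cycles):
        qalys += util_w[states]
        T = longterm.transition_matrix(t, draws, recurrence)[0]  # (7, 7)
        cum = T.cumsum(axis=1)
        u = rng.random(n_walkers)
        states = (u[:, None] > cum[states]).sum(axis=1)
    return qalys.mean(), qalys.std(ddof=1) / np.sqrt(n_walkers)


def toy_evsi_enumeration(prior_a, prior_b, p_ref, n_trial, wtp=1.0):
    """Exact EVSI for a 2-strategy, binary-outcome conjugate toy model.

    Strategy A has known success probability ``p_ref`` (NMB 0 by
    convention); strategy B's probability is Beta(a, b) distributed with
    per-person NMB ``wtp * (p_B - p_ref)``. A new study observes ``n``
    Bernoulli outcomes under B. The exact value enumerates every possible
    success count k (beta-binomial predictive), updates the conjugate
    posterior, and takes the better arm under each posterior mean.
    """
    prior_mean = prior_a / (prior_a + prior_b)
    current = max(0.0, wtp * (prior_mean - p_ref))
    k = np.arange(n_trial + 1)
    pred = betabinom.pmf(k, n_trial, prior_a, prior_b)
    post_mean = (prior_a + k) / (prior_a + prior_b + n_trial)
    preposterior = np.sum(pred * np.maximum(0.0, wtp * (post_mean - p_ref)))
    return preposterior - current


def toy_evsi_regression(
    prior_a, prior_b, p_ref, n_trial, wtp=1.0, n_draws=4_000, seed=0,
    regressor="gam",
):
    """The production regression-on-posterior-mean EVSI route on the toy."""
    from strokecea.voi import _fitted_value_contrast

    rng = np.random.default_rng(seed)
    p = rng.beta(prior_a, prior_b, size=n_draws)
    successes = rng.binomial(n_trial, p)
    post_mean = (prior_a + successes) / (prior_a + prior_b + n_trial)
    nmb = np.column_stack([np.zeros(n_draws), wtp * (p - p_ref)])
    return _fitted_value_contrast(nmb, post_mean[:, None], regressor, seed)


def lifetable_survival(params, n_cycles):
    """Closed-form survival with unit hazard ratios and no recurrence."""
    from strokecea.parameters import ACUTE_YEARS, baseline_weekly_mortality

    entry_age = params.settings.start_age + ACUTE_YEARS
    ages = entry_age + np.arange(n_cycles) / WEEKS_PER_YEAR
    rates = baseline_weekly_mortality(
        ages, params.mortality_rate_age80, params.mortality_rate_age99
    )
    return np.exp(-np.cumsum(rates))
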