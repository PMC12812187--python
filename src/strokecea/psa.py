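"""Probabilistic analysis: run the full model per parameter draw.

Each draw propagates one joint parameter vector through the decision tree
and the long-term cohort model for all eight strategies, giving a
(draws x strategies) matrix of discounted costs and QALYs. Summaries
include per-strategy means with Monte-Carlo standard errors,
cost-effectiveness acceptability curves (probability of having the
highest NMB) and the acceptability frontier (the probability attached to
the strategy with the highest *expected* NMB).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import acute_phase, longterm
from .cea import CEResult, frontier, nmb
from .parameters import (
    ParameterDraws,
    ParameterSet,
    UncertaintySpec,
    build_sampler,
    draws_from_means,
)
from .strategies import N_STRATEGIES, STRATEGIES

#: Default willingness-to-pay grid (euro/QALY) for CEAC/CEAF curves.
DEFAULT_LAMBDA_GRID = tuple(
    sorted(set(range(0, 100_001, 2_000)) | {20_000, 50_000, 80_000})
)


@dataclass
class PsaDraws:
    """Per-draw, per-strategy discounted model outcomes."""

    strategies: tuple[str, ...]
    cost: np.ndarray  # (n, 8) discounted euros
    qalys: np.ndarray  # (n, 8) discounted QALYs
    undisc_qalys: np.ndarray  # (n, 8)
    seed: int | None
    draws: ParameterDraws | None = None

    @property
    def n(self) -> int:
        return self.cost.shape[0]

    def mean_cost(self) -> np.ndarray:
        return self.cost.mean(axis=0)

    def mean_qalys(self) -> np.ndarray:
        return self.qalys.mean(axis=0)

    def se_cost(self) -> np.ndarray:
        if self.n < 2:
            return np.zeros(self.cost.shape[1])
        return self.cost.std(axis=0, ddof=1) / np.sqrt(self.n)

    def se_qalys(self) -> np.ndarray:
        if self.n < 2:
            return np.zeros(self.qalys.shape[1])
        return self.qalys.std(axis=0, ddof=1) / np.sqrt(self.n)

    def nmb_matrix(self, threshold: float) -> np.ndarray:
        """(n, 8) per-draw net monetary benefit at a threshold."""
        return nmb(self.cost, self.qalys, threshold)

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "strategy": list(self.strategies),
                "cost": self.mean_cost(),
                "cost_se": self.se_cost(),
                "qalys": self.mean_qalys(),
                "qalys_se": self.se_qalys(),
                "undisc_qalys": self.undisc_qalys.mean(axis=0),
            }
        )
        return df

    def scatter_frame(self) -> pd.DataFrame:
        """Long-format draw-level (cost, QALY) pairs for scatter plots."""
        frames = []
        for j, s in enumerate(self.strategies):
            frames.append(
                pd.DataFrame(
                    {
                        "draw": np.arange(self.n),
                        "strategy": s,
                        "cost": self.cost[:, j],
                        "qalys": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def ce_result(self, thresholds=(20_000.0, 50_000.0, 80_000.0)) -> CEResult:
        """Frontier analysis on the probabilistic means."""
        return frontier(
            list(self.strategies), self.mean_cost(), self.mean_qalys(), thresholds
        )


def evaluate_draws(draws: ParameterDraws) -> PsaDraws:
    """Run acute + long-term model for all strategies on given draws."""
    acute_cost, acute_qalys = acute_phase.acute_outcomes_all(draws)
    lt = longterm.run_longterm(draws, draws.mrs)
    return PsaDraws(
        strategies=STRATEGIES,
        cost=acute_cost + lt["disc_cost"],
        qalys=acute_qalys + lt["disc_qalys"],
        undisc_qalys=acute_qalys + lt["undisc_qalys"],
        seed=draws.seed,
        draws=draws,
    )


def run_psa(
    params: ParameterSet,
    unc: UncertaintySpec | None = None,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> PsaDraws:
    """Sample ``n_draws`` parameter vectors and run the model on each."""
    if n_draws < 2:
        raise ValueError("probabilistic analysis needs at least 2 draws")
    sampler = build_sampler(params, unc)
    draws = sampler.sample(n_draws, seed)
    return evaluate_draws(draws)


def run_deterministic(params: ParameterSet) -> PsaDraws:
    """Run the model once at the parameter means."""
    return evaluate_draws(draws_from_means(params))


@dataclass
class CeacCurve:
    """Acceptability curves over a willingness-to-pay grid."""

    lambdas: np.ndarray  # (L,)
    probability: np.ndarray  # (L, 8), rows sum to 1
    strategies: tuple[str, ...]
    frontier_strategy: list[str]  # max-mean-NMB strategy per lambda
    frontier_probability: np.ndarray  # (L,)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probability, columns=list(self.strategies))
        df.insert(0, "lambda", self.lambdas)
        df["ceaf_strategy"] = self.frontier_strategy
        df["ceaf_probability"] = self.frontier_probability
        return df


def ceac(psa: PsaDraws, lambdas=DEFAULT_LAMBDA_GRID) -> CeacCurve:
    """Cost-effectiveness acceptability curves and frontier.

    At each threshold, a strategy's CEAC value is the fraction of draws in
    which it attains the maximum NMB (exact per-draw ties broken toward
    the cheaper strategy); the CEAF follows the strategy with the highest
    mean NMB, which need not be the modal winner.
    """
    lambdas = np.asarray(list(lambdas), float)
    if lambdas.size == 0:
        raise ValueError("lambda grid must be non-empty")
    L = lambdas.size
    prob = np.zeros((L, len(psa.strategies)))
    front_s: list[str] = []
    front_p = np.zeros(L)
    # deterministic tie-break: subtract an epsilon of cost so that exact
    # NMB ties resolve toward the cheaper strategy
    eps = 1e-9
    for i, lam in enumerate(lambdas):
        values = psa.nmb_matrix(lam) - eps * psa.cost
        winner = np.argmax(values, axis=1)
        counts = np.bincount(winner, minlength=len(psa.strategies))
        prob[i] = counts / psa.n
        mean_values = values.mean(axis=0)
        best = int(np.argmax(mean_values))
        front_s.append(psa.strategies[best])
        front_p[i] = prob[i, best]
    return CeacCurve(
        lambdas=lambdas,
        probability=prob,
        strategies=psa.strategies,
        frontier_strategy=front_s,
        frontier_probability=front_p,
    )
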