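"""Cost-effectiveness economics: NMB, efficiency frontier, shortfall.

The decision rule is net monetary benefit, NMB = QALYs x lambda - cost,
maximized over the eight strategies at a willingness-to-pay threshold
lambda (ties broken toward the cheaper strategy). The efficiency frontier
ranks strategies by cost, removes strictly dominated options (more costly,
no more effective) and extendedly dominated ones (ICER not increasing
along the frontier), and reports the ICER of each successive frontier
strategy. Proportional shortfall — the fraction of the matched general
population's remaining QALE that the patient population loses to the
disease — selects the applicable Dutch threshold band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Dutch proportional-shortfall bands mapping to thresholds (euro/QALY).
SHORTFALL_BANDS = (
    (0.10, 0.40, 20_000.0),
    (0.41, 0.70, 50_000.0),
    (0.71, 1.00, 80_000.0),
)


def nmb(cost, qalys, threshold) -> np.ndarray | float:
    """Net monetary benefit: ``qalys * threshold - cost``."""
    if np.any(np.asarray(threshold) < 0):
        raise ValueError("willingness-to-pay threshold must be non-negative")
    return np.asarray(qalys) * threshold - np.asarray(cost)


@dataclass
class CEResult:
    """Per-strategy expected economics and frontier annotation."""

    strategies: list[str]
    cost: np.ndarray
    qalys: np.ndarray
    thresholds: tuple[float, ...]
    nmb: np.ndarray  # (n_strategies, n_thresholds)
    status: list[str]  # "frontier" | "dominated" | "extendedly dominated"
    icer: np.ndarray  # NaN off-frontier; NaN for the cheapest frontier point
    frontier: list[str] = field(default_factory=list)

    def optimal(self, threshold: float) -> str:
        """NMB-maximizing strategy at a threshold (ties -> lower cost)."""
        values = nmb(self.cost, self.qalys, threshold)
        best = np.max(values)
        tied = np.flatnonzero(np.isclose(values, best, rtol=0, atol=1e-9))
        cheapest = tied[np.argmin(self.cost[tied])]
        return self.strategies[cheapest]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "strategy": self.strategies,
                "cost": self.cost,
                "qalys": self.qalys,
            }
        )
        for i, lam in enumerate(self.thresholds):
            df[f"nmb_{int(lam)}"] = self.nmb[:, i]
        df["status"] = self.status
        df["icer"] = self.icer
        return df


def frontier(
    strategies: list[str],
    cost,
    qalys,
    thresholds: tuple[float, ...] = (20_000.0, 50_000.0, 80_000.0),
) -> CEResult:
    """Efficiency-frontier analysis over per-strategy (cost, QALY) pairs.

    Strictly dominated strategies (at least as costly and no more
    effective than some alternative, worse on at least one axis, or
    exactly tied with a strategy listed earlier) are flagged first; the
    remaining points are scanned in cost order, dropping any whose ICER
    exceeds that of the next frontier point (extended dominance).
    """
    cost = np.asarray(cost, float)
    qalys = np.asarray(qalys, float)
    n = len(strategies)
    if n < 2:
        raise ValueError("frontier analysis needs at least 2 strategies")
    if cost.shape != (n,) or qalys.shape != (n,):
        raise ValueError("cost and qalys must be vectors matching strategies")

    status = ["frontier"] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            tie = cost[j] == cost[i] and qalys[j] == qalys[i]
            if tie:
                if j < i:  # keep the first of identical points
                    status[i] = "dominated"
                continue
            if cost[j] <= cost[i] and qalys[j] >= qalys[i]:
                status[i] = "dominated"

    # extended dominance on the cost-sorted survivors
    while True:
        live = [i for i in range(n) if status[i] != "dominated"
                and status[i] != "extendedly dominated"]
        order = sorted(live, key=lambda i: (cost[i], -qalys[i]))
        icers = []
        for prev, cur in zip(order[:-1], order[1:]):
            icers.append((cost[cur] - cost[prev]) / (qalys[cur] - qalys[prev]))
        flagged = False
        for k in range(len(icers) - 1):
            if icers[k] > icers[k + 1]:
                status[order[k + 1]] = "extendedly dominated"
                flagged = True
                break
        if not flagged:
            break

    icer = np.full(n, np.nan)
    front = sorted(
        (i for i in range(n) if status[i] == "frontier"), key=lambda i: cost[i]
    )
    for prev, cur in zip(front[:-1], front[1:]):
        icer[cur] = (cost[cur] - cost[prev]) / (qalys[cur] - qalys[prev])

    nmb_matrix = np.stack([nmb(cost, qalys, lam) for lam in thresholds], axis=1)
    return CEResult(
        strategies=list(strategies),
        cost=cost,
        qalys=qalys,
        thresholds=tuple(thresholds),
        nmb=nmb_matrix,
        status=status,
        icer=icer,
        frontier=[strategies[i] for i in front],
    )


@dataclass
class ShortfallResult:
    patient_qale: float
    genpop_qale: float
    absolute_shortfall: float
    proportional_shortfall: float
    threshold: float | None  # euro/QALY band, None below the lowest band

    def to_dict(self) -> dict:
        return {
            "patient_qale": self.patient_qale,
            "genpop_qale": self.genpop_qale,
            "absolute_shortfall": self.absolute_shortfall,
            "proportional_shortfall": self.proportional_shortfall,
            "threshold": self.threshold,
        }


def proportional_shortfall(patient_qale: float, genpop_qale: float) -> ShortfallResult:
    """Disease-attributable QALE loss as a fraction of the matched
    general-population QALE, mapped to the Dutch threshold bands."""
    if genpop_qale <= 0:
        raise ValueError("general-population QALE must be positive")
    absolute = genpop_qale - patient_qale
    if absolute < 0:
        warnings.warn(
            "patient QALE exceeds general-population QALE; shortfall clamped at 0",
            stacklevel=2,
        )
        absolute = 0.0
    proportional = absolute / genpop_qale
    threshold = None
    for lo, hi, lam in SHORTFALL_BANDS:
        if lo <= proportional <= hi:
            threshold = lam
    return ShortfallResult(
        patient_qale=patient_qale,
        genpop_qale=genpop_qale,
        absolute_shortfall=absolute,
        proportional_shortfall=proportional,
        threshold=threshold,
    )
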