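"""Cost-effectiveness metrics: ICER efficiency frontier with strong and
extended dominance, net monetary benefit, and cost-effectiveness
acceptability curves (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import STRATEGIES
from .psa import PSASample

__all__ = ["FrontierTable", "CEACPoint", "icer_frontier", "nmb", "ceac"]

ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class FrontierTable:
    """Strategies sorted by ascending cost with dominance status and ICERs."""

    table: pd.DataFrame  # columns: strategy, cost, qaly, status,
    #                      incremental_cost, incremental_qaly, icer

    @property
    def frontier(self) -> list[str]:
        t = self.table
        return list(t.loc[t["status"] == ON_FRONTIER, "strategy"])

    def status(self, name: str) -> str:
        t = self.table
        return str(t.loc[t["strategy"] == name, "status"].iloc[0])

    def icer(self, name: str) -> float:
        t = self.table
        return float(t.loc[t["strategy"] == name, "icer"].iloc[0])


def icer_frontier(points: Iterable[tuple[str, float, float]]) -> FrontierTable:
    """Efficiency frontier of (name, cost, qaly) points.

    Points are sorted by cost (ties: higher QALY first, then input order — on
    exact cost/QALY ties the earlier-listed point stays and the later one is
    marked dominated).  Strongly dominated points (another point with cost <=
    and qaly >=, one strict) are removed; then interior points are removed by
    extended dominance until the chain's ICERs strictly increase.  Incremental
    cost/QALY and ICERs are reported along the surviving chain.
    """
    pts = [(str(n), float(c), float(q)) for n, c, q in points]
    if not pts:
        raise ValueError("icer_frontier requires at least one point")
    order = sorted(range(len(pts)), key=lambda i: (pts[i][1], -pts[i][2], i))
    status = {}
    # Strong dominance (ties resolved by input order).
    for a in range(len(pts)):
        na, ca, qa = pts[a]
        for b in range(len(pts)):
            if a == b:
                continue
            nb, cb, qb = pts[b]
            if cb <= ca and qb >= qa and (cb < ca or qb > qa):
                status[a] = DOMINATED
                break
            if cb == ca and qb == qa and b < a:
                status[a] = DOMINATED
                break
    chain = [i for i in order if status.get(i) is None]
    # Extended dominance: drop interior points with non-increasing ICERs.
    changed = True
    while changed and len(chain) >= 3:
        changed = False
        for j in range(1, len(chain) - 1):
            lo, mid, hi = chain[j - 1], chain[j], chain[j + 1]
            icer_in = _ratio(pts[mid], pts[lo])
            icer_out = _ratio(pts[hi], pts[mid])
            if icer_in >= icer_out:
                status[mid] = EXT_DOMINATED
                del chain[j]
                changed = True
                break
    rows = []
    prev = None
    on = set(chain)
    for i in order:
        name, cost, qaly = pts[i]
        row = {
            "strategy": name, "cost": cost, "qaly": qaly,
            "status": ON_FRONTIER if i in on else status.get(i, DOMINATED),
            "incremental_cost": np.nan, "incremental_qaly": np.nan, "icer": np.nan,
        }
        if i in on:
            if prev is not None:
                row["incremental_cost"] = cost - pts[prev][1]
                row["incremental_qaly"] = qaly - pts[prev][2]
                row["icer"] = _ratio(pts[i], pts[prev])
            prev = i
        rows.append(row)
    return FrontierTable(pd.DataFrame(rows))


def _ratio(hi: tuple[str, float, float], lo: tuple[str, float, float]) -> float:
    dq = hi[2] - lo[2]
    dc = hi[1] - lo[1]
    return dc / dq if dq != 0 else np.inf


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * qaly - cost`` at willingness-to-pay ``wtp``
    dollars per QALY.  Negative values mean the strategy's opportunity costs
    outweigh its health benefits at that threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return wtp * qaly - cost


@dataclass(frozen=True)
class CEACPoint:
    """Probability each strategy is cost-effective at one threshold."""

    wtp: float
    probabilities: dict[str, float]


def ceac(sample: PSASample, wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each threshold, each strategy's probability is the fraction of PSA
    draws in which it attains the maximum per-draw NMB; exact ties split the
    draw's mass equally among the tied strategies.
    """
    if sample.records.empty or len(wtp_grid) == 0:
        raise ValueError("ceac requires a nonempty sample and threshold grid")
    names = [s.value for s in STRATEGIES]
    piv_c = sample.records.pivot(index="draw", columns="strategy", values="cost")
    piv_q = sample.records.pivot(index="draw", columns="strategy", values="qaly")
    costs = piv_c[names].to_numpy()
    qalys = piv_q[names].to_numpy()
    n = costs.shape[0]
    points = []
    for wtp in wtp_grid:
        nb = wtp * qalys - costs
        best = nb.max(axis=1, keepdims=True)
        winners = nb == best
        weights = winners / winners.sum(axis=1, keepdims=True)
        probs = weights.sum(axis=0) / n
        points.append(CEACPoint(float(wtp), dict(zip(names, map(float, probs)))))
    return points


def ceac_frame(points: list[CEACPoint]) -> pd.DataFrame:
    """CEAC as a wide DataFrame (wtp, one probability column per strategy)."""
    rows = [{"wtp": p.wtp, **p.probabilities} for p in points]
    return pd.DataFrame(rows)
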