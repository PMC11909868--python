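"""Probabilistic sensitivity analysis: Monte Carlo propagation of the input
distributions through the decision tree.

Each draw realizes one full :class:`~ipfcea.parameters.ParameterSet` (common
random numbers: the same draw is evaluated under all four strategies, which is
what makes per-draw NMB comparisons and acceptability curves coherent) and
records the draw's *analytic* tree expectations — there is no patient-level
noise here; that lives in :mod:`ipfcea.microsim`.

Draw ``i`` gets its own RNG substream derived from ``(seed, stream, i)``, so
results for the first ``n`` draws do not change when ``n`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import STRATEGIES, Scenario, StrategyId, evaluate_all
from .parameters import ParameterRegistry

__all__ = ["PSASample", "PSASummary", "run_psa", "summarize", "draw_rng"]

#: RNG namespace tags so PSA and microsimulation never share a stream.
PSA_STREAM = 0
MICROSIM_STREAM = 1

_RECORD_COLUMNS = [
    "draw", "strategy", "cost", "qaly",
    "cost_supplemental_diag", "cost_biopsy", "cost_symptom_mgmt", "cost_treatment",
    "p_tp", "p_fp", "p_tn", "p_fn", "p_biopsy_death", "p_biopsied",
]


def draw_rng(seed: int, index: int, stream: int = PSA_STREAM) -> np.random.Generator:
    """Independent generator for one draw (or one microsim cohort)."""
    return np.random.default_rng(np.random.SeedSequence((seed, stream, index)))


@dataclass(frozen=True)
class PSASample:
    """Per-draw, per-strategy analytic tree results from one PSA run."""

    n_draws: int
    seed: int
    scenario: Scenario
    records: pd.DataFrame  # one row per (draw, strategy)

    def strategy_frame(self, strategy: StrategyId) -> pd.DataFrame:
        return self.records[self.records["strategy"] == StrategyId(strategy).value]


@dataclass(frozen=True)
class PSASummary:
    """Per-strategy means with 95% intervals.

    ``*_lo``/``*_hi`` are the 2.5th/97.5th percentiles of the per-draw cohort
    means; ``*_mean_ci_lo``/``*_mean_ci_hi`` are normal-theory 95% confidence
    intervals of the mean (mean ± 1.96·SE).  Both are reported because the two
    conventions differ by orders of magnitude for heavy-tailed costs.
    """

    n_draws: int
    table: pd.DataFrame  # indexed by strategy value


def run_psa(
    registry: ParameterRegistry,
    n: int,
    seed: int = 0,
    scenario: Scenario | None = None,
) -> PSASample:
    """Draw ``n`` parameter sets and evaluate all four strategies per draw."""
    if n < 1:
        raise ValueError("PSA requires n >= 1 draws")
    scenario = scenario or Scenario()
    rows = np.empty((n * len(STRATEGIES), len(_RECORD_COLUMNS) - 1), dtype=float)
    strat_col = []
    k = 0
    for i in range(n):
        params = registry.realize("sample", rng=draw_rng(seed, i))
        results = evaluate_all(params, scenario)
        for s in STRATEGIES:
            r = results[s]
            rows[k] = (
                i, r.total_cost, r.qalys,
                r.cost_supplemental_diag, r.cost_biopsy,
                r.cost_symptom_mgmt, r.cost_treatment,
                r.p_tp, r.p_fp, r.p_tn, r.p_fn, r.p_biopsy_death, r.p_biopsied,
            )
            strat_col.append(s.value)
            k += 1
    records = pd.DataFrame(rows, columns=[c for c in _RECORD_COLUMNS if c != "strategy"])
    records["draw"] = records["draw"].astype(int)
    records.insert(1, "strategy", strat_col)
    return PSASample(n_draws=n, seed=seed, scenario=scenario, records=records)


def summarize(sample: PSASample) -> PSASummary:
    """Per-strategy arithmetic means, percentile intervals, and mean CIs."""
    if sample.records.empty:
        raise ValueError("cannot summarize an empty PSA sample")
    out = {}
    for s in STRATEGIES:
        df = sample.strategy_frame(s)
        row: dict[str, float] = {}
        for col in _RECORD_COLUMNS[2:]:
            x = df[col].to_numpy()
            m = float(np.mean(x))
            se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
            row[f"{col}_mean"] = m
            row[f"{col}_lo"] = float(np.percentile(x, 2.5))
            row[f"{col}_hi"] = float(np.percentile(x, 97.5))
            row[f"{col}_mean_ci_lo"] = m - 1.96 * se
            row[f"{col}_mean_ci_hi"] = m + 1.96 * se
        row["diagnostic_cost_mean"] = (
            row["cost_supplemental_diag_mean"] + row["cost_biopsy_mean"]
        )
        out[s.value] = row
    table = pd.DataFrame(out).T
    table.index.name = "strategy"
    return PSASummary(n_draws=sample.n_draws, table=table)


def mean_points(sample: PSASample) -> list[tuple[str, float, float]]:
    """(strategy, mean cost, mean QALYs) triples, input for the ICER frontier."""
    summ = summarize(sample)
    return [
        (s.value, float(summ.table.loc[s.value, "cost_mean"]),
         float(summ.table.loc[s.value, "qaly_mean"]))
        for s in STRATEGIES
    ]
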