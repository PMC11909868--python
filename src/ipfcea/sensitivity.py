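"""Deterministic sensitivity analyses: one-way sweeps, tornado summaries,
threshold (bisection) searches, and named scenario re-runs of the PSA.

Deterministic analyses hold every other input at its base-case value; the
metric per grid point is evaluated for all four strategies.  Net monetary
benefit is reported at the conventional thresholds
$50,000-$250,000 per QALY.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .cea import FrontierTable, icer_frontier, nmb
from .model import STRATEGIES, Scenario, StrategyId, evaluate_all
from .parameters import ConfigError, ParameterRegistry
from .psa import PSASample, PSASummary, mean_points, run_psa, summarize

__all__ = [
    "WTP_THRESHOLDS",
    "SweepResult",
    "ThresholdResult",
    "one_way_sweep",
    "threshold_search",
    "tornado",
    "run_scenarios",
]

#: Willingness-to-pay thresholds ($/QALY) used for NMB reporting.
WTP_THRESHOLDS = (50_000.0, 100_000.0, 150_000.0, 200_000.0, 250_000.0)

#: metric name -> callable(StrategyResult, wtp) -> value
_METRICS: dict[str, Callable] = {
    "total_cost": lambda r, wtp: r.total_cost,
    "diagnostic_cost": lambda r, wtp: r.diagnostic_cost,
    "qalys": lambda r, wtp: r.qalys,
    "nmb": lambda r, wtp: nmb(r.total_cost, r.qalys, wtp),
}


@dataclass(frozen=True)
class SweepResult:
    """One-way sweep of a single input over a grid, all else at base."""

    parameter: str
    metric: str
    wtp: float | None
    grid: tuple[float, ...]
    table: pd.DataFrame  # long format: parameter, value, strategy, metric


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a bisection threshold search on one input."""

    parameter: str
    criterion: str
    found: bool
    threshold: float | None
    bracket: tuple[float, float] | None


def _metric_fn(metric: str, wtp: float | None) -> Callable:
    if metric not in _METRICS:
        raise ConfigError(
            f"unknown metric {metric!r}; choose from {sorted(_METRICS)}"
        )
    if metric == "nmb" and wtp is None:
        raise ConfigError("metric='nmb' requires a willingness-to-pay value")
    f = _METRICS[metric]
    return lambda r: f(r, wtp)


def one_way_sweep(
    registry: ParameterRegistry,
    param: str,
    grid: Sequence[float],
    metric: str = "nmb",
    wtp: float | None = None,
    scenario: Scenario | None = None,
) -> SweepResult:
    """Evaluate a metric for all strategies while one input traverses a grid."""
    try:
        spec = registry[param]
    except KeyError:
        raise ConfigError(f"unknown parameter {param!r}") from None
    lo, hi = spec.range_low, spec.range_high
    for v in grid:
        if not lo <= v <= hi:
            raise ConfigError(
                f"{param}: grid value {v} outside sensitivity range [{lo}, {hi}]"
            )
    fn = _metric_fn(metric, wtp)
    base = registry.realize("base")
    rows = []
    for v in grid:
        results = evaluate_all(base.replace(**{param: float(v)}), scenario)
        for s in STRATEGIES:
            rows.append(
                {"parameter": param, "value": float(v), "strategy": s.value,
                 "metric": metric, "result": fn(results[s])}
            )
    return SweepResult(
        parameter=param, metric=metric, wtp=wtp, grid=tuple(float(v) for v in grid),
        table=pd.DataFrame(rows),
    )


def _optimal_strategy(results: dict, wtp: float) -> StrategyId:
    return max(STRATEGIES, key=lambda s: nmb(results[s].total_cost, results[s].qalys, wtp))


def threshold_search(
    registry: ParameterRegistry,
    param: str,
    criterion: str | Callable[[dict], bool],
    wtp: float = 150_000.0,
    tolerance: float | None = None,
    scenario: Scenario | None = None,
) -> ThresholdResult:
    """Bisect for the input value at which a criterion flips.

    ``criterion`` is either a callable on the {strategy: StrategyResult}
    mapping, or the name of a strategy — shorthand for "that strategy is
    NMB-optimal at ``wtp``".  If the criterion does not change sign across the
    input's sensitivity range the result reports "no threshold in range"
    rather than raising.  The returned threshold is verified to separate the
    two criterion outcomes to within ``tolerance`` (default $1 for costs,
    1e-4 for probabilities/utilities).
    """
    spec = registry[param]
    lo, hi = spec.range_low, spec.range_high
    if tolerance is None:
        tolerance = 1.0 if spec.base_value > 1.0 else 1e-4
    if callable(criterion):
        crit_fn, crit_name = criterion, getattr(criterion, "__name__", "criterion")
    else:
        target = StrategyId(criterion)
        crit_fn = lambda res: _optimal_strategy(res, wtp) is target  # noqa: E731
        crit_name = f"{target.value} NMB-optimal at wtp={wtp:g}"
    base = registry.realize("base")

    def holds(v: float) -> bool:
        return bool(crit_fn(evaluate_all(base.replace(**{param: float(v)}), scenario)))

    f_lo, f_hi = holds(lo), holds(hi)
    if f_lo == f_hi:
        return ThresholdResult(param, crit_name, False, None, None)
    a, b = lo, hi
    while b - a > tolerance:
        mid = 0.5 * (a + b)
        if holds(mid) == f_lo:
            a = mid
        else:
            b = mid
    return ThresholdResult(param, crit_name, True, 0.5 * (a + b), (a, b))


def tornado(
    registry: ParameterRegistry,
    metric: str = "nmb",
    wtp: float | None = 150_000.0,
    strategy: StrategyId = StrategyId.ML_ALGORITHM,
    scenario: Scenario | None = None,
) -> pd.DataFrame:
    """One-way swing of every input between its range endpoints, ranked by span.

    Returns a frame with the metric at each input's low and high bound for the
    requested strategy, sorted by descending ``span = |high - low|``.
    """
    fn = _metric_fn(metric, wtp)
    base = registry.realize("base")
    strategy = StrategyId(strategy)
    rows = []
    for spec in registry:
        vals = {}
        for tag, v in (("at_low", spec.range_low), ("at_high", spec.range_high)):
            results = evaluate_all(base.replace(**{spec.name: v}), scenario)
            vals[tag] = fn(results[strategy])
        rows.append(
            {"parameter": spec.name, "low": spec.range_low, "high": spec.range_high,
             "metric_at_low": vals["at_low"], "metric_at_high": vals["at_high"],
             "span": abs(vals["at_high"] - vals["at_low"])}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("span", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class ScenarioRun:
    scenario: Scenario
    sample: PSASample
    summary: PSASummary
    frontier: FrontierTable


def run_scenarios(
    registry: ParameterRegistry,
    scenarios: Sequence[Scenario],
    n: int = 10_000,
    seed: int = 0,
) -> dict[str, ScenarioRun]:
    """Full PSA + frontier per scenario, sharing one seed for comparability."""
    out = {}
    for sc in scenarios:
        sample = run_psa(registry, n=n, seed=seed, scenario=sc)
        out[sc.name] = ScenarioRun(
            scenario=sc,
            sample=sample,
            summary=summarize(sample),
            frontier=icer_frontier(mean_points(sample)),
        )
    return out
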