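"""Patient-level microsimulation of the diagnostic decision tree.

This is the package's synthetic-data generator and brute-force oracle: each
simulated patient draws a disease status Bernoulli(prevalence) and then
traverses their strategy's tree with an independent Bernoulli draw at every
probability node, receiving exactly the payoffs the analytic cohort model
assigns to that pathway.  Empirical cohort means therefore converge to the
analytic expectations at the Monte Carlo 1/sqrt(n) rate — which is what
:func:`compare_to_analytic` checks with z-scores.

The traversal is vectorized over patients; cohorts of a few hundred thousand
simulate in milliseconds.  Microsimulation RNG streams are namespaced apart
from the PSA streams so oracle runs never perturb PSA reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Scenario, StrategyId, StrategyResult
from .parameters import ParameterSet
from .psa import MICROSIM_STREAM, draw_rng

__all__ = ["CohortSummary", "simulate_cohort", "summarize_cohort", "compare_to_analytic"]

_STATES = ("TP", "FP", "TN", "FN", "death")


def simulate_cohort(
    params: ParameterSet,
    strategy: StrategyId,
    n: int,
    seed: int = 0,
    scenario: Scenario | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` patients; one row per patient (a PatientRecord).

    Columns: ``id, has_ipf, strategy, test_result, biopsied, died_biopsy,
    terminal_state, fp_benefit, cost, qaly``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    strategy = StrategyId(strategy)
    if scenario is not None:
        params = scenario.apply(params)
    rng = draw_rng(seed, 0, stream=MICROSIM_STREAM)
    p = params

    has_ipf = rng.random(n) < p.prevalence
    test_result = np.full(n, "none", dtype=object)
    biopsied = np.zeros(n, dtype=bool)
    died = np.zeros(n, dtype=bool)
    treated = np.zeros(n, dtype=bool)
    state = np.empty(n, dtype=object)

    if strategy is StrategyId.TREAT_ALL:
        treated[:] = True
        state[:] = np.where(has_ipf, "TP", "FP")
    else:
        if strategy is StrategyId.BIOPSY_ALL:
            biopsied[:] = True
            fee = 0.0
        else:
            if strategy is StrategyId.ML_ALGORITHM:
                sens, spec, fee = p.sens_algo, p.spec_algo, p.c_algo
            else:
                sens, spec, fee = p.sens_gc, p.spec_gc, p.c_classifier + p.c_bronch
            u = rng.random(n)
            positive = np.where(has_ipf, u < sens, u >= spec)
            test_result[:] = np.where(positive, "positive", "inconclusive")
            treated |= positive
            state[positive & has_ipf] = "TP"
            state[positive & ~has_ipf] = "FP"
            inconclusive = ~positive
            referred = inconclusive & (rng.random(n) < p.p_referral)
            biopsied |= referred
            stay = inconclusive & ~referred
            empiric = stay & (rng.random(n) < p.p_inconclusive_treat)
            treated |= empiric
            state[empiric & has_ipf] = "TP"
            state[empiric & ~has_ipf] = "FP"
            untreated = stay & ~empiric
            state[untreated & has_ipf] = "FN"
            state[untreated & ~has_ipf] = "TN"
        died = biopsied & (rng.random(n) < p.p_biopsy_death)
        state[died] = "death"
        surv = biopsied & ~died
        u = rng.random(n)
        pos_biopsy = np.where(has_ipf, u < p.sens_biopsy, u >= p.spec_biopsy)
        state[surv & has_ipf & pos_biopsy] = "TP"
        state[surv & has_ipf & ~pos_biopsy] = "FN"
        state[surv & ~has_ipf & ~pos_biopsy] = "TN"
        state[surv & ~has_ipf & pos_biopsy] = "FP"
        treated |= surv & pos_biopsy

    if strategy is StrategyId.TREAT_ALL:
        fee = 0.0
    is_fp = state == "FP"
    b = p.p_fp_benefit_treatall if strategy is StrategyId.TREAT_ALL else p.p_fp_benefit_test
    fp_benefit = is_fp & (rng.random(n) < b)

    cost = np.full(n, fee, dtype=float)
    cost += np.where(biopsied, p.c_slb, 0.0)
    cost += np.where(treated & ~died, p.c_treat * p.treat_cost_multiplier, 0.0)
    negative = (state == "TN") | (state == "FN")
    cost += np.where(negative, p.c_symptom, 0.0)

    q_by_state = {
        "TP": p.q_tp, "FP": p.q_fp, "TN": p.q_tn, "FN": p.q_fn, "death": 0.0,
    }
    qaly = np.array([q_by_state[s] for s in state], dtype=float)
    qaly[fp_benefit] = p.q_tp
    qaly -= np.where(is_fp & ~fp_benefit, p.u_complication, 0.0)
    qaly -= np.where(biopsied & ~died, p.u_biopsy, 0.0)
    qaly[died] = 0.0

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "has_ipf": has_ipf,
            "strategy": strategy.value,
            "test_result": test_result,
            "biopsied": biopsied,
            "died_biopsy": died,
            "terminal_state": state.astype(str),
            "fp_benefit": fp_benefit,
            "cost": cost,
            "qaly": qaly,
        }
    )


@dataclass(frozen=True)
class CohortSummary:
    """Empirical cohort aggregates with standard errors."""

    strategy: StrategyId
    n: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    state_freq: dict[str, float]
    p_biopsied: float


def summarize_cohort(cohort: pd.DataFrame) -> CohortSummary:
    n = len(cohort)
    freq = {s: float((cohort["terminal_state"] == s).mean()) for s in _STATES}
    return CohortSummary(
        strategy=StrategyId(cohort["strategy"].iloc[0]),
        n=n,
        mean_cost=float(cohort["cost"].mean()),
        se_cost=float(cohort["cost"].std(ddof=1) / np.sqrt(n)),
        mean_qaly=float(cohort["qaly"].mean()),
        se_qaly=float(cohort["qaly"].std(ddof=1) / np.sqrt(n)),
        state_freq=freq,
        p_biopsied=float(cohort["biopsied"].mean()),
    )


def compare_to_analytic(
    cohort: CohortSummary, analytic: StrategyResult, z_max: float = 4.0
) -> pd.DataFrame:
    """z-scores of empirical cohort means against analytic tree expectations.

    For each quantity ``z = (empirical - analytic) / SE``; binomial SEs use
    the analytic probability.  Zero-variance quantities are compared exactly
    (z is 0 or inf).  The frame carries a ``passed`` column (|z| <= z_max).
    """
    if cohort.strategy != analytic.strategy:
        raise ValueError("cohort and analytic results are for different strategies")
    n = cohort.n
    rows = []

    def add(name: str, emp: float, ana: float, se: float) -> None:
        if se <= 1e-10 * max(1.0, abs(ana), abs(emp)):
            # degenerate quantity (constant payoff): exact agreement up to
            # float summation order
            z = 0.0 if np.isclose(emp, ana, rtol=1e-9, atol=1e-12) else np.inf
        else:
            z = (emp - ana) / se
        rows.append({"quantity": name, "empirical": emp, "analytic": ana,
                     "se": se, "z": z, "passed": abs(z) <= z_max})

    add("mean_cost", cohort.mean_cost, analytic.total_cost, cohort.se_cost)
    add("mean_qaly", cohort.mean_qaly, analytic.qalys, cohort.se_qaly)
    analytic_freq = {
        "TP": analytic.p_tp, "FP": analytic.p_fp, "TN": analytic.p_tn,
        "FN": analytic.p_fn, "death": analytic.p_biopsy_death,
    }
    def binom_se(pa: float) -> float:
        return float(np.sqrt(max(pa * (1 - pa), 0.0) / n))

    for s in _STATES:
        pa = analytic_freq[s]
        add(f"freq_{s}", cohort.state_freq[s], pa, binom_se(pa))
    pb = analytic.p_biopsied
    add("p_biopsied", cohort.p_biopsied, pb, binom_se(pb))
    return pd.DataFrame(rows)
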