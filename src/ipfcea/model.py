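"""Analytic evaluation of the four-strategy IPF diagnostic decision tree.

The cohort enters after a multidisciplinary discussion left the diagnosis
unresolved; a fraction ``prevalence`` truly has IPF.  Four strategies are
compared:

``ml_algorithm`` / ``genomic_classifier``
    A supplemental test classifies each patient as IPF-positive (treated
    immediately) or inconclusive.  Inconclusive patients are referred to
    surgical lung biopsy with probability ``p_referral``; non-referred
    patients go untreated (or, in a scenario, are treated empirically with
    probability ``p_inconclusive_treat``).  Biopsy carries a procedure
    mortality ``p_biopsy_death``; survivors are classified by the biopsy's
    own sensitivity/specificity.
``biopsy_all``
    Every patient goes straight to surgical lung biopsy.
``treat_all``
    No diagnostics: every patient is treated empirically.

Terminal states are TP/FP (treated), TN/FN (symptom management), or death
from biopsy.  All states are final — no later follow-up reclassifies anyone.
Payoffs are lifetime totals: costs split into supplemental-diagnostic,
biopsy, symptom-management, and treatment components; QALYs are the terminal
state's lifetime total minus a biopsy decrement (survivors of surgical biopsy
only) and, for treated false positives without treatment benefit, an expected
treatment-complication decrement (the true-positive total already reflects
the treatment experience of its source cohort).  Biopsy
deaths accrue the diagnostic and biopsy fees already incurred, no downstream
cost, and zero QALYs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .parameters import ConfigError, ParameterSet

__all__ = [
    "StrategyId",
    "Scenario",
    "Pathway",
    "StrategyResult",
    "enumerate_pathways",
    "evaluate_strategy",
    "evaluate_all",
]


class StrategyId(str, enum.Enum):
    """The four diagnostic/treatment strategies."""

    ML_ALGORITHM = "ml_algorithm"
    GENOMIC_CLASSIFIER = "genomic_classifier"
    BIOPSY_ALL = "biopsy_all"
    TREAT_ALL = "treat_all"


STRATEGIES = tuple(StrategyId)

#: Terminal states.
TP, FP, TN, FN, DEATH = "TP", "FP", "TN", "FN", "death"


@dataclass(frozen=True)
class Scenario:
    """Scenario knobs applied on top of a parameter set before evaluation.

    ``None`` leaves the corresponding ParameterSet value untouched.
    """

    treat_cost_multiplier: float = 1.0
    p_inconclusive_treat: float = 0.0
    p_fp_benefit_test: float | None = None
    p_fp_benefit_treatall: float | None = None
    name: str = "base"

    def apply(self, params: ParameterSet) -> ParameterSet:
        changes: dict = {
            "treat_cost_multiplier": self.treat_cost_multiplier,
            "p_inconclusive_treat": self.p_inconclusive_treat,
        }
        if self.p_fp_benefit_test is not None:
            changes["p_fp_benefit_test"] = self.p_fp_benefit_test
        if self.p_fp_benefit_treatall is not None:
            changes["p_fp_benefit_treatall"] = self.p_fp_benefit_treatall
        return params.replace(**changes)


@dataclass(frozen=True)
class Pathway:
    """One root-to-terminal route through a strategy's tree."""

    strategy: StrategyId
    labels: tuple[str, ...]
    probability: float
    cost: float
    qaly: float
    state: str  # TP / FP / TN / FN / death
    biopsied: bool
    treated: bool
    # cost components (sum to `cost`)
    cost_diag: float = 0.0
    cost_biopsy: float = 0.0
    cost_symptom: float = 0.0
    cost_treat: float = 0.0


@dataclass(frozen=True)
class StrategyResult:
    """Probability-weighted expectation of one strategy's tree."""

    strategy: StrategyId
    total_cost: float
    qalys: float
    cost_supplemental_diag: float
    cost_biopsy: float
    cost_symptom_mgmt: float
    cost_treatment: float
    p_tp: float
    p_fp: float
    p_tn: float
    p_fn: float
    p_biopsy_death: float
    p_biopsied: float

    @property
    def diagnostic_cost(self) -> float:
        """Diagnostic-only cost: supplemental test fee plus biopsy spend."""
        return self.cost_supplemental_diag + self.cost_biopsy


def _arm_test(params: ParameterSet, strategy: StrategyId) -> tuple[float, float, float]:
    """(sensitivity, specificity, per-patient supplemental fee) for a test arm."""
    if strategy is StrategyId.ML_ALGORITHM:
        return params.sens_algo, params.spec_algo, params.c_algo
    if strategy is StrategyId.GENOMIC_CLASSIFIER:
        # The classifier requires a bronchoscopy to collect tissue; both fees
        # are charged to every patient entering the arm.
        return params.sens_gc, params.spec_gc, params.c_classifier + params.c_bronch
    raise ConfigError(f"{strategy} is not a test arm")


def _terminal(
    params: ParameterSet,
    strategy: StrategyId,
    labels: tuple[str, ...],
    probability: float,
    state: str,
    *,
    fee: float,
    biopsied: bool,
    biopsy_survivor: bool,
    fp_benefit: bool = False,
) -> Pathway:
    """Build a terminal pathway with its full payoff decomposition."""
    cost_diag = fee
    cost_biopsy = params.c_slb if biopsied else 0.0
    cost_symptom = cost_treat = 0.0
    treated = state in (TP, FP)
    if state == DEATH:
        qaly = 0.0
    else:
        if treated:
            cost_treat = params.c_treat * params.treat_cost_multiplier
            if state == TP or fp_benefit:
                # the true-positive lifetime QALY total already reflects the
                # treatment experience of its source cohort
                qaly = params.q_tp
            else:
                # treated false positive without benefit: symptom-management
                # prognosis plus the expected treatment-complication decrement
                qaly = params.q_fp - params.u_complication
        else:
            cost_symptom = params.c_symptom
            qaly = params.q_tn if state == TN else params.q_fn
        if biopsy_survivor:
            qaly -= params.u_biopsy
    return Pathway(
        strategy=strategy,
        labels=labels,
        probability=probability,
        cost=cost_diag + cost_biopsy + cost_symptom + cost_treat,
        qaly=qaly,
        state=state,
        biopsied=biopsied,
        treated=treated and state != DEATH,
        cost_diag=cost_diag,
        cost_biopsy=cost_biopsy,
        cost_symptom=cost_symptom,
        cost_treat=cost_treat,
    )


def _fp_split(
    params: ParameterSet,
    strategy: StrategyId,
    labels: tuple[str, ...],
    probability: float,
    *,
    fee: float,
    biopsied: bool,
    biopsy_survivor: bool,
) -> list[Pathway]:
    """FP terminal, split by whether the patient gains treatment benefit.

    With probability ``p_fp_benefit`` (arm-specific, default 0) a treated
    false positive's QALY payoff is upgraded to the true-positive total
    (treatment costs are paid either way).
    """
    b = (
        params.p_fp_benefit_treatall
        if strategy is StrategyId.TREAT_ALL
        else params.p_fp_benefit_test
    )
    out = []
    if probability * (1.0 - b) > 0.0:
        out.append(
            _terminal(
                params, strategy, labels + ("fp_benefit=no",), probability * (1.0 - b),
                FP, fee=fee, biopsied=biopsied, biopsy_survivor=biopsy_survivor,
            )
        )
    if probability * b > 0.0:
        out.append(
            _terminal(
                params, strategy, labels + ("fp_benefit=yes",), probability * b,
                FP, fee=fee, biopsied=biopsied, biopsy_survivor=biopsy_survivor,
                fp_benefit=True,
            )
        )
    return out


def _biopsy_branch(
    params: ParameterSet,
    strategy: StrategyId,
    labels: tuple[str, ...],
    probability: float,
    has_ipf: bool,
    fee: float,
) -> list[Pathway]:
    """Surgical-biopsy subtree: procedure death, then classification."""
    d, sb, cb = params.p_biopsy_death, params.sens_biopsy, params.spec_biopsy
    out: list[Pathway] = []
    p_death = probability * d
    if p_death > 0.0:
        out.append(
            _terminal(
                params, strategy, labels + ("biopsy_outcome=death",), p_death, DEATH,
                fee=fee, biopsied=True, biopsy_survivor=False,
            )
        )
    p_surv = probability * (1.0 - d)
    if p_surv <= 0.0:
        return out
    survive = labels + ("biopsy_outcome=survive",)
    if has_ipf:
        if p_surv * sb > 0.0:
            out.append(
                _terminal(
                    params, strategy, survive + ("state=TP",), p_surv * sb, TP,
                    fee=fee, biopsied=True, biopsy_survivor=True,
                )
            )
        if p_surv * (1.0 - sb) > 0.0:
            out.append(
                _terminal(
                    params, strategy, survive + ("state=FN",), p_surv * (1.0 - sb), FN,
                    fee=fee, biopsied=True, biopsy_survivor=True,
                )
            )
    else:
        if p_surv * cb > 0.0:
            out.append(
                _terminal(
                    params, strategy, survive + ("state=TN",), p_surv * cb, TN,
                    fee=fee, biopsied=True, biopsy_survivor=True,
                )
            )
        if p_surv * (1.0 - cb) > 0.0:
            out.extend(
                _fp_split(
                    params, strategy, survive + ("state=FP",), p_surv * (1.0 - cb),
                    fee=fee, biopsied=True, biopsy_survivor=True,
                )
            )
    return out


def enumerate_pathways(params: ParameterSet, strategy: StrategyId) -> list[Pathway]:
    """All root-to-terminal pathways of one strategy, with probabilities and
    payoffs.  Zero-probability branches are pruned; the probabilities of the
    returned pathways sum to 1."""
    strategy = StrategyId(strategy)
    pi = params.prevalence
    out: list[Pathway] = []

    if strategy is StrategyId.TREAT_ALL:
        if pi > 0.0:
            out.append(
                _terminal(
                    params, strategy, ("disease=IPF", "state=TP"), pi, TP,
                    fee=0.0, biopsied=False, biopsy_survivor=False,
                )
            )
        if 1.0 - pi > 0.0:
            out.extend(
                _fp_split(
                    params, strategy, ("disease=none", "state=FP"), 1.0 - pi,
                    fee=0.0, biopsied=False, biopsy_survivor=False,
                )
            )
        return out

    if strategy is StrategyId.BIOPSY_ALL:
        for has_ipf, p_disease in ((True, pi), (False, 1.0 - pi)):
            if p_disease <= 0.0:
                continue
            tag = "disease=IPF" if has_ipf else "disease=none"
            out.extend(
                _biopsy_branch(
                    params, strategy, (tag, "biopsied=yes"), p_disease, has_ipf, 0.0
                )
            )
        return out

    # Test arms.
    s, c, fee = _arm_test(params, strategy)
    r = params.p_referral
    pit = params.p_inconclusive_treat
    for has_ipf, p_disease in ((True, pi), (False, 1.0 - pi)):
        if p_disease <= 0.0:
            continue
        tag = "disease=IPF" if has_ipf else "disease=none"
        p_pos = p_disease * (s if has_ipf else 1.0 - c)
        p_inc = p_disease - p_pos
        # Positive test: treated directly, no biopsy.
        if p_pos > 0.0:
            labels = (tag, "test=positive", f"state={'TP' if has_ipf else 'FP'}")
            if has_ipf:
                out.append(
                    _terminal(
                        params, strategy, labels, p_pos, TP,
                        fee=fee, biopsied=False, biopsy_survivor=False,
                    )
                )
            else:
                out.extend(
                    _fp_split(
                        params, strategy, labels, p_pos,
                        fee=fee, biopsied=False, biopsy_survivor=False,
                    )
                )
        if p_inc <= 0.0:
            continue
        inc = (tag, "test=inconclusive")
        # Not referred to biopsy.
        p_noref = p_inc * (1.0 - r)
        p_untreated = p_noref * (1.0 - pit)
        if p_untreated > 0.0:
            state = FN if has_ipf else TN
            out.append(
                _terminal(
                    params, strategy, inc + ("biopsied=no", "treated=no", f"state={state}"),
                    p_untreated, state,
                    fee=fee, biopsied=False, biopsy_survivor=False,
                )
            )
        # Scenario: empiric treatment after an inconclusive result, no biopsy.
        p_emp = p_noref * pit
        if p_emp > 0.0:
            labels = inc + ("biopsied=no", "treated=empiric",
                            f"state={'TP' if has_ipf else 'FP'}")
            if has_ipf:
                out.append(
                    _terminal(
                        params, strategy, labels, p_emp, TP,
                        fee=fee, biopsied=False, biopsy_survivor=False,
                    )
                )
            else:
                out.extend(
                    _fp_split(
                        params, strategy, labels, p_emp,
                        fee=fee, biopsied=False, biopsy_survivor=False,
                    )
                )
        # Referred to surgical biopsy.
        p_ref = p_inc * r
        if p_ref > 0.0:
            out.extend(
                _biopsy_branch(
                    params, strategy, inc + ("biopsied=yes",), p_ref, has_ipf, fee
                )
            )
    return out


def evaluate_strategy(params: ParameterSet, strategy: StrategyId) -> StrategyResult:
    """Expected costs (by component), QALYs, and terminal-event probabilities."""
    pathways = enumerate_pathways(params, strategy)
    tot = dict.fromkeys(
        ("cost", "qaly", "diag", "biopsy", "symptom", "treat",
         TP, FP, TN, FN, DEATH, "biopsied"), 0.0
    )
    for pw in pathways:
        p = pw.probability
        tot["cost"] += p * pw.cost
        tot["qaly"] += p * pw.qaly
        tot["diag"] += p * pw.cost_diag
        tot["biopsy"] += p * pw.cost_biopsy
        tot["symptom"] += p * pw.cost_symptom
        tot["treat"] += p * pw.cost_treat
        tot[pw.state] += p
        if pw.biopsied:
            tot["biopsied"] += p
    return StrategyResult(
        strategy=StrategyId(strategy),
        total_cost=tot["cost"],
        qalys=tot["qaly"],
        cost_supplemental_diag=tot["diag"],
        cost_biopsy=tot["biopsy"],
        cost_symptom_mgmt=tot["symptom"],
        cost_treatment=tot["treat"],
        p_tp=tot[TP],
        p_fp=tot[FP],
        p_tn=tot[TN],
        p_fn=tot[FN],
        p_biopsy_death=tot[DEATH],
        p_biopsied=tot["biopsied"],
    )


def evaluate_all(
    params: ParameterSet, scenario: Scenario | None = None
) -> dict[StrategyId, StrategyResult]:
    """Apply scenario knobs, then evaluate every strategy on the same inputs."""
    if scenario is not None:
        params = scenario.apply(params)
    return {s: evaluate_strategy(params, s) for s in STRATEGIES}
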