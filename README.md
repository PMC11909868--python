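# ipfcea

Decision-analytic cost-effectiveness model of diagnostic strategies for
idiopathic pulmonary fibrosis (IPF).

IPF is a progressive fibrosing lung disease (median survival ≈ 3.8 years)
whose diagnosis often remains uncertain after multidisciplinary discussion.
The historical gold standard, surgical lung biopsy, is expensive and carries
a real procedure mortality; lifetime antifibrotic treatment (nintedanib) is
effective but very costly.  This package evaluates four strategies for the
unresolved-diagnosis population on lifetime costs and quality-adjusted
life-years (QALYs), from a US health-sector perspective:

- **ml_algorithm** — a non-invasive machine-learning image classifier as a
  supplement to multidisciplinary discussion,
- **genomic_classifier** — a bronchoscopy-based genomic classifier,
- **biopsy_all** — surgical lung biopsy for everyone,
- **treat_all** — empiric antifibrotic treatment for everyone.

It is intended for health-economics analysts who want a scriptable,
reproducible version of this class of model: a decision tree evaluated
analytically, wrapped in probabilistic and deterministic sensitivity
machinery, with a patient-level microsimulation as an independent oracle.

## Model

With prevalence π, arm test sensitivity/specificity (s, c), biopsy referral
probability r for inconclusive results, biopsy accuracy (s_b, c_b) and
biopsy mortality d, a test arm allocates patients as

- positive: π·s → TP, (1−π)(1−c) → FP (treated, no biopsy);
- inconclusive, not referred (prob. 1−r): FN / TN (untreated);
- inconclusive, referred (prob. r): biopsy death d, survivors classified by
  (s_b, c_b).

`biopsy_all` sends everyone to biopsy; `treat_all` treats everyone (π → TP,
1−π → FP).  Terminal payoffs are lifetime totals: treated states pay the
lifetime treatment cost and receive the treated (TP) or false-positive QALY
total; negative states pay symptom-management costs; biopsy survivors lose a
small QALY decrement; biopsy deaths accrue diagnostic and biopsy costs and 0
QALYs.  All states are final.

Strategies are compared by incremental cost-effectiveness ratios
(ICER = ΔC/ΔE) along the efficiency frontier after removing strong and
extended dominance, by net monetary benefit (NMB = λ·E − C at
willingness-to-pay λ), and by cost-effectiveness acceptability curves
(probability of maximal per-draw NMB across Monte Carlo draws).

## Worked example

```python
from ipfcea import default_registry, run_psa, summarize, icer_frontier, ceac
from ipfcea.psa import mean_points

registry = default_registry()                  # packaged model inputs
sample = run_psa(registry, n=10_000, seed=1)   # probabilistic analysis
frontier = icer_frontier(mean_points(sample))
print(frontier.table[["strategy", "cost", "qaly", "status", "icer"]]
      .round(2).to_string(index=False))
```

```
          strategy      cost  qaly      status       icer
        biopsy_all 346277.98  3.63 on_frontier        NaN
      ml_algorithm 386477.82  3.75 on_frontier  334633.91
genomic_classifier 393733.55  3.77 on_frontier  403121.06
         treat_all 716727.10  3.86 on_frontier 3315556.56
```

Biopsy-all is cheapest but least effective; each step up the frontier buys
QALYs at a steeply increasing price — ≈ $335k/QALY for the machine-learning
arm over biopsy-all, ≈ $403k/QALY for the genomic classifier over the ML
arm, and ≈ $3.3M/QALY for treating everyone.  At a $250,000/QALY
willingness-to-pay the acceptability curve still favours biopsy-all:

```python
point = ceac(sample, [250_000.0])[0]
print({k: round(v, 3) for k, v in point.probabilities.items()})
```

```
{'ml_algorithm': 0.233, 'genomic_classifier': 0.217, 'biopsy_all': 0.42, 'treat_all': 0.13}
```

The driver is the lifetime treatment cost: the new diagnostics reliably cut
*diagnostic* spending (the ML arm by ≈ $15k per patient vs biopsy-all), but
they route more patients into treatment.

A command-line interface mirrors the library
(`ipfcea default-config | base-case | psa | ceac | one-way | tornado |
threshold | scenario | microsim`); every run writes CSVs plus a manifest
with the config checksum and seed for bit-identical reruns.

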