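# Methods

## Model structure

The model is a single-stage decision tree for a cohort entering ILD work-up
after multidisciplinary discussion failed to resolve the diagnosis; a
fraction `prevalence` truly has IPF.  Each of the four strategies
(`ml_algorithm`, `genomic_classifier`, `biopsy_all`, `treat_all`) routes
patients to one of five terminal states — TP, FP (treated), TN, FN (symptom
management), or death from surgical biopsy — via the branch probabilities
described in the README.  All states are terminal: there is no cycle
structure, no discounting, and no later reclassification of false results.
Lifetime costs and QALYs are attached directly to terminal states, inherited
from an upstream treatment cost-effectiveness model; this package makes no
attempt to re-derive them from survival or lung-function trajectories.

Structural choices worth making explicit:

- "Inconclusive" means any non-positive test output; the supplemental tests
  are binary-with-referral.  There is no confident-negative branch.
- The biopsy referral probability for inconclusive results is shared by both
  test arms.
- The genomic classifier requires bronchoscopic tissue collection, so every
  patient in that arm is charged both the classifier fee and the
  bronchoscopy fee (base case $5,793 + $11,170 = $16,963).
- Biopsy deaths accrue the arm's supplemental diagnostic fee and the biopsy
  cost (incurred before death) but no downstream treatment or
  symptom-management cost, and zero QALYs.
- The biopsy QALY decrement (0.013) applies to surgical-biopsy survivors
  only — not to the classifier arm's bronchoscopy.
- The treatment-complication decrement (mean 0.03, i.e. a 0.1 disutility for
  the ~30% of treated patients with serious adverse events) applies to
  treated false positives without treatment benefit, on top of their
  false-positive QALY total.  The true-positive QALY total (4.15) comes from
  the treatment arm of the source model and is taken to already reflect the
  treatment experience, so no further decrement is applied to TP — this
  reading follows the source's own quality-of-life description and
  reproduces its printed QALY and ICER values more closely than applying the
  decrement to all treated patients.
- Two scenario knobs extend the base tree: `p_inconclusive_treat` (empiric
  treatment of non-referred inconclusive results; such patients mirror
  direct test-positives) and the `p_fp_benefit_*` inputs (a false positive
  gains treatment benefit with some probability, upgrading their QALY payoff
  to the true-positive total while still paying treatment costs; they then
  mirror TP exactly, so no complication decrement).  Both default to off.

One deliberate inconsistency in the inputs is preserved: the biopsy-death
probability is 0.064 (the tabulated input) even though the source's prose
mentions 6.7%; 0.064 is what reconciles the printed biopsy-mortality deltas.

## Parameters and distributions

The packaged configuration (`ipfcea default-config`) holds one entry per
model input: base value, one-way sensitivity range `[low, high]`, and PSA
distribution.  Distributions are specified as their sources report them and
inverted in closed form:

- lognormal from (mean, median): `mu = ln(median)`,
  `sigma = sqrt(2 ln(mean/median))` — the unique two-parameter solution;
  mean = median degenerates to a point mass.
- beta from (mean, SD): method of moments,
  `nu = mean(1-mean)/sd^2 - 1`, `alpha = mean*nu`, `beta = (1-mean)*nu`.
- beta from an explicit shape pair where the source gives one: biopsy
  sensitivity Beta(27, 7) and prevalence Beta(626, 922).  Their distribution
  means (0.794, 0.404) deliberately differ from their base values; the
  probabilistic averages reported by the model depend on this.
- normal (complication decrement, mean 0.03, SD 0.01) truncated at 0 by
  resampling: a negative decrement is meaningless, and with the truncation
  point 3 SD below the mean the induced bias (~4e-5) is negligible.

All PSA draws are independent across parameters (no correlations are
specified by the sources).  Rows marked fixed (the biopsy disutility and the
two false-positive-benefit probabilities) are held at base value in every
draw.  `realize()` produces the base-case point, the distribution-mean
point, or a seeded draw; because the tree is multilinear in its independent
inputs, PSA means converge to the distribution-mean-point evaluation, which
the tests exploit.

## Probabilistic analysis

`run_psa` evaluates all four strategies on the same parameter draw (common
random numbers), records each draw's analytic tree expectations, and is
deterministic per seed: draw *i* uses an RNG substream keyed by
`(seed, stream, i)`, so the first *n* draws are unchanged when *n* grows,
and microsimulation uses a separate stream namespace.  The default run is
10,000 draws, matching the analysis it reproduces; it takes ~2 s on one CPU.

Summaries report per-strategy means plus two kinds of 95% interval: the
2.5th/97.5th percentiles of the per-draw cohort means, and a normal-theory
confidence interval of the mean (mean ± 1.96 SE).  The source's printed
intervals are numerically consistent with the latter (a percentile interval
for the heavy-tailed treat-all cost would be an order of magnitude wider);
both are provided and nothing downstream depends on the choice.

## Cost-effectiveness metrics

The ICER frontier sorts strategies by mean cost, removes strong dominance
(≤ cost and ≥ QALYs, one strict; exact ties keep the earlier-listed entry),
then iteratively removes extended dominance until ICERs strictly increase.
ICERs are computed from unrounded means — the published sequential ICERs are
not recoverable from rounded incremental columns.  The CEAC uses the
per-draw NMB-maximizer definition with ties splitting a draw's mass equally.
NMB is reported at the conventional $50k–$250k/QALY thresholds.

## Deterministic sensitivity analyses

One-way sweeps hold all other inputs at base-case values (not distribution
means): the published referral-rate endpoint figures ($37,373 / $25,410
savings at zero referral; $7,609 saving and $3,302 excess at universal
referral) reproduce exactly only at base values with prevalence 0.404.
"Diagnostic-only cost" is the supplemental-test component plus the biopsy
component.  Threshold searches bisect an input's sensitivity range (default
resolution $1 for costs, 1e-4 for probabilities) and verify the criterion on
both sides; an unchanged criterion is reported as "no threshold in range"
rather than raised.  The treatment-cost threshold below which treat-all
becomes NMB-optimal is evaluated at the highest conventional
willingness-to-pay threshold ($250,000/QALY), where it lands at ≈ $178k; the
source reports ≈ $177,000 without stating the threshold used, and at lower
willingness-to-pay values the crossover sits lower (≈ $157k at
$150,000/QALY).  Scenario analyses (treatment-cost reductions, empiric
treatment of inconclusives, false-positive benefit) re-run the full PSA
under one shared seed for comparability.

## Microsimulation oracle

`simulate_cohort` is the synthetic-data generator: patients individually
Bernoulli-sample the same tree with identical payoffs, vectorized over the
cohort.  It emulates exactly the cohort structure the analytic model
assumes — independent identically-distributed patients, perfectly known
branch probabilities, terminal lifetime payoffs.  It does *not* emulate
features of real ILD cohorts (age/sex case-mix, correlated test errors,
time-to-event structure, repeat testing), so agreement between the two
engines validates the implementation, not the model's clinical fidelity.
`compare_to_analytic` z-scores empirical means and state frequencies against
the analytic expectations (binomial SEs at the analytic probability;
constant-payoff quantities are compared exactly up to float summation
order); the acceptance-level check uses 200,000-patient cohorts and a |z| ≤ 4
pass bound for 10 random parameter sets per strategy.

## Problem sizes and numerics

Default analyses: 10,000 PSA draws; 200,000-patient oracle cohorts;
1,000,000-draw Monte Carlo verification of the distribution solvers (within
3 SE of the stated summaries); 500 random instances for the frontier
brute-force cross-check.  The full test suite runs in well under a minute on
one CPU.  Pathway probabilities are required to sum to 1 within 1e-12 and
cost components to totals within 1e-9 relative; zero-probability branches
are pruned from pathway enumerations.

## Known limitations

The model inherits all limitations of its terminal-payoff design: no
discounting (lifetime totals are used as given), no time-to-diagnosis
effects, no transbronchial/cryobiopsy pathways, no repeat testing, and no
societal-perspective costs.  Parameter uncertainty is propagated as
independent draws; correlated uncertainty (e.g. between a test's sensitivity
and specificity) is not modelled.
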