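# Default model inputs: costs (2022 USD), pathway probabilities, and lifetime
# quality-of-life payoffs for the four-strategy IPF diagnostic decision model.
# Each entry: base value, one-way sensitivity range [low, high], and the
# distribution sampled in probabilistic sensitivity analysis (psa_fixed rows
# are held at their base value in every draw).
parameters:
  - name: c_algo
    label: Machine-learning algorithm test fee ($)
    base: 5000
    low: 500
    high: 10000
    dist: {family: lognormal, parameterization: mean_median, mean: 5000, median: 4900}
  - name: c_classifier
    label: Genomic classifier fee ($)
    base: 5793
    low: 500
    high: 10000
    dist: {family: lognormal, parameterization: mean_median, mean: 5793, median: 5500}
  - name: c_bronch
    label: Bronchoscopy ($)
    base: 11170
    low: 872
    high: 35039
    dist: {family: lognormal, parameterization: mean_median, mean: 11170, median: 5689}
  - name: c_slb
    label: Surgical lung biopsy ($)
    base: 42373
    low: 27048
    high: 57698
    dist: {family: lognormal, parameterization: mean_median, mean: 42373, median: 34482}
  - name: c_symptom
    label: Lifetime symptom management ($)
    base: 84073
    low: 10000
    high: 120000
    dist: {family: lognormal, parameterization: mean_median, mean: 84073, median: 72000}
  - name: c_treat
    label: Lifetime nintedanib treatment ($)
    base: 711579
    low: 100000
    high: 900000
    dist: {family: lognormal, parameterization: mean_median, mean: 711579, median: 575000}
  - name: p_referral
    label: Inconclusive result referred to biopsy
    base: 0.75
    low: 0.0
    high: 1.0
    dist: {family: beta, parameterization: mean_sd, mean: 0.75, sd: 0.15}
  - name: sens_algo
    label: Sensitivity of the ML algorithm
    base: 0.53
    low: 0.41
    high: 0.65
    dist: {family: beta, parameterization: mean_sd, mean: 0.53, sd: 0.059}
  - name: spec_algo
    label: Specificity of the ML algorithm
    base: 0.86
    low: 0.77
    high: 0.93
    dist: {family: beta, parameterization: mean_sd, mean: 0.86, sd: 0.040}
  - name: sens_gc
    label: Sensitivity of the genomic classifier
    base: 0.68
    low: 0.55
    high: 0.73
    dist: {family: beta, parameterization: mean_sd, mean: 0.68, sd: 0.045}
  - name: spec_gc
    label: Specificity of the genomic classifier
    base: 0.92
    low: 0.81
    high: 0.95
    dist: {family: beta, parameterization: mean_sd, mean: 0.92, sd: 0.035}
  - name: p_biopsy_death
    label: Surgical biopsy results in death
    base: 0.064
    low: 0.01
    high: 0.17
    dist: {family: beta, parameterization: mean_sd, mean: 0.064, sd: 0.02}
  - name: sens_biopsy
    label: Biopsy sensitivity
    base: 0.75
    low: 0.5
    high: 1.0
    dist: {family: beta, parameterization: shape_pair, alpha: 27, beta: 7}
  - name: spec_biopsy
    label: Biopsy specificity
    base: 0.90
    low: 0.8
    high: 1.0
    dist: {family: beta, parameterization: mean_sd, mean: 0.9, sd: 0.05}
  - name: p_fp_benefit_test
    label: FP gets treatment benefit (algorithm/classifier/biopsy arms)
    base: 0.0
    low: 0.0
    high: 0.4
    psa_fixed: true
    dist: {family: fixed, parameterization: point, value: 0.0}
  - name: p_fp_benefit_treatall
    label: FP gets treatment benefit (treat-all arm)
    base: 0.0
    low: 0.0
    high: 0.2
    psa_fixed: true
    dist: {family: fixed, parameterization: point, value: 0.0}
  - name: prevalence
    label: Prevalence of IPF in the work-up population
    base: 0.404
    low: 0.1
    high: 0.6
    dist: {family: beta, parameterization: shape_pair, alpha: 626, beta: 922}
  - name: u_biopsy
    label: QoL decrement from undergoing surgical lung biopsy
    base: 0.013
    low: 0.0
    high: 0.026
    psa_fixed: true
    dist: {family: fixed, parameterization: point, value: 0.013}
  - name: q_fn
    label: Lifetime QALYs, false negative
    base: 3.78
    low: 2.78
    high: 4.78
    dist: {family: lognormal, parameterization: mean_median, mean: 3.78, median: 3.7}
  - name: q_fp
    label: Lifetime QALYs, false positive
    base: 3.7
    low: 2.7
    high: 4.7
    dist: {family: lognormal, parameterization: mean_median, mean: 3.7, median: 3.6}
  - name: q_tn
    label: Lifetime QALYs, true negative
    base: 3.78
    low: 2.85
    high: 4.85
    dist: {family: lognormal, parameterization: mean_median, mean: 3.78, median: 3.7}
  - name: q_tp
    label: Lifetime QALYs, true positive
    base: 4.15
    low: 3.15
    high: 5.15
    dist: {family: lognormal, parameterization: mean_median, mean: 4.15, median: 4.05}
  - name: u_complication
    label: QoL decrement for treatment complications
    base: 0.03
    low: 0.0
    high: 0.1
    dist: {family: normal, parameterization: mean_sd, mean: 0.03, sd: 0.01}
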