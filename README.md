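# pairrisk

Rank-based gene-pair risk scoring for survival stratification in
diffuse large B-cell lymphoma (DLBCL), for computational biologists who
want a transferable prognostic score and a fully testable derivation
pipeline.

Roughly 40% of DLBCL patients relapse under standard R-CHOP therapy,
and coefficient-based expression signatures transfer poorly between
array platforms because they depend on measurement scale.  `pairrisk`
implements the alternative: screen favorable (FPG) and unfavorable
(UPG) prognostic genes by dichotomised univariable Cox analysis in two
independent training cohorts, pair them, and keep the pairs whose
binary indicator

&nbsp;&nbsp;&nbsp;&nbsp;*s* = 1 if *q*<sub>UPG</sub> ≥ *q*<sub>FPG</sub>, else 0
&nbsp;&nbsp;&nbsp;&nbsp;(*q* = within-cohort percentile rank)

carries hazard ratio > 1.8 in both cohorts.  The risk score is the
plain sum *R* = Σ *s* over the signature's *k* pairs — an integer with
*k*+1 levels (five for *k* = 4, high risk at *R* ≥ 3) that is invariant
under any per-gene monotone transform of expression and therefore
portable across platforms.  Everything around the score is included:
empirical-Bayes (ComBat-style) batch integration, first-principles
survival statistics (Kaplan–Meier, log-rank, Gehan–Wilcoxon, Efron-tie
Cox, time-dependent ROC), a synthetic-cohort generator with planted
signal, ranked-AUC comparison against coefficient signatures, and
cell-line drug-sensitivity stratification.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (two 400-patient, two-batch cohorts with one favorable and one
unfavorable gene planted at |log HR| = ln 2.0 and their pair at
log HR = ln 2.2):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_derive_signature.py
python analysis/03_evaluate_risk_score.py
```

which prints

```
cohort 1: 400 patients in 2 batches, event fraction 0.70, planted pair ('G0001', 'G0000')
cohort 2: 400 patients in 2 batches, event fraction 0.74, planted pair ('G0001', 'G0000')

gene screen intersections: 1 FPG, 1 UPG
signature: 1 pair(s) over 2 gene(s): [('G0001', 'G0000')]
planted pair(s) recovered: [('G0001', 'G0000')]; spurious: []

cohort 1: risk levels [0, 1], KM log-rank p = 2.28e-23, mean 1-3y AUC = 0.682,
  IPI-stratified p = {'high': '2.6e-07', 'intermediate': '2.1e-08', 'low': '3.8e-11'}
cohort 2: risk levels [0, 1], KM log-rank p = 1.68e-16, mean 1-3y AUC = 0.679,
  IPI-stratified p = {'high': '1.5e-05', 'intermediate': '5.4e-06', 'low': '6.8e-09'}
```

Reading this: the two-gate screen (log-rank and Wilcoxon p < 0.01, same
class in both cohorts) finds exactly the planted genes, the pair screen
confirms their pair at HR > 1.8 in both cohorts with no spurious pairs,
and the resulting score separates survival strongly overall
(log-rank p ≈ 1e-23) and inside every IPI stratum, with a mean
1–3-year time-dependent AUC of ≈ 0.68.  Scripts `04`–`06` add the
ranked-AUC comparison against linear signatures, the 17-cell-line
drug-sensitivity stratification (9 low- vs 8 high-risk lines, Welch's
t per drug), and the null-calibration / recovery experiments.

The same steps are available programmatically
(`pairrisk.pipeline.run_pipeline` on a YAML config) and through the
`pairrisk` CLI (`simulate`, `run`, `screen-genes`, `score`,
`compare-drugs`).

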