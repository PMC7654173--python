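# polyrisk

Combined polygenic and phenotypic breast-cancer risk modelling for
case-control cohorts.

`polyrisk` implements, as a tested and reusable library, the analysis
pipeline of a combined genotype + phenotype risk-evaluation study: a
SNP-panel polygenic risk score (PRS) with explicit quality-control rules,
odds-ratio encoding of categorical risk factors (mammographic density,
reproductive history, family history), a multivariable logistic model with
age interaction terms, cross-validated discrimination (AUC), and
stratification of predicted risk into quantile bands against a 40–60%
reference. Because the clinical cohorts such studies analyse are not
publicly available, the package also ships a first-class synthetic cohort
generator that reproduces the statistical structure the analysis assumes —
so every stage is testable end to end, and methodological questions (power,
calibration, the value of interaction terms) can be explored by simulation.

It is aimed at statistical geneticists and epidemiologists building or
auditing PRS-plus-phenotype risk models.

## The model

For woman *i* with effect-allele counts $x_{ik} \in \{0,1,2\}$ over a panel
of $K$ SNPs with per-allele odds ratios $\mathrm{OR}_k$:

$$\mathrm{PRS}_i = \sum_{k=1}^{K} \beta_k x_{ik}, \qquad \beta_k = \log \mathrm{OR}_k .$$

The score is reported raw, normalized (divided by the control median) and
standardized (control mean 0, SD 1). Panel QC removes SNPs with
$0.95 < \mathrm{OR} < 1.05$ (strict) and flagged genotyping failures;
samples and SNPs with call rate < 0.95 are dropped. Categorical risk
factors are encoded quantitatively by their per-category odds ratios
(reference category = 1.0); age enters as the ordinal index of 5-year bins
spanning 30–70. The final model is a maximum-likelihood logistic regression

$$\operatorname{logit} P(\text{case}_i) = \alpha + \sum_j \gamma_j z_{ij}
  + \delta_1 (\text{age}_i \times \text{density}_i)
  + \delta_2 (\text{age}_i \times \text{menopause}_i) + \text{covariates},$$

with factors selected by a univariable screen at two-sided p < 0.05 (family
history and menarche forced in), interactions screened by likelihood ratio
tests, calibration checked by the Hosmer–Lemeshow decile test, and
discrimination summarised by the median AUC over repeated random 90/10
train/test splits. Predicted risks are cut at empirical quantiles into the
bands <10 / 10–20 / 20–40 / 40–60 / 60–80 / 80–90 / >90 percent, and each
band's odds ratio is estimated against the 40–60% reference band.

## Worked example

`python examples/risk_model_stratification.py` simulates a cohort of 455
cases and 642 controls with age×density and age×menopause interaction
effects and runs the whole pipeline:

```
selected factors:      ('density', 'menopause', 'menarche', 'family', 'prs')
selected interactions: (('age', 'density'),)
PRS OR per SD:         1.67
Hosmer-Lemeshow:       chi2=4.94, p=0.76
CV-AUC with interactions:    0.825 (95% CI 0.760-0.893)
CV-AUC without interactions: 0.822 (95% CI 0.751-0.895)
paired comparison p:         1.8e-08

risk bands vs 40-60% reference:
  band     or  ci_low  ci_high   p  pct_controls  pct_cases
  <10%  0.062   0.022    0.174 0.0        16.511      0.879
10-20%  0.239   0.128    0.446 0.0        14.953      3.077
20-40%  0.377   0.244    0.583 0.0        27.726      9.011
40-60%  1.000     NaN      NaN NaN        21.184     18.242
60-80%  2.139   1.460    3.134 0.0        14.798     27.253
80-90%  6.198   3.632   10.578 0.0         3.583     19.121
  >90% 20.892   9.676   45.106 0.0         1.246     22.418
```

The per-SD OR says how much the case odds multiply per control-SD of the
PRS; the Hosmer–Lemeshow p (not small) indicates the fitted probabilities
are internally well calibrated; the band table shows the model pushing
low-risk women's odds far below and high-risk women's far above the middle
of the distribution. `examples/simulate_cohort.py` and
`examples/prs_workflow.py` walk the generator and the QC/PRS stages one at
a time, and the `polyrisk` CLI exposes `simulate` and `pipeline` for shell
use.

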