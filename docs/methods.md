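# Methods

This note documents the statistical model the package implements, the
generative model behind the synthetic cohorts, the numerical conventions,
and the design decisions taken where more than one reading was defensible.

## The analysis pipeline

The target design is a retrospective case-control study of breast cancer
in women aged 30–70, combining a SNP-panel polygenic risk score with five
categorical risk factors (mammographic density on the Boyd semiquantitative
scale, age at first delivery, menopause status, age at menarche, family
history) recruited at two centres.

**Panel filtering and QC.** A candidate weight panel is reduced to the
scoring panel by removing SNPs whose per-allele OR lies strictly inside
(0.95, 1.05) — the strict inequality means ORs of exactly 0.95 or 1.05 are
retained — together with SNPs flagged as platform genotyping failures or as
failing control-duplicate checks (the duplicate criterion is a boolean flag
supplied with the panel; no quantitative rule is imposed). Samples with
call rate < 0.95 over the panel and SNPs with genotyping rate < 0.95 are
dropped. All removals are logged.

**PRS.** The score is Σₖ βₖ·xₖ with βₖ = log ORₖ. The package can also sum
raw ORs (`weights="or"`) because published descriptions of such scores are
sometimes written that way, but log-odds weights are the default: they are
the additive scale on which per-allele effects combine, and they are what
makes "OR per SD of the score" a meaningful quantity. Missing genotypes
default to expected-dosage imputation (2·eaf); zero-fill and drop-the-SNP
policies are selectable. Scores are emitted on three scales: raw;
normalized = raw / median(controls), the cohort-reporting scale on which a
typical woman sits near 1; and standardized = (raw − control mean)/control
SD, the scale used in association models so the coefficient is an OR per
control SD.

**Population structure.** The first five principal components of the
column-centred, unit-variance-scaled dosage matrix (missing calls
mean-imputed per SNP) adjust the PRS association. Genotypes are the only
stated PC source we consider plausible. Scaling by √(2p(1−p)) is available
as an alternative. Component signs are fixed by making each component's
largest-magnitude loading positive; explained-variance ties break by
column order.

**Phenotype encoding.** Each factor category maps to its odds ratio from an
external encoding table (reference category ≡ 1.0). The OR tables are
configuration data — the package never hard-codes literature values; the
repository's default tables are synthetic examples with
literature-plausible directions, and any real analysis must supply its own.
A menarche "Null" category is retained as its own level (OR 1.0 by
default) rather than treated as missing. Age is binned into
[30,35), [35,40), …, [65,70] (top bin closed); printed bin labels in such
studies overlap at the edges, so a convention is required, and
half-open-left is chosen so that, e.g., age 51 falls in "50–55". As a model
covariate age is the ordinal bin index; whether the original analyses used
the index or the bin midpoint is unstated, and the index is the simpler
choice consistent with "grouped then treated quantitatively".

**Association screens.** Each factor is screened by ML logistic regression
of case status on its encoded value adjusted for age bin and centre; Wald
95% CIs and two-sided p-values summarise single coefficients (the standard
default when no method is named). The standardized coefficient is
coefficient × SD(predictor). The PRS fit follows the design's own
description — standardized PRS + age bin + five PCs, without centre — and a
switch can harmonise it with the centre-adjusted screens. Interactions are
tested by the likelihood ratio test between nested fits (statistic floored
at 0, χ² with 1 df). Independence of the PRS and the phenotypes is checked
by pairwise Spearman correlations over controls only (average ranks for
ties; constant variables reported as undefined rather than dropped).

**Multivariable model.** Main effects are the screen's selections at
two-sided p < 0.05 plus family history and menarche, which are forced in as
established risk factors regardless of in-cohort significance. Candidate
interactions (age×density, age×menopause by default) enter when their LRT
p < 0.05. Age inside interaction products is the same ordinal bin index as
the main effect. Global model significance is the Wald chi-square that all
non-intercept coefficients are zero ("Wald test" alone does not pin down a
variant; per-term Wald statistics are reported as well). Calibration uses
the Hosmer–Lemeshow test over deciles of predicted probability, ties going
to the lower group and tied-empty groups merged with a warning; df =
groups − 2.

**Prediction.** The "individual risk factor" is the fitted probability. In
a case-control sample the intercept absorbs the ascertainment ratio, so
this is a *relative* risk score, not an absolute 5-year risk; the package
documents it as such. Downstream stratification is rank-based and therefore
indifferent to the intercept convention.

**Evaluation.** AUC is the Mann–Whitney probability with ties credited ½,
computed from average ranks. The cross-validated AUC repeats, by default
1000 times, a uniform random 90/10 split, refits the model spec on the
training women and scores the test women; the summary is the median and
the 2.5/97.5 percentile interval of the replicate distribution. (A
bootstrap-over-cohort option exists because interval strategies differ
between descriptions of this design; the CV reading is the default.) Two
model variants run on identical split sequences (same seed), so their AUC
difference is assessed by a paired two-sided Wilcoxon signed-rank test —
approximate, since replicates share women. Stratification cuts the full
cohort's predicted risks (cases and controls pooled; the natural choice
when reporting each band's share of cases and of controls) at empirical
quantiles 0.1/0.2/0.4/0.6/0.8/0.9, ties at a cut going to the lower band;
each outer band's OR against the 40–60% reference band is estimated by
indicator logistic regression restricted to that band plus the reference,
with degenerate bands reported as undefined rather than dropped. Tail
contrasts around the PRS use 5% tails against the same 40–60% middle.

## The synthetic cohort generator

The generator exists so the pipeline can be validated without patient
data. It draws a *prospective* population and then *retrospectively*
ascertains fixed numbers of cases and controls, mimicking case-control
recruitment; retrospective sampling preserves odds ratios (verified by a
simulation test) while absolute risk is deliberately not preserved.

Defaults encode the emulated study's conditions: 455 cases and 642
controls; 92 biallelic SNPs with effect-allele frequencies U(0.05, 0.5) and
independent Binomial(2, p) genotypes (Hardy–Weinberg, no linkage
disequilibrium); eight 5-year age bins with the control-column bin
probabilities of the emulated cohort; five categorical factors drawn at
their control-category frequencies; two recruitment centres with an
optional intercept shift; baseline log-odds logit(0.12), the assumed
population prevalence.

The linear predictor is baseline + Σβₖxₖ + per-factor category log-ORs +
optional interaction terms (coefficient × age-bin index × factor log-OR) +
centre shift, and the outcome is Bernoulli(expit(·)). By default every
effect term is mean-centred over its generative distribution. Centring is
a pure reparameterisation of the intercept — no odds ratio changes — but
without it a 92-SNP panel's mean contribution (≈ +4 on the log-odds scale)
would push the realised prevalence towards 1 and make `baseline_log_odds`
uninterpretable. The uncentred literal form is available via
`center_effects=False`.

Per-category effect sizes are configuration, not constants. The default
log-ORs are synthetic example values with conventional directions (denser
breasts, later first delivery, premenopausal status, earlier menarche and
stronger family history all increase risk). For calibrated experiments,
`calibrate_panel_per_sd_effect` rescales the panel's log-ORs so that
Var(Σβx) = Σβ²·2p(1−p) gives exactly the requested per-SD log-odds.

What the generator does **not** emulate: linkage disequilibrium, admixture
beyond an optional two-subpopulation mode (used to validate the PCs),
correlations between risk factors (each is drawn independently), age
effects on recruitment, and tumour subtypes. Tests passing on synthetic
cohorts therefore demonstrate correctness of the statistical machinery
under the stated generative assumptions, not performance on real data.

## Problem sizes used by the tests and the acceptance script

The package's own evidence is simulation-based, and sizes were chosen to
make the checks statistically decisive while staying quick: calibrated
per-SD-OR/AUC recovery uses 100 replicates of 1097-woman cohorts drawn from
populations of 6000; null-calibration checks use 200 replicates of n = 400;
Hosmer–Lemeshow self-consistency 40 replicates of n = 5000; effect-recovery
coverage 40–100 replicates at n = 4000–20000; CV-AUC model comparisons 20
cohort replicates with 60 paired splits each. The full 1000-split CV
default remains available and is exercised at reduced counts in tests.

## Expected values under calibration

With the generative per-SD effect set to log(1.41), the recovered per-SD OR
averages ≈ 1.41–1.42 (retrospective sampling preserves it; standardizing by
the control SD rather than the population SD biases it upward only
negligibly at this effect size). The Mann–Whitney AUC of a score whose
case/control distributions are near-normal with equal variance is
Φ(per-SD log-odds/√2) = Φ(0.343/1.414) ≈ 0.596 — the unadjusted-score
counterpart of a published age-and-PC-adjusted value of 0.62, and the
quantity the acceptance script reports.

## Known limitations

- With age×factor product interactions on these marginals, the interaction
  term is strongly collinear with its main effects: even generatively large
  interaction coefficients raise cross-validated AUC by only ~0.005–0.01
  over the additive model. The package reproduces the *direction* of the
  interaction-model advantage reliably, but an AUC gap as large as 0.06
  between the two variants is not reachable under this generator; gaps of
  that size likely require interaction structure (or factor dependence)
  this generator does not model.
- Band odds ratios in 1097-woman cohorts are noisy in adjacent middle
  bands; strict monotonicity across all seven bands holds in ~90% of
  replicates at a per-SD log-odds of 1.2 and should not be expected
  per-cohort.
- Separation in sparse strata (e.g. an outer band with zero cases) is
  reported as an undefined OR rather than regularised; Firth-type
  corrections are out of scope.
- The a-priori sample-size calculation of the emulated design is
  under-specified (no effect size stated) and is not reproduced.
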