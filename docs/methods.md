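# Methods

This note documents the statistical model, the numerical choices made in its
implementation, the scope of the synthetic-cohort generator, and the problem
sizes used in the package's own validation runs.

## Study design being modelled

The pipeline targets a case-control proteomic/clinical study of depression
onset. Three groups of samples exist:

- **Reference** individuals (healthy controls), outcome 0.
- **Training patients** with current subthreshold depressive symptoms,
  outcome 1; reference + training patients form the training cohort.
- **Extrapolation patients** who are healthy at sampling time but develop
  depressive symptoms later. They are scored with the trained model together
  with the reference group to probe generalization beyond the model's
  training scope.

Candidate predictors are peptide abundance log2 ratios from targeted mass
spectrometry (multiple reaction monitoring, MRM), sociodemographic variables
(continuous and categorical), and clinical symptom severities (ordinal 0-3)
plus their total score. Defaults: 146 peptides, 22 sociodemographic, 30
clinical features; 86 reference, 86 training, 37 extrapolation samples.

## MRM preprocessing

Raw data are transition-level peak areas: per sample x peptide, 3-4 fragment
transitions, each with an endogenous and a stable-isotope-labelled internal
standard (SIS) area. For each peptide one **quantifier transition** is
chosen from the peak areas summed across all samples: the transition with the
largest area in *both* channels if one exists, otherwise the one with the
largest endogenous + SIS sum (the tie-break is logged). Using sums across
samples rather than per-sample maxima guarantees every sample of a peptide is
quantified on the same transition. The peptide's abundance per sample is
`log2(endogenous / SIS)` on the quantifier.

Sample quality control: the complete sample x peptide ratio matrix is
column-centered and decomposed by SVD; samples whose score on principal
component 1 or 2 exceeds `k_sd` (default 4.0) standard deviations of that
component's scores are flagged as outliers. Flags are reported, not
automatically removed.

## Feature preparation

- **Missingness screen:** features missing in more than `missingness_max_rate`
  (default 5%) of samples are dropped before imputation.
- **Imputation:** multiple imputation by chained equations with `m = 5`
  chains of 3 sweeps each. Continuous features use linear regression
  predictions plus Gaussian residual-noise draws; categorical and ordinal
  features use multinomial logistic draws. The m completed tables are pooled
  by mean (continuous) or mode (discrete). Ridge damping (1e-8) keeps the
  within-chain linear solves defined when predictors are collinear.
- **Dummy coding:** each categorical/ordinal feature with L levels becomes
  L-1 indicator columns named `"feature; level"`, with the lowest level as
  the reference. All indicators of one feature form one penalty group, so
  the feature enters or leaves the model as a unit.
- **Standardization:** continuous columns are centered and scaled to unit
  variance; dummy columns are left as 0/1. Constant columns are dropped with
  a warning. Scaling parameters estimated on the training cohort are reused
  verbatim when building evaluation designs.

## Penalized model: group LASSO logistic regression

For design matrix X (n samples, p columns in G groups) and binary outcome y,
the fit minimizes

    (1/n) * NLL(beta0, beta) + lambda * sum_g sqrt(p_g) * ||beta_g||_2

where NLL is the binomial negative log-likelihood, p_g the group's column
count, and the intercept beta0 is unpenalized. The sqrt(p_g) weight makes
groups of different sizes comparable.

**Solver.** Blockwise proximal minimization-by-majorization coordinate
descent. Each group's partial likelihood is majorized by a quadratic with
curvature `L_g = lambda_max(X_g' X_g) / (4n)` (from the 1/4 Lipschitz bound
of the logistic loss), giving the closed-form update
`beta_g <- S(beta_g + grad_g / L_g, lambda sqrt(p_g) / L_g)` with S the
group soft-thresholding operator. The intercept uses the same bound. An
active-set strategy iterates the currently nonzero groups to convergence,
then makes a full pass over all groups; the fit terminates when a full pass
moves no coefficient by more than the tolerance. The kernel is JIT-compiled
(numba) over a Fortran-ordered design matrix.

**Penalty path.** `lambda_max = max_g ||(1/n) X_g'(y - ybar)||_2 / sqrt(p_g)`
is the smallest penalty with an all-zero stationary solution; the grid is
100 log-spaced values descending from lambda_max to 0.01 * lambda_max,
walked with warm starts.

**Tolerances.** Reported fits (the final refit per ensemble repeat, and any
direct `fit_group_lasso` call) use tol 1e-7 and up to 10,000 iterations.
Cross-validation *fold* fits — which feed only the held-out deviance curve,
never reported coefficients — use tol 1e-5 and at most 1,000 iterations, and
each fold's path walk stops early once it is 20 grid points past the running
deviance minimum or after 5 consecutive points exceeding minimum + 1 SE.
Rationale: with p > n, fold fits near the dense end of the path approach
separation and converge very slowly, while both CV selection rules can only
choose at or before the deviance minimum; the truncation provably cannot
change the selected lambda under the one-standard-error rule and was checked
empirically to leave chosen lambdas and selection fractions unchanged.

**Cross-validation.** 10-fold, unstratified seeded partition (redrawn once
if a fold lacks both classes). The default selection rule is the
one-standard-error rule: the largest lambda whose mean held-out deviance is
within one standard error of the minimum ("most regularised" model);
`cv_rule="min"` selects the minimizer instead.

## Ensemble, information criteria and averaging

The fit-and-select step is repeated R = 100 times (R = 25 in the scaled-down
validation runs), each repeat with an independently seeded CV partition.
Each repeat's selected model is refit on the chosen lambda at full tolerance;
non-convergent repeats are excluded with a warning.

Each model is scored by the small-sample Akaike information criterion,

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1),

with logL the binomial log-likelihood at the penalized fit's probabilities
and k the number of *features* in the model (a grouped dummy set counts
once; `k_mode="parameters"` counts columns, `logl_mode="refit"` substitutes
an unpenalized refit's likelihood). Akaike weights
`w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)` (computed shift-invariantly)
give each repeat's model a probability of being the best approximating
model; weights are normalized across the R repeats.

Repeats are grouped into **unique models** by their sorted feature set; a
unique model's probability is its members' summed weight. The final model is
then built by one of two paths:

1. **Dominant model:** if one unique model's probability strictly exceeds
   0.9, its members' coefficients are averaged with their weights
   renormalized.
2. **Extract-and-average:** otherwise, features whose selection fraction
   (share of repeats selecting them) is >= 0.9 (inclusive) are retained, and
   each retained coefficient is averaged over *all* R models with absent
   models contributing zero: `beta_bar = sum_i w_i beta_hat_i`. This
   shrinks features toward zero in proportion to their instability.

If neither path applies (no feature reaches the fraction threshold), the
result degrades to the intercept-only model, which predicts the training
prevalence for every sample.

## Evaluation

Risk scores are logistic probabilities from the averaged model on the
standardized design. AUC is computed two ways, which agree exactly: the
Mann-Whitney rank statistic with half-credit for ties, and the trapezoid
area under the ROC curve built from the distinct descending score
thresholds. Qualitative bands (upper-inclusive): >= 0.9 excellent, >= 0.8
good, >= 0.7 fair, >= 0.6 poor, >= 0.5 fail, below 0.5 "fail (worse than
chance)". Training performance is an apparent (resubstitution) estimate;
extrapolation performance scores the reference + extrapolation samples with
the frozen model and scaling.

## Synthetic-cohort generator: scope

The generator produces cohorts with known ground truth; its defaults are the
study conditions used in validation.

- **Proteomics:** Gaussian log2 ratios with compound-symmetry correlation
  blocks (block size 5, within-block correlation 0.3), emulating peptides
  that share a protein.
- **Sociodemographics:** a fixed panel of 6 continuous and 16 categorical
  variables with marginals anchored at plausible reference-group values.
- **Clinical:** 29 ordinal symptom severities (0-3) from a thresholded
  latent Gaussian (base probabilities 0.55/0.25/0.13/0.07), plus their
  derived total score.
- **Planted effects:** the default panel of 12 informative features (6
  peptides — one per correlation block — plus BMI, childhood trauma,
  education, and 3 symptoms) receives a standardized mean/latent shift of
  0.8 in the patient group. Extrapolation patients get every effect
  multiplied by `extrapolation_attenuation` (default 0.5), emulating weaker
  pre-onset indications; the reference group is drawn from a shared random
  substream so both evaluation cohorts use identical controls.
- **Raw MRM layer:** per peptide, 3-4 transitions with lognormal base
  intensities and per-sample spike factors; endogenous area = SIS area x
  2^(true ratio + Gaussian log2 noise, SD 0.05). This supports round-trip
  validation of the preprocessing.
- **Missingness:** missing-completely-at-random masking of non-proteomic
  cells at rate <= 5% (default 2%).

The generator does **not** emulate: batch or plate effects, informative
(non-random) missingness, measurement drift over time, label noise in the
outcome, or realistic linkage between sociodemographic and clinical
variables (features are independent across blocks apart from the planted
group shifts and the derived total score). Conclusions about those
phenomena are out of scope.

All randomness derives from a single integer seed through named
`SeedSequence` substreams (reference group, patients, extrapolation,
transitions, missingness, imputation chains, ensemble repeats), so every
stage is independently reproducible.

## Validation problem sizes

Chosen to exercise the study's dimensions within desk-scale runtimes:

- Solver checks: 50 random problems, n <= 200, up to 20 groups of 1-3
  columns; KKT tolerance 1e-5; unpenalized fits compared to a Newton
  reference within 1e-4 per coefficient; tiny problems (<= 3 groups of <= 2
  columns) compared to dense derivative-free minimization of the identical
  objective within 1e-4.
- Parameter recovery: 10 replicate cohorts at full dimensions (86/86
  samples, 198 candidate features, 12 planted effects at d = 0.8), R = 25
  repeats each, with the symptom total score excluded so the individual
  planted features compete; the planted features' median selection fraction
  must beat the null features' 95th percentile in >= 8 of 10 cohorts.
- Extrapolation gap: 10 replicate runs at attenuation 0.5 (median training
  AUC must exceed median extrapolation AUC) and at attenuation 0 (median
  extrapolation AUC within [0.35, 0.65], i.e. chance).
- Preprocessing round-trip: recovered vs true log2 ratios correlate with
  r > 0.99 at noise SD 0.01; a constructed +10 SD sample is flagged by the
  PCA screen while a null matrix yields no flags.

## Limitations

- Training AUC is an apparent estimate, not cross-validated; with p >> n it
  is optimistic by construction, exactly as in the modelled study design.
- AICc treats the penalized fit's likelihood as the model's likelihood and
  counts features rather than parameters by default; both are conventions
  (alternatives are exposed via `k_mode` / `logl_mode`), not derived
  optima.
- The intercept-only fallback makes null-signal runs well-defined (AUC 0.5
  by tie handling) but means a returned model is not evidence of signal on
  its own; consult the selection fractions.
- The imputation model is MCAR-consistent; under informative missingness the
  pooled estimates would be biased.
- The ensemble repeats differ only in CV partition seeds; they quantify
  selection instability, not sampling variability of the cohort.
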