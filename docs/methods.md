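# Methods

## The modeling problem

Each patient contributes a vector of secreted-protein concentrations
(pg/mL) measured in ascites by multiplex bead-based immunoassay, and a
platinum-free interval (PFI) in days. The goal is a sparse linear model of
the transformed PFI on the transformed analyte concentrations, fitted per
treatment cohort (NACT — neoadjuvant chemotherapy; PDS — primary debulking
surgery), with model error always reported in days. The central
methodological idea is that in the small-n / high-p regime the
accuracy-optimal L1 penalty produces models whose selected features and
coefficients vary substantially across cross-validation folds; deliberately
*relaxing* the penalty until the cross-validated error reaches a clinically
tolerable budget yields a sparser model whose feature set is far more
reproducible.

## Preprocessing

Order of operations: detection filter → censoring imputation → log10 →
Yeo–Johnson → standardization.

1. **Detection filter.** An analyte is retained iff it is detected in at
   least 75% of patients. Above-range cells count as detected (they are
   measurable signal); only below-limit cells count against detection. The
   fraction test is inclusive (8/10 ≥ 0.75 retains; 7/10 removes).
2. **Imputation.** Below-limit cells become `0.5 × LOD × dilution`,
   above-range cells `2 × ULOQ × dilution`, detected cells pass through.
   Limits are stored on the assay scale and concentrations on the sample
   scale, hence the dilution factor. Imputation happens *before* log10 —
   the only order in which "half the detection limit" is a concentration.
   A literal 0 concentration with no flag is treated as below-limit; a true
   zero is an instrument artifact, and this keeps log10 defined.
3. **Yeo–Johnson.** The power parameter λ is fitted per column (and for
   PFI days) by maximizing the Gaussian profile log-likelihood including
   the Jacobian term, with bounded scalar search on λ ∈ [−5, 5] to absolute
   tolerance 1e-8. Bounds and tolerance are implementation choices: ±5
   covers any skew arising in data already on a log scale, and the tight
   tolerance makes results reproducible to the last digit.
4. **Standardization.** After the power transform each column (and the
   outcome) is scaled to zero mean / unit SD. The L1 penalty is
   scale-sensitive; standardization makes it act uniformly across analytes.

Transforms are fitted once on the full cohort. The analyte transforms do
not use the outcome, so they leak nothing; the PFI transform does see all
outcomes, which mildly flatters LOOCV error. A strict variant
(`experiments.strict_loocv_rmse`) refits the entire preprocessing inside
each training fold and projects the held-out patient through the fold's
transforms; it is the fully nested estimator and in our experiments differs
from the shared-transform estimate by far less than the seed-to-seed spread.

Inverting predictions to days uses the closed-form Yeo–Johnson inverse.
A prediction on the transformed scale can fall outside the transform's
range (e.g. beyond −1/λ for λ < 0); when *scoring* predictions the input is
clamped just inside the boundary, mapping to an extreme but finite day
value that correctly penalizes the model. The user-facing
`invert_transform` raises on out-of-range input unless clipping is
requested.

## Penalty tuning, relaxation, evaluation

`fit_lasso` minimizes `(1/2n)·RSS + α·‖w‖₁` with an unpenalized intercept
(coordinate descent, tolerance 1e-7). Any reported α is tied to this
scaling. Tests verify every fit against the KKT stationarity certificate
and closed-form oracles rather than trusting the solver.

`tune_alpha` evaluates LOOCV RMSE (in days, after inversion) at each of 201
log-uniformly spaced penalties from 1e-5 to 1e5 — log spacing because on
standardized data all the action is within a few decades of
α_max = max|xⱼᵀ(y−ȳ)|/n ≈ 1. Ties at the minimum break toward the largest
α (the sparser model). Each fold's whole path is computed in one
coordinate-descent sweep with the fold's data centered, which is what makes
100-replicate studies affordable; the path solution agrees with per-α fits
to solver tolerance. A `rmse_scale="transformed"` option scores the curve
on the transformed scale instead of days, since reporting conventions vary.

`relax_alpha` returns the largest grid penalty whose LOOCV RMSE stays
within the error budget (default 20 days — roughly the scale below which a
recurrence-date prediction stops being clinically meaningful). If no grid
point meets the budget the accuracy-optimal penalty is returned flagged
infeasible.

`nested_loocv_rmse` re-runs the whole tuning inside each outer fold; it is
the honest generalization-error estimate and, as expected, is almost always
at least as large as the non-nested tuned LOOCV RMSE.

`cross_predict` applies one cohort's model to another cohort's panel. The
target is pushed through the *source* cohort's fitted transforms; source
features missing from the target contribute 0 in standardized space (the
source-cohort mean — the least-informative default), and predictions are
inverted through the source PFI transform.

## Stability analysis

For the full-cohort model at a given penalty and its n LOOCV fold fits:
per feature, the mean and sample SD (ddof = 1) of the coefficient across
*all* folds — zeros included, since a fold that drops the feature is
evidence of instability — the percent coefficient of variation
%CV = SD/|mean|×100 (undefined when |mean| ≤ 1e-12), and the number of
folds with a nonzero coefficient. The cohort-level aggregate %CV averages
the per-feature %CV over features retained by the full model with a defined
%CV. `rank_features` orders by signed full-model coefficient (most
positive = longest-PFI association), ties alphabetically.

The %CV is written here as SD over |mean|; the convention sometimes appears
printed inverted, but only SD/mean makes a large SD relative to the mean
read as a *large* %CV.

## The synthetic cohort generator

Per analyte, natural-log concentration means are drawn uniformly from
[2, 8] (≈ 7–3000 pg/mL) and log-SDs from [0.9, 1.5], giving natural-scale
CVs of roughly 110–370% — matching panels where most detected analytes
exceed 100% CV. Detection limits sit at the 10th (lower) and 98th (upper)
log-normal quantiles, so ~10% of cells are left-censored and ~2%
right-censored per analyte; censoring flags use strict inequalities (a
value exactly at a limit is detectable). The panel exposes only flags and
limits for censored cells; pre-censoring truth lives on the `GroundTruth`
sidecar.

The outcome is linear on the latent standardized-log scale:
`latent = Z β + ε`, with `n_informative` coefficients of equal magnitude
and alternating sign and ε ~ N(0, noise_sd²), and
`PFI = center + day_scale · latent`. The default day scale is
0.15 × center per latent SD: at the default shape (5 informative features,
300-day center) one informative feature's unique contribution is then worth
≈ 20 days of RMSE — the error budget marks exactly the boundary between
shedding redundant features and destroying signal, while remaining well
below the ≈ 30-day error of predicting the cohort-mean PFI. A configuration
whose latent spread would produce non-positive days raises rather than
truncates. One RNG stream per cohort, seeded from the config; identical
configs are bit-identical.

Default cohort shape: 25 patients × 57 analytes, 5 informative,
β = 1.0 ≫ noise_sd = 0.1 — the strong-signal regime in which an optimal
model reaches sub-two-week cross-validated error.

**What the generator does not emulate:** plate/batch effects, technical
replicates, the logistic standard curve, analyte–analyte correlation blocks
(real protease/cytokine families co-vary; here non-informative analytes are
independent), and treatment-cohort differences beyond the PFI center.
Passing recovery tests therefore show that the pipeline's machinery is
correct and that the stability-tuning effect is real in this regime — not
that any particular clinical panel will reach these error levels.

## Observed behavior at the study shape

Computed by the test suite and `scripts/acceptance.py`, not asserted as
constants: at 25 × 57 with 5 informative analytes, the tuned model's LOOCV
error is typically 7–16 days against a ~30-day null; budget relaxation
roughly halves both the support size and the aggregate %CV (medians across
replicates), which is the package's central property. Recovery of *all*
informative features is frequent but not guaranteed: in a minority of
replicates a chance-heavily-censored informative analyte (25–32% of values
imputed, occasionally failing the 75% detection filter outright — at
n = 25 the binomial tail makes this inevitable) weakens the realized signal
enough that one true feature is dropped, and fold-wise inclusion of every
informative feature in every fold is less frequent still. An oracle OLS fit
on the true support already has a ~10-day LOOCV floor from imputation
corruption at this sample size, so these limits are properties of the
regime, not of the implementation. At the 14-patient PDS shape the 20-day
budget is usually infeasible — a sample-size statement worth taking
seriously when a small cohort appears to achieve single-digit error.

## Numerical conventions

- Lasso convergence 1e-7; KKT certificates checked at 1e-6.
- Transform round-trips hold to 1e-8 over the λ range fitted in practice;
  far outside it (|λ| ≳ 2 with wide-range data) double precision cannot
  round-trip the power transform's dynamic range.
- LOOCV folds are patients in order; there is no randomness anywhere in
  fitting, tuning, or evaluation, so fixed inputs give bit-identical
  curves.
- Degenerate inputs raise: constant vectors for λ fitting, n < 3 for LOOCV,
  n < 4 for nested LOOCV, all-analytes-removed filtering (with the removal
  table attached), zero-variance patient profiles in the similarity matrix.
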