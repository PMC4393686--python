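# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `twinace`.

## The ACE model and its likelihood

A phenotype measured on twin pairs is modeled as y = μ + a·A + c·C + e·E
with latent standard-normal factors: A (additive genetic) correlated 1
across MZ twins and 0.5 across DZ twins, C (common environment) shared
within a pair, E (unique environment, including measurement error)
independent. Path coefficients are unconstrained in sign; reported
components are the squared paths standardized by the total variance, so
a² + c² + e² = 1 by construction. The bivariate correlated-factors model
gives each trait its own paths and correlates the like factors across
traits (r_a, r_c, r_e). The implied per-pair covariance matrices are in
`twinace.ace.expected_cov_univariate` / `expected_cov_bivariate`; the
cross-twin cross-trait entry α·a_X a_Y r_a + c_X c_Y r_c (α = 1 MZ, ½ DZ)
is what separates genetic from environmental sources of trait covariation.

**FIML.** The objective is the full-information −2 log-likelihood: each
pair contributes the multivariate-normal density of its observed subvector
against the matching rows/columns of its zygosity's implied covariance.
Pairs are grouped by missingness pattern and the likelihood is evaluated
from per-pattern sufficient statistics (count, mean, scatter), so one
evaluation costs O(#patterns), not O(#pairs); on complete data this reduces
exactly to the classical sufficient-statistic form (tested against that
closed form).

**Saturated reference.** Means and covariances free per zygosity group,
Cholesky-parameterized (univariate: 10 free parameters; bivariate: 28).
ACE-family models equate means across twins and zygosity (univariate ACE: 4
free parameters, hence the Δdf of 6 against the saturated model; bivariate
full ACE: 11, Δdf 17; dropping one factor correlation: Δdf 18).

**Model comparison.** LRT = −2LL(model) − −2LL(saturated) with p from
χ²(Δdf); BIC follows the Mx convention −2LL − df·ln(N) with N the number of
contributing pairs. The absolute BIC depends on the N convention, which
differs across software; only BIC *differences* and orderings are
meaningful, and only those are asserted anywhere. The selection rule is:
lowest BIC among models not rejected by the LRT at α = .05, ties broken
toward fewer parameters.

**Optimization.** Quasi-Newton (L-BFGS-B) on the free-parameter vector with
`ftol` 1e-8; factor correlations pass through tanh to stay inside (−1, 1);
non-PD covariances get a large finite penalty so line searches recover.
Path models use 8 seeded random multi-starts around a Falconer-informed
start (sample double-entry ICCs pushed through a² = 2(r_MZ − r_DZ),
c² = 2r_DZ − r_MZ, clipped to the interior); the saturated model starts at
pairwise-complete sample moments. Boundary solutions (a component within
1e-4 of 0 or 1, |r| > .999) are flagged, not errored.

**Profile confidence intervals.** The 95% bound for a reported quantity
(a standardized component, a factor correlation, a bivariate share) is
where the −2LL, re-minimized over all other parameters subject to the
quantity being fixed (SLSQP equality constraint), exceeds the optimum by
χ²₁(.95) = 3.841; the crossing is located by expanding bracket plus Brent
root-finding (xtol 1e-4). Bounds are clipped to the parameter domain and
reported at the edge when the likelihood never rises enough inside it —
this is how entries like a CI of (0.85, 1.00) on a bivariate share arise.
Against a delta-method oracle at large n the profile interval agrees to a
few percent (tested); near boundaries the profile interval is the one that
remains valid.

**Falconer closed forms** serve as independent oracles, not as the
estimator: on complete, balanced, moment-matched data the ACE model is
just-identified and the FIML solution must equal the Falconer arithmetic;
the test suite enforces this to 1e-4.

## The synthetic-data generator

The generator defines the conditions under which everything is tested. It
draws pair tables directly from the ACE generative model: C and E as
independent normals, and the DZ additive factor split as
A = √0.5·A_family + √0.5·A_individual, which gives an exact 0.5 cross-twin
additive correlation without rejection sampling (MZ twins share A_family
outright). Bivariate factors use the Kronecker structure (twin-sharing
pattern ⊗ trait-correlation matrix) drawn via Cholesky. Sample moments
therefore converge to the `expected_cov_*` matrices, which is asserted as a
cross-module oracle test.

Defaults and why:

- **Pair counts** 1719/1551 (MZ/DZ) for paranoia-like runs and 1418/1258
  for bullying-like runs — the cohort sizes the modeled study analyzed, so
  recovery studies run at realistic power.
- **Generating solutions** mirror the published best fits: bullying-like
  trait .35/.26/.39 (ACE), paranoia-like trait .52/–/.48 (AE; full-ACE
  variant .45/.07/.48), factor correlations r_a = .55, r_e = .04 with r_c
  dropped.
- **Sex/age effects**: linear shifts of 0.1 SD per sex contrast and
  0.05 SD per year (ages uniform on 15.8–16.8). The study these sizes
  emulate reports sex/zygosity explaining ≤6% of variance, so the shifts
  are deliberately small but nonzero — enough that the residualization
  stage has real signal to remove, removed exactly by OLS.
- **Missingness**: MCAR, element-wise; 0 by default (unit tests and
  recovery studies), 0.15 for pipeline fixtures. One random element of any
  fully-blanked pair is restored so no pair is entirely missing.
  Informative missingness is out of scope.
- **Raw scales**: `apply_raw_scale` pushes latent values through the normal
  CDF and a power, onto a bounded integer range (default 0–32), producing
  the positive skew typical of victimization/experience questionnaires so
  the square-root-transform path is exercised on realistic input. Realism
  is calibrated only to range/skew shape, not to any item-level structure.
- **Item fixtures**: `simulate_items` draws parallel items with common
  inter-item correlation ρ, for which Cronbach's α has the Spearman–Brown
  closed form kρ/(1+(k−1)ρ) used as the oracle.

What the generator does **not** emulate: assortative mating, sibling
interaction or rater contrast, selection/ascertainment, informative
attrition, sex-limitation of variance components, and ordinal item
measurement of the analysis traits (the latent scale is continuous).
Passing recovery tests therefore show the estimator is correct under the
stated generative model at realistic n — not that real cohort data meet
those assumptions.

## Preprocessing choices

- **Order**: square-root transform *before* sex/age residualization.
  Residuals can be negative, so transforming residuals is ill-defined; this
  is the only coherent ordering of the two stated steps.
- **Residualization** fits one OLS per trait over all persons (both twins
  stacked) and returns residuals standardized to mean 0, variance 1
  (ddof = 1). Pair clustering affects standard errors, not residuals, and
  the downstream twin model consumes only the residuals. Constant
  predictors are dropped with a logged warning.
- **Scale totals** are missing if any item is missing (conservative
  default; prorated mean imputation available). Sex is coded male = 1,
  female = 0; zygosity-specific means are not removed (they surface in the
  descriptives ANOVA instead).
- **One-random-member selection** is uniform per family and seeded; if the
  selected twin is missing the analysis trait the pair is dropped, not
  swapped — swapping would bias the sample toward complete pairs.

## Descriptive conventions

Double-entry Pearson correlations for ICC and CTCT (each pair enters in
both orders, making the estimate invariant to the arbitrary twin labels);
Fisher-z CIs computed on an effective n equal to the number of pairs, since
double entry duplicates rows and the naive n would be anti-conservative.
Kurtosis is non-excess (Gaussian = 3). The sex × zygosity ANOVA uses
type-II sums of squares on one random member per pair. The gate for
bivariate modeling is a strict r > threshold (default .25) on
one-random-member phenotypic correlations.

A consequence worth knowing: the default bivariate generating solution
implies a phenotypic correlation of √(.35·.52)·.55 + √(.39·.48)·.04 ≈ .252,
which sits essentially on the .25 gate; with one-random-member sampling
noise (SE ≈ .02 at these n) the gate decision is seed-dependent by design.
Tests therefore assert the gate *contract* (pass ⇔ r > threshold) rather
than a particular draw's outcome. Similarly, model selection on cohorts
drawn at that solution chooses the dropped-r_c model in most but not all
replicates (the dropped-C bivariate AE model occasionally survives the LRT
by chance); the modal choice is what is asserted.

## Pipeline

Stages run in a fixed order (load/generate → preprocess → descriptives →
gate → univariate suite → bivariate suite → covariate-adjusted refits →
report), every block carries the n it used, and the JSON report is written
atomically with sorted keys so identical configs yield byte-identical
reports. Covariate adjustment residualizes both analysis traits on the
covariate(s) per person, re-standardizes, and refits the bivariate suite —
the simplest mechanism consistent with leaving the model structure
unchanged; modeling covariates inside the SEM means model would be the
alternative and is not implemented. If no outcome passes the gate the
bivariate stage is skipped and the report says so. CLI exit codes: 0
success, 2 validation failure, 3 non-convergence of a required fit.

## Problem sizes in the shipped studies

Recovery studies in the test suite and acceptance script use 30 replicates
per target at the full cohort sizes above (mean-estimate Monte-Carlo SE
≈ 0.007 on variance shares, ≈ 0.012 on r_a); the profile-CI coverage study
uses 100 replicates; selection-rule and coverage spot checks use 6 and 100
seeds respectively. These sizes make the Monte-Carlo error comfortably
smaller than the ±0.03 recovery tolerance while keeping the full suite in
the low minutes on a single CPU.

## Known limitations

- No ADE, sex-limitation, ordinal/threshold-liability, >2-trait Cholesky,
  or direction-of-causation models.
- FIML assumes multivariate normality of the (transformed, residualized)
  phenotypes and MCAR/MAR missingness.
- Profile CIs for saturated-model parameters are not exposed (only
  ACE-family quantities are reportable).
- With a variance share truly at 0 (e.g., c² in an AE-generated trait), its
  estimate is boundary-censored; mean recovered shares show the expected
  small upward bias at 0 and the paired component a correspondingly small
  downward bias (≈.01–.02 at the shipped n). Together with the ratio form
  of the genetic correlation this lifts the mean recovered r_a by ≈.02–.03
  in the bivariate study at study-scale n (the estimator is consistent: at
  60 000 pairs the bias vanishes), consistent with the upward-skewed CI
  such solutions print. This is a property of boundary MLEs, not an
  implementation defect.
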