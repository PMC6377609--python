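# Methods

## Structural model and arms

The central model is one compartment with zero-order absorption and
first-order elimination, `dA/dt = ka − ke·A`, with `A` the total paracetamol
amount in one larva (pmole). Zero-order absorption is an amount-rate
(pmole/min), not concentration-dependent: during waterborne treatment the
medium concentration (1 mM) is effectively constant, so uptake across skin,
gills and (from 4 dpf) gut is a constant flux. Two experimental arms share
the time origin t = 0 at treatment start:

* **constant** — continuous treatment, sampled in [0, 180] min; closed form
  `A(t) = (ka/ke)(1 − e^{−ke t})`.
* **washout** — treatment for `T_d = 60` min, then drug-free medium, sampled
  in [60, 240] min; absorption switches off exactly at `T_d` and
  `A(t) = A(T_d) e^{−ke (t−T_d)}`. The prediction is continuous at the
  junction.

Candidate variants retained for model comparison: a peripheral compartment
(rates `k12`, `k21`; the *sum* of compartment amounts is fitted to the
observed totals, elimination from the central compartment only) and
Michaelis–Menten elimination (`vmax`, `km`). Both are integrated with LSODA
at rtol 1e−8 / atol 1e−10, split at the absorption discontinuity, so solver
error is negligible against model differences. Since these variants are
rejected by selection and no reference values exist for their parameters,
their defaults are testing-only choices, and covariates on the
Michaelis–Menten elimination parameters are not supported.

## Age covariates

Larval age in integer days post fertilisation (3, 4, 5 dpf; no fractional
interpolation) modifies a parameter `P` through one of:

* linear: `P = P_base (1 + slope (age − ref))`
* power: `P = P_base (1 + slope)^{age − ref}`
* discrete: either a single step factor above the reference age
  (`P_base (1 + factor)` for age > ref — the selected form for ka) or one
  multiplier per age level.

Reference age is 3 dpf. The selected model combines the discrete ka step
(absorption roughly doubles when the gastro-intestinal tract opens at 4 dpf,
with no further increase at 5 dpf) with a power ke relationship
(~17.5%/day, reflecting continuous growth and maturation of eliminating
organs).

## Likelihood and estimation

One pooled sample (5 larvae lysed together) yields a single observation, so
inter-individual variability cannot be separated from residual error and the
mixed-effects formulation degenerates to fixed-effects maximum likelihood
(extended least squares) with heteroscedastic Gaussian error:

    v_i = pred_i² σ²_prop + σ²_add        (terms per error-model form)
    OFV = −2 log L = Σ_i [ ln(2π v_i) + (obs_i − pred_i)² / v_i ]

Numerical choices:

* Rates, variances, `vmax`/`km`/`k12`/`k21` and per-age multipliers are
  log-transformed for optimisation; step/slope coefficients use log1p
  (bounded below at −1).
* Multi-start local search: Nelder–Mead (fatol 1e−8) followed by a BFGS
  polish, 10 starts by default, the first from data-driven initials (plateau
  amount anchors ka/ke), the rest jittered on the log scale with sd 0.4
  (seeded). Best objective wins.
* Standard errors: central finite-difference Hessian of the OFV on the
  estimation scale (relative step 1e−4), covariance `2 H⁻¹`,
  delta-transformed to the natural scale; RSE% = 100·SE/|estimate|. A
  non-positive-definite Hessian (typically a variance collapsed to its zero
  boundary on small datasets) withholds the RSEs and flags the fit.
* LRT: statistic `OFV_reduced − OFV_full` against χ² with df = added
  parameters; a numerically negative statistic is clamped to zero with a
  warning. Ties at the α boundary go to the reduced model (parsimony).
* Selection ladder (structure → covariates) accepts an extension only with
  LRT p < 0.01, convergence, and all *structural* RSEs < 50%. The precision
  gate deliberately excludes the error variances: the additive variance is
  weakly identified whenever proportional error dominates (its reference
  RSE is 48%, essentially at the gate), and letting its replicate-to-replicate
  noise veto a decisively better structural model would make selection
  erratic. The "3 significant digits" minimisation criterion of the original
  workflow is operationalised as the optimizer's OFV tolerance.

## Diagnostics

With no random effects, conditional weighted residuals coincide with
variance-weighted residuals, `wres_i = (obs_i − pred_i)/√v_i`; outputs are
labelled "weighted residuals (CWRES-equivalent)". A correctly specified fit
gives wres with mean ≈ 0, variance ≈ 1 and no trend over time or predicted
amount; age-stratified wres means expose missing age covariates. Tables are
the primary artifact; plots are a thin optional layer over them.

## Synthetic data generator

The generator emulates the study design: ages 3/4/5 dpf; constant-treatment
arm sampled on 8 times in [10, 180] min (geometric spacing, denser early
where the uptake curve bends); washout arm on 8 times in [75, 240] min after
60 min of treatment; 3 replicates per point; pools of 5 larvae. The exact
published sampling grid is not enumerated ("at least in triplicate"), so the
default is a faithful reconstruction of the windows and density, not of the
precise times. Noise is applied at the pooled-sample level — one
multiplicative and one additive Gaussian draw per sample,
`obs = pred (1 + ε₁) + ε₂` — matching the likelihood's variance formula;
pool size is metadata, never a variance divisor. Negative draws are truncated
at zero and counted (< 1% of samples at the reference parameter values).
Same config and seed give a byte-identical dataset.

What the generator does **not** emulate: medium-concentration depletion,
inter-larva parameter variability, below-quantification-limit censoring, or
assay calibration drift. Passing recovery tests therefore demonstrate that
the estimation machinery is unbiased and calibrated *under the assumed error
model*, not that real larval data are free of those complications.

## Allometric comparison

Larval clearance is `ke × total larval volume × 60` (nL/h), with reference
volumes 253/263/300 nL at 3/4/5 dpf and bodyweight = volume × 0.997 g/mL —
this assumes paracetamol distributes homogeneously over the whole larva.
The interspecies regression is ordinary least squares of log10(CL) on
log10(BW) over *mature* records only; the 95% band is the mean-prediction
(confidence) interval of the regression line, not the prediction interval.
Log base 10 is a reporting convention; any base is internally consistent.
Species tables declare their clearance units in a header comment and are
harmonised to nL/h on read. A larva's placement is reported as
100 × CL / (lower band bound at its bodyweight); larval bodyweights sit far
below the fitted range, so the bound is an extrapolation and flagged as such.
The published species table is external input and is not bundled; ordering
properties (larvae below the mature band, fraction rising with age) are
checked on synthetic tables of realistic scale.

## Problem sizes used in validation

Replicate recovery experiments use 20 simulate-and-refit replicates of the
full design (144 observations each); LRT calibration uses 500 null datasets
of a reduced two-age design (48 observations) with single-start fits, enough
for a binomial check of the 1% level; allometric band coverage uses 300
replicated 10-species tables. These sizes give stable medians and tight
binomial bands while keeping the whole validation suite around a minute.

## Known limitations

* Fixed-effects ML only; no random effects, shrinkage or Bayesian machinery.
* The OFV's additive constant follows the exact Gaussian likelihood and need
  not match other software's reported objective values; comparisons are
  internal.
* Medium depletion, metabolite kinetics and physiologically based
  distribution are out of scope.
* Ages are discrete levels; the covariate functions are not meant for
  extrapolation outside 3–5 dpf.
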