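# Methods

`fieldkrige` identifies, estimates and removes the effects of spatially
distributed soil properties on field-trial phenotypes and microbiome counts.
This note records the models, their assumptions, the defaults that matter,
the numerical choices, and what the synthetic studies do and do not
demonstrate.

## Design residualization

Spatial modelling assumes stationarity: a location-invariant mean and
covariance. A designed trial violates this through its treatment structure,
so every plot-level variable is first residualized against the
full-factorial fixed-effects model

    value = intercept + Treatment + Genotype + Treatment:Genotype + error

by OLS, and all spatial modelling operates on the residuals. Sum-to-zero
contrasts are used throughout the package so that the later type-III tests
are well defined. Rank-deficient designs (a genotype unobserved under one
treatment among the sampled plots) are handled by pivoted least squares
with a warning; residuals are defined only at observed plots.

A consequence worth knowing: with `q` design parameters fitted on `n`
observed plots, residualization removes roughly a fraction `q/n` of the
variance of *any* field, signal included. At a 25% soil-sampling lattice on
the default study (96 sampled plots, 48 parameters) about half the latent
spatial signal is absorbed; the removed component is spatially rough and is
largely soaked up by the fitted nugget during variogram estimation, but the
reconstruction ceiling for downstream adjustment is materially lowered.
This is a property of the procedure itself, not of this implementation.

## Semivariograms and fitting

Six families are implemented (nugget-only, exponential, spherical,
gaussian, Matern, Stein's Matern), parameterized by nugget n (value
units^2), partial sill s (units^2) and range r (plot units); the Matern
forms add a smoothness kappa, held at 0.5 by default with an optional
profile over {0.3, 0.5, 1, 2, 5} (continuous optimisation of kappa on a
dozen lags is ill-conditioned). The range follows the asymptotic
convention: exponential and Gaussian approach their sill (effective range
~3r and ~sqrt(3) r); spherical reaches it at r exactly.
`VariogramModel.effective_range` reports the derived value for comparison
with software using other conventions.

The empirical variogram is the Matheron estimator on equal-width lag bins
over (0, cutoff], cutoff defaulting to one third of the maximum inter-plot
distance and 15 lags; empty bins are dropped and bins are centred at their
mean pair distance. Fitting is weighted least squares with weights
N_h / h^2 (pair count over squared lag; N_h and uniform selectable),
box-constrained nonnegative, started from ranges {cutoff/10, cutoff/3,
cutoff} with the sill split evenly between nugget and partial sill. Model
selection takes the minimum of the *weighted* SSE — the same criterion the
fit minimised — with exact ties resolved by a fixed family order; the
unweighted SSE is stored alongside for tabulation. No complexity penalty is
applied (all families have three free parameters).

Recovery limits. On a single 16 x 24 realization of an exponential field
with range 4, parameter recovery is dominated by realization variance, not
estimator noise: the sample variance of such a field fluctuates with
sd/mean ~ 0.22, and fitting the range alone with nugget and sill fixed at
truth still leaves ~20% median relative error. Median relative errors of
~20-30% for sill and range, and a 50-65% rate of selecting the generating
family among six candidates, are the expected performance at this domain
size — larger fields or multiple realizations are needed for tighter
recovery.

## Testing for spatial structure

A variable is screened by REML likelihood ratio: an intercept-only Gaussian
model with iid errors against the same model with each of five correlation
structures (exponential, gaussian, spherical, linear, rational quadratic),
each with a single range parameter and no nugget, so the LRT is referred to
chi-square with 1 df. The iid model lies on the boundary of each
alternative, which makes the plain chi-square reference conservative (null
flag rates below nominal); no boundary-mixture correction is applied. A
variable is flagged spatial when any structure reaches p < 0.05; the five
tests are strongly dependent, so the union keeps its size close to nominal.

## Ordinary kriging

Predictions solve the standard augmented system with the weight-sum
constraint; all observations are used for every target (global
neighbourhood — the fields here have at most a few hundred plots). Ordinary
kriging is an exact interpolator: a target coinciding with an observation
returns that observation, with zero kriging variance when the nugget is
zero. Duplicate coordinates are permitted when the nugget is positive and
rejected (with the offending pairs named) when it is zero. Leave-one-out
cross-validation holds the variogram fixed across folds by default
(refitting per fold is selectable); standardized errors
(prediction - observation) / sqrt(kriging variance) should resemble a
standard normal sample when the model is well specified.

## Principal-component regression

Residualized soil properties are centred and scaled to unit variance before
PCA (the panel mixes ppm, mmho/cm, percent and pH scales; unscaled PCA
would be dominated by calcium). Component signs are fixed by making each
component's largest-magnitude loading positive. Components with at least
10% explained variance are kept, at most (number of blocks - 3) of them, so
the design remains estimable. Each kept score surface is kriged like any
other variable (all six families, minimum-SSE selection).

Continuous traits are adjusted with

    trait = alpha + sum_j beta_j PCj_krig + Z + eps

where Z is a zero-mean Gaussian process with exponential correlation
*nested within blocks* (plots in different blocks independent) plus a
nugget fraction, fitted by REML with sigma^2 profiled out and (range,
nugget fraction) optimised by a coarse grid plus Nelder-Mead. The adjusted
trait subtracts only the PC terms, keeping alpha so values stay on the
original scale; the reported change interval is the empirical 2.5/97.5
percentile band of the changes, not a model-based CI. On failure of the
spatial fit the model falls back to fixed effects with a warning.

Counts are adjusted per OTU and compartment with a zero-inflated
negative-binomial regression (statsmodels), log-mean = intercept + PC terms
+ block fixed effects, intercept-only inflation, per-OTU dispersion. OTUs
with fewer than 10 positive counts or non-converged fits are dropped and
tallied in a retention report. Adjusted counts divide the observation by
exp(per-sample PC linear predictor), so zeros are preserved and the
adjustment direction follows the sign of the predictor; a literal-constant
variant (dividing all samples by exp(b1 + b2 + b3)) is available behind a
flag for comparison but rescales without reordering.

## Association testing

Multivariate responses use Canberra distances (0/0 feature pairs contribute
nothing), a principal-coordinate embedding with negative-eigenvalue axes
dropped (summed negative inertia reported), and a constrained permutation
ANOVA: embedding and test columns are residualized on the condition terms,
the pseudo-F compares the test term's sum of squares to the residual, and
significance comes from freely permuting the reduced-model residual rows
with Freedman-Lane re-residualization (the permuted denominator excludes
what the condition space reabsorbs). p = (1 + #{F_perm >= F_obs}) /
(1 + n_perm); with 999 permutations the attainable floor is 0.001. The
scheme is approximately exact; at n ~ 48 with a dozen condition df the null
rejection rate at the 0.05 level fluctuates in roughly the 3-8% band across
simulation seeds. A within-group restricted permutation is available.

Univariate traits use the full design plus the kriged property with the
same spatial-in-block error structure, tested by a single-df type-III Wald
chi-square on the property coefficient (valid under the sum-to-zero
coding). Design partial R^2 is the drop in residual sum of squares when a
term is added last to a model containing all other design terms, divided by
the total sum of squares; for distance-matrix responses the same
computation runs on the PCoA embedding traces.

## Change-point screening

The hinge model y = mu + beta (x - e)_+ is profiled over candidate
thresholds at the distinct observed abundances, excluding the three
smallest and largest so both segments stay estimable; per candidate the
two remaining parameters are closed-form OLS, and the minimal-RSS
candidate wins (ties to the smallest threshold). The permutation p-value
uses the profile RSS reduction — a likelihood-ratio-type statistic — rather
than the fitted slope: under threshold selection the null slope
distribution is heavy-tailed (candidates near the edge have few supporting
points), which destroys power, while the RSS statistic respects the
selection. Permuting y against x breaks the pairing identically to
permuting x and lets the per-candidate design sums be reused, making the
999-permutation screen cheap. Screens across OTUs are corrected by
Benjamini-Hochberg; note the floor: with m OTUs and k true signals all at
the permutation floor 1/(n_perm+1), the adjusted value is m/(k (n_perm+1)),
so 199 permutations cannot reach FDR < 0.05 at m/k = 10 — screens default
to 999 permutations.

## Synthetic studies

The generator emulates the reference design: 24 genotypes x 2 watering
treatments x 8 blocks on a 16 x 24 grid; blocks are column bands, each
split into two whole-plots (top/bottom rows) receiving the treatments in
random order, genotypes randomized within whole-plots. Soil properties are
linear mixes of three latent exponential GRFs (nugget 0.1, partial sill
1.0, range 4 by default) grouped to mimic the cation / salinity-pH /
nutrient correlation blocks of real panels, shifted to a positive centre
with iid measurement noise (sd 0.3) on top. Soil sampling defaults to a
regular 1-in-2 lattice (~25% of plots), configurable; phenotypes add
genotype (sd 1), treatment (-2 for water stress), interaction (sd 0.3),
a soil term (coefficients (1.0, 0.5, 0) on the standardized latent
gradients) and unit noise around an intercept of 100. OTU counts are
zero-inflated negative binomial (inflation 0.2, dispersion 2) with log-mean
baselines uniform on (3, 6) and per-OTU latent-gradient coefficients. All
randomness flows from one seed through named SeedSequence children in the
fixed order (layout, latent, soil, phenotype, otu).

What the generator does not emulate: temporal drift in soil properties,
anisotropy, read-level sequencing noise, compositionality constraints, and
taxon-taxon interactions. Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the stated model, not
robustness to those real-data features.

## Problem sizes in the test and acceptance runs

Chosen to keep the default suite and the acceptance script at desk scale:
variogram recovery 50 realizations of the 16 x 24 grid; LOOCV calibration
20 x 200 plots; LRT size/power 200 null + 100 alternative simulations on a
10 x 10 grid; PERMANOVA size 200 simulations x 199 permutations at n = 48;
ZINB recovery one 384-plot field, one compartment, 100 OTUs with planted
coefficients (0.8, -0.5, 0); end-to-end denoising one fully-soil-sampled
field; hinge screen 20 cohorts of 100 samples x 100 OTUs (10 planted) at
999 permutations. The end-to-end denoising check uses a fully measured soil
panel deliberately: it isolates the adjustment machinery from the sampling
sparsity ceiling described under "Design residualization".

## Known limitations

- The spatial GLS estimates a single range and nugget fraction per fit; no
  anisotropy, no universal kriging, no co-kriging.
- The ZINB uses fixed block effects rather than the nested spatial random
  effect of the continuous-trait model; with few blocks and many samples
  per block the PC coefficients are insensitive to this, but small-block
  designs may differ.
- Exact reproduction of published per-property tables requires the deposited
  field data; the package's validation is parameter-recovery and
  calibration on synthetic studies.
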