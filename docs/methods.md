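# Methods

## Model

Biomass follows the logistic growth law

    dX/dt = mu_max (1 − X/Xmax) X,

with initial biomass `X0` (g/L or OD-equivalent), carrying capacity `Xmax`
(same units) and maximum specific growth rate `mu_max` (h⁻¹). The closed
form is evaluated as `Xmax / (1 + ((Xmax−X0)/X0) e^{−mu_max t})`, which is
algebraically identical to the usual textbook expression but never
overflows at large `t`.

Product (exopolysaccharide) formation follows the Luedeking–Piret rate law

    dP/dt = alpha·X + beta·dX/dt,

where `beta·dX/dt` is the growth-associated synthesis rate (`beta` in g
product per g biomass) and `alpha·X` the non-growth-associated one (`alpha`
in h⁻¹). Integrating along the logistic trajectory gives

    P(t) = P0 + beta (X(t) − X0) + alpha (Xmax/mu_max) ln D(t),
    D(t) = 1 − (X0/Xmax)(1 − e^{mu_max t}),

with `ln D` computed as `mu_max t + log1p(c e^{−mu_max t}) − log1p(c)`,
`c = (Xmax−X0)/X0`, to avoid overflow.

**Coefficient-labeling caveat.** A frequently reproduced printed variant of
the integrated form attaches the coefficient of `(X − X0)` to the symbol α
and that of the log term to β. That variant is the integral of
`dP/dt = alpha·dX/dt + beta·X`, i.e. the same two-parameter family with the
coefficient roles exchanged relative to the rate law above. This package
follows the rate-law convention throughout (alpha on `X`, beta on `dX/dt`,
matching the verbal growth-associated/non-growth-associated definitions);
a regression test pins the fact that swapping alpha and beta reproduces the
printed variant term for term. Users comparing coefficients across sources
should check which convention a given table uses.

The specific production rate is

    q_P(t) = (dP/dt)/X = alpha + beta·mu_max (1 − X(t)/Xmax),

non-increasing in time whenever both coefficients are non-negative, so its
maximum `q_P,max` is the value at t = 0. If a fitted coefficient is
negative, monotonicity is not guaranteed; `max_specific_production_rate`
then maximizes over a dense grid (step 0.01 h on [0, 120] h) and warns.

## Two-stage estimation

Stage 1 fits (X0, Xmax, mu_max) to pooled biomass observations by nonlinear
least squares (scipy `least_squares`, trust-region reflective, bounds > 0,
`ftol = xtol = gtol = 1e−10`, at most 10 000 evaluations). The carrying
capacity is parameterized as `X0 + dX` with `dX > 0`, so `Xmax > X0` holds
by construction. Stage 2 fits (P0, alpha, beta) to product observations
with the stage-1 growth parameters held fixed; `P0 >= 0`, alpha and beta
unbounded (negative estimates are retained and flagged, never clipped).
Sequential fitting is the default because the biomass curve is identified
on its own and fixing it makes the product fit a well-conditioned
three-parameter problem; a joint six-parameter fit (residual blocks scaled
by each signal's standard deviation) is available as `fit_joint`.

Starting values are deterministic and data-driven: X0 from the earliest
observations, Xmax as 1.05× the observed maximum, mu_max as the slope of
log-biomass over the first three scheduled times; P0 from the earliest
product observation, alpha and beta from ordinary least squares on the
finite-difference linearization of the rate law. Five jittered restarts
(lognormal factors, fixed sub-seeds) guard against local minima; the
lowest-cost successful solution is returned. Replicates are pooled as
independent observations by default; `average_replicates=True` averages per
time point first.

Goodness of fit is the coefficient of determination R² = 1 − SS_res/SS_tot
about the observed mean. (Bioprocess papers sometimes call this a
correlation coefficient; the determination coefficient is the standard
fit-quality meaning and is what is computed.)

A case-resampling bootstrap (`bootstrap_ci`) resamples observation rows
with replacement, refits both stages per resample (single-start inside the
loop for speed) and reports percentile intervals, default level 0.95, with
the fraction of failed resamples. In a 200-study Monte-Carlo experiment at
the default study conditions the 95% interval for mu_max covers the truth
about 87% of the time — the usual mild undercoverage of percentile
intervals at n = 24 observations.

Late-time biomass decline (observed in some hot cultures) cannot be
represented by a monotone logistic. The fitter flags systematic one-signed
residuals over the last quarter of the time range and offers
`truncate_at_peak=True`, which drops observations after the time of maximum
mean biomass before fitting. The generator's `decay_after`/`decay_rate`
contamination mode exists to exercise exactly this path.

## Synthetic study conditions

`default_scenarios()` encodes the emulated experiment: sampling at
6/12/24/36/48/72/96/120 h, three replicates, multiplicative Gaussian noise
with CV 3% (truncated at zero). Growth rates carry the published values
mu_max = 0.33528 h⁻¹ (30 °C heat stress) and 0.13286 h⁻¹ (15 °C normal
culture). The remaining parameters are not published and are package
defaults chosen once for well-conditioned recovery experiments: X0 = 0.1,
Xmax = 6 (heat) and 10 (normal; the cold culture grows further, matching
the qualitative pattern of the source experiment), P0 = 0.05 g/L,
beta = 0.5. The heat-stress alpha is solved from
`q_P,max = alpha + beta·mu_max (1 − X0/Xmax)` so that the construction
reproduces the published q_P,max = 0.87670 h⁻¹ exactly; the normal-condition
alpha defaults to 0.05 h⁻¹ (lower non-growth-associated production at the
optimal temperature). The experimental noise magnitude is not published
(figures show error bars only); 3% CV is the package's assumption and is a
config surface.

Per-condition randomness derives from a single study seed via a documented
stable hash (CRC-32 of the condition label mixed into a numpy
`SeedSequence`), so adding a scenario never perturbs existing draws.

What the generator does **not** emulate: the late biomass decline of hot
cultures (unless the contamination mode is switched on), assay-level raw
absorbances for the time courses, replicate-level batch effects, or
heteroscedasticity beyond the constant-CV structure. Passing recovery tests
therefore show that the estimator is unbiased and well-conditioned under
the stated design, not that real cultures obey the logistic model.

## Classification of growth association

`classify_association` labels production as mixed / growth_associated /
non_growth_associated / none according to whether |alpha| and |beta| exceed
a tolerance, default 1e−6 in each coefficient's own units — appropriate for
exact or theoretical parameter values. For *fitted* coefficients the
relevant scale is estimation noise: at the default study conditions a
truly-zero coefficient estimates below ~1e−3 in magnitude, while
biologically meaningful coefficients here are ≥ 0.05. The pipeline
therefore classifies fitted estimates with
`FITTED_CLASSIFICATION_TOL = 0.01`, an order of magnitude above the noise
floor and below the smallest real coefficient. With a 1e−6 tolerance every
noisy fit would be labeled "mixed" regardless of truth.

Identifiability note: in the heat-stress scenario the alpha term dominates
cumulative product (~99%), so beta is weakly identified there (its
estimate can even go negative at 3% CV); the normal scenario identifies
both coefficients well and is the right instrument for classification
experiments.

## Assay arithmetic

The phenol–sulfuric total-carbohydrate assay is quantified against a linear
standard curve, absorbance(490 nm) = slope·concentration + intercept,
fitted by ordinary least squares and inverted with an explicit dilution
factor; negative inverted concentrations are returned (below calibration
limit), not clipped. The alpha-amylase inhibition rate is
`[1 − (A − B)/C] × 100` % with A the sample reaction, B the sample
background (no enzyme) and C the uninhibited control — the conventional
reading of the three symbols; the arithmetic is agnostic to that
interpretation and values outside [0, 100] % are returned as computed.

## Problem sizes and numerical choices

Recovery experiments use 100 simulated studies per condition (2 000 fits
total including multi-start), the bootstrap coverage experiment 200 studies
× 100 resamples; both complete in minutes on one CPU. The Runge–Kutta
oracle (scipy `solve_ivp`, rtol 1e−11/atol 1e−13) checks the closed forms
to 1e−8 relative error on 100 random parameter draws. Degenerate inputs
are handled explicitly: constant biomass and < 4 distinct time points raise
typed errors; a perfectly constant product series short-circuits to
alpha = beta = 0 without optimization.

## Limitations

- A single multiplicative noise model; no weighted or heteroscedastic
  regression beyond it.
- No substrate-balance kinetics and no alternative growth laws (Gompertz,
  Baranyi) or temperature-dependence models.
- OD-to-dry-weight conversion is the user's responsibility; biomass is a
  generic concentration and OD600 can be fitted directly.
- Units of alpha (h⁻¹) and beta (g/g) follow dimensional analysis of the
  rate law; sources rarely state them.
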