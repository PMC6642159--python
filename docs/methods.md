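# Methods

This note documents the models, estimators and numerical choices behind
`chronopk`, and what its synthetic-data experiments do and do not show.

## Scientific setting

P-glycoprotein (P-gp/ABCB1), an ATP-driven efflux transporter, limits
intestinal absorption and drives biliary and renal excretion of many
drugs. Its expression and activity oscillate with circadian time and
differ by sex and feeding state, so the pharmacokinetics (PK) of a pure
P-gp substrate such as the beta-blocker talinolol depend on *when* the
dose is given (chronoPK). The package provides the quantitative
machinery to analyse such a study in mice: rhythm fitting for grouped
expression data and dense ex-vivo bioluminescence recordings, a
whole-body circadian PBPK model of oral talinolol, calibration of that
model against destructive-sampling PK data at two dosing times, global
sensitivity analysis of the resulting exposure metrics, and
non-compartmental summaries built combinatorially from destructive
sampling. No raw animal data are shipped; a synthetic-data module
generates all three experiment types with the statistical structure the
analysis assumes.

## Cosinor rhythmometry

Grouped circadian data (one animal per Zeitgeber time, ~every 3 h over
24 h, about five animals per ZT) are fitted by ordinary least squares to

    y(t) = M + sum_k [ a_k cos(2 pi t / T_k) + b_k sin(2 pi t / T_k) ],

with trial periods T_k of 24, 12 and 8 h (the fundamental and its first
two harmonics; the 3 h sampling resolves periods above 6 h). Each
harmonic is reported as an amplitude `sqrt(a_k^2 + b_k^2)` (half the
peak-trough difference; peak-trough is exposed as `2*amplitude`) and an
acrophase (time of the component maximum, hours after ZT0, in
[0, period)). Significance of a harmonic is the zero-amplitude partial
F-test: the full model against the model with that harmonic's
sine/cosine pair removed, with 2 and n-p degrees of freedom. For
noise-free data the test is undefined (reported as NaN when a component
is present, and 1.0 for genuinely constant input). Replicates are
treated as independent observations; phases are compared on the circle.

## Detrending and damped-cosine analysis

Long bioluminescence recordings (photon counts every 10 min for up to
6 days) are detrended by subtracting an OLS line, adding back the
pre-detrend mean and dividing by it, which preserves relative amplitude
and makes the mean exactly 1. The mean-1 series is then fitted by
bounded nonlinear least squares to

    y(t) = 1 + A exp(-lambda t) cos(2 pi (t - phi) / T),

where A is the maximum amplitude relative to the mesor, lambda the
damping rate (1/h) of the desynchronising ex-vivo oscillator, T the
endogenous period and phi the acrophase. Because the objective is
multimodal in T and phi, the fit multi-starts over a period grid of
16-32 h (step 2 h) and four phase quadrants per trial period with small
seed-controlled jitter, and keeps the global best; the returned optimum
is never worse than any start. A fit whose amplitude collapses to ~0 is
flagged degenerate (the period is unidentifiable on a flat series).
Note that detrending a *damped* cosine is slightly lossy — the decaying
envelope itself has a drift that the OLS line partially absorbs — so
exact parameter recovery holds on directly generated mean-1 series,
while round trips through detrending are accurate to ~0.01 h in period
at the study's sampling density.

## Circadian PBPK model of oral talinolol

Amounts (ug) in gut lumen, ileum mucosa, plasma and liver, with
cumulative urine and faeces, evolve as

    dA_lum/dt = -ka A_lum - r_int(t) A_lum + r_pgpI(t) A_il + r_pgpL(t) A_li
    dA_il/dt  =  ka A_lum + k_pl_il A_pl - r_pgpI(t) A_il - k_ib A_il
    dA_pl/dt  =  k_ib A_il - (k_pl_il + k_pl_li + r_ren(t)) A_pl + k_li_pl A_li
    dA_li/dt  =  k_pl_li A_pl - k_li_pl A_li - r_pgpL(t) A_li
    dA_ur/dt  =  r_ren(t) A_pl
    dA_fe/dt  =  r_int(t) A_lum

The oral dose (default 100 mg/kg at 25 g body weight = 2500 ug) enters
the lumen at t = 0. Ileal P-gp effluxes tissue drug back to the lumen;
hepatic P-gp secretes liver drug into bile and hence to the lumen
(enterohepatic recycling without an explicit bile compartment); renal
elimination drains plasma; intestinal (fecal) clearance drains the
lumen. Talinolol is not metabolised, so these are the only exits and
total drug is conserved exactly — the solver's mass-balance residual is
a direct accuracy probe.

Each circadian rate is a multiplicatively modulated first-order
constant,

    r_x(t) = mesor_x * (1 + sum_k alpha_k cos(2 pi (ZT(t) - phi_k)/T_k)),

with ZT(t) = (zt_dose + t) mod 24, component amplitudes alpha_k as
fractions of the mesor, periods restricted to {24, 12, 8} h and
sum_k alpha_k <= 1 enforced at construction so rates stay non-negative.

The plasma->ileum distribution term `k_pl_il` models perfusion of the
mucosa by systemic drug: measured tissue homogenate includes vascular
and interstitial drug in exchange with plasma. It defaults to 0 (purely
unidirectional absorption); the reference regime enables it because
without it systemic elimination cannot influence ileum exposure at all,
which contradicts the sensitivity structure the model is meant to
exhibit (renal elimination among the chief determinants of ileum AUC).

Tissue concentrations are amount divided by organ wet weight
(ileum 0.25 g, liver 1.3 g) and plasma amount by plasma volume
(1.2 mL); these defaults are nominal mouse physiology, and calibration
absorbs any scale error into the rate estimates because only
concentrations are fitted.

Integration uses LSODA with rtol 1e-8 / atol 1e-10 and a 0.1 h output
grid by default; calibration simulations relax to rtol 1e-6 at the
observation times only. Negative states beyond 1e-9 of the dose or
non-finite states raise immediately.

## Calibration (weighted least squares + CMA-ES)

One parameter set is estimated per sex x feeding group from the ZT3 and
ZT15 experiments jointly — phases are only identifiable when one
parameter set must explain both dosing times. The objective is

    sum_m w_m sum_{t,i} (C_model,m(t) - C_obs,m,t,i)^2,
    w_m = 1 / mean(obs_m)^2,

summing over matrices m (plasma ug/mL, ileum and liver ug/g), times and
individual mice. Matrix-mean weighting balances the roughly 100-fold
ileum/plasma scale difference so no matrix dominates. Rates and mesors
are fitted on the log scale; clearance acrophases on the natural scale
boxed to the nocturnal active phase [ZT12, ZT24]; fasted-group P-gp
amplitudes are boxed above by the fed-group values, and fasted periods
are fixed to the fed-animal periods of the same sex. Fed-group P-gp
rhythm shapes (periods, relative amplitudes, phases) are fixed from the
protein cosinor fits with only the activity mesor free, since the
protein-to-activity scale is unknown.

Minimisation uses an in-package implementation of the standard
(mu/mu_w, lambda)-CMA-ES (rank-one + rank-mu covariance updates,
cumulative step-size adaptation; default population 4 + floor(3 ln d),
initial step 0.3 of the box width). Box constraints are handled by
clip-repair plus a quadratic penalty on the repair distance. The
estimation loop restarts CMA-ES from the incumbent (step 0.1 of the box
width) until the relative improvement between rounds falls below 1e-4
or 10 rounds, and the incumbent never worsens.

Uncertainty follows the destructive-sampling Monte-Carlo scheme:
virtual datasets are assembled by drawing one mouse per time point
(by default the *same* animal across plasma/ileum/liver, respecting
that one mouse yields all three matrices at its sacrifice time; fully
independent draws are available), each virtual dataset is refitted
warm-started from the averaged-data fit (step 0.05 of the box width),
and per-parameter means and SDs are reported. 200 virtual datasets is
the documented production setting; validation experiments use fewer.

### Identifiability and the recovery experiment

Two preset regimes are provided. `reference_params()` (fast absorption,
perfusion exchange, strong ileal efflux, renal five orders of magnitude
above intestinal clearance) is for simulation and sensitivity analysis.
`recovery_params()` is the truth regime for estimator validation: its
absorption half-time exceeds the first sampling time (0.5 h) and it
uses the unidirectional topology, because at fast absorption the
absorption rate and ileal efflux are confounded through the
lumen-tissue shuttle and no optimizer can separate them. The default
free set holds seven parameters (ka, k_ib, k_pl_li, the two P-gp
mesors, renal mesor and renal acrophase); the liver-to-plasma return
k_li_pl is fixed because a local weighted-sensitivity screen puts its
influence on the predictions 4-5x below every other rate (the data see
the liver's output split only through downstream recycling), and the
intestinal clearance mesor is fixed because at five orders of magnitude
below renal clearance it has no measurable effect on any observation.
Recovery fits are started from a uniform random point in the bound box:
with log-symmetric bounds the box centre coincides with the truth, and
starting there would trivialise the experiment.

## Global sensitivity analysis

Exposure metrics are liver and ileum AUC over 0-8 h post-dose.
Parameter sets come from Saltelli's cross-sampling extension of Sobol's
method on a scrambled Sobol sequence: a base sample of N points gives
matrices A and B and the d radial matrices AB_i, N (d+2) model runs in
total. The production budget of 48,000 runs is read as *total
evaluations*, so N = floor(48000 / (d+2)). Total-order indices use the
Jansen estimator S_Ti = E[(f(A) - f(AB_i))^2] / (2 Var f); their
Monte-Carlo error is a bootstrap over base-sample rows (100 resamples);
first-order indices (Saltelli 2010) are computed internally only for
the S_Ti >= S_i consistency property. Rate-like factors with 10-fold
multiplicative bounds are sampled log-uniformly; phases and the
circadian time of administration uniformly. The dosing ZT is itself a
sampled factor in [0, 24); the perfusion constant k_pl_il is fixed
physiology (like organ volumes) and is not sampled. Failed simulations
propagate as NaN and are dropped (with accounting) up to 1% of the base
sample.

## Combinatorial PK summaries

Destructive sampling yields no within-animal curve, so candidate
profiles are built by choosing one mouse per time point. All
combinations are enumerated when their count is at most a cap (50,000
by default; 4 mice at 6 time points give 4^6 = 4096 curves), otherwise
a seeded random subset of the cap size is drawn. AUC(0-8 h) uses the
trapezoidal rule with a concentration-zero anchor at t = 0 (the first
sample is 30 min after an oral dose; the anchor is configurable off),
and Cmax is the maximum over observed time points without
interpolation. Because the trapezoid is linear, the combinatorial mean
AUC equals the AUC of the per-time mean curve — a built-in exactness
check.

## Synthetic-data generators

The generators emulate the three experimental designs at their
documented conditions: expression sampling every 3 h with 5 animals per
ZT; PK sampling at 0.5, 1, 2, 4, 6, 8 h with 4-5 mice per time and
dosing at ZT3 or ZT15 (100 mg/kg oral); bioluminescence at 10-min
sampling for 144 h. Noise defaults: 20% CV lognormal scatter on
expression; 20% CV lognormal inter-animal variability applied as
independent multipliers on each virtual mouse's rate parameters (shared
across matrices so one animal's plasma/ileum/liver values are
internally consistent — required for linked resampling); 7.5%
proportional assay CV (HPLC reproducibility spans roughly 2-10%) with a
0.05 ug/mL limit of determination below which values are floored when
censoring is on; additive Gaussian noise plus a linear trend on
bioluminescence. The ex-vivo rhythm presets are female
(T = 24 h, A = 127% of mesor, lambda = 0.0054 1/h, phi = 19 h 13 min)
and male (T = 26 h 35 min, A = 51%, lambda = 0.0096 1/h,
phi = 11 h 32 min); the ileum Abcb1a mRNA presets carry 24 h relative
amplitudes of 62% (female) vs 37% (male). The inter-animal variability
magnitudes are plausible placeholders, not measured values.

What passing tests show — and do not show. Recovery and calibration
tests demonstrate that the estimators work when the data-generating
process matches the model (correct ODE structure, lognormal noise, no
model misspecification). Real tissue data add matrix effects, assay
censoring, between-batch drift and structural mismatch that these
synthetic experiments deliberately exclude; the tests validate the
machinery, not the biology.

## Numerical choices and limitations

* Bateman-limit check: the one-compartment reduction uses a fast ileum
  transit (k_ib = 4000/h >> ka); the comparison is the maximum absolute
  deviation normalised by the curve maximum, since plasma vanishes at
  t -> 0 and pure relative error is ill-posed there.
* Problem sizes in the validation suite (20 recovery replications at
  ~4,000 objective evaluations each, 4 Monte-Carlo virtual datasets for
  the degenerate-variability check, 3,000-evaluation sensitivity runs,
  100 bioluminescence replicates) are scaled-down versions of the
  production settings, chosen to keep the full validation cycle at a
  few minutes on one core while leaving clear statistical margins.
* The model omits talinolol metabolism (a pure, unmetabolised
  substrate), plasma protein binding, a colon compartment, and the
  bile-acid micelle binding proposed to explain the fasted-male double
  peak; none of these is required for the analyses implemented here.
* Multi-factor ANOVA across organ/sex/feeding/ZT, Lomb-Scargle
  periodograms, mixed-effects cosinor and AUC extrapolation beyond 8 h
  are out of scope by design; standard statistics tooling covers them.
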