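# Methods

This note documents the models implemented in `mpes`, the numerical choices
behind them, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Evidence-synthesis models

### Pairwise meta-analysis

Study estimates `(y_i, se_i)` on the log hazard-ratio scale are pooled with
a common-effect model (`y_i ~ N(m, se_i^2)`) or a random-effects model
(`y_i ~ N(m, se_i^2 + tau^2)`, study effects marginalised analytically).
Priors are vague: `m ~ N(0, 1e3)` and `tau ~ HalfNormal(0, 1e3)` — written
as variances, not BUGS precisions; at these scales the two conventions are
indistinguishable, and both hyperparameters are config-overridable.  The
common-effect posterior mean must (and in the tests does) match the
closed-form inverse-variance estimate within Monte-Carlo error.

### Bivariate random-effects meta-analysis (BRMA)

The between-study model is the bivariate normal
`mu_i ~ N2((eta_os, lambda0), T)` with `T` built from heterogeneity SDs
`tau_os`, `tau_pfs` and the between-study correlation `rho_b`.  The
equivalent product-normal factorisation (reported per draw) has slope
`lambda1 = rho_b * tau_pfs / tau_os` and conditional variance
`psi_pfs^2 = tau_pfs^2 (1 - rho_b^2)`.  One representational choice: the
conditional regression is centred at the population mean `eta_os` rather
than at the latent sample mean of the `mu_os,i`.  Centring at the latent
sample mean is a common BUGS device for reducing posterior correlation
between intercept and slope, but it makes `lambda0` depend on the realised
study set; centring at `eta_os` makes the model exactly the standard
bivariate-normal BRMA, keeps `exp(lambda0)` interpretable as the pooled PFS
hazard ratio, and lets the latent `mu_i` be marginalised analytically.  The
likelihood is therefore evaluated on the marginal scale
(`Y_i ~ N2((eta_os, lambda0), T + Sigma_i)` per study, with the obvious
univariate margin when one outcome is unreported), which removes 2n latent
parameters from the sampler.  Per-draw `mu_i` values are recovered
afterwards by exact conditional-Gaussian draws, so the reported posterior
is identical to sampling the latents directly.

Within-study correlations `rho_w,i` carry Uniform(−1, 1) priors, exactly as
specified; they are weakly identified from a single bivariate observation
per study, and `fix_rho_w=` allows pinning them from external knowledge
(the calibration tests use this).

**Prediction of a missing effect.**  For a study missing (say) PFS, the
predicted observed effect is drawn per MCMC iteration from the conditional
of the marginal bivariate normal given the study's observed OS estimate —
the same distribution a BUGS sampler would draw the missing data node from.
The missing within-study SE comes from an exchangeable model on the
observed log variances: `ln(se_j^2) ~ N(m_v, s_v^2)` with `m_v ~ N(0, 1e3)`
and `s_v ~ HalfNormal(scale 1)`.  The hyper-SD scale is the one place a
fully vague prior is *not* used: with only two or three observed
log-variances, a HalfNormal with SD ≈ 31.6 lets `s_v` wander so far that
`exp(m_v + s_v z)` overflows, predicting within-study SEs of astronomically
many orders of magnitude.  A scale of 1 still permits roughly two orders of
magnitude of spread among within-study variances — far more than real
trial sets exhibit — while keeping the predictive distribution proper in
practice.  The choice is config-exposed (`priors.logvar_sd_scale`), and
predictions should be checked for sensitivity to it when the number of
observed studies is small.

**Identifiability guards.**  Fewer than two studies reporting both outcomes
leaves `rho_b` unidentified: the fit refuses unless forced.  An outcome
missing from every study is an error — there is nothing to identify its
margin, let alone predict with it.

### Network meta-analysis

Contrast-based normal model on log hazard ratios with basic parameters
`d_k` relative to a declared baseline (`d_baseline = 0`); the fixed variant
has no heterogeneity, the random variant adds a common heterogeneity SD
with a half-normal prior (study effects marginalised).  Connectivity is
checked up front (components are named in the error).  Predicted estimates
may substitute missing ones; substitutions are logged as such.  Contrast
antisymmetry and the three-way consistency identity hold per draw by
construction, and on a tree network the fixed-effect indirect contrast
equals the sum of edge estimates up to Monte-Carlo error — the package's
headline reproduction (0.641 × 0.619 → 0.397).

### Sampling and diagnostics

No probabilistic-programming framework is used: every model exposes a
vectorised log posterior and is sampled with `emcee`'s affine-invariant
ensemble using differential-evolution moves (80% `DEMove`, 20%
`DESnookerMove`), which handle the correlated, heavy-tailed geometries that
vague half-normal scale priors produce far better than the plain stretch
move.  Run lengths are counted as *total draws across the ensemble*: the
default 30,000 iterations with 15,000 burn-in — the case study's run
lengths — yield ~15,000 retained draws regardless of walker count.  Chains
are internally oversampled and thinned (factor ≈ dimension, capped at 10)
to keep autocorrelation low at fixed retained-draw counts.  Split-Rhat and
bulk ESS are computed over walker chains with `arviz`; `Rhat > 1.05` on any
monitored quantity raises a logged convergence flag on the results object,
never a silent pass.  All samplers are bit-reproducible given the seed.

## Survival fitting

The Weibull is parameterised as `S(t) = exp(-lam * t^gamma)` (t in months)
everywhere, because the Markov engine's transition-probability formula
depends on this exact convention; conversions from other shape/scale
conventions belong at the I/O boundary.  The right-censored MLE is found by
Newton iteration on `(ln lam, ln gamma)` with the analytic Hessian, whose
inverse provides the asymptotic covariance used by the PSA (bivariate
normal on the log parameters — the sampling mechanism is a package choice,
stated here because the source analyses do not specify theirs).  The Cox
partial likelihood for the single arm indicator is maximised by damped
Newton-Raphson with Breslow tie handling by default and Efron behind a
flag; `lifelines` (Efron) serves as the independent oracle on tie-free data
in the tests, where the two corrections coincide.

## Markov cohort models

Both structures run 180 monthly cycles (15 years) on a 10,000-patient
cohort by default.  The 2-state model (Alive/Dead) drives the alive→dead
transition from the baseline-treatment OS Weibull; the 3-state model
(StD/PD/Dead) drives StD→PD from the PFS Weibull, adds a fixed
0.005/cycle other-cause death probability out of StD (no uncertainty), and
uses a constant PD→dead probability.  Treatment effects enter as hazard
ratios on the cycle survival fraction, `1-(1-tp)^HR`, applied to the OS
transition (2-state) or the StD→PD transition (3-state) — posterior draws,
not summaries, so the synthesis uncertainty propagates.

**PD→dead from mean-survival decomposition.**  The PD residence time is not
estimable from unpaired reconstructed IPD, so it is derived from the
balance `os_mean = p * (pfs_mean + d_PD) + (1-p) * m_other`, where `p` is
the share of deaths occurring via progression and `m_other` the mean
survival of other-cause deaths; `d_PD` converts to a monthly probability as
`1 - exp(-1/d_PD)`.  This decomposition is a declared interpretation — the
original supplementary derivation is not available to this package — and
the packaged fixture uses `p = 1` (prostate-cancer deaths dominate in this
population, and the separate 0.005/cycle transition already routes
other-cause deaths out of StD).  An infeasible implied duration
(`d_PD <= 0`) raises with the offending value rather than being clipped.

**Accrual and discounting.**  Costs and utilities accrue on end-of-cycle
occupancy, with no half-cycle correction by default (a config flag enables
it); the sources report none, and the reported magnitudes match the
uncorrected convention.  Discounting is annual-step: factor 1 through
cycle 12, then `1.035^(-floor((t-1)/12))` — i.e. from cycle 13 — for both
costs and QALYs.  The terminal-care cost is charged once on entry to Dead.
The StD utility is the transition-probability-weighted average
`tp_stay*0.770 + tp_progress*0.538 + tp_other_death*0.564` recomputed each
cycle; the 2-state alive state uses the end-of-life value 0.538.

**PSA distributions.**  Utilities: normal(mean, SE) truncated to [0, 1].
Follow-up and terminal costs: gamma, moment-matched to mean and an SE
fraction (drug tariffs held fixed).  Follow-up cost split between PD and
StD: Uniform(0.70, 0.80) share to PD per draw, the published range having
no point value.  Weibull parameters: bivariate lognormal from the MLE
covariance.  Hazard ratios: posterior draws resampled with replacement.
The deterministic engine refuses infeasible rows (`tp + 0.005 > 1`), but
probabilistic draws from heavy-tailed predicted-HR posteriors can touch the
boundary; there the cycle probability is capped at its logical maximum
`1 - 0.005` ("progresses within the cycle with certainty") and the affected
draw fraction is logged — on the packaged fixture this is ~0.2% of D+P
draws.  The vectorised PSA path and the single-run cohort path are held to
agreement at 1e-10 by a dedicated test.

A 100,000-person microsimulator (`microsimulate`) exists purely to
cross-validate the cohort engine; analyses never use it.

## Decision metrics

ICER is the ratio of means over PSA draws (never the mean of ratios), with
dominance labelled instead of reporting a signed ratio; the SEs attached to
incremental means are the PSA-distribution SDs, matching how incremental
tables are conventionally reported.  CEAC probabilities are strict-argmax
frequencies with exact ties split equally, so columns sum to 1; a
regression test pins the fact that the CEAC winner need not be the
mean-net-benefit maximiser.  Per-person EVPI is `E[max NB] - max E[NB]`
(clamped at the exact lower bound 0 against float round-off) and matches a
brute-force two-loop computation exactly in the tests.  Population EVPI
multiplies by the discounted incident population over a 12-year horizon at
9,000 patients/year and 3.5%/year, first year undiscounted by default
(multiplier ≈ 10.0017 × 9,000); discounting the first year too is a config
switch and lowers the result by ~3.4%.

## Synthetic data and the packaged fixture

`gen_study_set` simulates exactly the hierarchical model the BRMA assumes:
latent effects from the between-study bivariate normal, observed effects
from within-study bivariate normals with SEs drawn uniformly from a range
(real SEs are driven by trial size and event counts; uniform keeps the
mechanism transparent), and arbitrary entries blanked afterwards.  Default
conditions are the calibration settings used throughout the tests
(20 studies, pooled effects at the case study's 0.903/0.641, tau 0.2,
rho_b 0.9).  `gen_ipd` draws Weibull survival times with the comparator arm
following `S(t)^HR` — exact proportional hazards, matching how the Markov
engine applies hazard ratios — under administrative censoring.  What the
generator does *not* emulate: curve-digitisation error and the
reconstruction process behind real reconstructed IPD, informative
censoring, multi-arm correlation structures, and any SE-size relationship.
Passing calibration tests therefore demonstrate correctness *under the
model's own assumptions*, not robustness to their violation.

The packaged fixture mirrors the four-trial case-study evidence base.  The
three mitoxantrone-trial log HR/SE values are synthetic stand-ins
constructed so their inverse-variance pooled results reproduce the
published fixed-effect summaries (OS 0.903 (0.751–1.084); PFS 0.641
(0.532–0.772)) with heterogeneity in the published random-effects range;
the docetaxel OS row is the published 0.76 (0.620–0.936).  Decision-model
inputs mix published values (utilities, 0.005 other-cause transition,
discounting, 70–80% follow-up split) with synthetic placeholders for
report-only inputs (Weibull parameters, cost levels); provenance is
recorded per field in `src/mpes/data/hta_model.yaml`.  Consequently the
packaged pipeline reproduces the published cost-effectiveness results to
order of magnitude only — by design, the fixture is honest about what is
and is not public.

## Limitations

* The BRMA prediction inherits the bivariate-normal assumption; under
  non-linearity or outliers it can overshrink.  Daniels–Hughes-type models
  and t-distributed random effects are natural extension points, not
  implemented.
* `rho_w,i` are weakly identified; fixing them externally changes
  predictions and should be explored in sensitivity analyses.
* No EVPPI, no tunnel states, no treatment-discontinuation modelling, no
  covariate-adjusted Cox beyond the arm indicator, no spline/flexible
  parametric survival models.
* Ensemble-chain Rhat/ESS are computed over interacting walkers and are
  somewhat optimistic relative to independent chains; the thinned DE
  ensemble mitigates but does not eliminate this.
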