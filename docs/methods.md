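# Methods

## Model

The package models the daily SOFA score of a septic patient as the sum
of a standard-of-care (placebo) response and a drug response, both
expressed as fractions of the observed baseline:

SOFA(t) = Base − Fplacebo·Base·(1 − e^(−(k+η)t)) − (1 − Fplacebo)·Base·(1 − R(t)) + ε.

The drug response is a latent variable R(t) obeying an inhibitory
indirect-response (turnover) model in which the subject's steady-state
exposure AUC₀₋₈ₕ inhibits the zero-order production rate:

dR/dt = kin·(1 − AUC/(AUC + EAUC50)) − kout·R, R(0) = 1.

The baseline condition R(0) = 1 forces kin = kout, which yields the
closed form R(t) = 1 − I·(1 − e^(−kout·t)) with I = AUC/(AUC + EAUC50).
The closed form is the production path inside the likelihood; an
adaptive-step ODE integration of the turnover equation is retained as
an independent oracle (the two agree to ≤1e−8 over the studied grid)
and as the hook for any future kin ≠ kout extension.

Assumptions worth stating plainly: exposure enters as a constant
per-subject scalar (steady-state AUC over one dosing interval), not as
a time-varying concentration; the only random effect is an additive η
on the standard-care rate k (so a subject can have k + η < 0 and a
*rising* score — non-responders are representable, and predictions are
deliberately not clipped to the 0–24 score range); the residual is
additive Gaussian; baseline is a covariate, never a parameter.

## Parameters, units, defaults

| parameter | meaning | unit | default (generator truth) |
|---|---|---|---|
| Fplacebo | maximal standard-care fraction | – | 0.792 |
| k | standard-care amelioration rate | 1/day | 0.263 |
| kin = kout | latent-response turnover rate | 1/day | 0.0569 |
| EAUC50 | exposure at half-maximal inhibition | h·ng/mL | 1320 |
| ω | SD of η on k | 1/day | 0.302·k ≈ 0.0794 |
| σ | residual SD | SOFA units | 1.96 |

The reported inter-individual variability of 30.2 on k is read as a
CV%, hence ω = 0.302·k; the alternative reading (ω = 0.302/day
directly) is available via `default_truth(iiv_as_cv=False)`. The IIV
printed against the residual row is treated as a typesetting artefact
of shrinkage reporting, not as a second random effect.

## Estimation

The marginal likelihood integrates the subject-level joint density over
η. Two routes are implemented on the same engine:

* **FOCE** (default): Laplace approximation at the per-subject
  posterior mode with the Gauss–Newton curvature Σg²/σ² + 1/ω²,
  g = ∂prediction/∂η. With a purely additive residual the interaction
  term of FOCE-I vanishes, so this matches the original analysis
  method. The inner mode search is a safeguarded Newton iteration,
  vectorised across subjects.
* **AGQ**: adaptive Gauss–Hermite quadrature (default 31 nodes)
  centred and scaled at the mode — the reference method. On the test
  fixtures the FOCE−AGQ gap is well under 2 OFV units (hard-checked at
  5); AGQ itself agrees with brute-force trapezoid quadrature over
  η ∈ [−8ω, 8ω] to 1e−6.

Optimisation runs on a transformed scale (logit for Fplacebo, log for
the positive parameters) with L-BFGS-B, box constraints expressing
plausibility ranges (e.g. EAUC50 ∈ [10, 20000] h·ng/mL — beyond about
4× the largest studied AUC the inhibition curve is indistinguishable
from linear and the parameter is unidentifiable), relative OFV
tolerance 1e−10, at most 2000 evaluations per start, and 5 seeded
jittered starts. ω = 0 is handled exactly (the marginal collapses to
the plain Gaussian −2LL, checked to 1e−10). Day-0 rows are excluded
from the likelihood by default: the day-0 observation *is* the baseline
covariate, so including it would reproduce it exactly and understate σ
(configurable via `include_day0`).

Standard errors come from the observed information of the marginal
log-likelihood — central finite differences on the transformed scale
(step 1e−3, cross-partials included), inverted and delta-method
back-transformed. A non-positive-definite information matrix produces
NaN for the affected parameters with a warning rather than a fake
number. Empirical Bayes estimates are the per-subject posterior modes;
η-shrinkage is 100·(1 − SD(η̂)/ω) and ε-shrinkage 100·(1 − SD(IWRES)).

### Identifiability of the drug-term pair

Over the 8-day window kout·t ≤ 0.46, so the drug term is close to
(1 − Fplacebo)·Base·(AUC/EAUC50)·kout·t: to leading order it depends on
kout/EAUC50, not on the two separately. The marginal likelihood is
therefore nearly flat along the joint (log kin, log EAUC50) direction —
even at ~1700 simulated subjects, scaling both by 1.5–3× costs only a
few OFV units. At the trial's size (34 subjects) a substantial fraction
of simulated replicates place the maximum-likelihood estimate at
implausibly extreme values of the pair (verified to be genuine MLEs:
their OFV beats the generating parameters'), while the standard-care
parameters, ω, σ, and the model's *predictions* across the studied
exposure range recover well. Consequently, simulation–re-estimation
recovers kin and EAUC50 in median but not in mean; the package reports
what the likelihood supports and does not constrain or post-select fits
to hide this. Users fitting data of this size should treat kin and
EAUC50 as a weakly identified pair and interpret their ratio (or the
predicted exposure–response curve) rather than either number alone.

## Diagnostics

Residuals follow population-PK conventions: PRED (η = 0), IPRED (at
η̂), IWRES = (DV − IPRED)/σ, and CWRES from the first-order expansion
around η̂ — the residual whitened by (GωG′·ω² + σ²I)^(−1/2) via a
symmetric eigendecomposition; with ω = 0 it degenerates to the plain
standardized residual. Under self-simulation at the generating
parameters ~95–97% of |CWRES| fall within ±2.

The pcVPC simulates replicate datasets on the observed design (same
ids, days, baselines, AUCs; fresh η and ε), bins by treatment arm ×
nominal study day (times are nominal, so no adaptive binning), applies
the standard ratio prediction-correction pcY = Y·med(PRED_bin)/PRED
with an additive fallback when any PRED in a bin comes within 0.5 SOFA
units of zero (the ratio correction degenerates near zero), and
summarises the 10/50/90th percentiles with an 80% confidence band per
percentile across 1000 simulations (80% reflects the small sample
size). Simulated DVs are not clipped to [0, 24] by default — the model
is its own reference — with clipping available for realism studies.

## Simulation for dose selection

`simulate_day7_vs_auc` fixes t = 7 and sweeps AUC from 0 to
5000 h·ng/mL (101 grid points) at baselines 15/10/5, drawing 1000
(η, ε) pairs per baseline and reporting 30/50/70th percentiles. The
pairs are drawn once per baseline and reused across the AUC grid
(common random numbers), so the percentile curves inherit the model's
monotonicity in AUC instead of burying it under Monte-Carlo noise.
Both η and ε are drawn by default (consistent with the pcVPC);
`draw_epsilon=False` gives η-only bands. `simulate_sofa_time` draws
per-subject baselines (truncated normal) and AUCs (lognormal) from arm
distributions and reports percentile bands over the day grid. With the
default parameters the day-7 median declines by ~0.36 SOFA units from
AUC 0 to 1500 and by <0.2 further units out to 5000 — the plateau that
motivates selecting the dose whose typical steady-state exposure
reaches ~1500 h·ng/mL.

## Synthetic trial generator

The generator emulates the Phase-IIa analyzable set: arms
placebo/0.06/0.12/0.24 mg/kg with n = 10/6/9/9 (only the drug total of
24 is published; the 6/9/9 split follows the pre-trial randomisation of
6 subjects to 0.06 mg/kg and is configurable), baseline summaries
12.10±4.36, 9.25±2.22, 9.56±3.09, 10.09±3.86 and AUC summaries
295.21±47.16, 827.85±334.10, 1482.51±378.34 (h·ng/mL), SOFA observed
pre-dose and daily for 8 days.

Baselines are drawn from a normal truncated to [3, 24] and rounded to
integers; the location is bias-corrected by root-finding so the
truncated mean hits the arm target (the raw truncation bias is ~0.16
SOFA units for the placebo arm; rounding adds O(1e−3), negligible).
AUCs are moment-matched lognormal (positivity). The day-0 DV equals the
baseline exactly — it *is* the baseline measurement — and later days
are prediction + ε, left continuous so σ recovery is unbiased; an
integer-DV mode (round + clip to [0, 24]) exists for realism studies
and is excluded from recovery testing. Dropout is off by default; a
preset solves the per-day hazard whose expected observation count
matches the published 245 measurable scores (of 306 possible).

PK profiles for the NCA stage come from a one-compartment
constant-rate-infusion superposition model (1-h infusions every 8 h, 21
doses), sampled at the protocol times (pre-dose and 0.5/1/2/6/8 h after
the first dose; pre-dose and 0.5/1/2/6/12 h after the last). No PK
model was published for the compound; the default elimination half-life
of 3 h is a choice consistent with all post-dose samples remaining
quantifiable out to 12 h after the last dose. Per-subject clearance is
calibrated so the subject's *measured* exposure — the protocol-time
linear-trapezoid NCA average of the first- and last-dose AUC₀₋₈ₕ —
equals an AUC drawn from the arm's lognormal. Calibrating to the
measurement rather than to the analytic steady-state dose/CL matters:
the analytic identity ignores both the trapezoid discretisation on the
sparse grid (−9% on the last-dose occasion) and the fact that the
first-dose AUC₀₋₈ₕ lacks accumulation (−15%), a combined −12% that
would otherwise be baked into every generated arm. The analytic mode is
retained as `calibration="analytic"` and its closed-form identity
(steady-state AUC₀₋₈ = dose/CL) is tested.

What the generator does *not* emulate: exclusion criteria and
withdrawal reasons, assay noise on concentrations, integer SOFA
observation by default, covariate effects, and any dose–exposure
nonlinearity. Passing tests on synthetic data therefore demonstrate
internal consistency of the pipeline under the stated model, not that
the model describes real sepsis trajectories.

## Numerical choices and degenerate inputs

Inner Newton: full second-order curvature where positive, Gauss–Newton
surrogate otherwise, step capped at 4 prior SDs, per-subject
backtracking; convergence at step < 1e−12 (quadratic tail). Subjects
with no post-baseline observations contribute nothing to the marginal
likelihood and get η̂ = 0. ω below 1e−10 is treated as exactly zero.
Concentrations below the 0.1 ng/mL LLOQ are zeroed at t = 0 and dropped
elsewhere (exact zeros are kept as idealised true zeros); NCA requires
a t = 0 sample and ≥2 points in [0, 8] h, never extrapolates, and flags
partial-interval integration. All stochastic components (generator,
fit multi-start jitter, pcVPC, simulations) take explicit seeds and are
bit-reproducible given them.

## Problem sizes

The test suite and the acceptance script run at the sizes the analysis
itself prescribes: 34-subject trials for the 100-replicate
simulation–re-estimation study, 1,000 subjects for the exposure
calibration, 10,000 for the baseline calibration, 200 trials for the
Wald-coverage check, 20 replicates × 200 simulations for pcVPC
self-consistency, and one ~500-subject trial for large-sample recovery.

## Known limitations

* kin/EAUC50 are a weakly identified pair at realistic sample sizes
  (see above); their point estimates from a single small trial should
  not be interpreted individually.
* FOCE standard errors ignore the Laplace approximation error; the AGQ
  route exists for verification but SEs are not recomputed under it by
  default.
* The residual model is homoscedastic additive; count-like or bounded
  behaviour of the score near 0 and 24 is not modelled.
* No time-varying exposure, no Hill coefficient on the inhibition, no
  mixture (non-responder) subpopulation, no covariate search.
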