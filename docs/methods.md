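# Methods

This note documents the models implemented in `fertsim`, the conventions
chosen where the problem was genuinely open, and what the synthetic-data
tests do and do not establish.

## Person-period restructuring

A lactation is at risk of conception between 20 and 220 days in milk (DIM).
The risk window is tiled with half-open two-day bins `[20,22) … [218,220)`,
so a fully observed lactation contributes exactly 100 risk periods.  A bin
is emitted while the cow is still at risk at the bin start, up to and
including the bin containing the lactation's end event (conception, cull,
sale/death or administrative censoring); the final bin carries outcome 1
iff the lactation ended in conception before 220 DIM.  A conception at or
after 220 DIM is outside the modelled window and contributes only censored
periods.

Duplicate lameness treatment records are removed by a sequential scan: an
event is dropped iff it falls within 7 days of the most recently *retained*
event (so `[0, 5, 10] → [0, 10]`: the 5 is a duplicate of the 0; the 10 is
not, because it is compared against the retained 0, not the dropped 5).

Lameness window flags use day offsets Δ = event DIM − anchor, with windows
(−100,−71), (−70,−43), (−42,−15), (−14,14), (15,42), (43,70), (71,100) —
adjacent and non-overlapping, so one event sets at most one flag.  The
anchor is the **bin start** by default.  Because the bins are only two days
wide the choice of anchor (start, midpoint, or any-day-overlap) moves flags
by at most one bin; all three conventions are exposed via the `anchor`
argument of the restructuring functions.

Yield enters as centred 305-day yield in thousands of litres; the centring
constant defaults to the grand mean of the input dataset (it is also stored
in the output table's `attrs`, since the fitted intercept is only
interpretable together with it).

## The discrete-time survival model

The conception hazard is a three-level Bernoulli-logit (periods in cows in
herds):

    logit(µ_tij) = α + β₁ lnDIM + β₂ (lnDIM)² + X_tij β₃ + X_ij β₄
                   + u_ij + v_j

with lnDIM evaluated at the bin-start DIM.  The model structure is fixed:
quadratic ln-DIM baseline; parity (1 ref, 2, 3, 4, >4), calendar year of
calving (≤2002 ref, 2003–2006, 2007–8), season of the risk period (calendar
quarters, Jan–Mar ref), centred yield, and four lameness windows (43–70 d
before, within 14 d, 43–70 d after, 71–100 d after).  The three remaining
windows carry coefficient 0 in the packaged estimates.  No stepwise
covariate search is performed; `hpd_retention` is provided as a utility for
users who want to re-screen terms by the exclude-zero HPD rule.

### Estimation

Fixed effects get independent Normal(0, 100²) priors (weakly informative on
the log-odds scale); random effects are zero-mean normals with free
variances.

* **Laplace backend (default).**  For given variances the joint mode of
  (β, u, v) is found by penalised Newton iterations.  The Newton system is
  solved exactly in O(n) per iteration by exploiting its sparsity: the
  cow-effect block is diagonal, each cow maps to one herd, so u and then v
  are eliminated by Schur complements, leaving a dense solve only for the
  ~20 fixed effects.  The two variance components are profiled out by
  Nelder-Mead on the Laplace-approximate marginal likelihood (all of
  β, u, v integrated).  The reported posterior for β is the Gaussian implied
  by the marginal curvature at the optimum; HPD intervals are computed from
  1,000 draws of that Gaussian.  The quadratic ln-DIM basis is centred
  internally for conditioning and transformed back on report.  A fit at
  ~500,000 risk periods with ~9,000 cow effects takes ~25 s on one CPU.
* **MCMC backend.**  An ensemble sampler (emcee) over (β, log σ²_cow,
  log σ²_herd), with the random effects integrated out at each evaluation
  by a Laplace approximation of the (u, v) block.  Intended for small
  datasets and as a cross-check of the Gaussian approximation; the test
  suite verifies agreement with the Laplace backend.

Non-convergence of either the inner Newton or the variance profile is
flagged on the returned object, and complete separation (a covariate level
with no events) raises a warning.

Known limitation: Laplace variance-component estimates for rare binary
outcomes are biased low at modest cluster counts (the classic
penalised-quasi-likelihood shrinkage); fixed-effect coverage is unaffected
at the problem sizes tested (95% nominal ≈ 95% observed in the null- and
truth-recovery experiments).

### Posterior predictions

`posterior_predictive_check` simulates Bernoulli outcomes per posterior
draw for a data subset (random effects at their conditional modes) and
compares the observed event proportion with the 2.5–97.5 percentile band of
simulated proportions.  `predicted_relative_risk` predicts every period
twice per draw (lameness flag on/off, everything else as observed) and
returns the ratio of average risks; for a per-period event probability of
~1.3% this population-averaged relative risk is numerically
indistinguishable from the odds ratio.

## Herd-level simulator and PSA

Each simulated herd draws seven inputs from independent uniforms:

| input | range | units |
|---|---|---|
| submission rate (SR) | 0.10–0.80 | proportion per 21 d |
| pregnancy rate (PR) | 0.10–0.60 | proportion per insemination |
| herd mean 305-d yield | 3,000–12,500 | litres |
| proportion in lactation 1 | 0.10–0.40 | proportion |
| lameness incidence | 0.1–1.5 | cases/cow-year |
| cost per extra empty day | 1.20–4.20 | £ |
| cost per FTC cull | 550–1,750 | £ |

Uniform ranges deliberately over-disperse relative to any real herd
population: the goal is coverage of plausible scenarios, not their joint
frequency.

Per lactation: parity 1 with probability `prop_lact1`, the rest split over
{2, 3, 4, >4} in ratio 1 : r : r² : r³/(1−r) with r = 0.75 (a geometric
survival profile approximating a ~22%/year cull rate, the open-ended top
category absorbing the tail).  Yield is Beta(4,4) on ±4,500 L around a base
mean — Beta(4,4) scaled this way has the required 1,500 L standard
deviation — multiplied by 0.90 for first lactations, the base rescaled by
1/(1 − 0.1·prop_lact1) so the parity-mixed mean equals the herd average,
and floored at 1,000 L.

Lameness histories place an event in each two-day bin independently with
probability `ir × (300/365) × pmf(bin)`, giving `ir × 300/365` expected
cases per 300-day lactation.  The default DIM distribution of cases is a
discretised gamma (shape 2, scale 60 d; mode near 60 DIM) — front-loaded
and declining through late lactation; any user mass function over the 150
bins is accepted.  The PSA conclusions are insensitive to this shape
because the lameness contribution to mFX is small under any of them.

Each lactation is then walked through two-day bins from 20 to 298 DIM.  The
survival model predicts µ with: cow and herd random effects at 0 (between-
herd variation is injected through the background-rate adjustment instead),
season at its reference level, year at the most recent level, and yield
centred at 8,329 L (the mean 305-day yield of the herds behind the packaged
coefficients).  Beyond 220 DIM the quadratic ln-DIM baseline is
extrapolated; it declines smoothly there, and its absolute level is largely
re-anchored by the background adjustment anyway.

**Background adjustment.**  The herd's SR and PR imply a per-two-day
conception probability `p_t = 1 − (1 − SR·PR)^(2/21)`.  The model
probability is adjusted on the odds scale, `odds(p) = odds(p_model) ×
odds(p_t)/odds(p_ref)` with reference `p_ref = 0.0134` (the overall
per-period conception proportion in the source data).  Odds-scale
multiplication is the unique choice that preserves every covariate odds
ratio exactly.

Conception is a Bernoulli draw per bin; a lactation ends at first success
or at 300 DIM (failure to conceive, FTC).  DIM at pregnancy is recorded as
the bin start.  A herd is 200 lactations; the number of random draws per
lactation is independent of the input values, so herds simulated from
identically seeded generators are coupled (common random numbers), which
the monotonicity and paired-contrast tests exploit.

**mFX score.**  `(mean DIM at pregnancy − 60) × cost_per_empty_day +
prop_FTC × cost_per_ftc_cull`, in £/cow/year; higher is worse.  Deviations
below target are *not* clamped by default — the published definition costs
the "difference from target" without a floor, and a herd beating the 60-day
target earns a credit; `clamp=True` floors both components.  A herd with
zero conceptions has no mean DIM; the day term is then evaluated at 300
(documented convention, also used by the simulator).

**Analysis.**  Spearman rank correlations input-vs-mFX (mFX is positively
skewed); OLS of ln(mFX) on the seven inputs, attributing to each input the
last-entry reduction in residual sum of squares as % of total — with
independent uniform inputs this is order-invariant up to Monte Carlo error,
so averaging over entry orders is unnecessary (asserted by test).  When any
mFX ≤ 0, the transform becomes `ln(mfx − min + 1)`; tornado deltas are
unaffected because the shift cancels in differences of back-transformed
predictions.  Tornado deltas move one input from its distribution median to
its upper quartile (others at medians) on the regression surface,
back-transformed from the log scale; a direct re-simulation mode with
common random numbers is provided for validation, and whether one evaluates
the regression surface or re-simulates changes the deltas only modestly
(the regression linearises a mildly convex response).

## Synthetic data generator

The generator is the package's stand-in for the unavailable farm data: it
draws herd effects v_j and cow effects u_ij from their normals, herd-level
lameness incidence uniform on 0.10–1.88 cases/cow-year and herd mean yield
uniform on 4,776–11,008 L (the ranges observed across the source herds),
calving dates uniform over 2002–2008 so every year category is populated,
and walks each lactation through the 20–218 DIM bins sampling conception
from the true coefficients.  Censoring is a constant two-day cull hazard
tuned to 22%/year, independent of covariates (no informative-censoring
model is attempted).  Lactations surviving the whole window are recorded as
administratively censored at 300 DIM.  Lameness events are generated by the
simulator's bin mechanism and deduped before use, so the emitted event
table round-trips exactly through the restructuring rules; the generator's
internal bin walk is the oracle for the restructuring count tests.

With the packaged coefficients at the source study's scale (39 herds × 320
cows) the generated per-period conception proportion is ~1.35%, matching
the 1.34% observed in the source data.  Random-effect variances are not
published; the generator defaults are σ²_cow = 0.09, σ²_herd = 0.04 (modest
clustering: herd-level odds multipliers mostly within ±1.5-fold).

What passing tests show — and don't.  Parameter recovery on synthetic data
shows the fitting machinery is correct and its intervals calibrated *under
the model's own assumptions* (correct functional form, non-informative
censoring, exchangeable random effects, one lactation per cow).  Real herd
data violate several of these (repeat lactations per cow, informative
culling, seasonal calving structure, recording artefacts), so recovery
results do not certify performance on real data.  Likewise the PSA results
inherit every convention above: they quantify influence *within the
simulated world* defined by the uniform input ranges and the background
adjustment, which is exactly the question the analysis is designed to
answer, not a forecast for any particular herd.

## Problem sizes and numerical conventions

* PSA: 5,000 herds × 200 lactations (the analysis is stable from ~1,000
  herds; Spearman and share estimates move by <0.02 / <1 point between
  5,000-herd replicates).
* Parameter recovery: 30 herds × 300 lactations × 10 replicates
  (~500,000 risk periods per replicate).
* Newton tolerance: gradient ∞-norm < 1e-6·√n; step-halving line search;
  IRLS weights floored at 1e-12.  Nelder-Mead on log-variances with
  xatol = fatol = 0.05.
* Bernoulli lameness bin probabilities are clipped at 1 with a warning for
  extreme incidence × mass combinations.
* Degenerate cases: empty risk window (end before 20 DIM) → no periods;
  empty posterior-predictive subset → error; constant input column →
  Spearman reported missing; zero-conception herd → NaN mean DIM with the
  300-DIM scoring convention.

## Out of scope

Block-calving herds; culling for reasons other than failure to conceive;
economic discounting; breed effects; the original study's data-quality
auditing and stepwise model building; continuous-time (Cox) alternatives;
Sobol-type global sensitivity indices (the regression partition is the
method implemented).
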