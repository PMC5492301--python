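# Methods

This note documents the model, the numerical choices, and the limits of
what the synthetic validation demonstrates.

## Signal model and estimation

A CGM trace from sensor i of a session is modelled as

    CGM_i(t) = a_i(t) · IG(t) + b_i(t) + v_i(t),      IG = h_τ * BG,

with `h_τ(t) = (1/τ) e^(−t/τ)` (unit-area first-order kernel, τ in
minutes), polynomial gain `a_i` and offset `b_i` in t (minutes from the
first CGM sample of the session), and noise `v_i = cc + ssc_i` split into
a common and a sensor-specific stationary AR process.

**Kinetics discretization.** The convolution is realized as the exact
zero-order-hold recursion `IG[k] = e^(−dt/τ) IG[k−1] + (1 − e^(−dt/τ)) BG[k]`
initialized at steady state (`IG[0] = BG[0]`). It is unconditionally
stable, has exactly unit steady-state gain for every τ and dt, and
degenerates to the identity at τ = 0.

**Joint fit.** For each session, one shared τ and sensor-specific
polynomial coefficients are estimated simultaneously by unweighted
trust-region nonlinear least squares (`scipy.optimize.least_squares`,
tolerances 1e-10, τ ∈ [0.1, 60] min, started at τ = 10, a0 = 1, all other
coefficients 0). Parameter covariance comes from the Jacobian
linearization at the optimum with σ² = RSS/(N − p); the coefficient of
variation is CV = 100·SE/|estimate|, reported as missing when the estimate
is numerically zero. Unweighted least squares is deliberately retained
even though the noise is autocorrelated: estimates stay unbiased, and the
precision loss is part of the method being characterized. A consequence
worth knowing: per-session estimates of (a0, b0) trade off along a
direction with slope ≈ −mean(IG), so individual b0 estimates scatter by
tens of mg/dL even when the fit is good; only batch means are tightly
determined.

## Order selection

For every candidate (m, l) in 0..3 × 0..3 the per-sensor residuals are
whitened and scored with `BIC = d ln(RSS) + p ln(d)`, `p = m + l + 3`,
`d` the sensor's observation count, RSS the mean squared whitened
residual. Ordered pairs (LO, EHO) with p_LO ≤ p_EHO are compared through
ΔBIC = BIC_LO − BIC_EHO; pairs significant at α = 0.05 are ranked by
(% positive ΔBIC) × (mean ΔBIC) and the EHO of the top pair is selected,
falling back to the most parsimonious candidate when nothing is
significant.

Two design choices here deviate from the most literal reading of the
procedure, both forced by measurement:

1. **Common whitening filter.** Whitening each candidate's residuals with
   an AR model fitted *on those same residuals* absorbs smooth calibration
   misfit together with the serial correlation — any AR(≥2) predicts a
   slowly drifting series almost perfectly one step ahead — which erases
   the very signal order selection needs. The whitening AR (order by the
   AR-BIC criterion, capped at 15) is therefore fitted on the residuals of
   the *richest* candidate (m = l = 3), which are essentially pure noise,
   and applied as a fixed filter to every candidate. All candidates then
   undergo the same linear transformation, so their BICs are comparable
   and deterministic misfit survives into the RSS.

2. **Paired location tests.** BIC values are paired by session × sensor,
   and between-session BIC variation is an order of magnitude larger than
   the order signal, so unpaired two-sample tests have essentially no
   power. The default tests are the paired t-test when the ΔBIC sample
   passes a Shapiro–Wilk normality check and the Wilcoxon signed-rank test
   otherwise; `rank_models(..., paired_tests=False)` restores the
   unpaired variant.

Detection power for *smooth* polynomial drift is intrinsically limited:
the common noise component is a near-unit-root AR(3) whose spectrum is
large exactly at the low frequencies where polynomial drift lives. At the
population mean drift magnitudes, a 40-session batch yields a
constant-vs-linear mean ΔBIC of roughly 3–10 and selects the linear model
at most, but not all, seeds. This is a property of the problem, not a
defect of the implementation: sharper drift (larger |a1|, |b1|, or
calibration steps) is detected far more reliably.

## Noise modelling

Residual decomposition is the exact per-instant mean/deviation split
(cc = mean over sensors, ssc_i = res_i − cc), which reconstructs the
residuals identically and makes the ssc_i sum to zero. AR models are
estimated by conditional least squares (the minimized mean squared
one-step prediction error doubles as the innovation-variance estimate and
as the loss inside the AR-order BIC `N ln(lss) + k ln(N)`). Orders are
scanned over 1..15, reduced automatically to length/10 for short series
(a 97-sample session residual supports k ≤ 9). The population AR fit
pools the lag-regression rows of all series, dropping rows whose lag
window would cross a series boundary. Innovations are validated with the
Anderson–Darling composite-normality test at α = 0.05. Stationarity is
enforced at simulation time (distinct error) but only warned about at fit
time, since an explosive fit is itself a reportable finding.

## Error dissection

MARD = 100 · mean |test − ref| / ref, with the reference-side signal of
each pair as denominator: BG vs CGM (global), BG vs IG (kinetics), IG vs
IGS (calibration), IGS vs CGM (noise). IG and IGS are model
reconstructions from the fitted parameters, evaluated at the aligned CGM
instants. Instants where a reconstructed denominator is non-positive
(possible under strong negative offset drift at glucose lows) are excluded
from the ratios. The component MARDs need not sum to the global value —
cancellation between components is expected and not asserted. Glycemic
stratification assigns pairs by their reference value to <70, 70–180
(inclusive), >180 mg/dL; rate-of-change profiles are first differences of
the smoothed 1-min BG.

## Synthetic sessions

The generator emulates an 8-h standardized mixed-meal session: 1-min BG =
basal level (normal, mean 132, SD 12 mg/dL) + a log-normal-shaped meal
excursion (amplitude mean 140, SD 30 mg/dL; peak uniform in 50–90 min;
log-width 0.75) − a late counter-regulatory dip (amplitude mean 36, SD
28; center 340 ± 40 min; log-width 0.35) + three slow sinusoids (RMS
8 mg/dL, periods 90–240 min) + two faster oscillations (amplitude 3.8,
periods 35–70 min). Draws whose nadir would cross 40 mg/dL are redrawn
(a supervised inpatient session would be rescued before that), making the
ensemble a truncated distribution. These amplitudes were chosen so the
default ensemble reproduces the study's descriptive statistics — ≈97.8%
of samples at or above 70 mg/dL, roughly a third above 180, and ≈77% of
1-min rates within ±1 mg/dL/min — and they are fixed; they are shape
conventions, not fitted physiology.

CGM traces are sampled every 5 min (configurable) through the full error
chain with AR noise simulated on the CGM grid (500-sample burn-in,
Gaussian innovations); the final CGM output is clipped at 0. Reference
samples follow the noiseless BG at whole-minute instants with gaps
uniform in [10, 20] min; reference measurement error is off by default
(laboratory analyzer treated as gold standard) and available as a
proportional SD. Population sampling draws per-session parameters from
the published means/SDs; τ is resampled until positive (lifting its mean
to the zero-truncated value ≈10.4) and gain polynomials are redrawn until
positive over the horizon (lifting mean a0 to ≈1.18 — the published
marginals are mutually incompatible with always-positive gain, so exact
mean reproduction under the positivity constraint is impossible).
Deliberately not modelled: physiological meal/insulin dynamics,
recalibration steps, pressure artifacts, dropout beyond the QC
gap-injection helper.

What passing the synthetic suite does **not** show about real data: real
calibration drift need not be polynomial (recalibration events create
steps), real noise need not be Gaussian or stationary across the wear
period, and the reference instrument has error. The suite shows the
estimators recover the truth *when the model is the generator* — the
appropriate standard for validating the pipeline itself.

## Reference smoothing

Sparse reference values y at instants t are turned into a 1-min profile x
by minimizing ‖Ax − y‖² + λ‖D₂x‖² (A: linear interpolation onto the
sample instants; D₂: second difference). Constants and straight lines are
in the penalty null space and reproduced exactly. With
`roughness_penalty="auto"`, λ is chosen by the discrepancy criterion —
bisection until the residual sum of squares equals Σ(assumed SD)², with
the assumed SD a configured fraction of each reading (2% by default,
typical laboratory precision). When the configured reference error is
zero the criterion degenerates and the smoother returns the
minimum-roughness interpolant (λ floor 1e-8); the pipeline wires the
generator's reference-error setting into the smoother so synthetic runs
use the correct assumed error by construction.

## Quality control

Sessions are excluded for structural inconsistency between traces, a
contiguous missing-CGM run longer than 30 min ("signal loss"), or
coverage below 90%. The thresholds are conventions — the study this
emulates reports only that three sessions were removed for signal loss —
and are configurable. `make_study_fixture` reproduces the study layout
(40 sessions, 10 subjects, two sensors; exactly 3 sessions carry an
injected 60-min gap) for worked-example tests.

## Problem sizes

Validation runs use desk-scale sizes chosen to keep Monte-Carlo error
well below the tolerances being checked: 10^5 samples for population AR
recovery (coefficient SE ≈ 0.003), 50 × 5,000 samples for order-mode
checks, 40 sessions × 16 model orders for the pipeline batch, and 200
sessions for generator ensemble statistics.
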