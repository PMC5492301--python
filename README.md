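# cgmdissect

Dissection of continuous glucose monitor (CGM) sensor error into its three
physical components — blood-to-interstitium kinetics, time-varying
calibration error, and autoregressive measurement noise — for meal-test
sessions in which several sensors are worn in parallel, plus a synthetic
session generator with known ground truth so every stage of the analysis
can be validated by parameter recovery.

## Who this is for

Researchers characterizing CGM accuracy (e.g. for artificial-pancreas
simulation, denoising, or non-adjunctive-use assessment) who have paired
data from inpatient sessions: n ≥ 2 parallel CGM traces sampled every 1–5
minutes and sparse laboratory reference blood glucose (BG) drawn every
15 ± 5 minutes over ~8 hours.

## The model

Each CGM trace is modelled as

    CGM_i(t) = a_i(t) · (h_τ * BG)(t) + b_i(t) + cc(t) + ssc_i(t)

where

- `h_τ(t) = (1/τ) e^(−t/τ)` is the first-order blood-to-interstitium
  kernel with time constant τ (minutes) — the sensor "time lag";
- `a_i(t) = Σ_k a_ik t^k` and `b_i(t) = Σ_k b_ik t^k` are sensor-specific
  polynomial gain and offset of degrees m and l, capturing calibration
  error and sensitivity drift;
- `cc(t)` is the residual noise component common to all sensors worn by
  one subject, and `ssc_i(t)` is the sensor-specific remainder; both are
  stationary AR processes with Gaussian innovations.

The pipeline: (1) quality-control sessions (signal loss, coverage);
(2) smooth the sparse reference into a 1-min BG profile with a
second-order-difference Tikhonov smoother; (3) estimate τ (shared) and the
polynomials (per sensor) jointly by nonlinear least squares for every
(m, l) in 0..3 × 0..3; (4) whiten the residuals and select (m, l) by a
statistical ranking of ΔBIC = BIC_LO − BIC_EHO, scored by (% positive) ×
(mean ΔBIC); (5) split the residuals into cc and ssc_i, select the AR
orders with a BIC over orders 1..15, validate innovations with the
Anderson–Darling test, and fit pooled population AR processes; and
(6) quantify global error and each component by MARD (mean absolute
relative difference), stratified by glycemic range and rate of change.

## Worked example

```python
import numpy as np
from cgmdissect import (PopulationConfig, RunConfig, run_pipeline)

# every session at the published mean linear model (no population spread)
pop = PopulationConfig(tau_sd=0, a0_sd=0, a1_sd=0, b0_sd=0, b1_sd=0)
cfg = RunConfig(seed=0, simulate=True, n_sessions=40,
                population=pop, out_dir="demo_run")
result = run_pipeline(cfg)

fits = result.fits[result.selected_order]
print("selected order:", result.selected_order)
print("mean tau_hat:", round(np.mean([f.tau_hat for f in fits]), 2), "min")
print("top pair p-value:", float(result.ranking.p_value.iloc[0]))
```

prints

```
selected order: (1, 1)
mean tau_hat: 10.09 min
top pair p-value: 0.0004154538567928172
```

i.e. the ΔBIC ranking identifies the generative linear calibration model
(m = l = 1), the recovered mean time lag is within Monte-Carlo error of
the generative 9.4 min, and the constant-vs-linear comparison is strongly
significant. `demo_run/` then contains the QC report, per-order fits,
the ΔBIC ranking, noise variance and MARD dissection tables, and a
manifest with the seed and selected orders.

A command-line interface mirrors the stages:

```bash
cgmdissect simulate --n-sessions 40 --seed 1 --out sessions/
cgmdissect run-all --seed 1 --n-sessions 40 --out run/
```

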