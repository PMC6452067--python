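# sonarcee

Analysis tools for **multi-scale controlled exposure experiments (CEEs)** on
deep-diving toothed whales: quantifying whether, when and how strongly a
tagged whale responds to naval-sonar transmissions, from high-resolution
biologging tags, satellite tags and moored passive-acoustic recorders
observed during the same exposure. The intended users are marine-mammal
behavioural ecologists and bioacousticians analysing CEE datasets — or, since
such field data are rarely public, validating analysis choices on simulated
data with known ground truth, which this package generates for every stage.

## What it computes

* **Tag features** — pitch/roll/heading from accelerometer + magnetometer,
  temperature-corrected depth, flow-noise speed (depth > 5 m), depth
  inflections, circular variances, pitching movement, ODBA, and per-pulse
  received SPL (max 200 ms RMS, dB re 1 µPa).
* **Change-point detection** — multivariate features are collapsed into
  Mahalanobis distances MD(w) = √((w−μ)ᵀΣ⁻¹(w−μ)) between 15-min window
  means and the pre-exposure baseline; the detection threshold is the 95th
  percentile of maxima over resampled baseline stretches, and the
  change-point is the first post-exposure window at or above it.
* **Response intensity** — a gamma GLM-style model of binned MDs,
  RI = β₀ + β₁L·e^{β₂(τ−t)}·(1+β₃R) after exposure and β₀ otherwise, with
  L = SPLmax − 79 dB, R = source distance; the full model and seven
  reductions (γ for β₁L, no decay, no distance) are compared by AIC.
* **Movement HMM** — 3-state hidden Markov model of hourly step lengths
  (gamma) and turn angles (von Mises) from speed-filtered satellite tracks,
  with time-to-recovery × SPLmax/distance covariates on transitions out of
  the tortuous state; AIC selection (simplest within ΔAIC < 2) and Viterbi
  decoding.
* **PAM click detection** — guard-band energy detector on normalized PSD
  frames (echo band 20–40 kHz minus guard band 4–8 kHz, top-1%-of-frames
  statistic per 2.5-min segment) plus a click-absence outlier test against
  the baseline 95th percentile.
* **Acoustic dose** — Monte-Carlo propagation of positional and depth
  uncertainty through a spherical-spreading + absorption model, yielding
  per-pulse SPL intervals and SPLmax with a 90% CI.

See `docs/methods.md` for model details, parameter conventions and
limitations.

## Worked example

Fit the response-intensity model family to a simulated CEE population
(4 exposed + 10 baseline whales, 10 bins each, true β₀ = 1, β₁ = 0.12,
ω = 4):

```python
from sonarcee import simulate as sim, response_intensity as ri

d = sim.simulate_ri_dataset(beta0=1.0, omega=4.0, beta1=0.12, seed=42)
spec = ri.RiModelSpec(include_decay=False, include_distance=False)
res = ri.ResponseIntensityModel(d, spec).fit()
print(res.summary())
```

```
Response-intensity model (gamma likelihood)
  spec: L   n=140   floored=0
  logLik=-124.192   AIC=254.384   k=3
  converged: True
  parameter   estimate    std.err
  beta0         1.0125     0.0457
  beta1         0.0985     0.0128
  omega         4.2380     0.4879
```

The truth (1.0, 0.12, 4.0) is recovered within ~2 standard errors. Ranking
all nine candidate models:

```python
tab = ri.compare_models(d, ri.MODEL_FAMILY + (ri.INTERCEPT_ONLY,))
print(tab.drop(columns=["results"]).round(2).to_string(index=False))
```

```
         model  k     llf    aic  converged  delta_aic     support
             L  3 -124.19 254.38       True       0.00 substantial
             g  3 -124.38 254.77       True       0.38 substantial
        g+dist  4 -123.65 255.30       True       0.92 substantial
        L+dist  4 -123.89 255.79       True       1.40 substantial
       L+decay  4 -124.19 256.38       True       2.00        some
       g+decay  4 -124.38 256.77       True       2.38        some
  g+decay+dist  5 -123.65 257.30       True       2.92        some
  L+decay+dist  5 -123.89 257.78       True       3.40        some
intercept-only  2 -201.89 407.78       True     153.40      little
```

The received-level model (`L`) ranks first and the intercept-only model is
rejected by ΔAIC ≈ 153 — the simulated whales' post-exposure behaviour is
overwhelmingly better explained with an exposure effect.

An end-to-end simulated experiment (tag record → features → change-point →
dose → HMM → PAM report) runs from one seed:

```bash
sonarcee run --seed 3 --out report_dir
```

or in Python via `sonarcee.pipeline.run_experiment(SimConfig(...))`.

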