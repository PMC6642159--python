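# chronopk

Circadian physiologically-based pharmacokinetics of P-glycoprotein
substrates in mice.

P-glycoprotein (P-gp/ABCB1) is an efflux transporter that limits
intestinal drug absorption and drives biliary and renal excretion. Its
expression and activity oscillate over the day and differ by sex and
feeding state, so the disposition of a pure P-gp substrate such as the
beta-blocker talinolol depends on the Zeitgeber time (ZT, hours after
light onset) of dosing. `chronopk` implements the full quantitative
workflow for such a chronoPK study:

* **Rhythmometry** — multi-harmonic cosinor fits
  `y(t) = M + Σ_k A_k cos(2π(t − φ_k)/T_k)` at T = 24, 12, 8 h with
  zero-amplitude F-tests, and damped-cosine fits
  `y(t) = 1 + A e^(−λt) cos(2π(t − φ)/T)` to detrended, mean-normalised
  ex-vivo bioluminescence recordings.
* **PBPK model** — a mass-conserving ODE model of oral talinolol
  (gut lumen, ileum mucosa, plasma, liver; renal and fecal elimination)
  whose efflux and clearance rate constants carry multiplicative cosine
  modulation `r(t) = mesor·(1 + Σ α_k cos(2π(ZT(t) − φ_k)/T_k))`.
* **Calibration** — weighted least squares
  (`w_m = 1/mean(obs_m)²` per matrix) over joint ZT3 + ZT15 datasets,
  minimised by an in-package CMA-ES with incumbent restarts, plus
  Monte-Carlo resampling of the destructive sampling design (one mouse
  per time point per virtual dataset) for parameter SDs.
* **Sensitivity** — Saltelli cross-sampling on a scrambled Sobol
  sequence and Jansen total-order indices (bootstrap SDs) for liver and
  ileum AUC(0–8 h), with the dosing ZT as a sampled factor.
* **PK summaries** — combinatorial curve construction for destructive
  sampling (all one-mouse-per-time-point combinations, e.g. 4⁶ = 4096
  curves for 4 mice × 6 times) with trapezoidal AUC(0–8 h) and Cmax
  means and SDs.
* **Synthetic data** — generators for all three experiment designs
  (grouped expression, two-ZT talinolol PK, dense bioluminescence) with
  documented noise structure, so every stage is testable end to end.

The library is organised statsmodels-style: model classes (`Cosinor`,
`DampedCosine`, `TalinololPKModel`) are built from data and their
`fit()` returns results objects carrying estimates, uncertainties and a
`summary()`. A thin `chronopk` CLI covers the pipeline stages
(`synthesize`, `cosinor`, `damped-cosine`, `simulate`, `auc`, `fit`,
`mc-fit`, `sensitivity`).

## Worked example

Fit a cosinor to synthetic ileum Abcb1a expression data generated at a
62%-of-mesor relative amplitude with 20% CV noise, then simulate the
PBPK model:

```python
import chronopk as cp
from chronopk.presets import abcb1a_cosinor, reference_params

data = cp.gen_expression(cp.ExperimentDesign(), abcb1a_cosinor("F"),
                         cp.NoiseModel(), seed=1)
fit = cp.fit_cosinor(data)
print(fit.summary())
```

```
Cosinor fit
===========
n_obs        40
mesor        0.985721
residual SS  1.33678

period (h)    amplitude  2xamplitude  acrophase (h)          p
        24      0.57375       1.1475          10.58   1.78e-13
        12     0.015335      0.03067          5.827      0.944
         8     0.063116      0.12623          2.461      0.385
```

The 24 h component is highly significant (amplitude 0.574 on a mesor of
0.986, i.e. a relative amplitude of 58% against the generating 62%,
peaking at ZT10.6 against the generating ZT10.5); the 12 h and 8 h
harmonics are correctly non-significant.

```python
sim = cp.simulate(reference_params(), cp.DoseEvent(zt_dose=3.0), t_end=8.0)
print(round(cp.mass_balance_residual(sim), 12),
      round(cp.model_auc(sim, "ileum"), 1))
```

```
0.0 11015.5
```

Total drug equals the administered 2500 µg dose to solver precision at
every time point, and the ileum AUC(0–8 h) is 11016 µg·h/g for a ZT3
dose.

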