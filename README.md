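# ssie

Models for predicting the daily water consumption of greenhouse crops from
solar radiation alone, built around the **Stochastic Segmentation of input
Energy (SSiE)** family, a simplified **GreenLab** tomato simulator, and the
estimation, identifiability and forecasting machinery that goes with them.

## The problem

In hydroponic greenhouses, per-plant water consumption
`W_c(t) = (V_irr(t) − R_off(t)) / n` (irrigation minus collected runoff over
the plants of a station) is measured once per day, alongside routine
meteorology.  Water uptake is closely proportional to biomass production,
which in turn depends on how much of the incoming radiation the canopy
intercepts.  When no destructive plant measurements are available, a full
crop model cannot be calibrated — but the *light interception ratio* (LIR)
leaves a footprint in the consumption record itself.

The SSiE idea: treat the day's radiative input `E(t)` as a large number of
elementary quanta, each absorbed independently with probability `LIR(t)`, and
let the LIR be the CDF of a positive random variable `X` evaluated at the
cumulated consumption before `t`:

```
W_c(t) ~ N( θ1 · E(t) · F_X(SW_c(t⁻)),  σ² ),      SW_c(t⁻) = c0 + Σ_{s<t} W_c(s)
```

`θ1` absorbs the radiation-use efficiency, the projected plant surface, the
biomass-to-water proportionality and the greenhouse transmission.  Choosing
`F_X` exponential recovers a Beer–Lambert law; the package also implements
gamma, Mittag-Leffler (the *fractional* Beer–Lambert law, with a dedicated
high-accuracy `E_a(x)` implementation), log-normal and Pareto interception
laws, plus two recurrence models driven by the green-biomass coefficients of
a simplified GreenLab tomato simulator, and a linear autoregressive baseline
`W_c(t) = b0 + b1 W_c(t−1) + b2 E(t)`.

All stochastic models are fitted by multi-start bounded maximum likelihood
(L-BFGS-B, noise sd profiled analytically) and compared by AICc/BIC; one-day-
ahead predictive skill is scored by RMSPE under an expanding-window protocol
with per-step refitting, optionally with noisy radiation forecasts.  A
practical-identifiability module generates virtual observations from the
compartmental (blade/body) simulator and maps the set of
likelihood-equivalent parameter combinations.

## Worked example

Everything below is reproducible — no external data is needed; the
synthetic-data module generates a greenhouse-like 54-day season (radiation
marginals calibrated to a Mediterranean summer, consumption from an
exponential-SSiE mechanism started at `c0 = 0.4` L):

```python
import numpy as np
import ssie

records = ssie.default_dataset(seed=7)           # 54 daily records
e = np.array([r.e_avg for r in records])          # W/m^2
w = np.array([r.w_c for r in records])            # liters/day

fits = [ssie.fit_mle(f, e, w, n_starts=200, seed=1, c0=0.4)
        for f in ("exp", "gamma", "lognorm", "pareto")]
print(ssie.compare_models(fits).to_string(index=False))

fc = ssie.expanding_forecast(e, w, "exp", n_starts=100, seed=2, c0=0.4)
print("m =", fc.m, " RMSPE =", round(fc.rmspe, 3))
```

which prints:

```
 family    loglik     rmse  k        bic       aicc
    exp 27.620394 0.145086  3 -43.273836 -48.760789
lognorm 28.000344 0.144069  4 -40.044752 -47.184361
  gamma 27.652328 0.145000  4 -39.348719 -46.488328
 pareto 26.842036 0.147193  4 -37.728135 -44.867745
m = 24  RMSPE = 0.163
```

Read: on data generated by an exponential-SSiE mechanism, the exponential
family wins by BIC (−43.27; `k` counts `θ1`, the interception parameters and
`σ`); the richer families buy a slightly higher log-likelihood but pay the
extra-parameter penalty.  The 55 % expanding-window split of a 54-day series
leaves `m = 24` one-step-ahead predictions, whose root mean square prediction
error (0.163 L/day) sits at the level of the generator's observation noise —
the irreducible error floor.

The same workflow is available from a shell:

```sh
ssie synth --n-days 54 --seed 7 --out season.csv
ssie fit --input season.csv --family exp --starts 200 --seed 1 --c0 0.4 --out exp.json
ssie forecast --input season.csv --family exp --starts 100 --seed 2 --c0 0.4
ssie identifiability --scenario 2 --starts 200 --seed 3
```

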