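# Methods

This note documents the models implemented in `ssie`, the choices made where
the design was genuinely open, the defaults of the synthetic-data generator,
and the package's numerical and statistical conventions.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Observation model and SSiE family

All predictive models share a homoskedastic Gaussian observation structure
for daily (or per-cycle) water consumption `W_c(t)`:

* **SSiE**: `W_c(t) ~ N(θ1·E(t)·F_X(SW_c(t⁻)), σ²)` where `E(t)` is the
  average solar radiation, `SW_c(t⁻) = c0 + Σ_{s<t} W_c(s)` the cumulated
  consumption strictly before `t` (offset by the pre-observation consumption
  `c0 ≥ 0`), and `F_X` one of five CDF families:
  exponential `1 − e^{−k·sw}`; gamma (regularized lower incomplete gamma,
  rate `k`, shape `a_γ`); Mittag-Leffler `1 − E_{a}(−(k·sw)^a)` with tail
  order `a ∈ (0,1]`; log-normal `(µ_log, σ_log)`; Pareto
  `1 − (η/sw)^θ` for `sw > η` and 0 otherwise (kept 0 at or below `η` so the
  spec remains a valid CDF).
* **Recurrence models**: `mean = θ1·E(t)·(1 − exp(−θ2·Σ_{n<t} r(n)·W_c(n)))`
  with `r(n)` the proportion of green (blade) to totally produced biomass.
  Two sources for `r`: a reference GreenLab simulation at the published
  tomato values (*GreenLab exp*: only `θ1, θ2` free), or the parametric
  family `r(t) = t^a / I(a)`, `I(a) = t_max^{a+1}/(a+1)` (*exp + rate*:
  `θ1, θ2, a` free, `a > −1`).
* **LR baseline**: `W_c(t) = b0 + b1·W_c(t−1) + b2·E(t) + ε`, ordinary least
  squares on rows `t ≥ 2`.

`θ1` (liters per radiation unit) absorbs RUE·S_p·µ0 together with the
greenhouse transmission coefficient; the compensation between `θ1` and the
scale of the LIR is exact in the likelihood (multiplying all `E(t)` by `c`
and dividing `θ1` by `c` changes nothing), which is why only products of
these quantities are ever interpreted.

**First observation.** When `c0 = 0` the first point of a series has an
empty history (`F_X(0) = 0` for every family except Pareto, where it is 0
anyway below `η`), so its mean is structurally zero; by default it is
excluded from the likelihood (it still feeds the cumulative sum), matching
an n of one less than the series length.  With `c0 > 0` the first point is
informative and is kept.  Recurrence models always drop the first point.

## 2. Estimation

The noise sd is profiled analytically: for any mean parameterization,
`σ̂² = RSS/n` and the concentrated log-likelihood is
`ℓ = −(n/2)(1 + ln(2π·RSS/n))`, so the numerical search runs over the mean
parameters only.  The in-sample RMSE therefore *equals* `σ̂` by construction,
and `σ` counts as one estimated parameter in
`BIC = −2ℓ + k·ln n` and `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` — a convention
that also makes the reported `(ℓ, σ)` pairs mutually consistent through
`σ̂ = sqrt(exp(−2ℓ/n − 1)/(2π))`.

Maximum likelihood uses bounded L-BFGS-B (up to 200 iterations) from
`n_starts` starting points drawn uniformly inside the bounds box with a
seeded generator; the best optimum is kept and the whole procedure is
bit-reproducible given the seed.  Default boxes: `θ1, θ2 ∈ (1e−6, 10]`,
`k ∈ (1e−6, 10]`, `a_γ ∈ (0.01, 20]`, `a_ML ∈ (0.01, 1]`,
`µ_log ∈ (−5, 10]`, `σ_log ∈ (1e−3, 20]`, `θ ∈ (1e−8, 50]`,
`η ∈ (1e−3, 5]`, `a ∈ (−0.99, 5]`; all overridable per call.  The RSS is
floored at `n·1e−24` so noiseless (simulated) data keeps the concentrated
likelihood finite.  Two optima are treated as "the same solution" when their
log-likelihoods differ by less than 1e−3 (absolute), the tolerance reused by
the identifiability module.  Negative fitted means are allowed inside the
likelihood (the model is Gaussian); point forecasts can optionally be
clamped at zero (off by default).

## 3. Mittag-Leffler numerics

`E_a(x) = Σ_j x^j/Γ(ja+1)` is evaluated for `a ∈ (0,1]` on the argument
range reachable from LIR evaluation (`x = −(k·sw)^a ≤ 0`; positive
arguments are served up to `x = 2` for cross-checks).  Branches, with
`t = −x`:

* `a = 1`: `exp(x)` exactly.
* `|x| ≤ 1` (a ≥ 0.35): fixed 64-term vectorized Taylor sum (tail
  < 1/Γ(0.35·64+1) ≈ 1e−21).
* `t ≥ 35^a` and `0.35 ≤ a ≤ 0.999`: asymptotic series
  `Σ_k (−1)^{k−1} t^{−k}/Γ(1−ka)`, written pole-free via the reflection
  formula and truncated at the minimum of the smooth envelope
  `t^{−k}Γ(ka)/π` (~`e^{−t^{1/a}}`, which also bounds the remainder; a
  convergence error is raised if the bound exceeds 1e−11 of the value).
  The expansion needs ~35/a terms, hence the lower limit on `a`; and it
  omits a beyond-all-orders `e^{−t}` contribution that becomes relatively
  significant as `a → 1`, hence the upper limit.
* everything else: Gauss-Legendre quadrature of the spectral (completely
  monotone) representation
  `E_a(−t) = (sin aπ/π)∫_0^∞ e^{−r·t^{1/a}} r^{a−1}/(r^{2a}+2r^a cos aπ+1) dr`,
  rewritten with `y = r^a` so the integrand is bounded.  For `a ≥ 0.35`
  composite panels merge a geometric grading (resolving the
  `e^{−(ty)^{1/a}}` decay layer) with panels scaled to the kernel's
  Lorentzian half-width `sin aπ` around `y = −cos aπ`, extended by factors
  of 4 so the algebraic tails stay resolved as `a → 1`.  For `a < 0.35` the
  exponential factor is a near-step at `y = 1/t`; the integral is computed
  in the scaled variable `z = ty` (nodes shared across the whole argument
  vector) with a closed-form arctangent head where the factor is 1 to
  machine precision.

During development the three branches were validated against 60-digit
arithmetic on a dense `(a, t)` grid covering `a ∈ [0.01, 1−10⁻⁵]` and the
full reachable argument range; the observed worst relative error was below
1e−10, and frozen high-precision reference values are asserted in the test
suite.  The only known soft spot is `a` within ~1e−9 of 1 at `t ≫ 10`,
where relative accuracy degrades to ~1e−5 on values of order `e^{−t}`
(absolutely ~1e−19 — irrelevant at LIR scale).  The independent small-
argument oracle (`mittag_leffler_series`) carries a rigorous
truncation-plus-roundoff bound and raises instead of returning a silently
inaccurate value.

## 4. GreenLab tomato simulator

Organogenesis is a deterministic automaton: one phytomer
(blade + petiole + internode) appears per development cycle (CD); after
`n_vegetative = 8` vegetative phytomers, a truss of `fruits_per_truss = 3`
fruits appears on every `truss_period = 3`rd phytomer (phytomers 9, 12, 15,
…).  Flowers and fruits are one organ; the fruit expansion clock starts at
the phytomer's birth cycle.  The phyllochron is fixed at 2 days (the
recorded thermal regime, ~10 °Cd per phytomer above a 12 °C base, makes it
stable); thermal-time-driven variable phyllochron is out of scope.

Each organ draws biomass from a common pool proportionally to
`p_o · f_o(u/T_o)`, where `f_o` is a discretized beta profile over the
expansion span `T_o`: the kernel `x^{a−1}(1−x)^{b−1}` evaluated at age-bin
midpoints `(j+0.5)/T_o` and normalized to sum 1 (normalization makes the
shape-mapping choice affect only the profile's shape, never the organ's
lifetime demand).  The single published sink-variation parameter `B_o` is
mapped to shapes by `(a_o, b_o) = (5B_o, 5(1−B_o))`, which preserves the
tomato constraint `a_o + b_o = 5` for any `B_o ∈ (0,1)`; the mapping is a
hook so alternatives (e.g. mode-based) can be swapped in.

Production follows Beer–Lambert:
`Q(t) = E(t)·RUE·S_p·(1 − exp(−k·S_L(t)/S_p))` with `S_L = SLA ×` blade
mass; allocation of `Q(t−1)` at cycle `t` conserves biomass exactly and the
per-cycle allocation fractions are invariant to the radiation series (the
pool size cancels).  There is no senescence and no root compartment.

Defaults are the published tomato values (`p_b:p_p:p_e:p_f =
1:1.09:0.93:61.3`, `B = 0.43/0.45/0.38/0.36`, `T = 10/10/8/15` CDs,
`S_p = 5047 cm²`, `k = 0.8`, `RUE = 0.05`).  Two quantities have no
published value and are simulator choices, fixed once: `SLA = 150 cm²/g`
(mid-range for greenhouse tomato leaves) and seed biomass `Q0 = 0.2 g`.
Neither affects allocation fractions.

The compartmental simplification (*comp1*) merges petiole, internode and
fruit into one "body" sink per phytomer, with strength `p_body`, its own
beta shape (`a_body + b_body = 5`) and expansion span `max(T_p,T_e,T_f) =
15` CDs; it adds the observation map `W_c = µ0·Q(t) + N(0, σ²)` with
defaults `µ0 = 2·10⁻⁵ L/g` (puts expected consumption at the ~1 L/day scale
for the default radiation), `σ = 0.1 L`.

**Blade allocation level — known limitation.**  Published greenhouse-tomato
simulations report the fraction of biomass allocated to blades during the
observation window (plant days 39–92) as nearly constant in 0.21–0.24.
Under the sink parameterization above, the per-cycle blade fraction in that
window is ≈ 0.015–0.016: once ~5 trusses expand simultaneously, fruit
demand (61.3 per fruit × 3 fruits per truss, against 3.02 for a whole
vegetative phytomer) dominates the pool, and no beta-shape convention can
change this — sampling any sum-normalized profile at every third age
averages one third of its mass.  The cumulative green/total ratio (the
`r(n)` of the recurrence models) starts near 1/3 and declines through the
window instead of holding a plateau.  The published band evidently reflects
a structurally richer reference simulation (pruning/senescence included);
this simulator reports what its own dynamics produce, and
`scripts/acceptance.py` prints those values rather than the published ones.

`r(n)` is taken as the *cumulative* blade/total-produced ratio (the wording
"proportion of green to the totally produced biomass"), extracted from a
reference simulation under constant radiation (574 per cycle — two days of
average summer radiation); the per-cycle allocation fraction is also exposed
on the trajectory for diagnostics.

## 5. Day-to-cycle aggregation

Within each block of `phyllochron = 2` days, consumption is combined with
weights proportional to each day's radiation (the plain mean when the
block's radiation is all zero, with a warning), while radiation is summed so
`E(t)` is the cycle's total input — production treats `E(t)` as the cycle's
radiative input, and summation keeps total radiation conserved across the
aggregation.  Both choices are switchable (`w_mode`, `e_mode`).  A trailing
partial block is dropped by default (weights at the series end would be
biased); `keep-partial` retains it.  Missing consumption days inside a
fitting window are rejected rather than imputed — the likelihood assumes a
complete series.

## 6. Forecasting protocol

The initial training window is `round_half_up(0.55 · length)` days (30 of
54); at each step the model is refitted by multi-start MLE on the current
window, the next day's mean is computed from that day's radiation and the
observed history, the true observation is appended, and the window grows by
one day to the end of the series (`m = 24` predictions for a 54-day
series).  Under the noisy-radiation setting, `N(0, sd²)` noise (default
`sd = 20 W/m²`, floored at zero) is applied *only* to the radiation of the
day being predicted — it models an imperfect radiation forecast for the
upcoming day — while the training window always uses recorded values (the
alternative, perturbing training radiation too, is switchable by perturbing
the input series upstream).  Per-step fit seeds and noise draws derive from
one seed through a `SeedSequence`, making the whole procedure reproducible
and leakage-testable (poisoning future observations cannot change earlier
predictions).  Reference protocol start counts are 1000 per step (20 for
the Mittag-Leffler family, whose evaluation is the most expensive); the test
suite runs 6–25 starts per step, which the one-step means tolerate because
the per-window likelihoods are low-dimensional.

## 7. Identifiability analysis

Virtual observations are drawn from a known comp1 truth
(`B_b = 0.43, B_body = 0.45, p_body = 3.0, µ0 = 2·10⁻⁵, σ = 0.1`; 46 cycles
of weather-generator radiation) and a multi-start bounded search is run with
a chosen free subset; `SLA, S_p, RUE, Q0` are always fixed (absorbed by
`µ0`).  Scenario 2 additionally fixes `p_body`; scenario 1 frees it.  All
optima within 1e−3 log-likelihood of the best are accepted.  Because
finite-difference gradients stall on the near-degenerate ridge slightly
above that tolerance, accepted candidates are first polished with a
derivative-free simplex pass (candidates within 0.05 of the best); without
it the accepted set fluctuates with the tolerance cliff rather than tracing
the solution manifold.  Distinct solutions are deduplicated at Euclidean
distance 1e−4 in bound-normalized parameter space (no published definition
of distinctness exists); `p_body` is reported normalized by its upper bound.
A parameter is flagged practically identifiable when its accepted-solution
range is within 10 % of its reference value.  The reference start count is
5000; the test suite uses 200 and treats spread findings as qualitative at
that scale.

## 8. Synthetic data generator

The generator emulates a Mediterranean-summer greenhouse season:

* **Radiation**: stationary AR(1) (autocorrelation 0.6 — daily weather is
  persistent; the value is a modelling assumption, not an observed
  quantity, and is a config knob) around mean 286.944 W/m² with marginal sd
  45.844, clipped to the observed range [114.59, 340.31].  Clipping pulls
  the long-run mean down by ~1 %, within the 5 % calibration band checked
  by the tests.  Daily maxima, temperature, humidity and pressure are
  filled from matching clipped-normal marginals with consistent
  min ≤ avg ≤ max ordering.
* **Consumption**: generated sequentially from a chosen mechanism — an SSiE
  model (each day's mean uses the already-generated history), the comp1
  simulator (per-cycle expected consumption split across the cycle's days
  by radiation share), or the LR recursion — plus Gaussian noise.  Negative
  draws are clipped at zero by default (the measurement process cannot
  produce them) with the clip count logged; a resample policy is available.
* **Default fixture**: 54 days starting at plant day 39 with an
  exponential-SSiE mechanism, `θ1 = 0.005`, `k = 0.8 /L`, `c0 = 0.4 L` (the
  pre-observation cumulative consumption suggested by the Pareto scale
  reading), `σ = 0.15 L`.  These values put saturated daily uptake near
  1.4 L at average radiation and keep ≥ 99 % of generated days inside the
  observed [0.09, 2.25] L range — a calibration property, not an exact
  claim.

What the generator does *not* emulate: greenhouse microclimate physics,
radiation transmission variability, sensor drift, irrigation-schedule
artifacts, heteroskedastic or autocorrelated measurement noise, or any
feedback from plant state to microclimate.  Passing recovery and forecast
tests on these data therefore demonstrates correctness of the estimation
machinery under the models' own assumptions, not predictive validity on real
greenhouse records.

## 9. Test-scale choices

The recovery study refits each SSiE family on 50 independently generated
200-cycle datasets (noise sd 0.05) with 100 starts (20 for Mittag-Leffler,
mirroring the reference protocol's reduced count for that family).
Tolerances on the median relative errors were calibrated once by a pilot
Monte-Carlo at exactly these conditions and carry more than 2.5× headroom;
the Pareto tail pair `(θ, η)` trades off along a near-flat likelihood ridge
on occasional draws — the same weak identifiability expected of Pareto
tails — which is why its tolerances are the widest and why medians, not
maxima, are asserted.  Forecast tests use 6–25 starts per step and series of
20–54 days; identifiability tests use 200 starts.
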