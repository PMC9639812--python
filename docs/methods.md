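# Methods

## The two-compartment OD model

A batch culture carries two optical compartments: living mass `L(t)` and
dead mass `D`. On exposure to an autotoxin dose, a fraction `d` of the
inoculum `a0` dies instantaneously, and the dead mass neither grows nor
lyses:

```
D        = a0·d                         (constant)
dL/dt    = 0                            for t < λ   (survivor lag)
dL/dt    = r·L·(1 − (L + D)/K)          for t ≥ λ
OD(t)    = L(t) + D                     (what the turbidimeter reports)
```

With inert dead mass the logistic has effective cap `K' = K − D` and rate
`r' = r·K'/K`, so `L(t)` is closed-form and so is the delay statistic —
the time at which OD reaches `2·a0`:

```
τ = λ + (K / (r·(K − a0·d))) · ln[ ((2−d)/(1−d)) · (K − a0)/(K − 2·a0) ]
```

which reduces to `τ = λ + ln((2−d)/(1−d))/r` as `K → ∞`. `tau_forward`
implements the exact form (it matches root-finding on the simulated
trajectory to machine precision at any cap); the simple exponential-regime
form is the basis of the closed-form inversion
`d̂ = (e^{r(τ−λ)} − 2)/(e^{r(τ−λ)} − 1)` in `death.estimate_death_from_curve`,
which can alternatively invert the exact form numerically when the growth
parameters are supplied.

Assumptions: killing is instantaneous at exposure (the dose acts on the
inoculum, not continuously); dead cells retain full optical cross-section
indefinitely; survivors grow at the unperturbed rate after an optional lag
(default `λ = 0`). A continuous death-rate variant is deliberately out of
scope.

## Dose response and conditioned-medium calibration

The kill fraction of unadapted cells follows a Hill curve below a hard
critical concentration and is complete above it:

```
d(c) = d_max · cⁿ/(cⁿ + hⁿ)   for c < c_crit,      d(c) = 1  for c ≥ c_crit
```

Defaults: HICA `c_crit = 30 mM, h = 20 mM, n = 4, d_max = 0.97`; 2K3MVA
`c_crit = 25 mM, h = 16 mM, n = 4, d_max = 0.97`. Glucose or prior
adaptation protects completely (`d = 0`). On a conditioned-medium
background the effective dose is multiplied by a potency factor
`s = 1000`, reflecting the ~3-orders-of-magnitude sensitisation observed
when the toxins are added back to CM. Mixtures combine additively on a
`c/c_crit`-normalised scale — the simplest convention consistent with the
observed mixture behaviour.

During CM preparation the producer culture secretes toxin at a rate
proportional to the **square** of its (pre-saturation) density, after an
induction delay `t_ind = 2 h`:

```
C(t) = k · ∫_{t_ind}^{t} (a0·e^{ru})² du
```

A per-culture rate ∝ N² (per-cell rate ∝ N) is the simplest law that
satisfies both reported accumulation constraints simultaneously —
`C(20)/C(10) > 5` and `C(30)/C(20) > 3`; with the defaults the ratios are
5.48 and 4.27. The default coefficient `k = 2r/a0²` normalises the signal
to `e^{2rt} − e^{2r·t_ind}` (calibration units).

The signal→dose calibration `cm_condition` is a sharp logistic in the
signal,

```
dose(S) = c_ref / (1 + (E_thresh/S)⁶)
```

with two anchors: `E_thresh` is the geometric mean of the 15-h and 20-h
signals (so only media incubated beyond ~15 h reach the killing range),
and `c_ref` is fixed so the 30-h wild-type CM kills exactly 2/3 of an
unadapted inoculum — which puts its recipient's τ at ~20 h, the observed
delay. A linear calibration cannot satisfy both anchors: it would spread
delay induction smoothly across all incubation times. The steepness 6 is
the smallest even integer that cleanly separates the 15-h (kill ≈ 1e-4)
and 20-h (kill ≈ 0.59) media; in the {5,10,15,20,25,30} h panel the
smallest delay-inducing incubation is 20 h.

## Synthetic measurement layer

`generate_od_trace` samples the forward model once per minute over a 75-h
horizon (the span of a typical multi-day assay) and applies
multiplicative log-normal noise (sd 0.02 in log units) plus an additive
Gaussian floor (sd = noise_sd/10, i.e. 0.002 OD at default), clipped at
zero — a standard turbidimeter error structure; the instrument's true
noise magnitude is not documented, so these are conventions. Flow counts
are multinomial draws over (label × viability) gates with probabilities
proportional to compartment masses; dead cells score in the `_dead` gates
only when counted (vital staining) and drop out of label gates otherwise
(competition default). Compound tables are constructed to match requested
Venn membership counts exactly, with criterion flags arranged so a chosen
number of candidate-region compounds survives the filter.

What the generator does **not** emulate: instrument drift and plate
effects, lysis or slow optical decay of dead cells, continuous killing
kinetics, biological replicate-to-replicate parameter variation, and
spectral overlap in flow gates. Passing tests therefore demonstrate
correctness of the estimators under the stated error model, not robustness
to every artefact of real instrument data.

## Estimation conventions

- **Smoothing.** Analyses run on a 61-min centred moving average of the
  1-min trace (edges shrink), mirroring how such curves are usually
  presented; at default noise a raw trace is too rough for stable
  fit-quality thresholds.
- **Baseline `a0`.** Intercept at t = 0 of a least-squares line over the
  first 90 min of the raw trace. The line intercept is first-order
  unbiased under early growth (a window *mean* overestimates a0 by up to
  ~1.7%, shifting τ by several minutes); 90 min keeps the curvature bias
  below one sampling interval while averaging down the 0.002-OD floor.
  The baseline is the precision bottleneck of τ: its ~8% standard error
  translates to ~1.4 h of τ jitter at default noise.
- **τ.** First time the smoothed OD reaches `2·a0` and stays there for
  30 min (spike rejection). If only `1.5·a0` is reached, τ is extrapolated
  as `t₁.₅·ln2/ln1.5` — exact for exponential growth; otherwise censored.
- **Growth rate.** A single least-squares line through the log of the
  smoothed OD over the steady-growth band `1.5·a0 ≤ OD ≤ 0.7·plateau`,
  with an R² ≥ 0.98 quality floor. When the carrying cap is known
  (default `K = 1.0` OD, the study-culture cap) the logit
  `ln(OD/(K−OD))` is fitted instead, which linearises logistic growth
  exactly and removes crowding bias; `K=None` gives the pure log fit. A
  maximum-of-sliding-windows variant was rejected: selecting the largest
  of many noisy window slopes is upward-biased by its own order
  statistics (≈ +9% at default noise), far outside the estimator's target
  precision. On strongly delayed traces the in-trace rate is biased low by
  the dead-mass offset; downstream inversions use the fresh-medium rate.
- **Delay classification.** Delay present iff τ is censored or exceeds a
  baseline τ by a 5-h margin — well above τ noise, well below the 10-h
  effect of the reference CM.
- **Critical concentration.** Smallest tested dose whose culture never
  doubles within the horizon; inconsistent censoring above it is flagged,
  not hidden. An optional log-bisection refinement generates fresh traces
  between grid points.
- **Competition.** Both labels share one culture and one cap. For equal
  rates the steady-state living fraction is
  `f∞ = w_A/(w_A+w_B)`, `w_X = N_X0(1−d_X)e^{−r·λ_X}` — exact in the
  pre-saturation regime (crowding during one competitor's lag perturbs it
  by O(a0/K)); the trajectory comes from fixed-step RK4 with lag
  boundaries aligned to the grid. Unequal rates give a degenerate limit
  (0 or 1) and are flagged; the transient trajectory is then the result.

## Default parameters

| parameter | value | meaning |
|---|---|---|
| r | ln2/10 h⁻¹ | steady growth rate in glucose-free minimal medium (10-h doubling) |
| a0 | 0.005 OD | inoculum density (typical microplate start; low enough that the steady-growth band is ~uncrowded) |
| K | 1.0 OD | carrying cap |
| λ | 0 h | survivor lag beyond dead-mass masking (none assumed) |
| noise_sd | 0.02 | multiplicative log-normal OD noise |
| floor | 0.002 OD | additive Gaussian instrument floor |
| t_ind | 2 h | secretion induction delay |
| E_thresh | √(S₁₅·S₂₀) | delay-inducing signal threshold |
| margin | 5 h | delay-classification margin over baseline τ |
| horizon | 75 h | observation window |

## Problem sizes

Simulated panels use 1-min sampling over 75 h (4 501 points per trace),
17-dose panels on a 2.5-mM grid, 20 random seeds for stochastic recovery
checks, 100 seeds (or 100 random parameter draws) for property checks,
100 000 events for viability staining and 500 000 for competition counts.

## Known limitations

- The kill-fraction round trip through a measured τ inherits the baseline
  noise: individual estimates scatter by ~±0.05–0.1 at default noise, and
  at `d = 0` clipping to [0, 1] makes the error one-sided; only the *bias*
  is small. The flow-staining estimate and the curve inversion measure
  different quantities (dead proportion at staining time vs kill fraction
  at exposure) and are reported side by side, not reconciled.
- The closed-form competition steady state assumes equal growth rates and
  pre-saturation lag dynamics.
- Criterion flags in the inhibitor screen are annotations supplied with
  the compound table (or constructed by the generator); the package does
  not derive them from chemistry.
- Cross-species reuse is supported only through per-strain
  `GrowthParams`/`ToxinResponse` sets; no strain library is bundled.
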