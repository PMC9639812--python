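# odelay

Quantitative analysis of **autotoxin-induced delay phases** in microbial
growth curves, built around a two-compartment optical-density model.

When unadapted fission-yeast-like cells are inoculated into glucose-free
conditioned medium (CM), secreted autotoxins (leucic acid / HICA and
L-2-keto-3-methylvalerate / 2K3MVA) kill a fraction *d* of the inoculum.
Dead cells keep scattering light, so a turbidimeter sees

```
OD(t) = a0·d  +  a0·(1−d)·exp(r·(t−λ))        (pre-saturation; logistic
        ^dead    ^surviving, growing            towards cap K in full)
```

and the culture *appears* to pause: the observed OD only doubles once the
survivors have grown from `a0(1−d)` to `a0(2−d)`. The delay statistic

```
τ = time at which OD reaches 2·a0,
τ = λ + (1/r)·ln((2−d)/(1−d))                  (K ≫ a0)
```

carries the kill fraction, which can therefore be *inferred from turbidity
alone*: `d̂ = (e^{r(τ−λ)} − 2)/(e^{r(τ−λ)} − 1)`. The package is aimed at
researchers analysing 1-min plate/turbidimeter traces, viability-staining
flow counts, and two-colour competition assays in this setting.

## What it provides

- `popdyn` — the deterministic forward model: dose→kill-fraction Hill
  response with a hard critical concentration, instantaneous killing,
  logistic survivor regrowth, density-dependent toxin secretion during CM
  preparation, and the signal→dose calibration for CM of any incubation time.
- `synth` — a seeded measurement layer: noisy 1-min OD traces, multinomial
  flow-cytometry count tables, dose panels, CM incubation series, and
  Venn-structured compound tables.
- `curves` — `GrowthCurveModel`/`GrowthCurveResults`: a0, the steady growth
  rate r (logit-linear band fit), τ (direct, log2/log1.5-extrapolated, or
  censored), and delay classification.
- `death` — kill-fraction inference by curve inversion vs dyed-cell
  fractions from staining, and their paired comparison.
- `dose` — `DoseResponseModel`: τ-vs-dose profiles, critical-concentration
  estimation, and background-potency shifts.
- `competition` — `CompetitionModel`: closed-form and simulated steady-state
  label fractions, fraction time courses with binomial errors.
- `screen` — the CM-metabolite Venn partition and the three-criterion
  inhibitor-candidate filter.
- `io`/`cli` — CSV schemas, YAML config, an end-to-end pipeline and the
  `odelay` command-line tool (`simulate`, `analyze`, `dose`, `compete`,
  `screen`, `run`).

## Worked example

Generate a synthetic 30-h conditioned-medium trace at default calibration,
measure the delay, and invert it to a kill fraction:

```python
from odelay import (DEFAULT_GROWTH, GrowthCurveModel, estimate_death_from_curve,
                    generate_cm_series, default_secretion)

sp = default_secretion(DEFAULT_GROWTH)
trace = generate_cm_series([30.0], sp, DEFAULT_GROWTH, seed=0)[0]
res = GrowthCurveModel(trace).fit(baseline_tau=10.07)
print(res.summary())
est = estimate_death_from_curve(res.tau, DEFAULT_GROWTH.r, growth=DEFAULT_GROWTH)
print("inferred kill fraction:", round(est.d_hat, 3))
```

prints

```
Growth curve delay-phase analysis
========================================
sample             cm_30h
a0 (OD)               0.00479
tau (h)                20.150
tau method         direct
r_hat (1/h)           0.06111
doubling time (h)      11.342
delay present      True

inferred kill fraction: 0.667
```

The culture's OD took ~20 h to double (vs ~10 h in fresh medium), flagging
a delay phase; inverting the dead+living model recovers the generator's
kill fraction of 2/3. (The in-trace `r_hat` is biased low on strongly
delayed traces because dead mass distorts the log slope — the inversion
therefore uses the fresh-medium rate.)

The end-to-end pipeline, with every intermediate table and a JSON summary:

```bash
odelay run --seed 1 --outdir results/run1
```

## Documentation

`docs/methods.md` describes the model, its assumptions, the default
parameter calibration, the synthetic-noise model, numerical conventions
and known limitations.
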