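# koalastpp

Bias-corrected wildlife density surfaces from incidental (citizen-science)
sightings, via a self-exciting spatio-temporal point process fitted by
partial likelihood.

Opportunistic sighting records — e.g. koala reports phoned in by the
public — carry two kinds of structure that break naive density mapping:
repeat sightings of the same animal, and detection effort that varies over
space (people mostly see animals near roads). This package implements a
complete pipeline for such data: monthly minimum-distance thinning of
repeat sightings, a conditional-intensity model with log-linear covariate
effects, a seasonal self-excitation term and an explicit detection-bias
factor, partial-likelihood estimation, and density/population reporting.
It is aimed at quantitative ecologists and biostatisticians who want the
method as reusable, tested code, exercised end to end on synthetic data
with known ground truth.

## Model

The conditional intensity of sightings at location `x` (km) and monthly
period `t`, given the history `H_t`, factorizes as

```
λ(x,t | H_t) = λ0 · q(x,t) · r(x,t | H_t) · b(x,t)

log q(x,t) = γᵀ e(x)          # habitat / density covariates
log b(x,t) = βᵀ d(x)          # detection bias (distance to primary roads)
r(x,t|H_t) = ∏_{j: t_j = t-1} { 1 + [θ(t) − 1] · f(‖x − x_j‖) }
f(s)       = exp(−s/φ) · 1{s < u}
```

with `u = √A` the square root of the home-range area (interaction range)
and `θ(t)` switching between an off-season value `θ1` and a mating-season
value `θ2` (August–September by default); `θ > 1` aggregates, `θ = 1` is
no interaction, `0 < θ < 1` inhibits. The product `λ0·q·r` with the bias
factor removed is interpreted as true animal density (animals·km⁻²).

Shape parameters `(γ, β, θ1, θ2, φ)` are estimated by maximizing the
partial likelihood

```
Lp = Σ_i log [ q b r (x_i,t_i)  /  ∫_A q b r dx ]
```

in which the intercept cancels; `λ0` is then recovered by equating the
model's expected total sighting count to the observed count `N`. Wald 95%
intervals come from the observed information at the optimum.

Before fitting, sightings are thinned per calendar month: assuming a
circular home range of area `A` (default 0.35 km²), two same-month records
closer than the diameter `2·√(A/π)` ≈ 0.667 km are treated as repeat
sightings of one animal and collapsed greedily to the earliest record.

## Worked example

Simulate a 20×20 km study (two smooth habitat covariates, a sparse road
network, 24 monthly periods) from known parameters, then refit:

```python
import koalastpp as k

study = k.recovery_study(seed=0, side=20, T=24, target_total=670)
fit, truth = study["fit"], study["truth"]
print(f"events analysed: {study['n_events']}")
print(f"log partial likelihood: {fit.logpl:.2f}  (converged: {fit.converged})")
for name, true_val in [("gamma_1", 0.6), ("gamma_2", -0.4), ("beta_1", -0.7),
                       ("theta1", 2.0), ("theta2", 2.5), ("phi", 0.4)]:
    lo, hi = fit.ci95[name]
    print(f"  {name:8s} truth {true_val:+.2f}   CI95 [{lo:+.3f}, {hi:+.3f}]")
print(f"  lambda0  truth {truth.lambda0:.5f}  estimate {fit.params.lambda0:.5f}")
```

which prints:

```
events analysed: 764
log partial likelihood: -4134.99  (converged: True)
  gamma_1  truth +0.60   CI95 [+0.492, +0.654]
  gamma_2  truth -0.40   CI95 [-0.498, -0.343]
  beta_1   truth -0.70   CI95 [-0.831, -0.640]
  theta1   truth +2.00   CI95 [+1.368, +3.561]
  theta2   truth +2.50   CI95 [+0.543, +4.328]
  phi      truth +0.40   CI95 [+0.116, +0.687]
  lambda0  truth 0.04286  estimate 0.04457
```

Every interval covers its generating value. The covariate and bias
coefficients are estimated sharply even at ~750 events; the interaction
parameters `θ1, θ2, φ` are intrinsically harder (they are informed only by
event pairs in consecutive months within ~0.6 km) and carry honest, wide
intervals at this sample size.

The same pipeline is available from the shell:

```
koalastpp simulate --config sim.yaml --out data/
koalastpp thin --sightings sightings.csv --start-year 1997 --end-year 2013 --out thin/
koalastpp fit --thinned thin/thinned.csv --stack-dir data/ --out fit/
koalastpp run --config sim.yaml --seed 1 --out run/   # end to end
```

`run` writes the fit report (`fit.json`), monthly expected-population
totals, annual mean density rasters, the density-category area table and
the detection-bias raster, plus an echo of the config and seed.

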