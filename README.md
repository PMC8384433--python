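# phylocomp

Phylogenetic models of continuous trait evolution in which the impact of
species interactions — competition — can differ between predefined groups
of lineages, such as tropical and temperate breeders.  The package is a
simulation and maximum-likelihood inference toolkit for comparative
biologists asking whether the *tempo* (rates) or *mode* (generating
process) of trait evolution varies across such regimes.

## Models

Six families of Gaussian trait models on a time-calibrated ultrametric
tree, each in single-regime and two-regime form (12 models total):

* **BM** — Brownian motion, dX = σ dW;
* **OU** — Ornstein–Uhlenbeck, dX = α(θ − X) dt + σ dW, with
  regime-specific optima θ_trop, θ_temp in the two-regime form;
* **EB** — early burst, rate σ²(t) = σ₀² e^{rt} declining with time since
  the root;
* **DD_exp / DD_lin** — diversity-dependent rates, σ²(t) = σ₀² e^{r d(t)}
  or σ₀² + b d(t), where d(t) is the number of co-occurring (sympatric)
  same-regime lineages;
* **MC** — matching competition,
  dX_j = S(x̄_j(t) − X_j) dt + σ dW, where x̄_j is the mean trait of the
  lineages sympatric with j; S < 0 means repulsion in trait space
  (character displacement).

Two-regime forms estimate the slope/coupling (or rate, or optimum)
separately for, e.g., exclusively-tropical vs temperate-breeding lineages,
with the regime assignment given by stochastic character maps.  Sympatry
enters through per-branch area-occupancy histories; species means carry
observational error (known SE² plus an estimated nuisance variance).
Model selection uses AICc with Akaike weights and a "prefer the simpler
model within 2 AICc" rule, averaged over banks of ≥ 20 stochastic maps.

Likelihoods are exact Gaussian: tip means and covariances are propagated
along an event timeline with closed-form interval updates (see
`docs/methods.md`), so even the interaction models fit in seconds on
100–200-tip clades.

## Worked example

Simulate a 50-tip clade (38 tropical / 12 temperate breeders, the shape of
a small Galliform family) under a two-regime matching-competition model
with 5-fold stronger repulsion in the tropics, then fit and compare
models:

```python
from phylocomp import ModelSpec, Params
from phylocomp.fixtures import make_scenario, template_spec
from phylocomp.fit import (compare_models, select_best, akaike_weights,
                           ln_abs_ratio)

spec = template_spec(
    "cracidae", seed=7,
    gen_spec=ModelSpec("MC", n_regimes=2),
    gen_params=Params(z0=5.0, sigma2=0.05,
                      S={"tropical": -0.10, "temperate": -0.02}),
)
sc = make_scenario(spec)
fits = compare_models(
    [ModelSpec("BM"), ModelSpec("BM", 2), ModelSpec("MC"), ModelSpec("MC", 2)],
    sc.tree, sc.regimes, sc.traits, n_starts=2, seed=0)
for f, w in zip(fits, akaike_weights([f.aicc for f in fits])):
    print(f"{f.name:10s} k={f.k}  logLik={f.loglik:8.2f}  AICc={f.aicc:7.2f}  w={w:.3f}")
best = select_best(fits)
print("best-fit model:", best.name)
print("S_tropical = %.4f, S_temperate = %.4f" % (
    best.params.S["tropical"], best.params.S["temperate"]))
print("ln(|S_trop|/|S_temp|) = %.3f" % ln_abs_ratio(best))
```

prints

```
BM_single  k=2  logLik= -191.90  AICc= 388.05  w=0.000
BM_two     k=3  logLik= -173.61  AICc= 353.74  w=0.000
MC_single  k=3  logLik= -137.56  AICc= 281.65  w=0.000
MC_two     k=4  logLik=  -91.39  AICc= 191.67  w=1.000
best-fit model: MC_two
S_tropical = -0.1043, S_temperate = -0.0310
ln(|S_trop|/|S_temp|) = 1.213
```

The two-regime MC model is correctly preferred (Akaike weight ≈ 1), the
repulsion estimates recover the generating values (−0.10, −0.02) up to
sampling noise, and the log ratio ln(|S_trop|/|S_temp|) — the quantity
used to compare competition strength between regimes — is positive, i.e.
stronger competition in the tropics, as simulated.

A command-line interface mirrors the library:

```
phylocomp simulate tree --tips 100 --height 50 --seed 1 -o t.nwk
phylocomp simulate regimes --tree t.nwk --rate 0.06 --seed 2 -o r.smap
phylocomp fit --model mc2 --tree t.nwk --traits y.csv --regimes r.smap -o fit.json
phylocomp compare --tree t.nwk --traits y.csv --maps bank/ -o comp/
phylocomp tree slice --tree big.nwk --max 200 --step 0.1 -o clades/
```

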