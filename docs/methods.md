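# Methods

## The models

All twelve models describe the evolution of a single continuous trait
X_t(j) along a rooted, binary, ultrametric chronogram with time t measured
forward from the root (t = 0) to the present (t = T, in Myr).  Each lineage
carries a piecewise-constant *regime* label g(j, t) ∈ {tropical, temperate}
(a stochastic character map), and optionally a piecewise-constant area
occupancy from which a 0/1 sympatry matrix A(t) is built: A_jl = 1 when
lineages j and l share at least one area (A_jj = 1 always, so full
sympatry is the single-area special case).

The six families, in single-regime (one parameter set) and two-regime
(separate values per regime) form:

| family  | SDE / rate                                           | single k | two k |
|---------|------------------------------------------------------|----------|-------|
| BM      | dX = σ dW                                            | 2        | 3     |
| OU      | dX = α(θ − X) dt + σ dW                              | 3        | 4     |
| EB      | dX = σ₀ e^{½ r t} dW                                 | 3        | 4     |
| DD_exp  | dX = σ₀ e^{½ r d_j(t)} dW                            | 3        | 4     |
| DD_lin  | dX = √(σ₀² + b d_j(t)) dW                            | 3        | 4     |
| MC      | dX = S (x̄_j(t) − X) dt + σ dW                        | 3        | 4     |

where d_j(t) counts the sympatric lineages in j's regime (self included)
and x̄_j(t) is the sympatry-weighted mean trait of those same lineages.
Two-regime BM varies σ², OU varies the optimum θ (shared α and σ², root
state fixed at the root-regime optimum), and EB/DD/MC vary the slope or
the coupling S.  S < 0 is repulsion (character displacement); the optimizer
constrains S ≤ 0 by default with an `allow_attraction` switch.  The ½
factors arise because the SDE carries the square root of the rate.  In the
biogeography-aware exponential DD model each regime branch uses its own
slope; formulations that repeat the first regime's slope symbol in both
branches are read as a typographical slip, since the non-spatial form of
the model fixes the intent.

Interactions are restricted to same-regime sympatric lineages by default.
Because the alternative reading (tropical and temperate members of one
clade still meet) is also defensible, an `interact_across_regimes` option
lets all sympatric lineages enter d_j and the MC mean, with the regime
setting only the coefficient.

An estimated species mean deviates from the modeled mean by sampling error
(known SE_i², supplied with the data) plus a nuisance variance σ_err²
("observational error", estimated when requested, adding 1 to k).  Both sit
on the diagonal of the tip covariance.

## Likelihood

Every model is Gaussian on the tips, so the likelihood is a dense
multivariate normal N(y; m, V + diag(SE² + σ_err²)) evaluated by Cholesky
factorization.  Tip moments come from two routes:

* **Path closed forms** (BM/OU/EB): V_ij integrates the rate over the
  shared root→MRCA path (regime-resolved segments); OU uses the fixed-root
  ultrametric covariance σ²/(2α)·e^{−α d_ij}(1 − e^{−2α t_MRCA}) and a mean
  that integrates the regime-switching optimum along each tip path.
  α → 0 and r → 0 limits are taken analytically.

* **Interval-exact moment propagation** (all families; required for DD/MC):
  the tree plus histories is discretized into an event timeline — one
  interval per branching, regime switch, or occupancy change — on which
  regimes, lineage counts, and A(t) are constant.  The joint moments obey
  dm/dt = R m, dV/dt = RV + VRᵀ + D with R, D constant per interval, so
  each interval is advanced *exactly*: for DD/EB/BM, R = 0 and D is
  diagonal (the rate integral); for MC with clique-structured sympatry
  (full sympatry, or any disjoint union of mutually-sympatric groups),
  R = −Σ_g S_g Q_g with orthogonal centered projectors Q_g, giving
  e^{RΔ} = I + Σ_g (e^{−S_gΔ}−1) Q_g and a closed-form noise integral; for
  arbitrary overlap graphs the propagator and noise integral come from a
  Van Loan block matrix exponential.  Branchings duplicate the parent's
  row/column.  This replaces adaptive ODE stepping with exact linear
  algebra — there is no integration tolerance to tune, and the two MC code
  paths agree to machine precision (tested).

The two routes are implemented independently and cross-checked in the test
suite, as are analytic moments against 10,000-replicate Euler–Maruyama
simulations.

## Fitting

Parameters that enter the Gaussian likelihood linearly are concentrated
analytically: the mean parameters (z₀, or both OU optima via a design
matrix built from the regime paths) by GLS, and the overall rate σ² (plus
DD_lin's slope, re-expressed per unit rate) whenever the covariance
diagonal carries no observational-error term.  The optimizer — Nelder–Mead
simplex over log-transformed variances, log(−S), and untransformed slopes,
with 4 starts by default (a BM-moment-matched start, ± unit perturbations,
and random starts) — therefore searches only 1–2 nonlinear parameters per
model.  A fit requires ≥ 10 tips, and ≥ 10 tips per regime for two-regime
models.

AICc = −2 logL + 2k + 2k(k+1)/(n−k−1) with n the number of tips with data.
The best model is the lowest-AICc fit unless a simpler model (fewer
parameters) lies within 2 AICc of the minimum, in which case the simplest
such model wins (ties: lower AICc, then name).  We anchor the Δ < 2 window
at the minimum rather than chaining it, so the selected model never sits
≥ 2 AICc above the best fit.  Support and parameter estimates are averaged
(arithmetic means of Akaike weights and MLEs) across banks of ≥ 20
stochastic maps; the across-bank verdict is the modal per-map best fit.

Derived quantities are defined as follows: rate at the present
(EB: σ₀²e^{rT}; DD_exp: σ₀²e^{rN}; DD_lin: σ₀² + bN, with N the extant
count of the fitted sympatric pool — the clade size without biogeography,
since no finer rule is stated), ln(|par_trop|/|par_temp|), the competition
support index max(w_MC, w_DDlin, w_DDexp)/(max(w_BM, w_OU, w_EB) +
max(w_MC, w_DDlin, w_DDexp)), the two-regime support index
max(w_two)/(max(w_two)+max(w_single)) − 0.5, and total error
σ̂_err² + mean(SE²).

## Discrete side

Breeding ranges are classified against the ±23.437° tropics: exclusively
inside (open interval) is tropical, wholly outside temperate, anything
touching or straddling the boundary "both"; "both" is collapsed into
"temperate" so that "tropical" means exclusively tropical breeding.  The
3-state all-rates-different Mk model is fitted by Felsenstein pruning
(equal root frequencies, the common mapping default) and stochastic maps
are drawn by node-conditional sampling followed by endpoint-conditioned
uniformization within branches.  Map banks default to 20.  Sympatry between
extant species uses the Szymkiewicz–Simpson coefficient
overlap/min(area₁, area₂) with a 0.20 threshold.  Trees above 200 tips are
sliced by sliding a cut line rootward-to-tipward in 0.1 Myr steps, freezing
each crossing lineage's clade as soon as it falls below 200 tips and
keeping clades of ≥ 10 tips.

Sympatry downsampling (for misspecification studies) retains, per area and
per regime, ⌊p · size⌋ of the co-occurring taxa as mutually sympatric,
sampled without replacement; dropped taxa become allopatric on their
terminal branches.  This is the "taxa were sympatric" (lineage-level)
reading; a pair-level variant (`level="pair"`, retaining a fraction of
same-regime pairs) is available because the wording also admits it.
Ancestral (internal) branches always interact according to occupancy:
downsampling is defined for extant taxa only.

## Synthetic scenarios

`phylocomp.fixtures` generates complete study-shaped datasets from a spec
and a seed: a birth–death chronogram (default birth 0.2/Myr, death
0.05/Myr, rescaled to 50 Myr — a typical terrestrial family age), a
two-state regime history resimulated until the tip split matches the
template within ±10% (clade templates 50 = 38 + 12, 122 = 89 + 33,
190 = 86 + 104), a 20-map bank drawn from the generating Mk model
conditioned on the realized tip states, optional K-area occupancy
histories, optional sympatry downsampling, and traits simulated under any
of the twelve models (Euler–Maruyama, default step T/1000).  What these
scenarios emulate is the *structure* of clade-level comparative data —
tree shape, regime mixing, reconstruction uncertainty, sampling error;
what they do not emulate is real morphology (no empirical trait
distributions, no principal-component structure, no phylogenetic signal in
sample sizes), so passing tests demonstrate correctness and statistical
behaviour of the machinery, not empirical conclusions about any taxon.

## Study-harness settings

Simulation-study defaults were chosen once, as plausible values a
comparative study of bird-family-sized clades would use, and are stated
here because no table of generating values ships with the package:

* trees: 100 tips (128 for the selection study), height 50 Myr;
* root state z₀ = 5.0 trait units (a log-mass-like scale), σ² = 0.05
  units²/Myr;
* two-regime contrasts: EB r = (−0.08, −0.03)/Myr; DD_exp
  r = (−0.02, −0.008)/lineage; DD_lin b = (−6e−4, −2.5e−4)
  units²/Myr/lineage (each regime's rate declines visibly but stays
  positive); MC S = (−0.10, −0.02)/Myr, a 5-fold repulsion ratio;
* two-regime BM selection study: σ² ratio 4 (0.2 vs 0.05);
* downsampling scenarios: 50%/50% and 33%/50% retention (the second
  equals "66.6% of tropical lineages set to allopatric");
* recovery/power studies use 20 replicates and 2 optimizer starts; the
  acceptance script uses 12 replicates per study.

These sizes keep a full run (test suite plus acceptance script) on one CPU
in well under an hour.

## Numerical choices and limitations

* Ultrametricity tolerance 1e−6·T (published chronograms carry rounding
  noise); segment tiling tolerance 1e−6·T; simultaneous timeline events
  are merged into one point.
* SIMMAP dialect: phytools ordering, root-ward segment first,
  `{state,duration:state,duration}`; occupancy labels are K-bit strings.
* DD_lin with a negative rate anywhere is an error naming the lineage and
  time — never a silent clamp — in both simulation and likelihood, because
  the likelihood is undefined there.
* Likelihoods use the dense tip covariance (clades are capped at 200 tips
  by slicing), not pruning: the interaction models break the independence
  structure pruning needs.
* The optimizer can, like any local search, stall on flat likelihoods
  (e.g. α → 0 with weak signal); multi-starts mitigate but do not remove
  this.  Fits flagged non-converged are excluded from model selection.
* Polytomies, non-ultrametric (fossil) trees, NEXUS input, multivariate
  traits, and ancestral-range estimation itself (occupancy histories are
  consumed, not inferred from range data) are out of scope.
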