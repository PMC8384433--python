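"""Maximum-likelihood fitting, AICc model selection, and study harnesses.

Fits profile out every parameter that enters the Gaussian likelihood
linearly: the mean parameters (z0, or the two OU optima) are always
concentrated by GLS, and the overall rate sigma^2 is concentrated whenever
no observational-error variance sits on the covariance diagonal.  The
optimizer therefore only searches the one or two genuinely nonlinear
parameters of each family (alpha, slopes, S), which keeps the interaction
models fast enough for replicated simulation studies.

Model selection follows the small-sample AICc with the "within 2 AICc,
prefer fewer parameters" rule, and support is averaged over banks of
stochastic maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .fixtures import ScenarioSpec, make_scenario
from .likelihood import (
    FAMILIES,
    InadmissibleParameters,
    ModelSpec,
    MomentEngine,
    Params,
    SingularCovariance,
)
from .tree import build_event_timeline

__all__ = [
    "FitResult",
    "ModelComparison",
    "fit_model",
    "compare_models",
    "standard_model_set",
    "aicc",
    "akaike_weights",
    "select_best",
    "aggregate_over_maps",
    "ln_abs_ratio",
    "competition_support_index",
    "two_regime_support_index",
    "rate_at_present",
    "total_error",
    "recovery_experiment",
    "selection_experiment",
    "sympatry_power_experiment",
]

REGIMES = ("tropical", "temperate")


def aicc(loglik, k, n):
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values):
    """Normalized relative likelihoods exp(-Delta_i/2) / sum."""
    a = np.asarray(aicc_values, dtype=float)
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


@dataclass
class FitResult:
    """One model fit: MLEs, log-likelihood, AICc, and bookkeeping."""

    spec: ModelSpec
    params: Params
    loglik: float
    n: int
    converged: bool = True
    n_starts: int = 1
    seed: int = 0
    start_logliks: list = field(default_factory=list)

    @property
    def k(self):
        return self.spec.k

    @property
    def aicc(self):
        return aicc(self.loglik, self.k, self.n)

    @property
    def name(self):
        return self.spec.name


# ----------------------------------------------------------------------
# Concentrated Gaussian likelihood
# ----------------------------------------------------------------------

def _gls_loglik(y, C, X):
    """Profile the mean over span(X): returns (loglik, beta_hat)."""
    C = 0.5 * (C + C.T)
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        raise SingularCovariance("singular covariance in GLS step") from None
    Ci_y = cho_solve(cf, y)
    Ci_X = cho_solve(cf, X)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    r = y - X @ beta
    q = float(r @ cho_solve(cf, r))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    n = len(y)
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + q)
    return ll, beta, q, logdet


def _profiled_scale_loglik(y, Vtilde, X):
    """Profile mean AND overall scale: C = s2 * Vtilde."""
    Vtilde = 0.5 * (Vtilde + Vtilde.T)
    try:
        cf = cho_factor(Vtilde, lower=True)
    except np.linalg.LinAlgError:
        raise SingularCovariance("singular shape matrix") from None
    Ci_y = cho_solve(cf, y)
    Ci_X = cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ Ci_X, X.T @ Ci_y)
    r = y - X @ beta
    q = float(r @ cho_solve(cf, r))
    n = len(y)
    if q <= 0:
        raise SingularCovariance("non-positive residual quadratic form")
    s2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (n * np.log(2 * np.pi) + logdet + n * np.log(s2) + n)
    return ll, beta, s2


# ----------------------------------------------------------------------
# Family parametrizations
# ----------------------------------------------------------------------

class _Parametrization:
    """Maps an unconstrained optimizer vector to Params (shape part only).

    ``profiled_scale`` is True when sigma^2 is concentrated analytically;
    the builder then produces shape params with sigma2 = 1 (DD_lin slopes
    are expressed per unit rate in that case).
    """

    def __init__(self, spec, regime_labels, T, allow_attraction, profiled_scale,
                 estimate_error):
        self.spec = spec
        self.labels = regime_labels if spec.n_regimes == 2 else None
        self.T = T
        self.allow_attraction = allow_attraction
        self.profiled_scale = profiled_scale
        self.estimate_error = estimate_error
        self.names = []
        if not profiled_scale:
            self.names.append("log_sigma2")
        if estimate_error:
            self.names.append("log_sigma_err2")
        fam = spec.family
        if fam == "BM":
            if spec.n_regimes == 2:
                self.names.append("log_rate_ratio" if profiled_scale
                                  else "log_sigma2_b")
        elif fam == "OU":
            self.names.append("log_alpha")
        elif fam in ("EB", "DD_exp"):
            self.names += ["r"] if spec.n_regimes == 1 else ["r_a", "r_b"]
        elif fam == "DD_lin":
            self.names += ["beta"] if spec.n_regimes == 1 else ["beta_a", "beta_b"]
        elif fam == "MC":
            self.names += ["s"] if spec.n_regimes == 1 else ["s_a", "s_b"]

    @property
    def dim(self):
        return len(self.names)

    def _regval(self, a, b):
        if self.spec.n_regimes == 1:
            return a
        return {self.labels[0]: a, self.labels[1]: b}

    def build(self, psi):
        """Shape Params from the optimizer vector (z0/theta left at 0)."""
        psi = np.asarray(psi, dtype=float)
        if np.any(np.abs(psi) > 60):
            raise InadmissibleParameters("parameter overflow")
        vals = dict(zip(self.names, psi))
        s2 = 1.0 if self.profiled_scale else np.exp(vals["log_sigma2"])
        err = np.exp(vals["log_sigma_err2"]) if self.estimate_error else 0.0
        fam = self.spec.family
        p = Params(z0=0.0, sigma2=s2, sigma_err2=err)
        if fam == "BM":
            if self.spec.n_regimes == 2:
                if self.profiled_scale:
                    s2b = s2 * np.exp(vals["log_rate_ratio"])
                else:
                    s2b = np.exp(vals["log_sigma2_b"])
                p.sigma2 = self._regval(s2, s2b)
        elif fam == "OU":
            p.alpha = np.exp(vals["log_alpha"])
            if self.spec.n_regimes == 2:
                p.theta = {self.labels[0]: 0.0, self.labels[1]: 0.0}
        elif fam in ("EB", "DD_exp"):
            if self.spec.n_regimes == 1:
                p.r = vals["r"]
            else:
                p.r = self._regval(vals["r_a"], vals["r_b"])
        elif fam == "DD_lin":
            scale = s2  # slopes parametrized relative to the rate
            if self.spec.n_regimes == 1:
                p.b = vals["beta"] * scale
            else:
                p.b = self._regval(vals["beta_a"] * scale,
                                   vals["beta_b"] * scale)
        elif fam == "MC":
            def to_S(u):
                return u if self.allow_attraction else -np.exp(u)
            if self.spec.n_regimes == 1:
                p.S = to_S(vals["s"])
            else:
                p.S = self._regval(to_S(vals["s_a"]), to_S(vals["s_b"]))
        return p

    def starts(self, n_starts, rng, sigma2_bm, T):
        """Start vectors: a BM-moment-matched start plus perturbations."""
        base = []
        for nm in self.names:
            if nm == "log_sigma2":
                base.append(np.log(max(sigma2_bm, 1e-12)))
            elif nm == "log_sigma2_b":
                base.append(np.log(max(sigma2_bm, 1e-12)))
            elif nm == "log_sigma_err2":
                base.append(np.log(max(0.05 * sigma2_bm * T, 1e-12)))
            elif nm == "log_rate_ratio":
                base.append(0.0)
            elif nm == "log_alpha":
                base.append(np.log(1.0 / T))
            elif nm in ("r", "r_a", "r_b"):
                base.append(-0.5 / T if self.spec.family == "EB" else -0.01)
            elif nm in ("beta", "beta_a", "beta_b"):
                base.append(-0.001)
            elif nm in ("s", "s_a", "s_b"):
                base.append(np.log(0.5 / T) if not self.allow_attraction
                            else -0.5 / T)
        base = np.array(base)
        out = [base]
        signs = [+1.0, -1.0]
        for i in range(n_starts - 1):
            if i < 2:
                out.append(base + signs[i] * 1.0)
            else:
                out.append(base + rng.normal(0, 1.5, self.dim))
        return out


def _mean_design(spec, params, engine, n):
    """Design matrix for the profiled mean parameters."""
    if spec.family == "OU" and spec.n_regimes == 2 and params.alpha > 0:
        tl = engine.timeline
        tree = tl.tree
        regimes = tl.regimes
        labels = list(dict.fromkeys(
            [regimes.root_label] + [s for segs in regimes.segments.values()
                                    for _, s in segs]))
        labels = [g for g in REGIMES if g in labels] or labels
        al = params.alpha
        T = tree.T
        from .tree import shared_path_segments
        X = np.zeros((n, len(labels)))
        col = {g: j for j, g in enumerate(labels)}
        for i in range(n):
            X[i, col[regimes.root_label]] += np.exp(-al * T)
            for t0, t1, g in shared_path_segments(tree, regimes, i, i):
                X[i, col[g]] += np.exp(-al * (T - t1)) - np.exp(-al * (T - t0))
        return X, labels
    return np.ones((n, 1)), None


def _finalize_params(spec, shape, beta, labels, s2_hat=None):
    """Fill profiled quantities back into a complete Params object."""
    p = replace(shape)
    if labels is not None:  # OU two-regime optima
        p.theta = {g: float(b) for g, b in zip(labels, beta)}
        p.z0 = p.theta[labels[0]] if labels else float(beta[0])
    else:
        p.z0 = float(beta[0])
        if spec.family == "OU":
            p.theta = p.z0
    if s2_hat is not None:
        if isinstance(p.sigma2, dict):
            p.sigma2 = {g: v * s2_hat for g, v in p.sigma2.items()}
        else:
            p.sigma2 = p.sigma2 * s2_hat
        if isinstance(p.b, dict):
            p.b = {g: v * s2_hat for g, v in p.b.items()}
        elif p.b:
            p.b = p.b * s2_hat
    return p


def fit_model(spec, tree, regimes, traits, biogeo=None, interactions=None,
              n_starts=4, seed=0, allow_attraction=False, engine=None,
              min_per_regime=10):
    """ML fit of one model to one dataset.

    Requires >= 10 tips overall and, for two-regime fits, >= 10 tips in each
    regime.  Runs a small multi-start simplex search over the nonlinear
    parameters; linear parameters are concentrated analytically, so the
    reported MLEs include them exactly.
    """
    td = traits.aligned_to(tree)
    n = len(td)
    if n < 10:
        raise ValueError(f"need at least 10 tips with data, got {n}")
    tip_states = regimes.tip_labels_at_present()
    labels2 = tuple(g for g in REGIMES if g in set(tip_states.values()))
    if not labels2:
        labels2 = tuple(sorted(set(tip_states.values())))
    if spec.n_regimes == 2:
        counts = {g: sum(1 for s in tip_states.values() if s == g)
                  for g in labels2}
        if len(labels2) < 2 or min(counts.values()) < min_per_regime:
            raise ValueError(
                f"two-regime fit needs >= {min_per_regime} tips per regime, "
                f"got {counts}")
    if engine is None:
        tl = build_event_timeline(
            tree, regimes, biogeo if spec.biogeography else None, interactions)
        engine = MomentEngine(tl, spec.interact_across_regimes)

    y = td.mean
    se2 = td.se2
    profiled_scale = (not spec.estimate_error) and np.all(se2 == 0)
    par = _Parametrization(spec, labels2, tree.T, allow_attraction,
                           profiled_scale, spec.estimate_error)

    # BM moment start for sigma^2: residual variance per unit depth
    sigma2_bm = max(float(np.var(y)) / tree.T, 1e-10)

    def objective(psi):
        try:
            shape = par.build(psi)
            _, V = engine.moments(spec, shape)
            X, labels = _mean_design(spec, shape, engine, n)
            if profiled_scale:
                ll, beta, s2 = _profiled_scale_loglik(y, V, X)
                return -ll, (beta, labels, s2)
            C = V + np.diag(se2 + shape.sigma_err2)
            ll, beta, _, _ = _gls_loglik(y, C, X)
            return -ll, (beta, labels, None)
        except (InadmissibleParameters, SingularCovariance,
                FloatingPointError, np.linalg.LinAlgError):
            return 1e10, None

    rng = np.random.default_rng(seed)
    best = None
    start_lls = []
    if par.dim == 0:
        f, aux = objective(np.zeros(0))
        best = (f, np.zeros(0), aux, True)
        start_lls.append(-f)
    else:
        for x0 in par.starts(n_starts, rng, sigma2_bm, tree.T):
            f0, _ = objective(x0)
            res = minimize(lambda v: objective(v)[0], x0,
                           method="Nelder-Mead",
                           options={"maxiter": 400 * par.dim,
                                    "xatol": 1e-4, "fatol": 1e-7})
            f, aux = objective(res.x)
            start_lls.append(-f if f < 1e9 else -np.inf)
            if aux is not None and (best is None or f < best[0]):
                best = (f, res.x, aux, bool(res.success))
    if best is None or best[2] is None:
        raise RuntimeError("all optimizer starts failed for "
                           f"{spec.name}; data or parameters pathological")
    f, psi, (beta, labels, s2_hat), ok = best
    shape = par.build(psi)
    params = _finalize_params(spec, shape, beta, labels, s2_hat)
    return FitResult(spec=spec, params=params, loglik=float(-f), n=n,
                     converged=bool(ok and f < 1e9), n_starts=max(1, n_starts),
                     seed=seed, start_logliks=start_lls)


# ----------------------------------------------------------------------
# Model sets and selection
# ----------------------------------------------------------------------

def standard_model_set(two_regime=True, biogeography=False,
                       estimate_error=False, families=FAMILIES):
    """The 6 single-regime models, optionally plus their two-regime forms."""
    specs = [ModelSpec(f, 1, biogeography and f in ("DD_exp", "DD_lin", "MC"),
                       estimate_error) for f in families]
    if two_regime:
        specs += [ModelSpec(f, 2, biogeography and f in ("DD_exp", "DD_lin", "MC"),
                            estimate_error) for f in families]
    return specs


def compare_models(specs, tree, regimes, traits, biogeo=None,
                   interactions=None, n_starts=4, seed=0, **kw):
    """Fit a set of models to one dataset, sharing timeline work."""
    engines = {}
    results = []
    for i, spec in enumerate(specs):
        key = (spec.biogeography, spec.interact_across_regimes)
        if key not in engines:
            tl = build_event_timeline(
                tree, regimes, biogeo if spec.biogeography else None,
                interactions)
            engines[key] = MomentEngine(tl, spec.interact_across_regimes)
        results.append(fit_model(spec, tree, regimes, traits, biogeo=biogeo,
                                 interactions=interactions, n_starts=n_starts,
                                 seed=seed + 17 * i, engine=engines[key], **kw))
    return results


def select_best(results, delta=2.0):
    """Best-fit model: lowest AICc, but prefer simpler models within delta.

    Among all usable fits within ``delta`` AICc of the minimum, the one with
    the fewest parameters wins; ties break by lower AICc, then by name.
    """
    usable = [r for r in results if r.converged]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable fits")
    amin = min(r.aicc for r in usable)
    cands = [r for r in usable if r.aicc - amin < delta]
    cands.sort(key=lambda r: (r.k, r.aicc, r.name))
    return cands[0]


@dataclass
class ModelComparison:
    """Support averaged across a bank of stochastic maps."""

    model_names: list
    mean_aicc: dict
    mean_weight: dict
    mean_params: dict          # name -> {param: mean MLE}
    best_per_map: list
    modal_best: str
    table: pd.DataFrame


def _flat_params(res):
    out = {}
    p = res.params
    for nm in ("z0", "sigma2", "alpha", "theta", "r", "b", "S", "sigma_err2"):
        v = getattr(p, nm)
        if v is None:
            continue
        if isinstance(v, dict):
            for g, x in v.items():
                out[f"{nm}_{g}"] = float(x)
        elif nm in ("z0", "sigma2", "sigma_err2") or np.any(v != 0):
            out[nm] = float(v)
    return out


def aggregate_over_maps(per_map_results, delta=2.0):
    """Average model support and MLEs over fits on a stochastic-map bank.

    ``per_map_results``: one list of FitResults (same model set, same order)
    per stochastic map.  Weights and parameter estimates are arithmetic
    means across maps; the verdict is the modal per-map best-fit model.
    """
    if not per_map_results:
        raise ValueError("need at least one map")
    names = [r.name for r in per_map_results[0]]
    for res in per_map_results:
        if [r.name for r in res] != names:
            raise ValueError("inconsistent model sets across maps")
    rows = []
    best_per_map = []
    for mi, res in enumerate(per_map_results):
        w = akaike_weights([r.aicc for r in res])
        best_per_map.append(select_best(res, delta=delta).name)
        for r, wi in zip(res, w):
            rows.append({"map": mi, "model": r.name, "logLik": r.loglik,
                         "k": r.k, "n": r.n, "AICc": r.aicc, "weight": wi,
                         **{f"par:{k}": v for k, v in _flat_params(r).items()}})
    table = pd.DataFrame(rows)
    mean_aicc = table.groupby("model")["AICc"].mean().to_dict()
    mean_weight = table.groupby("model")["weight"].mean().to_dict()
    mean_params = {}
    for nm in names:
        sub = table[table["model"] == nm]
        mean_params[nm] = {c[4:]: float(sub[c].mean())
                           for c in sub.columns if c.startswith("par:")
                           and sub[c].notna().any()}
    vals, counts = np.unique(best_per_map, return_counts=True)
    modal = sorted(zip(-counts, vals))[0][1]
    return ModelComparison(names, mean_aicc, mean_weight, mean_params,
                           best_per_map, modal, table)


# ----------------------------------------------------------------------
# Derived metrics
# ----------------------------------------------------------------------

_SLOPE_OF = {"EB": "r", "DD_exp": "r", "DD_lin": "b", "MC": "S", "BM": "sigma2"}


def ln_abs_ratio(result, tropical="tropical", temperate="temperate"):
    """ln(|par_tropical| / |par_temperate|) for a two-regime fit."""
    if result.spec.n_regimes != 2:
        raise ValueError("ln ratio requires a two-regime fit")
    nm = _SLOPE_OF.get(result.spec.family)
    if result.spec.family == "OU":
        nm = "theta"
    v = getattr(result.params, nm)
    return float(np.log(abs(v[tropical]) / abs(v[temperate])))


def competition_support_index(weights):
    """Relative support for any model with competition.

    max(MC, DD_lin, DD_exp weights) / (max(BM, OU, EB) + max(MC, DD_lin,
    DD_exp)), computed on single-regime Akaike weights.
    """
    comp = max(v for k, v in weights.items() if k.startswith(("MC", "DD")))
    nocomp = max(v for k, v in weights.items()
                 if k.startswith(("BM", "OU", "EB")))
    return comp / (comp + nocomp)


def two_regime_support_index(weights):
    """max(two-regime w) / (max(two-regime w) + max(single-regime w)) - 0.5.

    Positive values support a two-regime (latitudinal) model.
    """
    two = max(v for k, v in weights.items() if k.endswith("_two"))
    single = max(v for k, v in weights.items() if k.endswith("_single"))
    return two / (two + single) - 0.5


def rate_at_present(result, n_lineages=None, T=None):
    """Evolutionary rate at the present from root rate and slope.

    EB: sigma0^2 e^{r T}; DD_exp: sigma0^2 e^{r N}; DD_lin: sigma0^2 + b N,
    with N the extant count in the fitted sympatric pool (defaults to the
    clade size).  Two-regime fits return a dict per regime.
    """
    fam = result.spec.family
    p = result.params
    N = result.n if n_lineages is None else n_lineages

    def one(slope, sigma2, regime=None):
        if fam == "BM":
            return sigma2
        if fam == "EB":
            if T is None:
                raise ValueError("EB rate at present needs the tree height T")
            return sigma2 * np.exp(slope * T)
        if fam == "DD_exp":
            return sigma2 * np.exp(slope * N)
        if fam == "DD_lin":
            return sigma2 + slope * N
        raise ValueError(f"rate at present undefined for {fam}")

    slope_name = _SLOPE_OF.get(fam)
    slope = getattr(p, slope_name) if slope_name else 0.0
    if fam == "BM":
        if isinstance(p.sigma2, dict):
            return {g: v for g, v in p.sigma2.items()}
        return p.sigma2
    if isinstance(slope, dict):
        return {g: one(s, p.sigma2) for g, s in slope.items()}
    return one(slope, p.sigma2)


def total_error(result, traits):
    """MLE nuisance error variance plus the clade-mean squared SE."""
    return float(result.params.sigma_err2 + np.mean(traits.se2))


# ----------------------------------------------------------------------
# Simulation-study harnesses
# ----------------------------------------------------------------------

def _scenario_for(family, n_regimes, n_tips, params, seed, **kw):
    half = n_tips // 2
    spec = ModelSpec(family, n_regimes)
    sc = ScenarioSpec(n_tips=n_tips, n_tropical=half,
                      n_temperate=n_tips - half, gen_spec=spec,
                      gen_params=params, seed=seed, **kw)
    return make_scenario(sc)


def recovery_experiment(family, true_params, n_tips=100, n_reps=20, seed=0,
                        n_regimes=2, n_starts=2, scenario_kw=None):
    """Parameter-recovery study: simulate under a model, refit the model.

    Returns a tidy DataFrame with one row per (rep, parameter) holding the
    truth and the MLE; the fit uses the *true* regime history (estimation
    noise, not reconstruction noise, is what is being measured).
    """
    rows = []
    spec = ModelSpec(family, n_regimes)
    for rep in range(n_reps):
        sc = _scenario_for(family, n_regimes, n_tips, true_params,
                           seed * 10007 + rep, **(scenario_kw or {}))
        res = fit_model(spec, sc.tree, sc.regimes, sc.traits,
                        n_starts=n_starts, seed=rep)
        truth = _flat_params(FitResult(spec, true_params, 0.0, n_tips))
        est = _flat_params(res)
        for k in truth:
            if k in est:
                rows.append({"rep": rep, "param": k, "truth": truth[k],
                             "estimate": est[k], "logLik": res.loglik,
                             "converged": res.converged})
    return pd.DataFrame(rows)


def selection_experiment(gen_family, gen_params, n_tips=128, n_reps=20,
                         seed=0, gen_regimes=2, candidate_specs=None,
                         n_starts=2):
    """Model-selection study: which model wins on data of known origin."""
    if candidate_specs is None:
        candidate_specs = standard_model_set()
    rows = []
    for rep in range(n_reps):
        sc = _scenario_for(gen_family, gen_regimes, n_tips, gen_params,
                           seed * 20011 + rep)
        fits = compare_models(candidate_specs, sc.tree, sc.regimes, sc.traits,
                              n_starts=n_starts, seed=rep)
        best = select_best(fits)
        w = akaike_weights([f.aicc for f in fits])
        rows.append({"rep": rep, "best": best.name,
                     **{f"w:{f.name}": wi for f, wi in zip(fits, w)}})
    return pd.DataFrame(rows)


def sympatry_power_experiment(S_tropical, S_temperate, sigma2=0.05,
                              n_tips=100, n_reps=20, seed=0,
                              p_tropical=0.5, p_temperate=0.5, n_starts=2,
                              scenario_kw=None):
    """Power to sign ln(|S_trop|/|S_temp|) under downsampled sympatry.

    Traits evolve under a two-regime MC model in which only a fraction of
    co-occurring taxa are truly sympatric; the fit then assumes full
    (continental) sympatry, mirroring the misspecification of interest.
    Returns a DataFrame with the estimated ratio and its sign per rep.
    """
    truth = np.log(abs(S_tropical) / abs(S_temperate))
    params = Params(z0=0.0, sigma2=sigma2,
                    S={"tropical": S_tropical, "temperate": S_temperate})
    spec = ModelSpec("MC", 2)
    rows = []
    for rep in range(n_reps):
        sc = _scenario_for("MC", 2, n_tips, params, seed * 30013 + rep,
                           p_tropical=p_tropical, p_temperate=p_temperate,
                           **(scenario_kw or {}))
        # fit WITHOUT the downsampling filter: assumed full sympatry
        res = fit_model(spec, sc.tree, sc.regimes, sc.traits,
                        n_starts=n_starts, seed=rep)
        est = ln_abs_ratio(res)
        rows.append({"rep": rep, "true_ln_ratio": truth, "est_ln_ratio": est,
                     "sign_correct": bool(np.sign(est) == np.sign(truth))})
    return pd.DataFrame(rows)
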