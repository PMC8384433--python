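"""Tip moments and Gaussian log-likelihood for all twelve trait models.

Every model here is a Gaussian process on the tree, so the data likelihood
is a multivariate normal whose mean ``m`` and covariance ``V`` over tips are
propagated root-to-present.  Two routes are provided:

* closed-form path formulas for the independent-evolution families
  (BM, OU, EB, single- and two-regime), and
* exact interval-wise propagation of the joint moment equations
  dm/dt = R m, dV/dt = R V + V Rᵀ + D for the interaction families
  (DD_exp, DD_lin, MC) — within each timeline interval R and D are
  constant, so the update is a matrix exponential, not an ODE step.
  Clique-structured sympatry (including full sympatry) admits a projector
  closed form; arbitrary overlap graphs fall back to a Van Loan block
  exponential.

Observed species means deviate from the modeled means by sampling error
(known SE_i^2) plus an estimated nuisance variance sigma_err^2; both are
added to the diagonal of V before evaluating the density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, expm

from .tree import build_event_timeline, shared_path_segments

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "Params",
    "MomentEngine",
    "InadmissibleParameters",
    "SingularCovariance",
    "tip_moments_closed_form",
    "tip_moments_ode",
    "log_likelihood",
    "mvn_loglik",
]

FAMILIES = ("BM", "OU", "EB", "DD_exp", "DD_lin", "MC")

#: free-parameter counts (single, two regime) before the nuisance error term
_BASE_K = {"BM": (2, 3), "OU": (3, 4), "EB": (3, 4),
           "DD_exp": (3, 4), "DD_lin": (3, 4), "MC": (3, 4)}


class InadmissibleParameters(ValueError):
    """Parameters outside the model's admissible region (e.g. negative rate)."""


class SingularCovariance(ValueError):
    """Tip covariance not positive definite even after error inflation."""


@dataclass(frozen=True)
class ModelSpec:
    """Which of the 12 models: family x regime structure (+ options)."""

    family: str
    n_regimes: int = 1
    biogeography: bool = False
    estimate_error: bool = False
    interact_across_regimes: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_regimes not in (1, 2):
            raise ValueError("n_regimes must be 1 or 2")

    @property
    def k(self):
        return _BASE_K[self.family][self.n_regimes - 1] + int(self.estimate_error)

    @property
    def uses_interactions(self):
        return self.family in ("DD_exp", "DD_lin", "MC")

    @property
    def name(self):
        return f"{self.family}_{'two' if self.n_regimes == 2 else 'single'}"


@dataclass
class Params:
    """Parameter container spanning all families.

    Regime-varying parameters (``theta``, ``r``, ``b``, ``S``) may be a
    scalar (single-regime) or a dict keyed by regime label.  ``sigma2`` is
    the rate at the root (sigma_0^2) for BM/EB/DD and the diffusion rate for
    OU/MC; ``sigma_err2`` the nuisance observational variance.
    """

    z0: float = 0.0
    sigma2: object = 1.0  # scalar; BM_two: dict of per-regime rates
    alpha: float = 0.0
    theta: object = None
    r: object = 0.0
    b: object = 0.0
    S: object = 0.0
    sigma_err2: float = 0.0

    def regime(self, name, label):
        v = getattr(self, name)
        if isinstance(v, dict):
            return v[label]
        return v

    def regime_array(self, name, labels):
        return np.array([self.regime(name, g) for g in labels], dtype=float)


def _validate(spec, params):
    s2 = params.sigma2
    vals = list(s2.values()) if isinstance(s2, dict) else [s2]
    if any(v <= 0 for v in vals):
        raise InadmissibleParameters("sigma2 must be > 0")
    if params.sigma_err2 < 0:
        raise InadmissibleParameters("sigma_err2 must be >= 0")
    if spec.family == "OU" and params.alpha < 0:
        raise InadmissibleParameters("alpha must be >= 0")


# ----------------------------------------------------------------------
# Closed forms: BM / OU / EB
# ----------------------------------------------------------------------

def _ebint(r, t0, t1):
    """Integral of e^{r t} on [t0, t1], with the r -> 0 limit."""
    if abs(r) < 1e-12:
        return t1 - t0
    return (np.exp(r * t1) - np.exp(r * t0)) / r


def tip_moments_closed_form(spec, params, tree, regimes=None):
    """Tip mean vector and covariance for BM, OU, and EB models.

    BM accumulates sigma^2(regime) x duration along shared paths; EB
    accumulates sigma_0^2 e^{r t} with t measured from the root; OU (shared
    alpha and sigma^2, regime-specific optima) uses the fixed-root
    ultrametric covariance with the root state at the root-regime optimum.
    """
    if spec.family not in ("BM", "OU", "EB"):
        raise ValueError("closed forms cover BM, OU, EB only")
    _validate(spec, params)
    if regimes is not None and regimes.tree is not tree:
        regimes = regimes.remapped_to(tree)
    n = tree.n_tips
    T = tree.T
    V = np.zeros((n, n))
    al = params.alpha

    if spec.family == "OU" and al > 0:
        for i in range(n):
            for j in range(i, n):
                tm = T if i == j else float(tree.depth[tree.mrca(i, j)])
                dij = 2.0 * (T - tm)
                V[i, j] = V[j, i] = params.sigma2 / (2 * al) * np.exp(-al * dij) \
                    * (1 - np.exp(-2 * al * tm))
    else:
        for i in range(n):
            for j in range(i, n):
                segs = shared_path_segments(tree, regimes, i, j)
                acc = 0.0
                for t0, t1, g in segs:
                    if spec.family == "BM" or (spec.family == "OU" and al == 0):
                        s2 = params.sigma2 if g is None else params.regime("sigma2", g)
                        acc += s2 * (t1 - t0)
                    else:  # EB
                        rg = params.r if g is None else params.regime("r", g)
                        acc += params.sigma2 * _ebint(rg, t0, t1)
                V[i, j] = V[j, i] = acc

    # means
    if spec.family != "OU" or params.theta is None:
        m = np.full(n, params.z0)
    else:
        theta = params.theta
        if not isinstance(theta, dict):
            m = np.full(n, theta)
        elif al == 0:
            m = np.full(n, theta[regimes.root_label])
        else:
            th_root = theta[regimes.root_label]
            m = np.zeros(n)
            for i in range(n):
                segs = shared_path_segments(tree, regimes, i, i)
                acc = th_root * np.exp(-al * T)
                for t0, t1, g in segs:
                    acc += theta[g] * (np.exp(-al * (T - t1)) - np.exp(-al * (T - t0)))
                m[i] = acc
    return m, V


# ----------------------------------------------------------------------
# Interval-exact moment propagation (all families)
# ----------------------------------------------------------------------

class MomentEngine:
    """Propagates (m, V) across a fixed event timeline.

    The timeline (tree + regime history + sympatry structure) is digested
    once; each :meth:`moments` call is then pure numeric work, which is what
    makes ML optimization over the interaction models tractable.
    """

    def __init__(self, timeline, interact_across_regimes=False):
        self.timeline = timeline
        self.across = interact_across_regimes
        tree = timeline.tree
        self.n_tips = tree.n_tips
        labels = list(dict.fromkeys(
            [timeline.regimes.root_label]
            + [s for segs in timeline.regimes.segments.values()
               for _, s in segs]))
        pref = [g for g in ("tropical", "temperate") if g in labels]
        self.labels = tuple(pref + [g for g in labels if g not in pref])
        lab_idx = {g: i for i, g in enumerate(self.labels)}
        self._steps = []
        prev_pos_map = None
        for iv in timeline.intervals:
            pos = {v: i for i, v in enumerate(iv.alive)}
            if prev_pos_map is None:
                src = None
            else:
                src = np.array(
                    [prev_pos_map[v] if v in prev_pos_map
                     else prev_pos_map[tree.parent[v]] for v in iv.alive],
                    dtype=int)
            prev_pos_map = pos
            A = iv.sympatry
            g = np.asarray(iv.regime, dtype=object)
            gi = np.array([lab_idx[x] for x in iv.regime], dtype=int)
            same = (gi[:, None] == gi[None, :]).astype(float)
            mask = A.copy() if self.across else A * same
            d = mask.sum(axis=1)
            cliques = self._clique_partition(A)
            blocks = None
            if cliques is not None and not self.across:
                blocks = []
                for comp in cliques:
                    for li in np.unique(gi[comp]):
                        idx = comp[gi[comp] == li]
                        if len(idx) >= 2:
                            blocks.append((idx, int(li)))
            self._steps.append({
                "t0": iv.t0, "t1": iv.t1, "dt": iv.dt, "alive": iv.alive,
                "src": src, "g": g, "gi": gi, "A": A, "mask": mask, "d": d,
                "cliques": cliques, "blocks": blocks,
            })
        last = timeline.intervals[-1]
        if sorted(last.alive) != list(range(self.n_tips)):
            raise ValueError("timeline does not end with all tips alive")

    @staticmethod
    def _clique_partition(A):
        """Connected components of A if every component is complete, else None."""
        n = A.shape[0]
        seen = np.zeros(n, dtype=bool)
        comps = []
        for s in range(n):
            if seen[s]:
                continue
            comp = [s]
            seen[s] = True
            stack = [s]
            while stack:
                u = stack.pop()
                for v in np.flatnonzero(A[u] > 0):
                    if not seen[v]:
                        seen[v] = True
                        comp.append(v)
                        stack.append(v)
            comp = np.array(sorted(comp))
            if not np.all(A[np.ix_(comp, comp)] > 0):
                return None
            comps.append(comp)
        return comps

    # ------------------------------------------------------------------
    def _by_label(self, params, name):
        return np.array([params.regime(name, g) for g in self.labels],
                        dtype=float)

    def moments(self, spec, params):
        """Tip means and covariance under ``spec``/``params``."""
        _validate(spec, params)
        fam = spec.family
        # per-regime parameter lookup tables, indexed by gi
        if fam == "BM":
            tab = self._by_label(params, "sigma2")
        elif fam in ("EB", "DD_exp"):
            tab = self._by_label(params, "r")
        elif fam == "DD_lin":
            tab = self._by_label(params, "b")
        elif fam == "MC":
            tab = self._by_label(params, "S")
        elif fam == "OU":
            if params.theta is None:
                tab = np.full(len(self.labels), float(params.z0))
            elif isinstance(params.theta, dict):
                tab = self._by_label(params, "theta")
            else:
                tab = np.full(len(self.labels), float(params.theta))
        m = None
        V = None
        for st in self._steps:
            if st["src"] is None:
                k = len(st["alive"])
                z0 = params.z0
                if fam == "OU" and params.theta is not None:
                    z0 = tab[st["gi"][0]] if isinstance(params.theta, dict) \
                        else float(params.theta)
                    # root state = root-regime optimum
                    ri = self.labels.index(self.timeline.regimes.root_label)
                    z0 = tab[ri]
                m = np.full(k, float(z0))
                V = np.zeros((k, k))
            else:
                src = st["src"]
                m = m[src]
                V = V[np.ix_(src, src)]
            self._advance(st, spec, params, tab, m, V)
        # final alive set is the tips; reorder to tip-id order
        alive = np.array(self._steps[-1]["alive"])
        idx = np.argsort(alive)
        return m[idx].copy(), V[np.ix_(idx, idx)].copy()

    # ------------------------------------------------------------------
    def _advance(self, st, spec, params, tab, m, V):
        fam = spec.family
        dt = st["dt"]
        if dt <= 0:
            return
        gi = st["gi"]
        k = len(gi)
        if fam in ("BM", "EB", "DD_exp", "DD_lin"):
            V[np.diag_indices(k)] += self._diffusion_integral(st, spec, params,
                                                              tab[gi])
        elif fam == "OU":
            al = params.alpha
            s2 = params.sigma2
            th = tab[gi]
            if al == 0:
                V[np.diag_indices(k)] += s2 * dt
            else:
                e = np.exp(-al * dt)
                m[:] = th + e * (m - th)
                V *= e * e
                V[np.diag_indices(k)] += s2 / (2 * al) * (1 - e * e)
        elif fam == "MC":
            S = tab[gi]
            if np.all(S == 0):
                V[np.diag_indices(k)] += params.sigma2 * dt
                return
            if st["blocks"] is not None:
                self._mc_clique_update(st, params, tab, m, V)
            else:
                E, Qint = self._mc_vanloan(st, params, S)
                m[:] = E @ m
                V[:, :] = E @ V @ E.T + Qint
        else:  # pragma: no cover
            raise ValueError(fam)

    def _diffusion_integral(self, st, spec, params, vals):
        """Per-lineage integral of sigma^2(t) over the interval (diagonal D)."""
        fam = spec.family
        dt = st["dt"]
        if fam == "BM":
            return vals * dt  # vals = per-lineage sigma^2
        if fam == "EB":
            r = vals
            out = np.full(len(r), dt)
            nz = np.abs(r) > 1e-12
            out[nz] = (np.exp(r[nz] * st["t1"]) - np.exp(r[nz] * st["t0"])) / r[nz]
            return params.sigma2 * out
        d = st["d"]
        if fam == "DD_exp":
            return params.sigma2 * np.exp(vals * d) * dt
        # DD_lin
        rate = params.sigma2 + vals * d
        if np.any(rate < 0):
            j = int(np.argmin(rate))
            raise InadmissibleParameters(
                f"DD_lin rate is negative ({rate[j]:.4g}) for lineage node "
                f"{st['alive'][j]} on interval [{st['t0']:.4g}, {st['t1']:.4g}]"
            )
        return rate * dt

    def _mc_clique_update(self, st, params, tab, m, V):
        """In-place exact MC update when sympatry is a union of cliques.

        e^{R dt} = I + sum_g c_g Q_g over disjoint centered projectors, so
        the conjugation reduces to per-block row and column sweeps.
        """
        dt = st["dt"]
        s2 = params.sigma2
        k = len(st["gi"])
        acts = []
        for idx, li in st["blocks"]:
            Sg = tab[li]
            if Sg == 0:
                continue
            c = np.exp(-Sg * dt) - 1.0
            phi = (1 - np.exp(-2 * Sg * dt)) / (2 * Sg) - dt
            acts.append((idx, c, phi))
        # left: E V, and E m
        for idx, c, _ in acts:
            rows = V[idx, :]
            V[idx, :] = rows + c * (rows - rows.mean(axis=0))
            mm = m[idx]
            m[idx] = mm + c * (mm - mm.mean())
        # right: (E V) E^T
        for idx, c, _ in acts:
            cols = V[:, idx]
            V[:, idx] = cols + c * (cols - cols.mean(axis=1, keepdims=True))
        # integrated noise
        V[np.diag_indices(k)] += s2 * dt
        for idx, _, phi in acts:
            q = len(idx)
            blk = np.full((q, q), -s2 * phi / q)
            blk[np.diag_indices(q)] += s2 * phi
            V[np.ix_(idx, idx)] += blk

    def _mc_vanloan(self, st, params, S):
        """Propagator for an arbitrary sympatry graph (Van Loan exponential)."""
        k = len(S)
        dt = st["dt"]
        s2 = params.sigma2
        mask = st["mask"]
        d = mask.sum(axis=1)
        W = mask / d[:, None]
        R = S[:, None] * (W - np.eye(k))
        D = s2 * np.eye(k)
        H = np.zeros((2 * k, 2 * k))
        H[:k, :k] = R
        H[:k, k:] = D
        H[k:, k:] = -R.T
        F = expm(H * dt)
        E = F[:k, :k]
        Qint = F[:k, k:] @ E.T
        Qint = 0.5 * (Qint + Qint.T)
        return E, Qint


def tip_moments_ode(spec, params, timeline):
    """Tip moments for the interaction families via interval-exact propagation."""
    eng = MomentEngine(timeline, interact_across_regimes=spec.interact_across_regimes)
    return eng.moments(spec, params)


# ----------------------------------------------------------------------
# Log-likelihood
# ----------------------------------------------------------------------

def mvn_loglik(y, m, C):
    """Stable multivariate-normal log-density via Cholesky."""
    C = 0.5 * (C + C.T)
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        raise SingularCovariance(
            "tip covariance is singular; consider a small jitter or check "
            "for pathological parameters") from None
    r = y - m
    alpha = cho_solve(cf, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    n = len(y)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ alpha))


def log_likelihood(spec, params, tree, regimes, traits, biogeo=None,
                   engine=None, timeline=None, interactions=None):
    """Log-likelihood of observed species means under one of the 12 models.

    ``traits`` must cover every tip; rows are aligned to the tree
    internally, so the value is invariant to row order.  The observational
    variance SE_i^2 + sigma_err^2 is added to the tip covariance diagonal.
    """
    td = traits.aligned_to(tree)
    if spec.family in ("BM", "OU", "EB") and engine is None:
        m, V = tip_moments_closed_form(spec, params, tree, regimes)
    else:
        if engine is None:
            if timeline is None:
                timeline = build_event_timeline(
                    tree, regimes, biogeo if spec.biogeography else None,
                    interactions)
            engine = MomentEngine(
                timeline, interact_across_regimes=spec.interact_across_regimes)
        m, V = engine.moments(spec, params)
    C = V + np.diag(td.se2 + params.sigma_err2)
    return mvn_loglik(td.mean, m, C)
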