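"""Forward simulation: traits under all 12 models, plus fixture generators.

Trait paths follow the Euler–Maruyama recursion per alive lineage per
timeline interval,

    X <- X + drift * h + sqrt(rate * h) * N(0, 1),

with drift 0 for BM/EB/DD, alpha (theta_regime - X) for OU, and
S_regime (sympatric same-regime weighted mean - X) for MC; the diffusion
rate is sigma0^2 e^{r t} (EB), sigma0^2 e^{r d_j} (DD_exp),
sigma0^2 + b d_j (DD_lin, negative rates are a hard error), or sigma^2
(BM/OU/MC), where d_j counts same-regime sympatric lineages, self included.
Branchings copy the parent state to both daughters.

The stepping here is intentionally independent of the likelihood module's
moment propagation: agreement between simulated tip moments and the
analytic ones is a two-route consistency check, not a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import InadmissibleParameters, ModelSpec, Params
from .tree import (
    BiogeoHistory,
    PhyloTree,
    RegimeHistory,
    TraitData,
    build_event_timeline,
)

__all__ = [
    "SimConfig",
    "simulate_traits",
    "simulate_tip_ensemble",
    "add_observational_error",
    "simulate_bd_tree",
    "simulate_regime_history",
    "simulate_biogeo_history",
]


@dataclass
class SimConfig:
    """Simulation settings: spec/params plus step size and seed."""

    spec: ModelSpec
    params: Params
    dt: float = None  # default T/1000
    seed: int = 0
    n_reps: int = 1


def simulate_tip_ensemble(tree, regimes, spec, params, biogeo=None, dt=None,
                          seed=0, n_reps=1, interactions=None, timeline=None):
    """Simulate ``n_reps`` independent trait histories; returns (n_reps, n_tips).

    Columns follow the tree's tip order.  Identical seeds give identical
    output.
    """
    if timeline is None:
        timeline = build_event_timeline(
            tree, regimes, biogeo if spec.biogeography else None, interactions)
    T = tree.T
    if dt is None:
        dt = T / 1000.0
    if not (0 < dt <= T / 100.0):
        raise ValueError("dt must be positive and at most T/100")
    rng = np.random.default_rng(seed)
    fam = spec.family

    z0 = params.z0
    if fam == "OU" and params.theta is not None:
        z0 = params.theta[regimes.root_label] if isinstance(params.theta, dict) \
            else params.theta

    X = None
    prev_pos = None
    for iv in timeline.intervals:
        if X is None:
            X = np.full((n_reps, len(iv.alive)), float(z0))
        else:
            src = np.array(
                [prev_pos[v] if v in prev_pos else prev_pos[tree.parent[v]]
                 for v in iv.alive], dtype=int)
            X = X[:, src]
        prev_pos = {v: i for i, v in enumerate(iv.alive)}
        if iv.dt <= 0:
            continue
        g = np.asarray(iv.regime, dtype=object)
        k = len(g)
        same = (g[:, None] == g[None, :]).astype(float)
        mask = iv.sympatry.copy() if spec.interact_across_regimes \
            else iv.sympatry * same
        d = mask.sum(axis=1)

        if fam in ("DD_exp", "DD_lin"):
            if fam == "DD_exp":
                r = params.regime_array("r", g)
                rate = params.sigma2 * np.exp(r * d)
            else:
                b = params.regime_array("b", g)
                rate = params.sigma2 + b * d
                if np.any(rate < 0):
                    j = int(np.argmin(rate))
                    raise InadmissibleParameters(
                        f"DD_lin rate negative for lineage node {iv.alive[j]} "
                        f"at time {iv.t0:.4g}")
        elif fam == "BM":
            rate = params.regime_array("sigma2", g)
        elif fam in ("OU", "MC"):
            rate = np.full(k, float(params.sigma2))

        n_sub = max(1, int(np.ceil(iv.dt / dt)))
        h = iv.dt / n_sub
        if fam == "MC":
            S = params.regime_array("S", g)
            W = mask / d[:, None]
        elif fam == "OU":
            al = params.alpha
            if params.theta is None:
                th = np.full(k, params.z0)
            elif isinstance(params.theta, dict):
                th = np.array([params.theta[x] for x in g])
            else:
                th = np.full(k, float(params.theta))
        t = iv.t0
        for _ in range(n_sub):
            if fam == "EB":
                r = params.regime_array("r", g)
                rate = params.sigma2 * np.exp(r * t)
            if fam == "MC":
                drift = S * (X @ W.T - X)
            elif fam == "OU":
                drift = al * (th - X)
            else:
                drift = 0.0
            X = X + drift * h + np.sqrt(rate * h) * rng.standard_normal((n_reps, k))
            t += h

    alive = np.array(timeline.intervals[-1].alive)
    idx = np.argsort(alive)
    return X[:, idx]


def simulate_traits(tree, regimes, spec, params, biogeo=None, dt=None, seed=0,
                    interactions=None, timeline=None):
    """Simulate one realization and wrap the true tip means as TraitData."""
    x = simulate_tip_ensemble(tree, regimes, spec, params, biogeo=biogeo,
                              dt=dt, seed=seed, n_reps=1,
                              interactions=interactions, timeline=timeline)[0]
    n = tree.n_tips
    return TraitData(list(tree.tip_labels), x, np.ones(n, dtype=int), np.zeros(n))


def add_observational_error(traits, sigma_err2=0.0, seed=0, se2=None):
    """Add independent N(0, SE_i^2 + sigma_err^2) noise to species means."""
    if sigma_err2 < 0:
        raise ValueError("sigma_err2 must be >= 0")
    se2 = traits.se2 if se2 is None else np.asarray(se2, dtype=float)
    if np.any(se2 < 0):
        raise ValueError("se2 must be >= 0")
    rng = np.random.default_rng(seed)
    var = se2 + sigma_err2
    obs = traits.mean + np.sqrt(var) * rng.standard_normal(len(traits))
    return TraitData(list(traits.species), obs, traits.n.copy(), se2.copy())


# ----------------------------------------------------------------------
# Fixture generators
# ----------------------------------------------------------------------

def simulate_bd_tree(n_tips, birth=1.0, death=0.0, seed=0, max_retries=100):
    """Constant-rate birth–death tree conditioned on ``n_tips`` survivors.

    Forward (Gillespie) simulation from the root split; when the standing
    diversity first reaches ``n_tips`` the present is placed an exponential
    waiting time later, extinct lineages are pruned, and unifurcations
    suppressed.  Full extinction triggers a bounded resimulation.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth <= 0 or death < 0:
        raise ValueError("need birth > 0 and death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        tree = _bd_attempt(n_tips, birth, death, rng)
        if tree is not None:
            return tree
    raise RuntimeError("birth-death simulation went extinct in every retry")


def _bd_attempt(n_tips, birth, death, rng):
    # lineage records: parent, t_birth, t_end (None while alive), children
    parent = [-1, 0, 0]
    t_birth = [0.0, 0.0, 0.0]
    t_end = [0.0, None, None]
    children = [[1, 2], [], []]
    alive = [1, 2]
    t = 0.0
    while len(alive) < n_tips:
        tot = len(alive) * (birth + death)
        t += rng.exponential(1.0 / tot)
        lin = alive[rng.integers(len(alive))]
        if rng.random() < birth / (birth + death):
            for _ in range(2):
                parent.append(lin)
                t_birth.append(t)
                t_end.append(None)
                children.append([])
                children[lin].append(len(parent) - 1)
                alive.append(len(parent) - 1)
            t_end[lin] = t
            alive.remove(lin)
        else:
            t_end[lin] = t
            alive.remove(lin)
            if not alive:
                return None
    t_present = t + rng.exponential(1.0 / (len(alive) * (birth + death)))
    for lin in alive:
        t_end[lin] = t_present
    alive_set = set(alive)

    # prune extinct subtrees, suppress unifurcations
    def survives(v):
        if v in alive_set:
            return True
        return any(survives(c) for c in children[v])

    import sys
    sys.setrecursionlimit(max(10000, 10 * len(parent)))

    def build(v, t_start):
        """Return (node_repr) for surviving part of lineage v; contract chains."""
        while True:
            kids = [c for c in children[v] if survives(c)]
            if v in alive_set:
                return ("tip", v, t_end[v] - t_start)
            if len(kids) == 2:
                left = build(kids[0], t_end[v])
                right = build(kids[1], t_end[v])
                return ("int", v, t_end[v] - t_start, left, right)
            # single surviving child: extend through
            v = kids[0]
            # keep same t_start; loop continues with child's children

    root_kids = [c for c in children[0] if survives(c)]
    if len(root_kids) < 2:
        # one root child died out entirely: re-root at first bifurcation
        node = build(root_kids[0], 0.0)
        node = _strip_stem(node)
        if node[0] != "int":
            return None
    else:
        node = ("int", 0, 0.0, build(root_kids[0], 0.0), build(root_kids[1], 0.0))

    # flatten to arrays
    tips, ints = [], []

    def collect(nd):
        if nd[0] == "tip":
            tips.append(nd)
        else:
            ints.append(nd)
            collect(nd[3])
            collect(nd[4])

    collect(node)
    n = len(tips)
    if n != n_tips:
        return None
    ids = {}
    for i, nd in enumerate(tips):
        ids[id(nd)] = i
    for j, nd in enumerate(ints):
        ids[id(nd)] = n + j
    parent_arr = np.full(n + len(ints), -1, dtype=int)
    blen = np.zeros(n + len(ints))

    def assign(nd, pid):
        v = ids[id(nd)]
        parent_arr[v] = pid
        blen[v] = nd[2] if pid >= 0 else 0.0
        if nd[0] == "int":
            assign(nd[3], v)
            assign(nd[4], v)

    assign(node, -1)
    labels = [f"t{i + 1}" for i in range(n)]
    return PhyloTree(parent_arr, blen, labels)


def _strip_stem(node):
    """Drop the stem of a re-rooted subtree (root branch length -> 0)."""
    if node[0] == "tip":
        return node
    return ("int", node[1], 0.0, node[3], node[4])


def simulate_regime_history(tree, model, seed=0, root_state=None):
    """Unconditional Mk simulation of a regime history along a tree."""
    rng = np.random.default_rng(seed)
    states = model.states
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    if root_state is None:
        root = int(rng.choice(k, p=model.root_freq / model.root_freq.sum()))
    else:
        root = sidx[root_state]
    node_state = {tree.root: root}
    segments = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = node_state[tree.parent[v]]
        L = float(tree.blen[v])
        t = 0.0
        segs = []
        while True:
            out = -model.Q[s, s]
            if out <= 0:
                segs.append((L - t, states[s]))
                break
            w = rng.exponential(1.0 / out)
            if t + w >= L:
                segs.append((L - t, states[s]))
                break
            segs.append((w, states[s]))
            t += w
            p = model.Q[s].copy()
            p[s] = 0.0
            p = p / p.sum()
            s = int(rng.choice(k, p=p))
        # merge zero-length artifacts
        segments[v] = [(d, st) for d, st in segs if d > 0] or [(L, states[s])]
        node_state[v] = s
    return RegimeHistory(tree, segments, states[root], states)


def simulate_biogeo_history(tree, areas, gain=0.1, loss=0.1, seed=0,
                            root_occupancy=None):
    """Simulate per-area occupancy histories (independent gain/loss).

    ``areas`` is a count or a tuple of names.  Loss of the last occupied
    area is suppressed so every lineage always occupies at least one area.
    The root occupancy defaults to a uniform random non-empty subset.
    """
    if isinstance(areas, int):
        areas = tuple(f"area{i + 1}" for i in range(areas))
    K = len(areas)
    if gain < 0 or loss < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    full = (1 << K) - 1
    if root_occupancy is None:
        root = 0
        while root == 0:
            root = int(rng.integers(1, full + 1))
    else:
        root = int(root_occupancy)
        if not (0 < root <= full):
            raise ValueError("root occupancy must be a non-empty subset")
    node_state = {tree.root: root}
    segments = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = node_state[tree.parent[v]]
        L = float(tree.blen[v])
        t = 0.0
        segs = []
        while True:
            occ = [a for a in range(K) if s >> a & 1]
            rates = []
            for a in range(K):
                if s >> a & 1:
                    rates.append(loss if len(occ) > 1 else 0.0)
                else:
                    rates.append(gain)
            tot = sum(rates)
            if tot <= 0:
                segs.append((L - t, s))
                break
            w = rng.exponential(1.0 / tot)
            if t + w >= L:
                segs.append((L - t, s))
                break
            segs.append((w, s))
            t += w
            a = int(rng.choice(K, p=np.array(rates) / tot))
            s ^= 1 << a
        segments[v] = [(d, st) for d, st in segs if d > 0] or [(L, s)]
        node_state[v] = s
    return BiogeoHistory(tree, segments, root, areas)
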