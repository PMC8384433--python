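"""Regime and sympatry construction.

Covers the discrete side of the toolkit: classifying species into
tropical / temperate / both from breeding-range latitudes, fitting an
all-rates-different Mk model to tip states by Felsenstein pruning, drawing
stochastic character maps consistent with the fitted model, collapsing the
three-state maps onto two competitive regimes, range-overlap (sympatry)
coefficients, slicing oversized trees into tractable subclades, and
downsampling continental sympatry for misspecification studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .tree import HistoryError, PhyloTree, RegimeHistory

__all__ = [
    "LatitudeBand",
    "MkModel",
    "TROPICS_BOUNDARY",
    "STATES3",
    "classify_latitude",
    "collapse_states",
    "collapse_history",
    "fit_mk",
    "mk_loglik",
    "mk_node_conditionals",
    "sample_stochastic_maps",
    "szymkiewicz_simpson",
    "is_sympatric",
    "tropicality_index",
    "slice_tree",
    "downsample_sympatry",
    "InteractionFilter",
]

#: Latitude of the tropics of Cancer/Capricorn used to delimit the tropics.
TROPICS_BOUNDARY = 23.437

STATES3 = ("tropical", "temperate", "both")


@dataclass(frozen=True)
class LatitudeBand:
    """Breeding-range latitudinal extent, degrees in [-90, 90]."""

    lat_min: float
    lat_max: float

    def __post_init__(self):
        if not (-90 <= self.lat_min <= self.lat_max <= 90):
            raise ValueError(f"invalid latitude band {self.lat_min}..{self.lat_max}")


def classify_latitude(band, boundary=TROPICS_BOUNDARY):
    """Classify a breeding range as tropical, temperate, or both.

    A range strictly inside (-boundary, +boundary) is tropical; one wholly
    outside the closed tropics is temperate; anything else — including a
    range touching the boundary exactly — is "both".
    """
    if not isinstance(band, LatitudeBand):
        band = LatitudeBand(*band)
    if -boundary < band.lat_min and band.lat_max < boundary:
        return "tropical"
    if band.lat_min > boundary or band.lat_max < -boundary:
        return "temperate"
    return "both"


def collapse_states(state):
    """Collapse the 3 breeding-habitat states onto 2 competitive regimes.

    Species whose range includes any temperate breeding ("both") are pooled
    with "temperate"; only exclusively tropical breeders stay "tropical".
    """
    if state == "tropical":
        return "tropical"
    if state in ("temperate", "both"):
        return "temperate"
    raise ValueError(f"unknown breeding-habitat state {state!r}")


def collapse_history(history):
    """Apply :func:`collapse_states` segment-wise to a stochastic map."""
    return history.mapped(collapse_states)


# ----------------------------------------------------------------------
# Mk model: ARD rates, pruning likelihood, ML fit
# ----------------------------------------------------------------------

@dataclass
class MkModel:
    """Continuous-time Markov model on discrete states (all-rates-different).

    ``Q[i, j]`` is the instantaneous rate from state i to state j; rows sum
    to zero. Root state frequencies are fixed equal (the make.simmap
    default) unless given.
    """

    states: tuple
    Q: np.ndarray
    root_freq: np.ndarray = None
    loglik: float = None
    boundary: bool = False  # MLE pinned at a rate boundary (e.g. uniform tips)

    def __post_init__(self):
        self.states = tuple(self.states)
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise ValueError("Q has wrong shape")
        off = self.Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-8 * (1 + np.max(np.abs(self.Q))):
            raise ValueError("generator rows must sum to 0")
        if self.root_freq is None:
            self.root_freq = np.full(k, 1.0 / k)
        self.root_freq = np.asarray(self.root_freq, dtype=float)

    @property
    def k(self):
        return len(self.states)


def _tip_partials(tree, states, tip_states):
    n = tree.n_tips
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    L = np.zeros((tree.n_nodes, k))
    for i in range(n):
        lab = tree.tip_labels[i]
        if lab not in tip_states:
            raise ValueError(f"tip {lab!r} has no state")
        s = tip_states[lab]
        if s not in index:
            raise ValueError(f"state {s!r} not in {states}")
        L[i, index[s]] = 1.0
    return L


def mk_loglik(tree, model, tip_states, return_partials=False):
    """Felsenstein-pruning log-likelihood of tip states under ``model``."""
    L = _tip_partials(tree, model.states, tip_states)
    P = {}
    for v in range(tree.n_nodes):
        if v != tree.root:
            P[v] = expm(model.Q * tree.blen[v])
    scale = 0.0
    for v in tree.postorder():
        if v < tree.n_tips:
            continue
        part = np.ones(model.k)
        for c in tree.children[v]:
            part = part * (P[c] @ L[c])
        m = part.max()
        if m <= 0:
            return (-np.inf, L, P) if return_partials else -np.inf
        L[v] = part / m
        scale += np.log(m)
    ll = float(np.log(model.root_freq @ L[tree.root]) + scale)
    if return_partials:
        return ll, L, P
    return ll


def fit_mk(tree, tip_states, states=None, n_starts=3, seed=0):
    """ML fit of the all-rates-different Mk model to tip states.

    Returns an :class:`MkModel` with the ML generator and its log-likelihood.
    Degenerate data (all tips identical) yields a boundary MLE with rates
    pinned near zero and ``boundary=True`` — flagged, not an error.
    """
    if states is None:
        states = tuple(sorted(set(tip_states.values()),
                              key=lambda s: (STATES3.index(s) if s in STATES3 else 99, s)))
    k = len(states)
    observed = set(tip_states[l] for l in tree.tip_labels)
    if len(observed) == 1:
        Q = np.zeros((k, k))
        model = MkModel(states, Q, boundary=True)
        model.loglik = mk_loglik(tree, model, tip_states)
        return model

    npar = k * (k - 1)
    rng = np.random.default_rng(seed)
    # characteristic rate scale: one expected change over the tree depth
    scale0 = 1.0 / max(tree.T, 1e-9)

    def build_Q(logr):
        r = np.exp(logr)
        Q = np.zeros((k, k))
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = r[idx]
                    idx += 1
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def nll(logr):
        if np.any(logr > 12) or np.any(logr < -40):
            return 1e10
        model = MkModel(states, build_Q(np.clip(logr, -40, 12)))
        ll = mk_loglik(tree, model, tip_states)
        return -ll if np.isfinite(ll) else 1e10

    best = None
    for s in range(n_starts):
        x0 = np.full(npar, np.log(scale0))
        if s > 0:
            x0 = x0 + rng.normal(0, 1.0, npar)
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    Q = build_Q(np.clip(best.x, -40, 12))
    model = MkModel(states, Q, boundary=bool(np.any(best.x <= -35)))
    model.loglik = -best.fun
    return model


def mk_node_conditionals(tree, model, tip_states):
    """Exact marginal posterior state probabilities at every internal node.

    Computed by pruning up and a root-to-tip downward pass; used as the
    oracle against which stochastic-map frequencies converge.
    """
    ll, L, P = mk_loglik(tree, model, tip_states, return_partials=True)
    k = model.k
    # downward partial G[v]: prob of data outside clade v given state at v
    G = np.zeros((tree.n_nodes, k))
    G[tree.root] = model.root_freq
    for v in tree.preorder():
        if v < tree.n_tips:
            continue
        kids = tree.children[v]
        down = [P[c] @ L[c] for c in kids]
        for a, c in enumerate(kids):
            sib = np.ones(k)
            for b, d in enumerate(down):
                if b != a:
                    sib = sib * d
            G[c] = (G[v] * sib) @ P[c]
    post = G * L
    Z = post.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        post = post / Z
    return {v: post[v] for v in range(tree.n_nodes)}


# -- endpoint-conditioned path sampling via uniformization ---------------

def _sample_path(Q, P_l, length, a, b, rng, n_max=500):
    """Sample a CTMC path on [0, length] conditioned on endpoints a -> b."""
    k = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        if a != b:
            raise HistoryError("zero-rate model cannot connect differing states")
        return [(length, a)]
    R = np.eye(k) + Q / mu
    pab = P_l[a, b]
    if pab <= 0:
        raise HistoryError("endpoint combination has zero probability")
    # sample number of uniformized jumps
    Rpow = [np.eye(k)]
    u = rng.random() * pab
    acc = 0.0
    pois = np.exp(-mu * length)
    n = 0
    while True:
        acc += pois * Rpow[-1][a, b]
        if acc >= u or n >= n_max:
            break
        n += 1
        pois *= mu * length / n
        Rpow.append(Rpow[-1] @ R)
    # jump times and states
    times = np.sort(rng.random(n)) * length
    seq = [a]
    for i in range(1, n):
        w = Rpow[1][seq[-1]] * Rpow[n - i][:, b]
        w = w / w.sum()
        seq.append(int(rng.choice(k, p=w)))
    if n:
        seq.append(b)
    # collapse virtual (self) jumps into segments
    path_states = seq
    segs = []
    cur_state = path_states[0]
    cur_start = 0.0
    for i, t in enumerate(times):
        nxt = path_states[i + 1]
        if nxt != cur_state:
            segs.append((t - cur_start, cur_state))
            cur_state = nxt
            cur_start = t
    segs.append((length - cur_start, cur_state))
    return segs


def sample_stochastic_maps(tree, model, tip_states, count=20, seed=0):
    """Draw a bank of stochastic character maps (Bollback sampling).

    Node states are sampled from their joint conditional distribution, then
    each branch's internal history is drawn by uniformization conditioned on
    its endpoint states. Returns ``count`` :class:`RegimeHistory` objects on
    ``tree`` (pre-collapse: the full model alphabet).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    ll, L, P = mk_loglik(tree, model, tip_states, return_partials=True)
    if not np.isfinite(ll):
        raise HistoryError("tip states impossible under this model "
                           "(zero-rate transitions required)")
    k = model.k
    index = {s: i for i, s in enumerate(model.states)}
    maps = []
    for _ in range(count):
        node_state = {}
        w = model.root_freq * L[tree.root]
        node_state[tree.root] = int(rng.choice(k, p=w / w.sum()))
        for v in tree.preorder():
            for c in tree.children[v]:
                w = P[c][node_state[v]] * L[c]
                node_state[c] = int(rng.choice(k, p=w / w.sum()))
        segments = {}
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            a, b = node_state[tree.parent[v]], node_state[v]
            segs = _sample_path(model.Q, P[v], float(tree.blen[v]), a, b, rng)
            segments[v] = [(d, model.states[s]) for d, s in segs]
        maps.append(RegimeHistory(tree, segments,
                                  model.states[node_state[tree.root]],
                                  model.states))
    return maps


# ----------------------------------------------------------------------
# Sympatry
# ----------------------------------------------------------------------

def szymkiewicz_simpson(overlap_area, area1, area2):
    """Range-overlap coefficient: overlap / min(area1, area2)."""
    if area1 <= 0 or area2 <= 0:
        raise ValueError("range areas must be positive")
    m = min(area1, area2)
    if overlap_area < 0 or overlap_area > m * (1 + 1e-12):
        raise ValueError("overlap cannot exceed the smaller range")
    return min(overlap_area, m) / m


def is_sympatric(coefficient, threshold=0.20):
    """Sympatry call at the default 20% overlap threshold."""
    return coefficient >= threshold


def tropicality_index(tip_regimes):
    """Proportion of species with exclusively tropical breeding ranges.

    ``tip_regimes``: mapping or iterable of regime labels ("tropical" /
    "temperate") for the tips of a clade.
    """
    vals = list(tip_regimes.values()) if hasattr(tip_regimes, "values") else list(tip_regimes)
    if not vals:
        raise ValueError("need at least one tip")
    return sum(1 for v in vals if v == "tropical") / len(vals)


# ----------------------------------------------------------------------
# Tree slicing
# ----------------------------------------------------------------------

def _extract_clade(tree, v):
    """Subtree rooted at node v (stem dropped), as a new PhyloTree."""
    nodes = []
    stack = [v]
    while stack:
        u = stack.pop()
        nodes.append(u)
        stack.extend(tree.children[u])
    remap = {}
    tips = [u for u in nodes if u < tree.n_tips]
    internals = [u for u in nodes if u >= tree.n_tips]
    for i, u in enumerate(tips + internals):
        remap[u] = i
    m = len(nodes)
    parent = np.full(m, -1, dtype=int)
    blen = np.zeros(m)
    for u in nodes:
        if u != v:
            parent[remap[u]] = remap[tree.parent[u]]
            blen[remap[u]] = tree.blen[u]
    labels = [tree.tip_labels[u] for u in tips]
    return PhyloTree(parent, blen, labels)


def slice_tree(tree, max_tips=200, step=0.1, min_tips=10):
    """Cut an oversized tree into monophyletic subclades.

    Slides from the root toward the tips in increments of ``step`` (Myr),
    cutting until every resulting clade has fewer than ``max_tips`` tips;
    subclades with fewer than ``min_tips`` tips are discarded.  A tree
    already below ``max_tips`` is returned unchanged (so slicing is
    idempotent).
    """
    if tree.n_tips < max_tips:
        return [tree]
    frozen = []  # node ids whose subtree has been frozen
    claimed_nodes = set()
    claimed_tips = set()
    t = step
    while len(claimed_tips) < tree.n_tips and t <= tree.T + step:
        # lineages whose branch crosses time t
        crossing = [v for v in range(tree.n_nodes)
                    if v != tree.root
                    and tree.depth[tree.parent[v]] <= t < tree.depth[v]]
        for v in crossing:
            if v in claimed_nodes:
                continue
            sub_tips = tree.clade_tips(v)
            if len(sub_tips) < max_tips:
                frozen.append(v)
                claimed_tips.update(sub_tips)
                claimed_nodes.update(_descendant_nodes(tree, v))
                claimed_nodes.add(v)
        t += step
    out = []
    for v in frozen:
        if len(tree.clade_tips(v)) >= max(min_tips, 2):
            out.append(_extract_clade(tree, v))
    return out


def _descendant_nodes(tree, v):
    out, stack = set(), list(tree.children[v])
    while stack:
        u = stack.pop()
        out.add(u)
        stack.extend(tree.children[u])
    return out


# ----------------------------------------------------------------------
# Sympatry downsampling
# ----------------------------------------------------------------------

@dataclass
class InteractionFilter:
    """Restriction of the sympatry matrix produced by downsampling.

    ``dropped``: per-area sets of tip node ids removed from that area's
    interacting set (lineage-level reading).  ``excluded_pairs``: unordered
    tip-id pairs forced allopatric (pair-level reading).  Internal branches
    always interact according to occupancy.
    """

    n_areas: int
    dropped: dict = field(default_factory=dict)       # area -> set(tip ids)
    excluded_pairs: set = field(default_factory=set)  # frozenset({i, j})

    def apply(self, tree, alive, occupancies, A):
        m = len(alive)
        A = A.copy()
        if occupancies is None:
            occupancies = [(1 << self.n_areas) - 1] * m
        for a in range(m):
            for b in range(a + 1, m):
                i, j = alive[a], alive[b]
                if frozenset((i, j)) in self.excluded_pairs:
                    A[a, b] = A[b, a] = 0.0
                    continue
                if A[a, b] == 0:
                    continue
                ok = False
                for ar in range(self.n_areas):
                    if not (occupancies[a] >> ar & 1 and occupancies[b] >> ar & 1):
                        continue
                    if i < tree.n_tips and i in self.dropped.get(ar, ()):
                        continue
                    if j < tree.n_tips and j in self.dropped.get(ar, ()):
                        continue
                    ok = True
                    break
                if not ok:
                    A[a, b] = A[b, a] = 0.0
        return A


def downsample_sympatry(tree, biogeo, tip_regimes, p_tropical, p_temperate,
                        seed=0, level="lineage"):
    """Downsample continental sympatry to emulate true (finer) sympatry.

    For each area and regime, only a fraction ``p`` of the co-occurring taxa
    (lineage reading, the default) or of the co-occurring same-regime pairs
    (``level="pair"``) remain mutually sympatric; the retained count is the
    floor of ``p`` times the stratum size, sampled without replacement.
    Returns an :class:`InteractionFilter` to pass to the timeline builder.
    """
    for p in (p_tropical, p_temperate):
        if not (0 < p <= 1):
            raise ValueError("retention fractions must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pmap = {"tropical": p_tropical, "temperate": p_temperate}
    K = biogeo.K if biogeo is not None else 1
    filt = InteractionFilter(n_areas=K)
    if p_tropical == 1 and p_temperate == 1:
        return filt

    def tip_occ(i):
        if biogeo is None:
            return (1 << K) - 1
        return biogeo.segments[i][-1][1]

    regs = {i: tip_regimes[tree.tip_labels[i]] if isinstance(tip_regimes, dict)
            else tip_regimes[i] for i in range(tree.n_tips)}

    for ar in range(K):
        members = [i for i in range(tree.n_tips) if tip_occ(i) >> ar & 1]
        if level == "lineage":
            drop = set()
            for reg, p in pmap.items():
                stratum = sorted(i for i in members if regs[i] == reg)
                keep = int(np.floor(p * len(stratum)))
                kept = set(rng.choice(stratum, size=keep, replace=False)) if keep else set()
                drop.update(set(stratum) - kept)
            if drop:
                filt.dropped[ar] = drop
        elif level == "pair":
            for reg, p in pmap.items():
                stratum = sorted(i for i in members if regs[i] == reg)
                pairs = [frozenset((i, j)) for a, i in enumerate(stratum)
                         for j in stratum[a + 1:]]
                keep = int(np.floor(p * len(pairs)))
                if pairs:
                    kept_idx = set(rng.choice(len(pairs), size=keep, replace=False))
                    filt.excluded_pairs.update(
                        pr for q, pr in enumerate(pairs) if q not in kept_idx)
        else:
            raise ValueError("level must be 'lineage' or 'pair'")
    return filt
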