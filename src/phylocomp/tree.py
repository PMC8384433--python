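"""Core phylogenetic data structures: time trees, branch histories, timelines.

Trees are rooted, binary, ultrametric chronograms with time measured
*forward* from the root (t = 0 at the root, t = T at the present).  Branch
histories attach piecewise-constant labels (competitive regimes, or area
occupancies) to every branch; an :class:`EventTimeline` discretizes a tree
plus its histories into intervals on which everything — alive lineages,
regimes, and the sympatry matrix A(t) — is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "RegimeHistory",
    "BiogeoHistory",
    "EventTimeline",
    "Interval",
    "TraitData",
    "TreeError",
    "HistoryError",
    "parse_newick",
    "parse_simmap",
    "build_event_timeline",
    "shared_path_segments",
    "uniform_history",
]

ULTRAMETRIC_RTOL = 1e-6  # relative to root age; chronograms carry rounding noise


class TreeError(ValueError):
    """Raised for malformed trees (polytomies, non-ultrametric tips...)."""


class HistoryError(ValueError):
    """Raised for branch histories inconsistent with their tree."""


class PhyloTree:
    """Rooted binary ultrametric time tree.

    Nodes are integer ids ``0 .. 2n-2``; tips are ``0 .. n-1`` in the order
    of ``tip_labels``. ``depth[v]`` is the time of node ``v`` measured from
    the root, so every tip depth equals the root age ``T`` (within
    tolerance).  The branch *above* node ``v`` spans
    ``[depth[parent[v]], depth[v]]``.
    """

    def __init__(self, parent, blen, tip_labels, check=True):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.tip_labels = list(tip_labels)
        self.n_tips = len(self.tip_labels)
        self.n_nodes = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        # depths by preorder
        self.depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                self.depth[v] = self.depth[self.parent[v]] + self.blen[v]
        self.T = float(self.depth[: self.n_tips].max()) if self.n_tips else 0.0
        if check:
            self._validate()

    # ------------------------------------------------------------------
    def _validate(self):
        if self.n_tips < 2:
            raise TreeError("tree needs at least 2 tips")
        if len(set(self.tip_labels)) != self.n_tips:
            raise TreeError("tip labels must be unique")
        if np.any(self.blen[np.arange(self.n_nodes) != self.root] < 0):
            raise TreeError("negative branch length")
        for v in range(self.n_nodes):
            nc = len(self.children[v])
            if v < self.n_tips:
                if nc:
                    raise TreeError(f"tip node {v} has children")
            elif nc != 2:
                raise TreeError(
                    f"polytomy or unifurcation at node {v} ({nc} children); "
                    "only strictly binary trees are supported"
                )
        tol = ULTRAMETRIC_RTOL * max(self.T, 1.0)
        for i in range(self.n_tips):
            if abs(self.depth[i] - self.T) > tol:
                raise TreeError(
                    f"tree is not ultrametric: tip {self.tip_labels[i]!r} has "
                    f"depth {self.depth[i]:.8g} but root age is {self.T:.8g}"
                )

    # ------------------------------------------------------------------
    def preorder(self):
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order

    def postorder(self):
        return list(reversed(self.preorder()))

    @property
    def internal_nodes(self):
        return [v for v in range(self.n_nodes) if v >= self.n_tips]

    def tip_index(self, label):
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise TreeError(f"unknown tip {label!r}") from None

    def branching_times(self):
        """Depths of internal nodes (time from the root), sorted ascending."""
        return np.sort(self.depth[self.n_tips :])

    def mrca(self, i, j):
        ai = set()
        v = i
        while v >= 0:
            ai.add(v)
            v = self.parent[v]
        v = j
        while v not in ai:
            v = self.parent[v]
        return v

    def path_to_root(self, v):
        """Nodes from ``v`` (inclusive) up to the root (inclusive)."""
        out = []
        while v >= 0:
            out.append(v)
            v = self.parent[v]
        return out

    def clade_tips(self, v):
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                out.append(u)
            stack.extend(self.children[u])
        return out

    def rescale(self, height):
        """Return a copy rescaled to root age ``height``."""
        f = height / self.T
        return PhyloTree(self.parent, self.blen * f, self.tip_labels)

    # ------------------------------------------------------------------
    def to_newick(self):
        def rec(v):
            if v < self.n_tips:
                lab = _quote_label(self.tip_labels[v])
            else:
                lab = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return lab
            return f"{lab}:{self.blen[v]:.12g}"

        return rec(self.root) + ";"

    def __repr__(self):
        return f"<PhyloTree {self.n_tips} tips, T={self.T:.4g}>"


def _quote_label(lab):
    if any(c in lab for c in " (),:;[]{}'"):
        return "'" + lab.replace("'", "''") + "'"
    return lab


# ----------------------------------------------------------------------
# Newick I/O (dendropy does the parsing; we convert to array form)
# ----------------------------------------------------------------------

def parse_newick(text):
    """Parse a Newick string into a :class:`PhyloTree`.

    Rejects polytomies and non-ultrametric trees (naming the offending tip).
    """
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from None
    return _from_dendropy(dt)


def _from_dendropy(dt):
    leaves = [lf for lf in dt.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon else (lf.label or "") for lf in leaves]
    n = len(leaves)
    index = {}
    for i, lf in enumerate(leaves):
        index[id(lf)] = i
    nxt = n
    for nd in dt.preorder_node_iter():
        if nd.is_leaf():
            continue
        index[id(nd)] = nxt
        nxt += 1
    parent = np.full(nxt, -1, dtype=int)
    blen = np.zeros(nxt)
    for nd in dt.preorder_node_iter():
        v = index[id(nd)]
        if nd.parent_node is not None:
            parent[v] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeError("every branch must carry a length")
            blen[v] = float(nd.edge.length)
    return PhyloTree(parent, blen, labels)


# ----------------------------------------------------------------------
# Branch histories
# ----------------------------------------------------------------------

class _BranchHistory:
    """Piecewise-constant per-branch labels.

    ``segments[v]`` is an ordered list of ``(duration, label)`` pairs for the
    branch above node ``v``, root-ward segment first (phytools convention).
    ``root_label`` is the label at the root itself.
    """

    def __init__(self, tree, segments, root_label, check=True):
        self.tree = tree
        self.segments = {int(v): [(float(d), s) for d, s in segs]
                         for v, segs in segments.items()}
        self.root_label = root_label
        if check:
            self._validate()

    def _labels_ok(self, lab):  # overridden
        return True

    def _validate(self):
        tr = self.tree
        tol = 1e-6 * max(tr.T, 1.0)
        for v in range(tr.n_nodes):
            if v == tr.root:
                continue
            if v not in self.segments:
                raise HistoryError(f"branch above node {v} has no segments")
            segs = self.segments[v]
            tot = sum(d for d, _ in segs)
            if abs(tot - tr.blen[v]) > tol:
                raise HistoryError(
                    f"segments on branch above node {v} sum to {tot:.8g} but "
                    f"branch length is {tr.blen[v]:.8g}"
                )
            for d, s in segs:
                if d < 0:
                    raise HistoryError(f"negative segment duration on branch {v}")
                if not self._labels_ok(s):
                    raise HistoryError(f"label {s!r} not in alphabet (branch {v})")
        if not self._labels_ok(self.root_label):
            raise HistoryError(f"root label {self.root_label!r} not in alphabet")

    def label_at(self, v, t):
        """Label of the lineage ending at node ``v`` at absolute time ``t``."""
        tr = self.tree
        if v == tr.root:
            return self.root_label
        t0 = tr.depth[tr.parent[v]]
        if t < t0 - 1e-9 * max(tr.T, 1.0):
            raise HistoryError(f"time {t} precedes branch above node {v}")
        acc = t0
        segs = self.segments[v]
        for d, s in segs:
            acc += d
            if t <= acc + 1e-12 * max(tr.T, 1.0):
                return s
        return segs[-1][1]

    def tip_labels_at_present(self):
        return {self.tree.tip_labels[i]: self.segments[i][-1][1]
                for i in range(self.tree.n_tips)}

    def event_times(self):
        """Absolute times of within-branch label changes."""
        tr = self.tree
        out = []
        for v, segs in self.segments.items():
            t = tr.depth[tr.parent[v]]
            for d, _ in segs[:-1]:
                t += d
                out.append(t)
        return out

    def remapped_to(self, tree):
        """Re-key this history onto an equivalent tree (matched by clades).

        Branches are matched by the tip-label set they subtend; topologies
        must agree and branch lengths must match within tolerance.
        """
        if tree is self.tree:
            return self

        def clade_keys(t):
            keys = {}
            for v in t.postorder():
                if v < t.n_tips:
                    keys[v] = frozenset([t.tip_labels[v]])
                else:
                    keys[v] = frozenset().union(*(keys[c] for c in t.children[v]))
            return keys

        src = clade_keys(self.tree)
        dst = clade_keys(tree)
        dst_by_key = {k: v for v, k in dst.items() if v != tree.root}
        tol = 1e-6 * max(tree.T, 1.0)
        segments = {}
        for v in range(self.tree.n_nodes):
            if v == self.tree.root:
                continue
            key = src[v]
            if key not in dst_by_key:
                raise HistoryError(
                    f"history topology mismatch: no branch subtending {sorted(key)[:3]}…")
            w = dst_by_key[key]
            if abs(tree.blen[w] - self.tree.blen[v]) > tol:
                raise HistoryError(
                    f"branch length mismatch on clade {sorted(key)[:3]}…")
            segments[w] = list(self.segments[v])
        return type(self)(tree, segments, self.root_label, **self._extra_kwargs())

    def mapped(self, fn):
        """Apply ``fn`` to every label, merging adjacent equal segments."""
        segs = {}
        for v, ss in self.segments.items():
            merged = []
            for d, s in ss:
                s2 = fn(s)
                if merged and merged[-1][1] == s2:
                    merged[-1] = (merged[-1][0] + d, s2)
                else:
                    merged.append((d, s2))
            segs[v] = merged
        return type(self)(self.tree, segs, fn(self.root_label),
                          **self._extra_kwargs())

    def _extra_kwargs(self):
        return {}


class RegimeHistory(_BranchHistory):
    """Per-branch competitive-regime labels (e.g. tropical vs temperate)."""

    def __init__(self, tree, segments, root_label, alphabet, check=True):
        self.alphabet = tuple(alphabet)
        super().__init__(tree, segments, root_label, check=check)

    def _labels_ok(self, lab):
        return lab in self.alphabet

    def _extra_kwargs(self):
        return {"alphabet": self.alphabet}

    def mapped(self, fn):
        segs = {}
        for v, ss in self.segments.items():
            merged = []
            for d, s in ss:
                s2 = fn(s)
                if merged and merged[-1][1] == s2:
                    merged[-1] = (merged[-1][0] + d, s2)
                else:
                    merged.append((d, s2))
            segs[v] = merged
        alpha = tuple(dict.fromkeys(fn(a) for a in self.alphabet))
        return RegimeHistory(self.tree, segs, fn(self.root_label), alpha)

    def to_simmap(self):
        return _write_simmap(self.tree, self.segments, str)


class BiogeoHistory(_BranchHistory):
    """Per-branch area occupancies over ``K`` named areas.

    Labels are integer bitmasks over ``areas``; every lineage occupies at
    least one area at all times.
    """

    def __init__(self, tree, segments, root_label, areas, check=True):
        self.areas = tuple(areas)
        super().__init__(tree, segments, root_label, check=check)

    def _labels_ok(self, lab):
        full = (1 << len(self.areas)) - 1
        return isinstance(lab, (int, np.integer)) and 0 < lab <= full

    def _extra_kwargs(self):
        return {"areas": self.areas}

    @property
    def K(self):
        return len(self.areas)

    def occupancy_string(self, mask):
        return "".join("1" if mask >> a & 1 else "0" for a in range(self.K))

    def to_simmap(self):
        return _write_simmap(self.tree, self.segments, self.occupancy_string)


def uniform_history(tree, label, alphabet=None):
    """A :class:`RegimeHistory` assigning one label everywhere."""
    segs = {v: [(float(tree.blen[v]), label)]
            for v in range(tree.n_nodes) if v != tree.root}
    return RegimeHistory(tree, segs, label, alphabet or (label,))


# ----------------------------------------------------------------------
# SIMMAP-annotated Newick (phytools dialect: {state,dur:state,dur:...},
# root-ward segment first).  Hand-written: no installed library reads it.
# ----------------------------------------------------------------------

def parse_simmap(text, alphabet=None, areas=None):
    """Parse a SIMMAP-annotated Newick string.

    Returns ``(PhyloTree, RegimeHistory)``, or ``(PhyloTree, BiogeoHistory)``
    when ``areas`` is given (labels are then occupancy bit-strings such as
    ``"101"``).  Segment durations must tile each branch; the first-listed
    segment of each branch is the root-ward one.
    """
    s = text.strip()
    pos = [0]

    def peek():
        return s[pos[0]] if pos[0] < len(s) else ""

    def take(ch):
        if peek() != ch:
            raise TreeError(f"SIMMAP parse error at {pos[0]}: expected {ch!r}")
        pos[0] += 1

    def read_label():
        if peek() == "'":
            pos[0] += 1
            out = []
            while True:
                c = s[pos[0]]
                pos[0] += 1
                if c == "'":
                    if peek() == "'":
                        out.append("'")
                        pos[0] += 1
                    else:
                        break
                else:
                    out.append(c)
            return "".join(out)
        out = []
        while peek() and peek() not in "(),:;{}[]":
            out.append(s[pos[0]])
            pos[0] += 1
        return "".join(out)

    nodes = []  # (label, children, segments)

    def read_segments():
        take(":")
        take("{")
        j = s.index("}", pos[0])
        body = s[pos[0] : j]
        pos[0] = j + 1
        segs = []
        for part in body.split(":"):
            st, dur = part.split(",")
            segs.append((st.strip(), float(dur)))
        return segs

    def read_clade():
        if peek() == "(":
            take("(")
            kids = [read_clade()]
            while peek() == ",":
                take(",")
                kids.append(read_clade())
            take(")")
            lab = read_label()
            me = len(nodes)
            nodes.append([lab, kids, None])
        else:
            lab = read_label()
            me = len(nodes)
            nodes.append([lab, [], None])
        if peek() == ":":
            nodes[me][2] = read_segments()
        return me

    root = read_clade()
    take(";")

    # convert to PhyloTree arrays: tips first
    tip_ids = [i for i, nd in enumerate(nodes) if not nd[1]]
    order = tip_ids + [i for i, nd in enumerate(nodes) if nd[1]]
    remap = {old: new for new, old in enumerate(order)}
    n_all = len(nodes)
    parent = np.full(n_all, -1, dtype=int)
    blen = np.zeros(n_all)
    segments = {}
    for i, (lab, kids, segs) in enumerate(nodes):
        for k in kids:
            parent[remap[k]] = remap[i]
        if segs is not None:
            blen[remap[i]] = sum(d for _, d in segs)
            segments[remap[i]] = segs
    labels = [nodes[i][0] for i in tip_ids]
    tree = PhyloTree(parent, blen, labels)
    segments.pop(tree.root, None)

    if areas is not None:
        areas = tuple(areas)
        K = len(areas)

        def decode(st):
            if len(st) != K or set(st) - {"0", "1"}:
                raise HistoryError(f"occupancy label {st!r} is not a {K}-bit pattern")
            return sum(1 << a for a in range(K) if st[a] == "1")

        segs2 = {v: [(d, decode(st)) for st, d in ss] for v, ss in segments.items()}
        root_lab = segs2[tree.children[tree.root][0]][0][1]
        return tree, BiogeoHistory(tree, segs2, root_lab, areas)

    segs2 = {v: [(d, st) for st, d in ss] for v, ss in segments.items()}
    root_lab = segs2[tree.children[tree.root][0]][0][1]
    if alphabet is None:
        alphabet = sorted({st for ss in segs2.values() for _, st in ss})
    return tree, RegimeHistory(tree, segs2, root_lab, tuple(alphabet))


def _write_simmap(tree, segments, fmt):
    def rec(v):
        if v < tree.n_tips:
            lab = _quote_label(tree.tip_labels[v])
        else:
            lab = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        if v == tree.root:
            return lab
        body = ":".join(f"{fmt(s)},{d:.12g}" for d, s in segments[v])
        return lab + ":{" + body + "}"

    return rec(tree.root) + ";"


# ----------------------------------------------------------------------
# Trait data
# ----------------------------------------------------------------------

@dataclass
class TraitData:
    """Per-species observed trait means with sampling information.

    ``se2`` is the squared standard error of each species mean (the "known"
    part of observational error); ``n`` the within-species sample size.
    """

    species: list
    mean: np.ndarray
    n: np.ndarray
    se2: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.se2 = np.asarray(self.se2, dtype=float)
        if not (len(self.species) == len(self.mean) == len(self.n) == len(self.se2)):
            raise ValueError("trait columns have unequal lengths")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in trait table")
        if np.any(self.se2 < 0):
            raise ValueError("se2 must be non-negative")
        if np.any(self.n < 1):
            raise ValueError("sample sizes must be >= 1")

    @classmethod
    def from_frame(cls, df):
        return cls(list(df["species"]), df["mean"].to_numpy(),
                   df["n"].to_numpy(), df["se2"].to_numpy())

    @classmethod
    def read_csv(cls, path_or_buf, sep=None):
        df = pd.read_csv(path_or_buf, sep=sep, engine="python")
        return cls.from_frame(df)

    def to_frame(self):
        return pd.DataFrame(
            {"species": self.species, "mean": self.mean, "n": self.n, "se2": self.se2}
        )

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def aligned_to(self, tree, drop_extra=False):
        """Reorder rows to the tree's tip order; every tip must have data."""
        idx = {sp: i for i, sp in enumerate(self.species)}
        missing = [lb for lb in tree.tip_labels if lb not in idx]
        if missing:
            raise ValueError(f"species missing from trait table: {missing[:5]}")
        extra = set(self.species) - set(tree.tip_labels)
        if extra and not drop_extra:
            raise ValueError(f"trait table has species absent from tree: {sorted(extra)[:5]}")
        order = [idx[lb] for lb in tree.tip_labels]
        return TraitData(list(tree.tip_labels), self.mean[order],
                         self.n[order], self.se2[order])

    def __len__(self):
        return len(self.species)


# ----------------------------------------------------------------------
# Event timeline
# ----------------------------------------------------------------------

@dataclass
class Interval:
    """One constant piece of the tree-plus-histories process.

    ``alive`` lists node ids of the lineages present on ``[t0, t1]``;
    ``regime`` holds each one's regime label, ``sympatry`` the 0/1 matrix
    A(t) restricted to alive lineages (unit diagonal, symmetric).
    """

    t0: float
    t1: float
    alive: list
    regime: list
    sympatry: np.ndarray

    @property
    def dt(self):
        return self.t1 - self.t0


@dataclass
class EventTimeline:
    tree: PhyloTree
    regimes: RegimeHistory
    intervals: list

    @property
    def regime_alphabet(self):
        return self.regimes.alphabet


def build_event_timeline(tree, regimes, biogeo=None, interactions=None):
    """Discretize ``tree`` + histories into constant intervals.

    ``interactions`` is an optional :class:`~phylocomp.regimes.InteractionFilter`
    (produced by sympatry downsampling) that removes lineages or pairs from
    the sympatry matrix.  With ``biogeo=None`` the sympatry matrix is
    all-ones (full sympatry).
    """
    if regimes.tree is not tree:
        regimes = regimes.remapped_to(tree)  # raises on topology mismatch
    if biogeo is not None and biogeo.tree is not tree:
        biogeo = biogeo.remapped_to(tree)

    T = tree.T
    tol = 1e-9 * max(T, 1.0)
    events = [0.0, T]
    events.extend(float(t) for t in tree.depth[tree.n_tips:] if t > tol)
    events.extend(regimes.event_times())
    if biogeo is not None:
        events.extend(biogeo.event_times())
    events = sorted(e for e in events if -tol < e < T + tol)
    merged = [0.0]
    for e in events:
        if e - merged[-1] > tol:
            merged.append(e)
    if merged[-1] < T - tol:
        merged.append(T)
    merged[-1] = T

    intervals = []
    for t0, t1 in zip(merged[:-1], merged[1:]):
        tm = 0.5 * (t0 + t1)
        alive = [v for v in range(tree.n_nodes)
                 if v != tree.root
                 and tree.depth[tree.parent[v]] <= tm < tree.depth[v]
                 or (v < tree.n_tips and t1 >= T - tol
                     and tree.depth[tree.parent[v]] <= tm)]
        alive = sorted(set(alive))
        reg = [regimes.label_at(v, tm) for v in alive]
        m = len(alive)
        if biogeo is None:
            A = np.ones((m, m))
        else:
            occ = [biogeo.label_at(v, tm) for v in alive]
            A = np.zeros((m, m))
            for a in range(m):
                for b in range(m):
                    A[a, b] = 1.0 if (occ[a] & occ[b]) else 0.0
        if interactions is not None:
            A = interactions.apply(tree, alive,
                                   None if biogeo is None else
                                   [biogeo.label_at(v, tm) for v in alive], A)
        np.fill_diagonal(A, 1.0)
        intervals.append(Interval(t0, t1, alive, reg, A))
    return EventTimeline(tree, regimes, intervals)


def shared_path_segments(tree, regimes, i, j):
    """Regime segments along the shared root-to-MRCA path of tips i and j.

    Returns ``(t0, t1, regime)`` triples in root-to-tip order whose total
    duration is the MRCA depth (the full root-to-tip path when ``i == j``).
    Tips may be given as labels or indices.
    """
    if regimes is not None and regimes.tree is not tree:
        regimes = regimes.remapped_to(tree)
    if isinstance(i, str):
        i = tree.tip_index(i)
    if isinstance(j, str):
        j = tree.tip_index(j)
    if not (0 <= i < tree.n_tips and 0 <= j < tree.n_tips):
        raise TreeError("shared_path_segments expects tips")
    m = tree.mrca(i, j) if i != j else i
    path = [v for v in reversed(tree.path_to_root(m)) if v != tree.root]
    out = []
    for v in path:
        t = float(tree.depth[tree.parent[v]])
        if regimes is None:
            out.append((t, float(tree.depth[v]), None))
            continue
        for d, s in regimes.segments[v]:
            out.append((t, t + d, s))
            t += d
    return out
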