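"""Latitude classification, Mk model, stochastic maps, sympatry, slicing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from phylocomp.regimes import (
    STATES3,
    MkModel,
    classify_latitude,
    collapse_history,
    collapse_states,
    downsample_sympatry,
    fit_mk,
    is_sympatric,
    mk_loglik,
    mk_node_conditionals,
    sample_stochastic_maps,
    slice_tree,
    szymkiewicz_simpson,
    tropicality_index,
)
from phylocomp.simulate import simulate_bd_tree
from phylocomp.tree import parse_newick


class TestLatitude:
    @pytest.mark.parametrize("band,expected", [
        ((-10, 5), "tropical"),
        ((30, 45), "temperate"),
        ((-30, 10), "both"),
        ((-23.437, 10), "both"),    # touching the boundary is not exclusive
        ((23.437, 40), "both"),
        ((-89, -24), "temperate"),
        ((0, 0), "tropical"),       # degenerate point band
    ])
    def test_classification(self, band, expected):
        assert classify_latitude(band) == expected

    def test_collapse_rule(self):
        assert collapse_states("both") == "temperate"
        assert collapse_states("tropical") == "tropical"
        assert collapse_states("temperate") == "temperate"
        with pytest.raises(ValueError):
            collapse_states("arctic")

    def test_collapse_is_projection(self):
        for s in STATES3:
            assert collapse_states(collapse_states(s)) == collapse_states(s)

    def test_collapse_history_merges_segments(self, three_tip):
        from phylocomp.tree import RegimeHistory
        segs = {0: [(0.3, "tropical"), (0.4, "both"), (0.3, "temperate")],
                1: [(1.0, "both")], 2: [(2.0, "tropical")],
                4: [(1.0, "temperate")]}
        h = RegimeHistory(three_tip, segs, "tropical", STATES3)
        h2 = collapse_history(h)
        assert h2.segments[0] == [(0.3, "tropical"), (pytest.approx(0.7), "temperate")]
        assert set(h2.alphabet) == {"tropical", "temperate"}


class TestSympatryCoefficient:
    @pytest.mark.parametrize("o,a1,a2,coef", [
        (2, 4, 10, 0.5), (0, 4, 10, 0.0), (4, 4, 10, 1.0)])
    def test_values(self, o, a1, a2, coef):
        c = szymkiewicz_simpson(o, a1, a2)
        assert c == pytest.approx(coef)
        assert is_sympatric(c) == (coef >= 0.2)

    def test_overlap_larger_than_min_rejected(self):
        with pytest.raises(ValueError):
            szymkiewicz_simpson(5, 4, 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(o=st.floats(0, 1), a1=st.floats(0.01, 100), a2=st.floats(0.01, 100),
           c=st.floats(0.01, 50))
    def test_symmetry_and_scale_invariance(self, o, a1, a2, c):
        ov = o * min(a1, a2)
        v = szymkiewicz_simpson(ov, a1, a2)
        assert v == pytest.approx(szymkiewicz_simpson(ov, a2, a1))
        assert v == pytest.approx(szymkiewicz_simpson(c * ov, c * a1, c * a2),
                                  rel=1e-9)
        assert 0 <= v <= 1


class TestTropicality:
    def test_example_counts(self):
        assert tropicality_index(["tropical"] * 38 + ["temperate"] * 12) == 0.76
        assert tropicality_index(["temperate"] * 10) == 0.0
        assert tropicality_index(["tropical"] * 89 + ["temperate"] * 33) == \
            pytest.approx(89 / 122)


class TestMk:
    def brute_force_loglik(self, tree, Q, states, tip_states):
        """Sum over all internal-state combinations (oracle)."""
        k = len(states)
        idx = {s: i for i, s in enumerate(states)}
        P = {v: expm(Q * tree.blen[v]) for v in range(tree.n_nodes)
             if v != tree.root}
        internals = tree.internal_nodes
        total = 0.0
        for combo in itertools.product(range(k), repeat=len(internals)):
            assign = dict(zip(internals, combo))
            for i in range(tree.n_tips):
                assign[i] = idx[tip_states[tree.tip_labels[i]]]
            p = 1.0 / k  # equal root frequencies
            for v in range(tree.n_nodes):
                if v != tree.root:
                    p *= P[v][assign[tree.parent[v]], assign[v]]
            total += p
        return np.log(total)

    @pytest.mark.parametrize("newick,tips", [
        ("((A:1,B:1):1,C:2);", {"A": "tropical", "B": "both", "C": "temperate"}),
        ("((A:1,B:1):1,(C:1.5,D:1.5):0.5);",
         {"A": "tropical", "B": "temperate", "C": "both", "D": "tropical"}),
        ("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);",
         {"A": "both", "B": "both", "C": "tropical", "D": "temperate",
          "E": "tropical"}),
    ])
    def test_pruning_equals_enumeration(self, newick, tips):
        tree = parse_newick(newick)
        rng = np.random.default_rng(0)
        Q = rng.uniform(0.05, 0.6, (3, 3))
        np.fill_diagonal(Q, 0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        model = MkModel(STATES3, Q)
        ll = mk_loglik(tree, model, tips)
        oracle = self.brute_force_loglik(tree, Q, STATES3, tips)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_rate_time_scaling_identity(self, three_tip):
        tips = {"A": "tropical", "B": "both", "C": "temperate"}
        Q = np.array([[-0.5, 0.3, 0.2], [0.1, -0.4, 0.3], [0.2, 0.2, -0.4]])
        m1 = MkModel(STATES3, Q)
        from phylocomp.tree import PhyloTree
        t2 = PhyloTree(three_tip.parent, three_tip.blen * 2, three_tip.tip_labels)
        m2 = MkModel(STATES3, Q / 2)
        assert mk_loglik(three_tip, m1, tips) == \
            pytest.approx(mk_loglik(t2, m2, tips), abs=1e-12)

    def test_degenerate_uniform_tips_boundary(self, three_tip):
        tips = {"A": "tropical", "B": "tropical", "C": "tropical"}
        model = fit_mk(three_tip, tips, states=STATES3)
        assert model.boundary
        assert np.all(model.Q == 0)
        # logLik -> log(root freq of the observed state)
        assert model.loglik == pytest.approx(np.log(1 / 3), abs=1e-9)

    def test_ml_fit_beats_arbitrary_generators(self, three_tip):
        tips = {"A": "tropical", "B": "both", "C": "temperate"}
        fitted = fit_mk(three_tip, tips, states=STATES3, n_starts=2)
        rng = np.random.default_rng(1)
        for _ in range(3):
            Q = rng.uniform(0.05, 1.0, (3, 3))
            np.fill_diagonal(Q, 0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            assert fitted.loglik >= mk_loglik(three_tip, MkModel(STATES3, Q),
                                              tips) - 1e-6


class TestStochasticMaps:
    def setup_model(self):
        tree = parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        Q = np.array([[-0.6, 0.4, 0.2], [0.3, -0.5, 0.2], [0.25, 0.25, -0.5]])
        model = MkModel(STATES3, Q)
        tips = {"A": "tropical", "B": "temperate", "C": "both", "D": "tropical"}
        return tree, model, tips

    def test_maps_consistent_and_tile(self):
        tree, model, tips = self.setup_model()
        maps = sample_stochastic_maps(tree, model, tips, count=20, seed=3)
        assert len(maps) == 20
        for h in maps:
            ends = h.tip_labels_at_present()
            assert ends == tips
            for v, segs in h.segments.items():
                assert sum(d for d, _ in segs) == pytest.approx(
                    float(tree.blen[v]), abs=1e-9)

    def test_seed_reproducible(self):
        tree, model, tips = self.setup_model()
        a = sample_stochastic_maps(tree, model, tips, count=5, seed=11)
        b = sample_stochastic_maps(tree, model, tips, count=5, seed=11)
        assert [h.to_simmap() for h in a] == [h.to_simmap() for h in b]

    def test_node_frequencies_match_exact_conditionals(self):
        tree, model, tips = self.setup_model()
        cond = mk_node_conditionals(tree, model, tips)
        n_maps = 2000
        maps = sample_stochastic_maps(tree, model, tips, count=n_maps, seed=5)
        sidx = {s: i for i, s in enumerate(model.states)}
        for v in tree.internal_nodes:
            if v == tree.root:
                t_v = 1e-9
            else:
                t_v = float(tree.depth[v])
            freq = np.zeros(3)
            for h in maps:
                if v == tree.root:
                    freq[sidx[h.root_label]] += 1
                else:
                    freq[sidx[h.label_at(v, t_v)]] += 1
            freq /= n_maps
            se = np.sqrt(np.maximum(cond[v] * (1 - cond[v]), 1e-12) / n_maps)
            assert np.all(np.abs(freq - cond[v]) <= 3 * se + 1e-9), \
                f"node {v}: {freq} vs {cond[v]}"

    def test_zero_rate_conflict_rejected(self):
        tree, _, tips = self.setup_model()
        zero = MkModel(STATES3, np.zeros((3, 3)))
        with pytest.raises(Exception):
            sample_stochastic_maps(tree, zero, tips, count=1, seed=0)


class TestSliceTree:
    def test_small_tree_unchanged(self):
        tree = simulate_bd_tree(20, 0.3, 0.0, seed=1)
        out = slice_tree(tree, max_tips=200)
        assert len(out) == 1 and out[0] is tree

    def test_large_tree_sliced(self):
        tree = simulate_bd_tree(300, 0.3, 0.0, seed=2)
        out = slice_tree(tree, max_tips=200, step=0.1, min_tips=10)
        assert len(out) >= 2
        for sub in out:
            assert 10 <= sub.n_tips < 200
        # tip sets partition a subset of the input tips
        all_tips = [lb for sub in out for lb in sub.tip_labels]
        assert len(all_tips) == len(set(all_tips))
        assert set(all_tips) <= set(tree.tip_labels)
        # monophyly: each subclade's tip set is a clade of the input
        clades = {frozenset(tree.tip_labels[i] for i in tree.clade_tips(v))
                  for v in range(tree.n_nodes)}
        for sub in out:
            assert frozenset(sub.tip_labels) in clades

    def test_idempotent(self):
        tree = simulate_bd_tree(300, 0.3, 0.0, seed=3)
        out = slice_tree(tree, max_tips=200, min_tips=10)
        again = [s for sub in out for s in slice_tree(sub, max_tips=200,
                                                      min_tips=10)]
        assert [s.n_tips for s in again] == [s.n_tips for s in out]


class TestDownsampling:
    def _setup(self, n=20):
        tree = simulate_bd_tree(n, 0.3, 0.0, seed=9)
        regs = {lb: ("tropical" if i % 2 == 0 else "temperate")
                for i, lb in enumerate(tree.tip_labels)}
        return tree, regs

    def test_identity_when_p_one(self):
        tree, regs = self._setup()
        filt = downsample_sympatry(tree, None, regs, 1.0, 1.0, seed=0)
        assert not filt.dropped and not filt.excluded_pairs

    def test_lineage_counts(self):
        tree, regs = self._setup(20)  # 10 tropical, 10 temperate, one area
        filt = downsample_sympatry(tree, None, regs, 0.5, 0.8, seed=1)
        ntrop = sum(1 for i in filt.dropped[0]
                    if regs[tree.tip_labels[i]] == "tropical")
        ntemp = sum(1 for i in filt.dropped[0]
                    if regs[tree.tip_labels[i]] == "temperate")
        assert ntrop == 10 - int(np.floor(0.5 * 10))
        assert ntemp == 10 - int(np.floor(0.8 * 10))

    def test_retained_mutually_sympatric(self):
        tree, regs = self._setup(20)
        filt = downsample_sympatry(tree, None, regs, 0.5, 1.0, seed=2)
        from phylocomp.tree import RegimeHistory, build_event_timeline
        segs = {v: [(float(tree.blen[v]),
                     regs[tree.tip_labels[min(tree.clade_tips(v))]])]
                for v in range(tree.n_nodes) if v != tree.root}
        hist = RegimeHistory(tree, segs, "tropical", ("tropical", "temperate"))
        tl = build_event_timeline(tree, hist, None, interactions=filt)
        last = tl.intervals[-1].sympatry
        dropped = filt.dropped[0]
        for a, i in enumerate(tl.intervals[-1].alive):
            for b, j in enumerate(tl.intervals[-1].alive):
                if a == b:
                    continue
                expect = 0.0 if (i in dropped or j in dropped) else 1.0
                assert last[a, b] == expect

    def test_seed_reproducible_and_bad_p(self):
        tree, regs = self._setup()
        f1 = downsample_sympatry(tree, None, regs, 0.5, 0.5, seed=7)
        f2 = downsample_sympatry(tree, None, regs, 0.5, 0.5, seed=7)
        assert f1.dropped == f2.dropped
        with pytest.raises(ValueError):
            downsample_sympatry(tree, None, regs, 0.0, 0.5)

    def test_pair_level_counts(self):
        tree, regs = self._setup(12)  # 6/6 split: 15 pairs per regime
        filt = downsample_sympatry(tree, None, regs, 0.4, 1.0, seed=3,
                                   level="pair")
        trop_pairs_excluded = sum(
            1 for pr in filt.excluded_pairs
            if all(regs[tree.tip_labels[i]] == "tropical" for i in pr))
        assert trop_pairs_excluded == 15 - int(np.floor(0.4 * 15))
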