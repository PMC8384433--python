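"""Moment and likelihood tests against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal

from phylocomp.likelihood import (
    InadmissibleParameters,
    ModelSpec,
    MomentEngine,
    Params,
    SingularCovariance,
    log_likelihood,
    mvn_loglik,
    tip_moments_closed_form,
    tip_moments_ode,
)
from phylocomp.tree import (
    TraitData,
    build_event_timeline,
    parse_newick,
    uniform_history,
)

from conftest import REGIMES, random_fixture


class TestClosedForms:
    def test_bm_path_lengths(self, three_tip, three_tip_regimes):
        m, V = tip_moments_closed_form(ModelSpec("BM"), Params(z0=0.5, sigma2=1.0),
                                       three_tip, three_tip_regimes)
        assert np.allclose(m, 0.5)
        assert np.allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_eb_r0_equals_bm(self, three_tip, three_tip_regimes):
        _, Vbm = tip_moments_closed_form(ModelSpec("BM"), Params(sigma2=1.0),
                                         three_tip, three_tip_regimes)
        _, Veb = tip_moments_closed_form(ModelSpec("EB"),
                                         Params(sigma2=1.0, r=0.0),
                                         three_tip, three_tip_regimes)
        assert np.allclose(Veb, Vbm, atol=1e-12)

    def test_eb_quadrature_oracle(self, three_tip, three_tip_regimes):
        r = -0.5
        _, V = tip_moments_closed_form(ModelSpec("EB"), Params(sigma2=1.0, r=r),
                                       three_tip, three_tip_regimes)
        oracle, _ = quad(lambda s: np.exp(r * s), 0, 2)
        assert V[0, 0] == pytest.approx(oracle, abs=1e-10)
        assert V[0, 0] == pytest.approx((1 - np.exp(-1)) / 0.5, abs=1e-10)
        # shared part integrates over [0, 1] only
        oracle01, _ = quad(lambda s: np.exp(r * s), 0, 1)
        assert V[0, 1] == pytest.approx(oracle01, abs=1e-10)

    def test_ou_alpha0_is_bm_limit(self, three_tip, three_tip_regimes):
        _, Vbm = tip_moments_closed_form(ModelSpec("BM"), Params(sigma2=0.7),
                                         three_tip, three_tip_regimes)
        _, Vou = tip_moments_closed_form(ModelSpec("OU"),
                                         Params(sigma2=0.7, alpha=0.0),
                                         three_tip, three_tip_regimes)
        assert np.allclose(Vou, Vbm, atol=1e-12)

    def test_ou_ultrametric_formula(self, three_tip, three_tip_regimes):
        al, s2 = 0.8, 1.3
        _, V = tip_moments_closed_form(ModelSpec("OU"),
                                       Params(sigma2=s2, alpha=al, z0=0.0),
                                       three_tip, three_tip_regimes)
        # var at tip: fixed-root OU variance over T=2
        assert V[0, 0] == pytest.approx(s2 / (2 * al) * (1 - np.exp(-4 * al)))
        # A,B: t_mrca=1, d=2
        assert V[0, 1] == pytest.approx(
            s2 / (2 * al) * np.exp(-2 * al) * (1 - np.exp(-2 * al)))
        # A and C coalesce at the root (t_mrca = 0): no shared history
        assert V[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_regime_ou_mean_integral(self):
        # one tip switches regime halfway: m = theta-weighted exponential mix
        tree = parse_newick("(A:1,B:1);")
        from phylocomp.tree import RegimeHistory
        segs = {0: [(0.5, "tropical"), (0.5, "temperate")],
                1: [(1.0, "tropical")]}
        h = RegimeHistory(tree, segs, "tropical", REGIMES)
        al = 1.1
        th = {"tropical": 2.0, "temperate": -1.0}
        m, _ = tip_moments_closed_form(
            ModelSpec("OU", 2), Params(sigma2=1.0, alpha=al, theta=th), tree, h)
        ora_A = th["tropical"] * np.exp(-al) \
            + al * quad(lambda t: (th["tropical"] if t < 0.5 else th["temperate"])
                        * np.exp(-al * (1 - t)), 0, 1)[0]
        ora_B = th["tropical"] * np.exp(-al) \
            + al * quad(lambda t: th["tropical"] * np.exp(-al * (1 - t)), 0, 1)[0]
        assert m[tree.tip_index("A")] == pytest.approx(ora_A, abs=1e-9)
        assert m[tree.tip_index("B")] == pytest.approx(ora_B, abs=1e-9)


class TestEngineAgainstClosedForms:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("family,params", [
        ("BM", Params(z0=0.3, sigma2=0.8)),
        ("BM", Params(z0=0.3, sigma2={"tropical": 0.8, "temperate": 0.2})),
        ("EB", Params(z0=-1.0, sigma2=1.1, r={"tropical": -0.6, "temperate": 0.2})),
        ("OU", Params(z0=0.5, sigma2=0.9, alpha=0.7, theta=0.5)),
        ("OU", Params(sigma2=0.9, alpha=0.7,
                      theta={"tropical": 1.0, "temperate": -1.0})),
    ])
    def test_propagation_equals_path_formulas(self, seed, family, params):
        tree, regimes, _ = random_fixture(seed, n_tips=7)
        n_reg = 2 if isinstance(
            params.sigma2 if family == "BM" else
            params.r if family == "EB" else params.theta, dict) else 1
        spec = ModelSpec(family, n_reg)
        m1, V1 = tip_moments_closed_form(spec, params, tree, regimes)
        tl = build_event_timeline(tree, regimes, None)
        m2, V2 = tip_moments_ode(spec, params, tl)
        assert np.allclose(m1, m2, atol=1e-9)
        assert np.allclose(V1, V2, atol=1e-9)


class TestInteractionMoments:
    def test_mc_s0_is_bm(self, three_tip, three_tip_regimes):
        tl = build_event_timeline(three_tip, three_tip_regimes)
        m, V = tip_moments_ode(ModelSpec("MC"), Params(sigma2=1.0, S=0.0), tl)
        assert np.allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=1e-12)

    @pytest.mark.parametrize("S", [-0.9, 0.6])
    def test_two_lineage_difference_closed_form(self, S):
        # dD = -S D dt + sqrt(2) sigma dW  =>  Var(D)(t) = (s2/S)(1-e^{-2St})
        tree = parse_newick("(A:1.5,B:1.5);")
        h = uniform_history(tree, "tropical", REGIMES)
        tl = build_event_timeline(tree, h)
        _, V = tip_moments_ode(ModelSpec("MC"), Params(sigma2=1.0, S=S), tl)
        vd = V[0, 0] + V[1, 1] - 2 * V[0, 1]
        assert vd == pytest.approx((1.0 / S) * (1 - np.exp(-2 * S * 1.5)),
                                   abs=1e-8)

    def test_dd_exp_epoch_sum(self, three_tip, three_tip_regimes):
        r = -0.3
        tl = build_event_timeline(three_tip, three_tip_regimes)
        _, V = tip_moments_ode(ModelSpec("DD_exp"), Params(sigma2=1.0, r=r), tl)
        # lineage counts: 2 on [0,1), 3 on [1,2)
        assert V[0, 0] == pytest.approx(np.exp(2 * r) + np.exp(3 * r), abs=1e-8)
        assert V[0, 1] == pytest.approx(np.exp(2 * r), abs=1e-8)

    def test_dd_lin_negative_rate_errors(self, three_tip, three_tip_regimes):
        tl = build_event_timeline(three_tip, three_tip_regimes)
        with pytest.raises(InadmissibleParameters, match="lineage"):
            tip_moments_ode(ModelSpec("DD_lin"), Params(sigma2=1.0, b=-0.5), tl)

    def test_full_sympatry_biogeo_equals_none(self):
        # single area: biogeography-aware moments == full-sympatry moments
        tree, regimes, _ = random_fixture(5, n_tips=6)
        from phylocomp.simulate import simulate_biogeo_history
        bio = simulate_biogeo_history(tree, 1, gain=0.0, loss=0.0, seed=1)
        p = Params(sigma2=1.0, S={"tropical": -0.8, "temperate": -0.1})
        for biogeo, flag in ((None, False), (bio, True)):
            tl = build_event_timeline(tree, regimes, biogeo)
            m, V = tip_moments_ode(ModelSpec("MC", 2, biogeography=flag), p, tl)
            if biogeo is None:
                ref = V
            else:
                assert np.allclose(V, ref, atol=1e-10)

    def test_clique_and_vanloan_agree(self):
        tree, regimes, bio = random_fixture(7, n_tips=6, n_areas=2)
        tl = build_event_timeline(tree, regimes, bio)
        eng = MomentEngine(tl)
        p = Params(z0=0.2, sigma2=1.0, S={"tropical": -1.0, "temperate": 0.4})
        m1, V1 = eng.moments(ModelSpec("MC", 2, biogeography=True), p)
        for st in eng._steps:
            st["blocks"] = None  # force the general-path propagator
        m2, V2 = eng.moments(ModelSpec("MC", 2, biogeography=True), p)
        assert np.allclose(m1, m2, atol=1e-10)
        assert np.allclose(V1, V2, atol=1e-10)

    @pytest.mark.parametrize("family,params", [
        ("MC", Params(sigma2=1.0, S={"tropical": -0.8, "temperate": -0.2})),
        ("DD_exp", Params(sigma2=1.0, r={"tropical": -0.3, "temperate": 0.1})),
        ("DD_lin", Params(sigma2=1.0, b={"tropical": -0.1, "temperate": 0.05})),
    ])
    def test_psd_and_symmetric(self, family, params):
        tree, regimes, bio = random_fixture(11, n_tips=8, n_areas=2)
        tl = build_event_timeline(tree, regimes, bio)
        _, V = tip_moments_ode(ModelSpec(family, 2, biogeography=True),
                               params, tl)
        assert np.max(np.abs(V - V.T)) < 1e-10
        assert np.min(np.linalg.eigvalsh(V)) > -1e-10


class TestLogLikelihood:
    def test_univariate_standard_normal(self):
        # single observation at the mean of a unit-variance normal
        assert mvn_loglik(np.array([0.0]), np.array([0.0]),
                          np.array([[1.0]])) == pytest.approx(
            -0.5 * np.log(2 * np.pi))

    def test_dense_mvn_oracle(self, three_tip, three_tip_regimes):
        y = TraitData(["A", "B", "C"], [0.0, 0.0, 0.0], [1, 1, 1],
                      [0.0, 0.0, 0.0])
        ll = log_likelihood(ModelSpec("BM"), Params(z0=0.0, sigma2=1.0),
                            three_tip, three_tip_regimes, y)
        V = np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2.0]])
        oracle = multivariate_normal(mean=np.zeros(3), cov=V).logpdf(np.zeros(3))
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_row_order_invariance(self, three_tip, three_tip_regimes):
        y1 = TraitData(["A", "B", "C"], [0.1, -0.2, 0.4], [1, 1, 1],
                       [0.01, 0.02, 0.0])
        y2 = TraitData(["C", "A", "B"], [0.4, 0.1, -0.2], [1, 1, 1],
                       [0.0, 0.01, 0.02])
        p = Params(z0=0.0, sigma2=0.5)
        a = log_likelihood(ModelSpec("BM"), p, three_tip, three_tip_regimes, y1)
        b = log_likelihood(ModelSpec("BM"), p, three_tip, three_tip_regimes, y2)
        assert a == pytest.approx(b, abs=1e-12)

    def test_observational_error_inflates_diagonal(self, three_tip,
                                                   three_tip_regimes):
        y = TraitData(["A", "B", "C"], [0.1, -0.2, 0.4], [1, 1, 1],
                      [0.3, 0.1, 0.2])
        p = Params(z0=0.0, sigma2=0.5, sigma_err2=0.25)
        ll = log_likelihood(ModelSpec("BM", estimate_error=True), p, three_tip,
                            three_tip_regimes, y)
        V = 0.5 * np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2.0]])
        C = V + np.diag([0.3 + 0.25, 0.1 + 0.25, 0.2 + 0.25])
        oracle = multivariate_normal(mean=np.zeros(3), cov=C).logpdf(
            [0.1, -0.2, 0.4])
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_singular_covariance_raises(self):
        with pytest.raises(SingularCovariance):
            mvn_loglik(np.zeros(2), np.zeros(2), np.zeros((2, 2)))
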