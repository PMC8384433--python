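"""Scenario generators producing bird-family-shaped test datasets.

A scenario bundles everything a model fit consumes: an ultrametric tree of
the requested size, a true tropical/temperate regime history with tip
counts near the template's split, a bank of stochastic maps expressing
reconstruction uncertainty, optional biogeography and sympatry
downsampling, and trait data simulated under a chosen generating model.
Everything is a deterministic function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import ModelSpec, Params
from .regimes import MkModel, downsample_sympatry, sample_stochastic_maps
from .simulate import (
    add_observational_error,
    simulate_bd_tree,
    simulate_biogeo_history,
    simulate_regime_history,
    simulate_traits,
)
__all__ = ["ScenarioSpec", "Scenario", "TEMPLATES", "make_scenario",
           "template_spec"]

#: clade templates: (n_tips, n_tropical, n_temperate)
TEMPLATES = {
    "cracidae": (50, 38, 12),
    "nectariniidae": (122, 89, 33),
    "picidae": (190, 86, 104),
}

REGIMES = ("tropical", "temperate")


@dataclass
class ScenarioSpec:
    """Recipe for one synthetic clade-level dataset."""

    n_tips: int
    n_tropical: int
    n_temperate: int
    gen_spec: ModelSpec = None
    gen_params: Params = None
    tree_height: float = 50.0       # Myr; typical family-level clade age
    birth: float = 0.2              # per-lineage speciation rate (1/Myr)
    death: float = 0.05
    switch_rate: float = None       # total Mk switch rate; default 3/height
    n_areas: int = 1
    area_gain: float = 0.05
    area_loss: float = 0.05
    map_bank_size: int = 20
    p_tropical: float = 1.0         # sympatry retention fractions
    p_temperate: float = 1.0
    sigma_err2: float = 0.0
    seed: int = 0
    tip_tolerance: float = 0.10     # regime split must land within +/-10%
    max_retries: int = 200

    def __post_init__(self):
        if self.n_tropical + self.n_temperate != self.n_tips:
            raise ValueError("regime targets must sum to n_tips")


@dataclass
class Scenario:
    spec: ScenarioSpec
    tree: object
    regimes: object            # true RegimeHistory (2-state)
    regime_bank: list          # stochastic maps conditioned on tip states
    mk_model: MkModel
    biogeo: object             # BiogeoHistory or None
    interactions: object       # InteractionFilter or None (the *true* one)
    traits: object             # observed TraitData
    true_traits: object        # noise-free tip means

    @property
    def tip_regimes(self):
        return self.regimes.tip_labels_at_present()


def _regime_mk(spec):
    """Mk generator whose stationary split matches the template counts."""
    c = spec.switch_rate if spec.switch_rate is not None else 3.0 / spec.tree_height
    pi_trop = spec.n_tropical / spec.n_tips
    pi_trop = min(max(pi_trop, 0.05), 0.95)
    Q = np.array([[-c * (1 - pi_trop), c * (1 - pi_trop)],
                  [c * pi_trop, -c * pi_trop]])
    return MkModel(REGIMES, Q, root_freq=np.array([pi_trop, 1 - pi_trop]))


def make_scenario(spec):
    """Build a :class:`Scenario`; deterministic in (spec, seed).

    The regime history is resimulated (bounded retries) until the tip split
    is within ``tip_tolerance`` of the targets; the map bank is drawn from
    the generating Mk model conditioned on the realized tip states.
    """
    root = np.random.default_rng(spec.seed)
    tree_seed, hist_seed, bio_seed, bank_seed, trait_seed, ds_seed, err_seed = \
        root.integers(0, 2**31 - 1, size=7)
    tree = simulate_bd_tree(spec.n_tips, birth=spec.birth, death=spec.death,
                            seed=int(tree_seed)).rescale(spec.tree_height)
    mk = _regime_mk(spec)
    tol = max(1, int(np.floor(spec.tip_tolerance * spec.n_tips)))
    regimes = None
    for i in range(spec.max_retries):
        cand = simulate_regime_history(tree, mk, seed=int(hist_seed) + i)
        counts = list(cand.tip_labels_at_present().values())
        n_trop = sum(1 for s in counts if s == "tropical")
        if abs(n_trop - spec.n_tropical) <= tol:
            regimes = cand
            break
    if regimes is None:
        raise RuntimeError(
            f"could not hit regime split {spec.n_tropical}/{spec.n_temperate} "
            f"within {spec.max_retries} tries")

    tip_states = regimes.tip_labels_at_present()
    bank = sample_stochastic_maps(tree, mk, tip_states,
                                  count=spec.map_bank_size, seed=int(bank_seed))

    biogeo = None
    if spec.n_areas > 1:
        biogeo = simulate_biogeo_history(tree, spec.n_areas,
                                         gain=spec.area_gain,
                                         loss=spec.area_loss,
                                         seed=int(bio_seed))
    interactions = None
    if spec.p_tropical < 1 or spec.p_temperate < 1:
        interactions = downsample_sympatry(tree, biogeo, tip_states,
                                           spec.p_tropical, spec.p_temperate,
                                           seed=int(ds_seed))

    gspec = spec.gen_spec or ModelSpec("BM")
    gparams = spec.gen_params or Params(z0=0.0, sigma2=0.05)
    true_traits = simulate_traits(
        tree, regimes, gspec, gparams,
        biogeo=biogeo if gspec.biogeography else None,
        interactions=interactions, seed=int(trait_seed))
    traits = true_traits
    if spec.sigma_err2 > 0:
        traits = add_observational_error(true_traits, spec.sigma_err2,
                                         seed=int(err_seed))
    return Scenario(spec, tree, regimes, bank, mk, biogeo, interactions,
                    traits, true_traits)


def template_spec(name, **overrides):
    """ScenarioSpec for one of the named clade templates."""
    n, ntr, nte = TEMPLATES[name]
    return ScenarioSpec(n_tips=n, n_tropical=ntr, n_temperate=nte, **overrides)
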