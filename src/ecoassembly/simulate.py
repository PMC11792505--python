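"""Synthetic communities under known assembly regimes.

Ground-truth generators for validating the classification and attribution
machinery: a Yule (pure-birth) phylogeny, Brownian-motion traits along
its branches, and abundance tables assembled under one of the five
regimes the classifier is meant to recover.

* ``heterogeneous_selection`` -- sites spread along a wide environmental
  gradient; each taxon's expected abundance is a Gaussian niche filter
  exp(-(trait - env)^2 / 2w^2) times a lognormal carrying capacity, and
  the site total is drawn multinomially.  Because traits are Brownian
  (phylogenetically conserved), environmentally distant sites diverge
  phylogenetically.
* ``homogeneous_selection`` -- the same filter with every site at one
  environmental value, plus strong per-site lottery (priority-effect)
  noise.  The noise matters: sites that select identical communities are
  indistinguishable from homogenized ones (shared taxa sit at distance
  zero under every tip shuffle); homogeneous selection is only visible
  as taxonomic turnover that stays phylogenetically shallow.
* ``drift`` -- every site is a multinomial draw from one shared
  metacommunity distribution (no filter).
* ``dispersal_limitation`` -- each taxon has a home position on a line of
  sites; access decays exponentially with distance, so sites sample
  spatially (not phylogenetically) structured subsets of the pool.
* ``homogenizing_dispersal`` -- the same spatially patchy base, but site
  compositions are mixed toward their common mean before the draw,
  mimicking mass effects.  (Against a perfectly uniform pool the
  Raup-Crick null could not scatter taxon sets, so homogenization would
  be undetectable in principle; a patchy base keeps the regional pool
  informative.)

Default parameters live in ``data/default_scenario.json`` (versioned so
recovery tests stay stable).  Every generator is deterministic given its
seed.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass
from importlib import resources

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import CommunityMatrix, Phylogeny
from .nulls import PROCESSES

__all__ = [
    "SyntheticScenario",
    "DEFAULTS",
    "simulate_tree",
    "simulate_traits",
    "simulate_regime",
]

_TAG_TRAITS = 31
_TAG_REGIME = 37

DEFAULTS: dict = json.loads(
    resources.files("ecoassembly.data").joinpath("default_scenario.json").read_text()
)


@dataclass
class SyntheticScenario:
    """Parameters of one simulated assembly regime.

    ``niche_width`` is expressed in units of the trait standard
    deviation; ``dispersal_scale`` as a fraction of the unit site
    gradient; ``mixing`` is the mass-effect mixing weight in [0, 1].
    ``env`` overrides the per-site environmental values (selection
    regimes derive them from the simulated trait range by default).
    """

    regime: str
    n_taxa: int = DEFAULTS["n_taxa"]
    n_sites: int = DEFAULTS["n_sites"]
    total_per_site: int = DEFAULTS["total_per_site"]
    birth_rate: float = DEFAULTS["birth_rate"]
    trait_sigma: float = DEFAULTS["trait_sigma"]
    niche_width: float = DEFAULTS["niche_width"]
    dispersal_scale: float = DEFAULTS["dispersal_scale"]
    mixing: float = DEFAULTS["mixing"]
    capacity_sigma: float = DEFAULTS["capacity_sigma"]
    site_noise_sigma: float = DEFAULTS["site_noise_sigma"]
    env: tuple | None = None
    divergent_taxon: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.regime not in PROCESSES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {PROCESSES}")
        if min(self.n_taxa, self.n_sites, self.total_per_site) <= 0:
            raise ValueError("sizes must be positive")
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must be in [0, 1]")
        if self.env is not None and len(self.env) != self.n_sites:
            raise ValueError("env must provide one value per site")


def simulate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Ultrametric Yule tree with ``n_taxa`` tips labeled T1..Tn."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(int(seed)),
    )
    return Phylogeny(tree)


def simulate_traits(tree: Phylogeny, sigma: float, seed: int = 0) -> pd.Series:
    """Brownian-motion trait values at the tips (root value 0).

    Along each branch the trait gains an independent Gaussian increment
    with variance sigma^2 * branch length.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng([int(seed), _TAG_TRAITS])
    values: dict[int, float] = {}
    tips: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            # the stem (root) edge, when present, is part of the history
            # from the ancestral state at its base
            length = node.edge.length or 0.0
            val = sigma * np.sqrt(length) * rng.standard_normal()
        else:
            length = node.edge.length or 0.0
            val = values[id(parent)] + sigma * np.sqrt(length) * rng.standard_normal()
        values[id(node)] = val
        if node.is_leaf():
            tips[node.taxon.label] = val
    return pd.Series(tips, dtype=float).sort_index()


def _site_ids(n_sites: int) -> list[str]:
    width = max(2, len(str(n_sites)))
    return [f"S{i + 1:0{width}d}" for i in range(n_sites)]


def simulate_regime(
    scenario: SyntheticScenario,
    tree: Phylogeny | None = None,
    traits: pd.Series | None = None,
) -> tuple[CommunityMatrix, Phylogeny, pd.DataFrame]:
    """Simulate a count table under ``scenario.regime``.

    Returns ``(community, tree, metadata)``; the metadata carries each
    site's gradient position, environmental value (selection regimes) and
    a low/mid/high band label for grouped analyses.  Taxa never drawn are
    dropped from the table (the tree is left intact; alignment prunes it).
    """
    sc = scenario
    if tree is None:
        tree = simulate_tree(sc.n_taxa, birth_rate=sc.birth_rate, seed=sc.seed)
    if traits is None:
        traits = simulate_traits(tree, sc.trait_sigma, seed=sc.seed)
    taxa = sorted(tree.tip_labels)
    traits = traits.reindex(taxa)
    if traits.isna().any():
        raise ValueError("traits must cover every tree tip")
    trait_vals = traits.to_numpy(dtype=float).copy()
    rng = np.random.default_rng([int(sc.seed), _TAG_REGIME])

    width = sc.niche_width * max(trait_vals.std(), 1e-9)
    divergent = None
    if sc.divergent_taxon:
        coph = tree.cophenetic(order=taxa)
        divergent = int(np.argmax(coph.to_numpy().mean(axis=1)))
        # A single-causal-taxon world: under fully Brownian traits every
        # clade diverges and no one taxon is necessary for significance,
        # so the background trait-to-taxon assignment is shuffled
        # (phylogenetically unconserved niches) and the signal is carried
        # solely by the most isolated tip.  Its trait sits 1.5 niche
        # widths beyond the background maximum -- dominant at the top of
        # the gradient yet still coexisting, so removal never empties a
        # site -- and it gets the median carrying capacity so the causal
        # structure does not hinge on a lucky lognormal draw.
        others = np.array([i for i in range(len(taxa)) if i != divergent])
        trait_vals[others] = trait_vals[others][rng.permutation(others.size)]
        trait_vals[divergent] = trait_vals[others].max() + 1.5 * width
        # a relict lineage: elongate the divergent terminal branch to twice
        # the tree depth on a copy of the tree, so the tip-shuffle null
        # rarely places comparable abundance at so deep a position
        tree = Phylogeny.from_newick(tree.to_newick())
        depth = next(tree.tree.leaf_node_iter()).distance_from_root()
        leaf = next(
            lf for lf in tree.tree.leaf_node_iter()
            if lf.taxon.label == taxa[divergent]
        )
        leaf.edge.length += 2.0 * depth

    n, s = len(taxa), sc.n_sites
    capacity = rng.lognormal(0.0, sc.capacity_sigma, size=n)
    if divergent is not None:
        capacity[divergent] = float(np.median(capacity))
    positions = np.linspace(0.0, 1.0, s)
    env = np.full(s, np.nan)

    if sc.regime in ("heterogeneous_selection", "homogeneous_selection"):
        if sc.env is not None:
            env = np.asarray(sc.env, dtype=float)
            if np.isnan(env).any():
                raise ValueError("selection regimes need environmental values for every site")
        elif sc.regime == "heterogeneous_selection":
            env = np.linspace(trait_vals.min(), trait_vals.max(), s)
        else:
            env = np.full(s, float(np.median(trait_vals)))
        W = capacity[None, :] * np.exp(
            -((trait_vals[None, :] - env[:, None]) ** 2) / (2.0 * width**2)
        )
        if sc.regime == "homogeneous_selection":
            # independent per-site lotteries among taxa passing the filter
            W = W * rng.lognormal(0.0, sc.site_noise_sigma, size=(s, n))
    elif sc.regime == "drift":
        meta = capacity / capacity.sum()
        W = np.tile(meta, (s, 1))
    else:  # dispersal_limitation / homogenizing_dispersal share the patchy base
        homes = rng.uniform(0.0, 1.0, size=n)
        W = capacity[None, :] * np.exp(
            -np.abs(positions[:, None] - homes[None, :]) / sc.dispersal_scale
        )
        if sc.regime == "homogenizing_dispersal":
            local = W / W.sum(axis=1, keepdims=True)
            W = (1.0 - sc.mixing) * local + sc.mixing * local.mean(axis=0, keepdims=True)

    W = W / W.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(sc.total_per_site, W[k]) for k in range(s)]
    ).astype(float)
    sites = _site_ids(s)
    table = pd.DataFrame(counts, index=sites, columns=taxa)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # expected all-zero-taxon drops
        community = CommunityMatrix(table)
    bands = np.array(["low", "mid", "high"])[
        np.minimum((np.arange(s) * 3) // s, 2)
    ]
    meta_df = pd.DataFrame(
        {"position": positions, "env": env, "band": bands}, index=sites
    )
    if divergent is not None:
        meta_df.attrs["divergent_taxon"] = taxa[divergent]
    return community, tree, meta_df
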