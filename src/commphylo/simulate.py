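"""Synthetic gradients with known ground truth.

Emulates the structure of a dryland dung-beetle survey: a 10-site transect
with aridity increasing along it, two seasons in each of two years, a pool
of ~60 species split into two deep clades, traits with a tunable fraction
of Brownian-motion phylogenetic signal, and abundances shaped by one of
three assembly scenarios:

* ``neutral`` — every pool species equally likely; the calibration case
  for the null models;
* ``filtering`` — relative abundance follows a Gaussian filter on a focal
  trait whose optimum moves along the gradient; the dry season applies a
  narrower filter everywhere, mimicking the seasonal homogenization of
  harsh conditions;
* ``repulsion`` — species are drawn sequentially with probability
  proportional to their minimum trait distance to the species already in
  the site (limiting similarity).

Total individuals per site are 50 plus a log-series draw, giving the
strongly uneven totals typical of dung-beetle samples.  Every output uses
the same containers and file formats the readers accept, so simulate ->
analyze is a closed loop.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CommunityTable, TraitTable, ValidationError
from .trees import _root_depths, tree_height

log = logging.getLogger("commphylo")


@dataclass
class Scenario:
    """Ground-truth parameters of a simulated gradient."""

    n_species: int = 60
    n_sites: int = 10
    n_years: int = 2
    assembly: str = "neutral"        # neutral | filtering | repulsion
    filter_strength: float = 0.5     # Gaussian filter width, trait sd units
    dry_filter_factor: float = 0.5   # dry-season width = factor * filter_strength
    signal: float = 0.5              # fraction of trait variance from BM on the tree
    optimum_shift: float = 1.0       # trait-optimum movement per unit standardized log-aridity
    n_traits: int = 5
    repulsion_richness: int = 15
    logseries_p: float = 0.995       # shape of the per-site total-abundance draw
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assembly not in ("neutral", "filtering", "repulsion"):
            raise ValidationError(f"unknown assembly {self.assembly!r}")
        if not 0.0 <= self.signal <= 1.0:
            raise ValidationError("signal must be in [0, 1]")
        if min(self.n_species, self.n_sites, self.n_traits) < 2:
            raise ValidationError("counts must be >= 2")


def aridity_gradient(n_sites: int, low: float = 1.0, high: float = 3.5
                     ) -> np.ndarray:
    """Aridity index per site, uniform on the log scale (the threefold
    rainfall contrast of a semiarid-to-Saharan transect)."""
    return np.logspace(np.log10(low), np.log10(high), n_sites)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def _scale_to_height(tree: dendropy.Tree, height: float = 1.0) -> dendropy.Tree:
    h = tree_height(tree)
    if h <= 0:
        raise ValidationError("degenerate tree of zero height")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= height / h
    return tree


def _yule(labels: list[str], rng) -> dendropy.Tree:
    """Pure-birth tree over ``labels``, grown by random bifurcation of a
    uniformly chosen extant lineage with exponential waiting times."""
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    tips = [tree.seed_node]
    t = 0.0
    times = {tree.seed_node: 0.0}
    while len(tips) < len(labels):
        t += rng.exponential(1.0 / len(tips))
        node = tips.pop(rng.integers(len(tips)))
        times[node] = t
        for _ in range(2):
            child = node.new_child()
            tips.append(child)
    t_end = t + rng.exponential(1.0 / len(tips))
    for node, label in zip(tips, rng.permutation(labels)):
        times[node] = t_end
        node.taxon = taxa.get_taxon(label)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = times[node] - times[node.parent_node]
    return tree


def simulate_tree(n_species: int, rng, two_clades: bool = True,
                  split_depth: float = 0.5) -> dendropy.Tree:
    """Ultrametric pure-birth tree of height 1.

    With ``two_clades`` (default) the tree has a deep basal split at
    ``split_depth`` below the root, emulating a pool drawn from two major
    subfamilies.
    """
    if n_species < 2:
        raise ValidationError("need >= 2 species")
    labels = [f"sp{i+1:03d}" for i in range(n_species)]
    if not two_clades or n_species < 4:
        return _scale_to_height(_yule(labels, rng))
    n1 = n_species // 2
    sub1 = _scale_to_height(_yule(labels[:n1], rng), 1.0 - split_depth)
    sub2 = _scale_to_height(_yule(labels[n1:], rng), 1.0 - split_depth)
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    for sub in (sub1, sub2):
        sub.seed_node.edge.length = split_depth
        tree.seed_node.add_child(sub.seed_node)
    tree.migrate_taxon_namespace(taxa)
    return tree


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _brownian_tips(tree: dendropy.Tree, rng) -> pd.Series:
    """One Brownian-motion trait (unit rate) evaluated at the tips."""
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        else:
            step = rng.normal(0.0, np.sqrt(max(node.edge.length or 0.0, 0.0)))
            values[node] = values[node.parent_node] + step
    out = {lf.taxon.label: values[lf] for lf in tree.leaf_node_iter()}
    return pd.Series(out)


def simulate_traits(tree: dendropy.Tree, n_traits: int, signal: float, rng,
                    categorical: bool = True) -> TraitTable:
    """Traits as a mixture sqrt(signal)*BM + sqrt(1-signal)*iid normal.

    On a height-1 tree both parts have unit marginal variance, so ``signal``
    is the fraction of trait variance attributable to phylogeny.  With
    ``categorical`` an extra qualitative trait is derived by thresholding a
    latent BM trait at its median (a conserved binary strategy, e.g. dung
    relocation behaviour).
    """
    if not 0.0 <= signal <= 1.0:
        raise ValidationError("signal must be in [0, 1]")
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    cols = {}
    for j in range(n_traits):
        bm = _brownian_tips(tree, rng).reindex(labels)
        noise = rng.normal(size=len(labels))
        cols[f"trait_{j+1}"] = np.sqrt(signal) * bm.to_numpy() + \
            np.sqrt(1.0 - signal) * noise
    quant = pd.DataFrame(cols, index=labels)
    if categorical:
        latent = _brownian_tips(tree, rng).reindex(labels).to_numpy()
        strategy = np.where(latent > np.median(latent), "endocoprid", "paracoprid")
        cat = pd.DataFrame({"relocation": strategy}, index=labels)
    else:
        cat = pd.DataFrame(index=labels)
    return TraitTable(quant, cat)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def _site_weights(scenario: Scenario, x: np.ndarray, mu: float,
                  width: float, rng) -> np.ndarray:
    n = len(x)
    if scenario.assembly == "neutral":
        return np.full(n, 1.0 / n)
    if scenario.assembly == "filtering":
        w = np.exp(-((x - mu) ** 2) / (2.0 * width ** 2))
        if w.sum() <= 0:
            w = np.full(n, 1.0)
        return w / w.sum()
    # repulsion: sequential draws penalizing trait proximity to chosen set
    chosen = [int(rng.integers(n))]
    target = min(scenario.repulsion_richness, n)
    while len(chosen) < target:
        dist = np.min(np.abs(x[:, None] - x[chosen][None, :]), axis=1)
        dist[chosen] = 0.0
        if dist.sum() == 0:
            break
        chosen.append(int(rng.choice(n, p=dist / dist.sum())))
    w = np.zeros(n)
    w[chosen] = 1.0
    return w / w.sum()


def simulate_gradient_communities(scenario: Scenario, tree: dendropy.Tree,
                                  traits: TraitTable, rng
                                  ) -> list[CommunityTable]:
    """One CommunityTable per season x year under the scenario's assembly
    rule.  The focal (filtered) trait is the first quantitative trait,
    standardized across the pool; the filter optimum moves with
    standardized log-aridity at rate ``optimum_shift``."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    x = traits.quantitative.iloc[:, 0].reindex(labels).to_numpy()
    x = (x - x.mean()) / x.std(ddof=1)
    aridity = aridity_gradient(scenario.n_sites)
    z = np.log10(aridity)
    z = (z - z.mean()) / z.std(ddof=1)
    sites = [f"site_{i+1:02d}" for i in range(scenario.n_sites)]
    out = []
    for year in range(2013, 2013 + scenario.n_years):
        for season in ("wet", "dry"):
            width = scenario.filter_strength
            if season == "dry":
                width *= scenario.dry_filter_factor
            rows = []
            for s in range(scenario.n_sites):
                mu = scenario.optimum_shift * z[s]
                for attempt in range(20):
                    w = _site_weights(scenario, x, mu, width, rng)
                    total = 50 + int(sps.logser.rvs(scenario.logseries_p,
                                                    random_state=rng))
                    counts = rng.multinomial(total, w)
                    if (counts > 0).sum() >= 2:
                        break
                    log.warning("resampling empty/degenerate site %s", sites[s])
                rows.append(counts)
            ab = pd.DataFrame(np.array(rows), index=sites, columns=labels)
            ab.index.name = "site"
            out.append(CommunityTable(ab, pd.Series(aridity, index=sites),
                                      season, year))
    return out


def simulate_scenario(scenario: Scenario):
    """Full closed loop: tree, traits, and per-campaign communities from a
    single seed.  Returns (tree, traits, campaigns)."""
    rng = np.random.default_rng(scenario.seed)
    tree = simulate_tree(scenario.n_species, rng)
    traits = simulate_traits(tree, scenario.n_traits, scenario.signal, rng)
    campaigns = simulate_gradient_communities(scenario, tree, traits, rng)
    return tree, traits, campaigns
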