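"""Pairwise beta diversity with turnover/nestedness partition.

Three kinds share the same Sorensen-family algebra over a triple
(a, b, c) = (shared, unique-to-first, unique-to-second):

* taxonomic  — species counts;
* phylogenetic — branch lengths on root-to-tip paths of a tree (branches
  counted from the MRCA of the union of the two sites' species), computed
  on the UPGMA back-transformation of the phylogenetic distance fraction;
* functional — convex-hull volumes of the two communities in synthetic
  (PCoA) trait space, with the intersection volume playing the role of the
  shared component.

In every case:
    beta_sor = (b + c) / (2a + b + c)       total dissimilarity
    beta_sim = min(b, c) / (a + min(b, c))  turnover
    beta_sne = beta_sor - beta_sim          nestedness-resultant

The number of synthetic-trait dimensions for the hulls follows
min(4, min richness - 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .containers import BetaPartition, CommunityTable, ValidationError
from .traitspace import TraitSpace
from .trees import _mrca, _root_depths

log = logging.getLogger("commphylo")


class DegenerateHullError(ValidationError):
    """Vertex set is (near) degenerate: no full-dimensional hull exists."""


# ---------------------------------------------------------------------------
# shared partition algebra
# ---------------------------------------------------------------------------

def _partition(a: float, b: float, c: float, kind: str) -> BetaPartition:
    denom = 2 * a + b + c
    if denom == 0:
        raise ValidationError("both components empty")
    beta_sor = (b + c) / denom
    m = min(b, c)
    beta_sim = m / (a + m) if (a + m) > 0 else 0.0
    return BetaPartition(beta_sor=beta_sor, beta_sim=beta_sim,
                         beta_sne=beta_sor - beta_sim, kind=kind)


def sorensen_partition(species_a, species_b) -> BetaPartition:
    """Taxonomic Sorensen/Simpson partition on two species sets."""
    sa, sb = set(species_a), set(species_b)
    if not sa or not sb:
        raise ValidationError("empty site")
    shared = len(sa & sb)
    return _partition(shared, len(sa - sb), len(sb - sa), "taxonomic")


# ---------------------------------------------------------------------------
# phylogenetic kind
# ---------------------------------------------------------------------------

def _branch_sets(tree, union):
    """Edges on the path from the MRCA of ``union`` down to each tip, as a
    mapping tip label -> set of edge ids, plus edge lengths."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()
              if lf.taxon.label in union}
    missing = union - set(leaves)
    if missing:
        raise ValidationError(f"species absent from tree: {sorted(missing)}")
    mrca = _mrca(list(leaves.values())) if len(leaves) > 1 else None
    lengths, paths = {}, {}
    for label, leaf in leaves.items():
        path = set()
        cur = leaf
        while cur is not None and cur is not mrca:
            eid = id(cur.edge)
            lengths[eid] = cur.edge.length or 0.0
            path.add(eid)
            cur = cur.parent_node
        paths[label] = path
    return paths, lengths


def phylo_beta_pair(tree, presence_a, presence_b) -> BetaPartition:
    """Branch-length Sorensen partition between two sites on a tree."""
    sa, sb = set(presence_a), set(presence_b)
    if not sa or not sb:
        raise ValidationError("empty site")
    if sa == sb:
        return BetaPartition(0.0, 0.0, 0.0, "phylogenetic")
    paths, lengths = _branch_sets(tree, sa | sb)
    edges_a = set().union(*(paths[s] for s in sa))
    edges_b = set().union(*(paths[s] for s in sb))
    a = sum(lengths[e] for e in edges_a & edges_b)
    b = sum(lengths[e] for e in edges_a - edges_b)
    c = sum(lengths[e] for e in edges_b - edges_a)
    part = _partition(a, b, c, "phylogenetic")
    return part


# ---------------------------------------------------------------------------
# functional kind: convex hulls in synthetic-trait space
# ---------------------------------------------------------------------------

def choose_dimensions(richness_a: int, richness_b: int) -> int:
    """Hull dimensionality: min(4, min richness - 1)."""
    if min(richness_a, richness_b) < 2:
        raise ValidationError("both sites need richness >= 2")
    return min(4, min(richness_a, richness_b) - 1)


def hull_volume(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    k = points.shape[1]
    if k == 1:
        return float(points.max() - points.min())
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:
        raise DegenerateHullError(str(exc)) from None


def _halfspaces(points: np.ndarray) -> np.ndarray:
    """Half-space representation A x + b <= 0 of the hull of ``points``."""
    return ConvexHull(points).equations


def _chebyshev_center(halfspaces: np.ndarray):
    """Largest inscribed ball of {x : A x + b <= 0}; returns (center, radius)."""
    A = halfspaces[:, :-1]
    b = -halfspaces[:, -1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    k = A.shape[1]
    # maximize r subject to A x + r ||A_i|| <= b
    res = linprog(c=np.r_[np.zeros(k), -1.0],
                  A_ub=np.hstack([A, norms]), b_ub=b,
                  bounds=[(None, None)] * k + [(0, None)], method="highs")
    if not res.success:
        return None, 0.0
    return res.x[:k], float(res.x[k])


def _points_in_hull(points: np.ndarray, halfspaces: np.ndarray,
                    tol: float = 1e-9) -> np.ndarray:
    A = halfspaces[:, :-1]
    b = halfspaces[:, -1]
    return np.all(points @ A.T + b <= tol, axis=1)


def hull_intersection_volume(points_a: np.ndarray, points_b: np.ndarray,
                             rng=None, n_mc: int = 100_000):
    """Volume of the intersection of two convex hulls (same dimension).

    The exact path intersects the half-space representations and takes the
    hull of the feasible region.  When a robust interior point cannot be
    found (thin or touching intersections), a seeded Monte-Carlo rejection
    estimate in the joint bounding box is used and its standard error
    returned alongside.

    Returns ``(volume, se)``; ``se`` is 0.0 on the exact path.
    """
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    if pa.shape[1] != pb.shape[1]:
        raise ValidationError("dimension mismatch between hulls")
    k = pa.shape[1]
    if k == 1:
        lo = max(pa.min(), pb.min())
        hi = min(pa.max(), pb.max())
        return max(hi - lo, 0.0), 0.0
    try:
        hs = np.vstack([_halfspaces(pa), _halfspaces(pb)])
    except QhullError as exc:
        raise DegenerateHullError(str(exc)) from None
    center, radius = _chebyshev_center(hs)
    if center is None or radius <= 0.0:
        return 0.0, 0.0
    if radius > 1e-9:
        try:
            inter = HalfspaceIntersection(hs, center)
            return float(ConvexHull(inter.intersections).volume), 0.0
        except QhullError:
            pass
    # Monte-Carlo fallback for numerically thin intersections
    rng = np.random.default_rng(0) if rng is None else rng
    lo = np.maximum(pa.min(axis=0), pb.min(axis=0))
    hi = np.minimum(pa.max(axis=0), pb.max(axis=0))
    if np.any(hi <= lo):
        return 0.0, 0.0
    box = np.prod(hi - lo)
    samples = rng.uniform(lo, hi, size=(n_mc, k))
    inside = _points_in_hull(samples, hs)
    p = inside.mean()
    se = box * np.sqrt(p * (1 - p) / n_mc)
    return float(box * p), float(se)


def monte_carlo_intersection_volume(points_a, points_b, rng,
                                    n_mc: int = 100_000):
    """Independent Monte-Carlo estimate of the hull-intersection volume
    (rejection sampling in the joint bounding box); returns (volume, se)."""
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    k = pa.shape[1]
    lo = np.maximum(pa.min(axis=0), pb.min(axis=0))
    hi = np.minimum(pa.max(axis=0), pb.max(axis=0))
    if np.any(hi <= lo):
        return 0.0, 0.0
    box = float(np.prod(hi - lo))
    samples = rng.uniform(lo, hi, size=(n_mc, k))
    if k == 1:
        ina = (samples[:, 0] >= pa.min()) & (samples[:, 0] <= pa.max())
        inb = (samples[:, 0] >= pb.min()) & (samples[:, 0] <= pb.max())
        inside = ina & inb
    else:
        inside = (_points_in_hull(samples, _halfspaces(pa)) &
                  _points_in_hull(samples, _halfspaces(pb)))
    p = inside.mean()
    # Laplace-smoothed hit rate keeps the SE positive for sliver overlaps
    p_se = (inside.sum() + 1.0) / (n_mc + 2.0)
    return box * float(p), box * float(np.sqrt(p_se * (1 - p_se) / n_mc))


def functional_beta_pair(space: TraitSpace, presence_a, presence_b,
                         k: int | None = None) -> BetaPartition:
    """Hull-volume Sorensen partition between two sites in synthetic-trait
    space, on the first ``k`` axes (default: the dimension rule)."""
    sa, sb = set(presence_a), set(presence_b)
    if not sa or not sb:
        raise ValidationError("empty site")
    if k is None:
        k = choose_dimensions(len(sa), len(sb))
    if min(len(sa), len(sb)) < k + 1:
        raise ValidationError(f"need >= {k + 1} species per site for {k}-D hulls")
    if sa == sb:
        return BetaPartition(0.0, 0.0, 0.0, "functional")
    ids = list(space.ids)
    pos = {s: i for i, s in enumerate(ids)}
    pa = space.coordinates[[pos[s] for s in sorted(sa)], :k]
    pb = space.coordinates[[pos[s] for s in sorted(sb)], :k]
    va = hull_volume(pa)
    vb = hull_volume(pb)
    if va <= 0 or vb <= 0:
        raise DegenerateHullError("zero-volume hull")
    v_int, _se = hull_intersection_volume(pa, pb)
    v_int = min(v_int, va, vb)
    return _partition(v_int, va - v_int, vb - v_int, "functional")


# ---------------------------------------------------------------------------
# transect summaries and SES of beta components
# ---------------------------------------------------------------------------

def pairwise_beta_matrix(pair_fn, sites: list) -> dict:
    """Evaluate ``pair_fn(site_i, site_j)`` over all unordered pairs; pairs
    where the partition is undefined map to None."""
    out = {}
    for i, j in itertools.combinations(range(len(sites)), 2):
        try:
            out[(sites[i], sites[j])] = pair_fn(sites[i], sites[j])
        except ValidationError as exc:
            log.info("pair (%s, %s) dropped: %s", sites[i], sites[j], exc)
            out[(sites[i], sites[j])] = None
    return out


def pairwise_beta_summaries(partitions: dict, transect_order: list
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site mean pairwise beta (n values) and the consecutive-pair
    series along the transect (n - 1 values)."""
    def get(i, j):
        p = partitions.get((i, j), partitions.get((j, i)))
        if p is None:
            raise ValidationError(f"missing pair ({i}, {j})")
        return p

    mean_rows = []
    for s in transect_order:
        parts = [get(s, t) for t in transect_order if t != s]
        mean_rows.append({
            "site": s,
            "beta_sor": np.mean([p.beta_sor for p in parts]),
            "beta_sim": np.mean([p.beta_sim for p in parts]),
            "beta_sne": np.mean([p.beta_sne for p in parts]),
        })
    consec_rows = []
    for s, t in zip(transect_order[:-1], transect_order[1:]):
        p = get(s, t)
        consec_rows.append({"site_from": s, "site_to": t,
                            "beta_sor": p.beta_sor, "beta_sim": p.beta_sim,
                            "beta_sne": p.beta_sne})
    return pd.DataFrame(mean_rows), pd.DataFrame(consec_rows)


def beta_ses(pair_fn, null_pair_factory, n_null: int, rng) -> dict:
    """SES per partition component for one site pair.

    ``pair_fn()`` returns the observed BetaPartition; ``null_pair_factory(rng)``
    returns one null-draw BetaPartition.  Returns {"beta_sor": SesResult, ...}.
    """
    from .nulls import ses_from_null
    observed = pair_fn()
    draws = {"beta_sor": [], "beta_sim": [], "beta_sne": []}
    excluded = 0
    for _ in range(n_null):
        try:
            p = null_pair_factory(rng)
        except ValidationError:
            excluded += 1
            continue
        draws["beta_sor"].append(p.beta_sor)
        draws["beta_sim"].append(p.beta_sim)
        draws["beta_sne"].append(p.beta_sne)
    if excluded > 0.10 * n_null:
        raise ValidationError(f"{excluded}/{n_null} null draws undefined")
    out = {}
    for comp, values in draws.items():
        res = ses_from_null(getattr(observed, comp), values)
        res.n_excluded = excluded
        out[comp] = res
    return out
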