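"""Tree handling built on dendropy.

Covers cophenetic distances, pruning to a species pool, random grafting of
taxa that are missing from the molecular trees (placed uniformly within a
taxonomically assigned clade, keeping the tree ultrametric), and UPGMA
back-transformation of a distance matrix into a synthetic ultrametric tree.

Trees are dendropy :class:`~dendropy.Tree` objects; branch-length units are
carried opaquely (typically Myr for dated trees, arbitrary for synthetic
ones).
"""

from __future__ import annotations

import copy
import logging
import warnings
from pathlib import Path

import dendropy
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import CladeAssignment, DistanceMatrix, ValidationError

log = logging.getLogger("commphylo")

ULTRAMETRIC_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Newick I/O: one tree per line in multi-tree files
# ---------------------------------------------------------------------------

def read_trees(path) -> list[dendropy.Tree]:
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    if not len(trees):
        raise ValidationError(f"no trees in {path}")
    for t in trees:
        if not is_ultrametric(t):
            warnings.warn(f"tree in {path} is not ultrametric within "
                          f"{ULTRAMETRIC_RTOL} relative tolerance")
    return list(trees)


def write_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


def tree_from_newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# basic geometry
# ---------------------------------------------------------------------------

def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _root_depths(tree: dendropy.Tree) -> dict:
    """Distance from the root to every node."""
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    depths = _root_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    depths = _root_depths(tree)
    tips = [depths[leaf] for leaf in tree.leaf_node_iter()]
    h = max(tips)
    if h == 0:
        return True
    return (h - min(tips)) <= rtol * h


def cophenetic_distance(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic distance between every pair of tips (sum of branch lengths
    on the connecting path)."""
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValidationError("cophenetic distance needs >= 2 tips")
    labels = [lf.taxon.label for lf in leaves]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
    return DistanceMatrix(labels, d, check=False)


def prune_to_pool(tree: dendropy.Tree, pool) -> dendropy.Tree:
    """Induced subtree on ``pool``; path lengths between retained tips are
    preserved exactly (suppressed degree-2 nodes have their branch lengths
    summed)."""
    pool = set(pool)
    labels = set(tip_labels(tree))
    missing = pool - labels
    if missing:
        raise ValidationError(f"pool species absent from tree: {sorted(missing)}")
    if len(pool) < 2:
        raise ValidationError("pruned tree would have < 2 tips")
    taxa = [t for t in tree.taxon_namespace if t.label in pool]
    return tree.extract_tree_with_taxa(taxa=taxa)


# ---------------------------------------------------------------------------
# random insertion of unplaced taxa
# ---------------------------------------------------------------------------

def _mrca(nodes) -> dendropy.Node:
    paths = []
    for node in nodes:
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(path[::-1])
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidates = {id(p[depth]) for p in paths}
        if len(candidates) == 1:
            mrca = paths[0][depth]
        else:
            break
    return mrca


def _candidate_edges(tree: dendropy.Tree, anchor: set):
    """Branches on which a taxon assigned to the ``anchor`` clade may attach:
    every branch of the clade's induced subtree; the clade stem is excluded
    when the anchor has >= 2 tips, while a single-tip anchor means the
    terminal branch of that tip."""
    leaves = [lf for lf in tree.leaf_node_iter() if lf.taxon.label in anchor]
    if len(leaves) != len(anchor):
        found = {lf.taxon.label for lf in leaves}
        raise ValidationError(f"anchor tips absent from tree: {sorted(anchor - found)}")
    if len(leaves) == 1:
        return [leaves[0].edge]
    mrca = _mrca(leaves)
    edges = []
    for node in mrca.preorder_iter():
        if node is mrca:
            continue  # stem (mrca's own edge) excluded; descend within clade
        if node.edge.length and node.edge.length > 0:
            edges.append(node.edge)
    if not edges:
        raise ValidationError("anchor clade has no internal branch to attach on")
    return edges


def insert_missing_taxa(tree: dendropy.Tree, assignments, rng) -> dendropy.Tree:
    """Graft each unplaced taxon at a uniformly chosen branch within its
    anchor clade, at a uniform depth along that branch, with a pendant length
    that keeps the tree exactly ultrametric.  Returns a new tree; the input
    is untouched."""
    out = copy.deepcopy(tree)  # independent taxon namespace
    height = tree_height(out)
    for asg in assignments:
        depths = _root_depths(out)
        edges = _candidate_edges(out, set(asg.anchor))
        edge = edges[rng.integers(len(edges))]
        child = edge.head_node
        parent = edge.tail_node
        lo, hi = depths[parent], depths[child]
        t = lo + rng.random() * (hi - lo)
        pendant = height - t
        if pendant < 0:
            raise ValidationError(f"attachment of {asg.species_id} would need a "
                                  "negative pendant branch")
        taxon = out.taxon_namespace.new_taxon(label=asg.species_id)
        parent.remove_child(child)
        knot = parent.new_child(edge_length=t - lo)
        knot.add_child(child)
        child.edge.length = hi - t
        knot.new_child(taxon=taxon, edge_length=pendant)
    return out


# ---------------------------------------------------------------------------
# UPGMA back-transformation
# ---------------------------------------------------------------------------

def upgma_from_distance(d: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomerative tree from a distance matrix.

    Node heights are half the average inter-cluster distance at each merge,
    so the output is ultrametric; when the input is itself an ultrametric
    (cophenetic) matrix the output reproduces it exactly.
    """
    n = len(d)
    if n < 2:
        raise ValidationError("UPGMA needs >= 2 labels")
    linkage = hierarchy.linkage(squareform(d.values, checks=False), method="average")
    taxa = dendropy.TaxonNamespace(d.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, label in enumerate(d.ids):
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[i] = (node, 0.0)
    for k, (a, b, dist, _cnt) in enumerate(linkage):
        height = dist / 2.0
        parent = dendropy.Node()
        for idx in (int(a), int(b)):
            child, child_height = nodes.pop(idx)
            child.edge.length = max(height - child_height, 0.0)
            parent.add_child(child)
        nodes[n + k] = (parent, height)
    root, _ = nodes.popitem()[1]
    tree.seed_node = root
    tree.is_rooted = True
    return tree
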