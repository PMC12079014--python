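"""Randomization null models and standardized effect sizes.

Two label-permutation nulls are provided; both leave the community matrix
untouched, so observed and virtual communities share identical richness and
abundance distributions:

* random tips — permute tip names within the species-pool tree (or,
  equivalently, the rows/columns of its cophenetic matrix), answering
  "what would diversity be if species were differently related?";
* random traits — permute species names on the (decoupled) functional
  distance matrix, answering "what would diversity be if species had
  different trait values?".

The SES is (observed - null mean) / null sd with the sample (n-1) standard
deviation, and a two-sided rank p computed with the observed value included
among the draws.
"""

from __future__ import annotations

import copy

import numpy as np

from .containers import DistanceMatrix, SesResult, ValidationError


def permute_pool_labels(d: DistanceMatrix, pool, rng) -> DistanceMatrix:
    """One null draw: a uniformly random relabelling of pool species on the
    distance matrix.  Labels outside the pool keep their identity; the
    multiset of pairwise distances is unchanged."""
    pool = [p for p in d.ids if p in set(pool)]
    if len(pool) < 2:
        raise ValidationError("pool must contain >= 2 species present in the matrix")
    perm = rng.permutation(len(pool))
    idx = d.index_of(pool)
    order = np.arange(len(d.ids))
    order[idx] = idx[perm]
    return DistanceMatrix(d.ids, d.values[np.ix_(order, order)], check=False)


# the two nulls share the same permutation machinery; the difference is the
# object they act on (phylogenetic vs functional distances)
random_tips_null = permute_pool_labels
random_traits_null = permute_pool_labels


def shuffle_tip_labels(tree, pool, rng):
    """Random-tips null directly on a tree: permute tip names within the pool."""
    pool = sorted(set(pool))
    if len(pool) < 2:
        raise ValidationError("pool must contain >= 2 species")
    out = copy.deepcopy(tree)
    leaves = [lf for lf in out.leaf_node_iter() if lf.taxon.label in set(pool)]
    if len(leaves) != len(pool):
        raise ValidationError("pool species absent from tree")
    labels = [lf.taxon.label for lf in leaves]
    perm = rng.permutation(len(labels))
    for leaf, j in zip(leaves, perm):
        leaf.taxon = out.taxon_namespace.get_taxon(labels[j])
    return out


def ses_from_null(observed: float, null_values) -> SesResult:
    """SES and two-sided rank p for an observed value against null draws."""
    nulls = np.asarray(null_values, dtype=float)
    n = len(nulls)
    if n < 2:
        raise ValidationError("need >= 2 null draws")
    avg = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    degenerate = sd <= 1e-12 * max(abs(avg), 1.0)
    ses = 0.0 if degenerate else (observed - avg) / sd
    r_low = int(np.sum(nulls <= observed)) + 1
    r_high = int(np.sum(nulls >= observed)) + 1
    p = min(2.0 * min(r_low, r_high) / (n + 1), 1.0)
    return SesResult(observed=float(observed), null_values=nulls, avg_exp=avg,
                     sd_exp=sd, ses=ses, p_rank=p, degenerate=degenerate)


def ses(observed: float, metric, null_source, n_null: int, rng,
        max_excluded_frac: float = 0.10) -> SesResult:
    """Run a null model: ``null_source(rng)`` yields one permuted distance
    source per draw and ``metric`` maps it to a number.

    Draws on which the metric is undefined (raise or NaN) are excluded and
    counted; more than ``max_excluded_frac`` exclusions is a hard error.
    """
    if n_null < 2:
        raise ValidationError("n_null must be >= 2")
    values, excluded = [], 0
    for _ in range(n_null):
        source = null_source(rng)
        try:
            v = metric(source)
        except ValidationError:
            v = np.nan
        if np.isnan(v):
            excluded += 1
        else:
            values.append(v)
    if excluded > max_excluded_frac * n_null:
        raise ValidationError(
            f"{excluded}/{n_null} null draws had an undefined metric")
    result = ses_from_null(observed, values)
    result.n_excluded = excluded
    return result
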