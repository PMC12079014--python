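"""Decoupling functional from phylogenetic species dissimilarity.

Trait variation and phylogenetic relatedness are typically correlated, so
analysing them in parallel double-counts the conserved part of trait
variation.  The decoupling procedure separates them by a matrix residual
analysis: both distance matrices are embedded by principal coordinates,
the functional coordinates are regressed (multivariate least squares) on a
set of phylogenetic coordinate axes, and the Euclidean distance among the
*residual* functional coordinates is the decoupled functional distance
(dcFdist).  The whole phylogenetic fraction (Pdist) is returned unchanged:
the procedure deliberately gives preeminence to phylogeny, because it may
proxy conserved traits that were never measured.

The shared fraction jointFPdist is the proportion of total functional
coordinate variance explained by the regression, in [0, 1].

Axis-selection for the phylogenetic predictors matters: using every
positive axis saturates the regression (p approaches the number of species)
and drives the apparent shared fraction toward 1 even for traits simulated
independently of the tree.  The default therefore retains the leading
phylogenetic axes by the broken-stick rule, which keeps the handful of
axes that encode real tree structure; ``phylo_axes="all"`` restores the
saturated variant (capped at species - 2 to keep residual degrees of
freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix, ValidationError
from .traitspace import TraitSpace, broken_stick_axes, pcoa

log = logging.getLogger("commphylo")


@dataclass
class DecoupleResult:
    pdist: DistanceMatrix          # whole phylogenetic fraction (input, unchanged)
    dc_fdist: DistanceMatrix       # decoupled functional distance
    joint_fp: float                # shared fraction of functional variance
    n_phylo_axes: int
    n_func_axes: int
    residual_ratio: float          # residual / total functional variance (diagnostic)


def decouple_distances(fdist: DistanceMatrix, pdist_m: DistanceMatrix,
                       phylo_axes: str | int = "broken_stick") -> DecoupleResult:
    """Split functional dissimilarity into its phylogenetically shared and
    phylogeny-independent fractions.

    Parameters
    ----------
    fdist, pdist_m
        Functional and phylogenetic distance matrices over the same species.
    phylo_axes
        ``"broken_stick"`` (default), ``"all"`` (every positive axis, capped
        at species - 2), or an explicit axis count.
    """
    if list(fdist.ids) != list(pdist_m.ids):
        if set(fdist.ids) != set(pdist_m.ids):
            raise ValidationError("functional and phylogenetic matrices "
                                  "cover different species sets")
        pdist_m = pdist_m.submatrix(fdist.ids)
    n = len(fdist)
    if n < 3:
        raise ValidationError("decoupling needs >= 3 species")

    f_space = pcoa(fdist)
    p_space = pcoa(pdist_m)

    if phylo_axes == "broken_stick":
        k = min(broken_stick_axes(p_space.eigenvalues), n - 2)
    elif phylo_axes == "all":
        k = min(p_space.n_axes, n - 2)
    else:
        k = int(phylo_axes)
        if k < 1:
            raise ValidationError("phylo_axes must be >= 1")
        if k > n - 2:
            raise ValidationError("phylogenetic predictors saturate the "
                                  f"regression (need <= {n - 2} axes for "
                                  f"{n} species)")
        k = min(k, p_space.n_axes)

    P = p_space.coordinates[:, :k]          # n x k, centred by construction
    F = f_space.coordinates                 # n x m, centred
    beta, *_ = np.linalg.lstsq(P, F, rcond=None)
    fitted = P @ beta
    resid = F - fitted

    ss_tot = float(np.sum(F ** 2))
    ss_res = float(np.sum(resid ** 2))
    joint = 0.0 if ss_tot == 0 else min(max(1.0 - ss_res / ss_tot, 0.0), 1.0)

    dc_values = squareform(pdist(resid)) if resid.shape[1] else np.zeros((n, n))
    dc = DistanceMatrix(list(fdist.ids), dc_values, check=False)
    log.info("decouple: %d phylo axes, %d functional axes, jointFPdist = %.3f",
             k, f_space.n_axes, joint)
    return DecoupleResult(pdist=pdist_m, dc_fdist=dc, joint_fp=joint,
                          n_phylo_axes=k, n_func_axes=f_space.n_axes,
                          residual_ratio=0.0 if ss_tot == 0 else ss_res / ss_tot)
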