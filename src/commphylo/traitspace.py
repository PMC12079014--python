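"""Species trait space: mixed-data distances, principal coordinates, CWM.

The mixed-data metric standardizes quantitative traits to zero mean and
unit variance and one-hot encodes categorical traits with each indicator
scaled by 1/sqrt(2), so that a single-level mismatch contributes exactly 1
to the squared distance.  The construction is Euclidean by design, matching
the requirement that every distance matrix entering the ordinations be
Euclidean-embeddable.  Sporadic missing entries are handled by Gower-style
availability weighting: the squared distance over the shared observed
traits is rescaled by (total traits / shared traits).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (CommunityTable, DistanceMatrix, TraitTable,
                         ValidationError)

log = logging.getLogger("commphylo")


@dataclass
class TraitSpace:
    """Species coordinates on orthogonal synthetic-trait axes (PCoA)."""

    ids: list
    coordinates: np.ndarray          # species x axes
    eigenvalues: np.ndarray          # non-increasing
    proportion_explained: np.ndarray
    correction_applied: str = "none"  # none | lingoes

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis_{i+1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


# ---------------------------------------------------------------------------
# mixed-data distance
# ---------------------------------------------------------------------------

def _standardize(col: np.ndarray) -> np.ndarray:
    mu = np.nanmean(col)
    sd = np.nanstd(col, ddof=1)
    return (col - mu) / sd


def trait_distance(traits: TraitTable) -> DistanceMatrix:
    """Pairwise Euclidean distance among species in mixed trait space."""
    species = traits.species_ids
    n = len(species)
    if n < 2:
        raise ValidationError("need >= 2 species for a trait distance")

    blocks: list[np.ndarray] = []   # per trait: species x dims
    for name in traits.quantitative.columns:
        col = traits.quantitative[name].to_numpy(dtype=float)
        if np.nanstd(col, ddof=1) == 0 or np.isnan(np.nanstd(col, ddof=1)):
            warnings.warn(f"zero-variance quantitative trait {name!r} dropped")
            continue
        blocks.append(_standardize(col)[:, None])
    for name in traits.categorical.columns:
        col = traits.categorical[name]
        levels = sorted({v for v in col.dropna().unique()}, key=str)
        if len(levels) < 2:
            warnings.warn(f"single-level categorical trait {name!r} dropped")
            continue
        enc = np.full((n, len(levels)), np.nan)
        observed = col.notna().to_numpy()
        for j, lev in enumerate(levels):
            enc[observed, j] = (col[observed] == lev).to_numpy(dtype=float)
        blocks.append(enc / np.sqrt(2.0))
    if not blocks:
        raise ValidationError("no usable traits for the distance")

    n_traits = len(blocks)
    d2 = np.zeros((n, n))
    shared = np.zeros((n, n))
    for block in blocks:
        obs = ~np.isnan(block[:, 0])
        both = np.outer(obs, obs)
        diff2 = np.zeros((n, n))
        filled = np.nan_to_num(block)
        for k in range(block.shape[1]):
            diff2 += (filled[:, k][:, None] - filled[:, k][None, :]) ** 2
        d2 += np.where(both, diff2, 0.0)
        shared += both
    no_overlap = ~np.all(shared > 0)
    if np.any(np.diag(shared) == 0):
        bad = [species[i] for i in np.where(np.diag(shared) == 0)[0]]
        raise ValidationError(f"species with no observed traits: {bad}")
    if no_overlap:
        raise ValidationError("some species pair shares no observed trait")
    d2 = d2 * (n_traits / shared)
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(species, np.sqrt(np.maximum(d2, 0.0)), check=False)


# ---------------------------------------------------------------------------
# principal coordinates with Lingoes correction
# ---------------------------------------------------------------------------

def _gram(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d2 @ j


def pcoa(d: DistanceMatrix, n_axes: int | None = None,
         eig_tol: float = 1e-8) -> TraitSpace:
    """Classical scaling of a distance matrix into orthogonal axes.

    If the matrix is not Euclidean-embeddable (a negative eigenvalue below
    -``eig_tol`` on the scale of the largest), the Lingoes correction is
    applied: add a constant to all squared off-diagonal distances so that
    the smallest eigenvalue becomes zero.  Axis signs are fixed by making
    each axis's largest-magnitude coordinate positive.
    """
    n = len(d)
    if n < 2:
        raise ValidationError("PCoA needs >= 2 points")
    d2 = d.values ** 2
    eigvals, eigvecs = np.linalg.eigh(_gram(d2))
    scale = max(abs(eigvals).max(), 1.0)
    correction = "none"
    if eigvals.min() < -eig_tol * scale:
        c = -eigvals.min()
        d2 = d2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        eigvals, eigvecs = np.linalg.eigh(_gram(d2))
        correction = "lingoes"
        log.info("PCoA: Lingoes correction applied (c = %.6g)", c)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > eig_tol * scale
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    # sign convention
    for k in range(coords.shape[1]):
        imax = np.argmax(np.abs(coords[:, k]))
        if coords[imax, k] < 0:
            coords[:, k] = -coords[:, k]
    total = lam.sum()
    prop = lam / total if total > 0 else lam
    if n_axes is not None:
        if n_axes < 1:
            raise ValidationError("n_axes must be >= 1")
        if n_axes > coords.shape[1]:
            warnings.warn(f"requested {n_axes} axes but only {coords.shape[1]} "
                          "positive axes available; truncating")
            n_axes = coords.shape[1]
        coords = coords[:, :n_axes]
        lam = lam[:n_axes]
        prop = prop[:n_axes]
    return TraitSpace(list(d.ids), coords, lam, prop, correction)


def broken_stick_axes(eigenvalues: np.ndarray) -> int:
    """Number of leading axes whose explained proportion exceeds the
    broken-stick expectation (contiguous run from the first axis; >= 1)."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    k = len(lam)
    if k == 0:
        return 0
    prop = lam / lam.sum()
    bs = np.array([np.sum(1.0 / np.arange(i + 1, k + 1)) / k for i in range(k)])
    n_keep = 0
    for i in range(k):
        if prop[i] > bs[i]:
            n_keep += 1
        else:
            break
    return max(n_keep, 1)


# ---------------------------------------------------------------------------
# community weighted means
# ---------------------------------------------------------------------------

def cwm(comm: CommunityTable, traits: TraitTable) -> pd.DataFrame:
    """Community weighted mean of every trait, per site.

    Quantitative traits give the abundance-weighted mean over species with
    an observed value; categorical traits give one column per level with
    the abundance-weighted proportion of that level.
    """
    missing = set(comm.species_ids) - set(traits.species_ids)
    if missing:
        raise ValidationError(f"species without traits: {sorted(missing)}")
    ab = comm.abundance
    totals = ab.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError(
            f"zero total abundance at sites {list(totals.index[totals == 0])}")
    out = {}
    for name in traits.quantitative.columns:
        x = traits.quantitative[name].reindex(ab.columns)
        w = ab.to_numpy(dtype=float) * x.notna().to_numpy()
        denom = w.sum(axis=1)
        num = np.nansum(ab.to_numpy(dtype=float) * np.nan_to_num(x.to_numpy()), axis=1)
        out[name] = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    for name in traits.categorical.columns:
        col = traits.categorical[name].reindex(ab.columns)
        levels = sorted({v for v in col.dropna().unique()}, key=str)
        obs = col.notna()
        denom = (ab.loc[:, obs[obs].index]).sum(axis=1).to_numpy(dtype=float)
        for lev in levels:
            sel = (col == lev)
            num = ab.loc[:, sel[sel].index].sum(axis=1).to_numpy(dtype=float)
            out[f"{name}={lev}"] = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.DataFrame(out, index=ab.index)
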