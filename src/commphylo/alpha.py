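"""Abundance-weighted alpha diversity: MPD and MNTD per site.

MPD (mean pairwise distance) reflects the overall volume of phylogenetic or
trait space occupied by a community; MNTD (mean nearest taxon distance)
reflects how densely that space is filled.  Both operate on any labelled
distance matrix — a cophenetic matrix for the phylogenetic side, a
(decoupled) functional matrix for the trait side — and are weighted by
abundance, since very different proportions of the same species occur along
a gradient.

Sites with richness < 2 have no defined value and are reported as NaN,
never as zero (zero would fake perfect clustering).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CommunityTable, DistanceMatrix, ValidationError


def mpd_aw(abundance: np.ndarray, d: np.ndarray) -> float:
    """Abundance-weighted mean pairwise distance,
    sum_{i != j} a_i a_j d_ij / sum_{i != j} a_i a_j over present species."""
    a = np.asarray(abundance, dtype=float)
    present = a > 0
    if present.sum() < 2:
        raise ValidationError("MPD undefined for richness < 2")
    a = a[present]
    dd = d[np.ix_(present, present)]
    num = a @ dd @ a          # diagonal is zero
    den = a.sum() ** 2 - (a ** 2).sum()
    return float(num / den)


def mntd_aw(abundance: np.ndarray, d: np.ndarray) -> float:
    """Abundance-weighted mean nearest taxon distance,
    sum_i a_i min_{j != i} d_ij / sum_i a_i over present species."""
    a = np.asarray(abundance, dtype=float)
    present = a > 0
    if present.sum() < 2:
        raise ValidationError("MNTD undefined for richness < 2")
    a = a[present]
    dd = d[np.ix_(present, present)].copy()
    np.fill_diagonal(dd, np.inf)
    nearest = dd.min(axis=1)
    return float((a * nearest).sum() / a.sum())


def alpha_metrics(comm: CommunityTable, d: DistanceMatrix,
                  matrix_kind: str = "phylogenetic") -> pd.DataFrame:
    """MPD and MNTD for every site of a campaign (tidy table).

    Species present in the community but absent from the distance matrix
    raise; extra matrix species are ignored.
    """
    idx = d.index_of(comm.species_ids)
    dd = d.values[np.ix_(idx, idx)]
    rows = []
    ab = comm.abundance.to_numpy(dtype=float)
    for i, site in enumerate(comm.site_ids):
        a = ab[i]
        if (a > 0).sum() < 2:
            mpd = mntd = np.nan
        else:
            mpd = mpd_aw(a, dd)
            mntd = mntd_aw(a, dd)
        rows.append({"site": site, "season": comm.season, "year": comm.year,
                     "matrix_kind": matrix_kind, "mpd": mpd, "mntd": mntd})
    return pd.DataFrame(rows)
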