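"""Reading, validating and writing the delimited-text inputs.

Community matrices and trait tables are CSV/TSV (delimiter sniffed from the
file extension); trees are Newick, one per line in multi-tree files.  Missing
values may be written as an empty field or ``NA``; ``NA`` is canonical on
write.  Site order along the transect always comes from an explicit integer
``position`` metadata column, never from the site labels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (CommunityTable, TraitTable, ValidationError)

log = logging.getLogger("commphylo")

_NA_VALUES = ["", "NA"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    names = [h.strip() for h in header[1:]]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate column labels in {path}: {dupes}")
    return pd.read_csv(path, sep=sep, index_col=0, na_values=_NA_VALUES,
                       keep_default_na=False)


def _write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, na_rep="NA")


def read_community(path, metadata_path) -> CommunityTable:
    """Read a site x species abundance matrix plus its site metadata.

    The metadata table is indexed by site and must carry ``aridity``,
    ``season``, ``year`` and integer ``position`` columns.  Sites are
    returned sorted by transect position.
    """
    ab = _read_table(path)
    meta = _read_table(metadata_path)
    for col in ("aridity", "season", "year", "position"):
        if col not in meta.columns:
            raise ValidationError(f"metadata missing column {col!r}")
    missing = [s for s in ab.index if s not in meta.index]
    if missing:
        raise ValidationError(f"sites absent from metadata: {missing}")
    meta = meta.loc[ab.index].sort_values("position")
    ab = ab.loc[meta.index]
    values = ab.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise ValidationError("non-numeric abundance values")
    seasons = set(meta["season"])
    years = set(int(y) for y in meta["year"])
    if len(seasons) != 1 or len(years) != 1:
        raise ValidationError("one campaign (single season and year) per community file")
    table = CommunityTable(values, meta["aridity"].astype(float),
                           seasons.pop(), years.pop())
    log.info("read community %s: %d sites x %d species", path,
             len(table.site_ids), len(table.species_ids))
    return table


def write_community(comm: CommunityTable, path, metadata_path) -> None:
    _write_table(comm.abundance, path)
    meta = pd.DataFrame({
        "aridity": comm.aridity,
        "season": comm.season,
        "year": comm.year,
        "position": np.arange(1, len(comm.site_ids) + 1),
    })
    meta.index.name = comm.abundance.index.name or "site"
    _write_table(meta, metadata_path)


def read_traits(path, categorical: list[str] | None = None) -> TraitTable:
    """Read a species x trait table; ``categorical`` names the qualitative
    columns (default: every non-numeric column).

    Individual-level tables (several rows per species) are collapsed to
    species means for quantitative traits and to the modal level for
    categorical ones.
    """
    raw = _read_table(path)
    if categorical is None:
        # a column is categorical when any non-missing entry fails numeric parsing
        categorical = [
            c for c in raw.columns
            if (pd.to_numeric(raw[c], errors="coerce").isna() & raw[c].notna()).any()
        ]
    quant_cols = [c for c in raw.columns if c not in categorical]
    quant = raw[quant_cols].apply(pd.to_numeric, errors="raise")
    cat = raw[categorical].astype("object")
    if raw.index.duplicated().any():   # individual-level table
        n_ind = raw.groupby(level=0).size()
        log.info("collapsing individual-level traits: %d rows -> %d species",
                 len(raw), len(n_ind))
        quant = quant.groupby(level=0).mean()
        if len(cat.columns):
            cat = cat.groupby(level=0).agg(
                lambda s: s.mode().iloc[0] if s.notna().any() else np.nan)
        else:
            cat = cat.loc[~cat.index.duplicated()].sort_index()
    return TraitTable(quant, cat)


def write_traits(traits: TraitTable, path) -> None:
    _write_table(pd.concat([traits.quantitative, traits.categorical], axis=1), path)


def filter_traits_by_coverage(traits: TraitTable, threshold: float = 0.80) -> TraitTable:
    """Drop traits measured for fewer than ``threshold`` of the species."""
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("coverage threshold must be in (0, 1]")
    cov = traits.coverage()
    keep = cov.index[cov >= threshold - 1e-12]
    dropped = [t for t in traits.trait_names if t not in set(keep)]
    if dropped:
        log.info("coverage filter (threshold %.2f): dropped %s", threshold, dropped)
    quant = traits.quantitative[[c for c in traits.quantitative.columns if c in set(keep)]]
    cat = traits.categorical[[c for c in traits.categorical.columns if c in set(keep)]]
    if not len(quant.columns) and not len(cat.columns):
        raise ValidationError("coverage filter removed every trait")
    return TraitTable(quant, cat)


def filter_rare_species(comm: CommunityTable, traits: TraitTable,
                        min_measured: int = 1,
                        n_measured: pd.Series | None = None
                        ) -> tuple[CommunityTable, TraitTable]:
    """Remove species whose quantitative traits could not be measured.

    A species is dropped when all its quantitative traits are missing, or —
    if ``n_measured`` (individuals measured per species) is supplied — when
    fewer than ``min_measured`` individuals were measured.  Abundances of
    removed species are dropped, never redistributed.  A site emptied by the
    filter is retained with richness 0 and a warning (downstream metrics
    exclude it).
    """
    if min_measured < 0:
        raise ValidationError("min_measured must be >= 0")
    species = traits.species_ids
    drop = set()
    if len(traits.quantitative.columns):
        all_missing = traits.quantitative.isna().all(axis=1)
        drop |= set(all_missing.index[all_missing])
    if n_measured is not None:
        counts = n_measured.reindex(species).fillna(0)
        drop |= set(counts.index[counts < min_measured])
    keep = [s for s in comm.species_ids if s not in drop]
    if drop:
        log.info("rare-species filter: dropped %d of %d species: %s",
                 len(drop), len(comm.species_ids), sorted(drop))
    out_comm = comm.restrict_species(keep)
    emptied = out_comm.richness() == 0
    if emptied.any():
        log.warning("sites emptied by rare-species filter: %s",
                    list(emptied.index[emptied]))
    out_traits = traits.restrict_species([s for s in species if s not in drop])
    return out_comm, out_traits


def define_species_pool(campaigns: list[CommunityTable], season: str) -> set[str]:
    """Species pool = all species sampled during a given season across the
    whole transect (union over campaigns of that season)."""
    matched = [c for c in campaigns if c.season == season]
    if not matched:
        raise ValidationError(f"no campaign with season {season!r}")
    pool: set[str] = set()
    for c in matched:
        pool |= c.species_sampled()
    return pool
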