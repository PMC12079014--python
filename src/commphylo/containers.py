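"""Typed in-memory containers shared by every analysis stage.

The containers are deliberately thin wrappers around pandas/numpy objects:
a community matrix with transect metadata, a mixed quantitative/categorical
trait table, a labelled symmetric distance matrix, and small result records.
All validation happens at construction so downstream code can assume clean
inputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "TraitTable",
    "CladeAssignment",
    "AnalysisConfig",
    "DistanceMatrix",
    "SesResult",
    "BetaPartition",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


SEASONS = ("wet", "dry")


@dataclass
class CommunityTable:
    """Site x species abundance matrix for one sampling campaign.

    Sites are ordered along the transect (position 1 = least arid end).
    ``aridity`` is an arbitrary positive covariate supplied with the site
    metadata; no unit is assumed.
    """

    abundance: pd.DataFrame            # sites x species, non-negative integers
    aridity: pd.Series                 # indexed by site
    season: str
    year: int

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.index.duplicated().any():
            raise ValidationError("duplicate site labels")
        if ab.columns.duplicated().any():
            raise ValidationError("duplicate species labels")
        values = ab.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric abundance values")
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValidationError("abundances must be finite and non-negative")
        if self.season not in SEASONS:
            raise ValidationError(f"season must be one of {SEASONS}, got {self.season!r}")
        self.aridity = self.aridity.reindex(ab.index)
        if self.aridity.isna().any():
            missing = list(self.aridity.index[self.aridity.isna()])
            raise ValidationError(f"sites missing from metadata: {missing}")
        if (self.aridity <= 0).any():
            raise ValidationError("aridity must be positive")

    # -- convenience -------------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def richness(self) -> pd.Series:
        return (self.abundance > 0).sum(axis=1)

    def present_species(self, site: str) -> list[str]:
        row = self.abundance.loc[site]
        return list(row.index[row > 0])

    def species_sampled(self) -> set[str]:
        return set(self.abundance.columns[(self.abundance > 0).any(axis=0)])

    def restrict_species(self, species: list[str]) -> "CommunityTable":
        keep = [s for s in self.abundance.columns if s in set(species)]
        return CommunityTable(self.abundance[keep].copy(), self.aridity.copy(),
                              self.season, self.year)


@dataclass
class TraitTable:
    """Species x trait values; quantitative and categorical blocks.

    Missing values are NaN (quantitative) or NaN/None (categorical).
    """

    quantitative: pd.DataFrame
    categorical: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.quantitative) and len(self.categorical):
            if not self.quantitative.index.equals(self.categorical.index):
                raise ValidationError("quantitative and categorical blocks disagree on species")
        for block in (self.quantitative, self.categorical):
            if block.index.duplicated().any():
                raise ValidationError("duplicate species labels in trait table")

    @property
    def species_ids(self) -> list[str]:
        base = self.quantitative if len(self.quantitative.columns) else self.categorical
        return list(base.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.quantitative.columns) + list(self.categorical.columns)

    def coverage(self) -> pd.Series:
        """Fraction of species with a non-missing value, per trait."""
        parts = []
        if len(self.quantitative.columns):
            parts.append(self.quantitative.notna().mean(axis=0))
        if len(self.categorical.columns):
            parts.append(self.categorical.notna().mean(axis=0))
        return pd.concat(parts) if parts else pd.Series(dtype=float)

    def restrict_species(self, species: list[str]) -> "TraitTable":
        idx = [s for s in self.species_ids if s in set(species)]
        return TraitTable(self.quantitative.loc[idx].copy(),
                          self.categorical.loc[idx].copy()
                          if len(self.categorical.columns) else
                          self.categorical.reindex(idx))


@dataclass(frozen=True)
class CladeAssignment:
    """Where an unsampled species may be grafted: the MRCA of ``anchor``
    defines the admissible clade (a single anchor tip means attachment on
    that terminal branch)."""

    species_id: str
    anchor: frozenset

    def __post_init__(self) -> None:
        if len(self.anchor) < 1:
            raise ValidationError("anchor must contain at least one tip label")


@dataclass
class AnalysisConfig:
    """Run configuration with the study defaults."""

    n_null: int = 100
    n_trees: int = 1000
    n_perm_mantel: int = 999
    trait_coverage_threshold: float = 0.80
    keep_x: int = 5
    alpha_family: float = 0.05
    n_tests_family: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_null", "n_trees", "n_perm_mantel", "keep_x"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0.0 < self.trait_coverage_threshold <= 1.0:
            raise ValidationError("trait_coverage_threshold must be in (0, 1]")
        if not 0.0 < self.alpha_family <= 1.0:
            raise ValidationError("alpha_family must be in (0, 1]")

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)


class DistanceMatrix:
    """Symmetric species-pairwise dissimilarity with labels.

    Carries a lazily computed flag for Euclidean embeddability (all
    eigenvalues of the double-centred Gram matrix >= -1e-8 relative).
    """

    def __init__(self, ids, values, check: bool = True):
        self.ids = list(ids)
        self.values = np.asarray(values, dtype=float)
        if check:
            n = len(self.ids)
            if self.values.shape != (n, n):
                raise ValidationError("distance matrix shape does not match labels")
            if len(set(self.ids)) != n:
                raise ValidationError("duplicate labels in distance matrix")
            if not np.allclose(self.values, self.values.T, atol=1e-10):
                raise ValidationError("distance matrix is not symmetric")
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
                raise ValidationError("distance matrix diagonal is not zero")
            if np.any(self.values < -1e-12):
                raise ValidationError("negative distances")
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, labels) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.ids)}
        try:
            return np.array([pos[lab] for lab in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"label not in distance matrix: {exc.args[0]!r}") from None

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = self.index_of(labels)
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], check=False)

    def permuted(self, mapping: dict) -> "DistanceMatrix":
        """Relabel entries according to ``mapping`` (old label -> new label);
        labels absent from the mapping keep their name.  The multiset of
        pairwise distances is untouched."""
        new_ids = [mapping.get(lab, lab) for lab in self.ids]
        if len(set(new_ids)) != len(new_ids):
            raise ValidationError("label permutation is not a bijection")
        out = DistanceMatrix(new_ids, self.values, check=False)
        return out.submatrix(self.ids) if set(new_ids) == set(self.ids) else out

    def is_euclidean(self, tol: float = 1e-8) -> bool:
        d2 = self.values ** 2
        n = len(self.ids)
        j = np.eye(n) - np.full((n, n), 1.0 / n)
        gram = -0.5 * j @ d2 @ j
        eigvals = np.linalg.eigvalsh(gram)
        scale = max(abs(eigvals).max(), 1.0)
        return bool(eigvals.min() >= -tol * scale)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            df = df.loc[df.index, df.index]
        return cls(list(df.index), df.to_numpy(dtype=float))

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


@dataclass
class SesResult:
    """Observed metric against a randomization null."""

    observed: float
    null_values: np.ndarray
    avg_exp: float
    sd_exp: float
    ses: float
    p_rank: float
    degenerate: bool = False
    n_excluded: int = 0


@dataclass
class BetaPartition:
    """Sorensen-family dissimilarity split into turnover and nestedness."""

    beta_sor: float
    beta_sim: float
    beta_sne: float
    kind: str = "taxonomic"

    def __post_init__(self) -> None:
        if self.kind not in ("taxonomic", "phylogenetic", "functional"):
            raise ValidationError(f"unknown beta kind {self.kind!r}")

    def as_tuple(self):
        return (self.beta_sor, self.beta_sim, self.beta_sne)
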