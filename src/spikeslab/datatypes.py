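"""Core data containers for genotype, expression and phenotype data.

Genotypes are fully inbred recombinant-inbred-line (RIL) codes, so every
entry is exactly 0 or 1 (the two parental alleles; no heterozygotes).
Containers are thin wrappers over pandas objects that validate their
invariants on construction and keep id bookkeeping in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "PhenotypeVector",
    "TruthRecord",
]


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions with adjacent-marker recombination fractions.

    ``chromosomes`` maps chromosome id to ``(marker_ids, rec_fractions)``
    where ``rec_fractions[i]`` is the meiotic recombination fraction between
    marker ``i`` and marker ``i + 1`` (so it has one fewer entry than
    ``marker_ids``). Fractions live in [0, 0.5].
    """

    chromosomes: dict[str, tuple[list[str], np.ndarray]]

    def __post_init__(self):
        seen: set[str] = set()
        validated: dict[str, tuple[list[str], np.ndarray]] = {}
        for chrom, (markers, r) in self.chromosomes.items():
            r = np.asarray(r, dtype=float)
            if len(r) != max(len(markers) - 1, 0):
                raise ValueError(
                    f"chromosome {chrom!r}: {len(markers)} markers need "
                    f"{len(markers) - 1} recombination fractions, got {len(r)}"
                )
            if not np.all(np.isfinite(r)) or np.any(r < 0) or np.any(r > 0.5):
                raise ValueError(
                    f"chromosome {chrom!r}: recombination fractions must be finite and in [0, 0.5]"
                )
            dup = seen.intersection(markers)
            if dup or len(set(markers)) != len(markers):
                raise ValueError(f"duplicate marker ids in map: {sorted(dup) or 'within chromosome'}")
            seen.update(markers)
            validated[chrom] = (list(markers), r)
        object.__setattr__(self, "chromosomes", validated)

    @property
    def marker_ids(self) -> list[str]:
        out: list[str] = []
        for markers, _ in self.chromosomes.values():
            out.extend(markers)
        return out

    @property
    def n_markers(self) -> int:
        return sum(len(m) for m, _ in self.chromosomes.values())


@dataclass
class GenotypeMatrix:
    """Lines x markers binary genotype codes with optional map metadata."""

    values: pd.DataFrame  # index = line ids, columns = marker ids
    map: GeneticMap | None = None

    def __post_init__(self):
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValueError(
                f"genotype codes must be 0 or 1; offending entry at line "
                f"{self.values.index[bad[0]]!r}, marker {self.values.columns[bad[1]]!r}"
            )
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicated line or marker ids in genotype matrix")
        if self.map is not None:
            missing = set(self.values.columns) - set(self.map.marker_ids)
            if missing:
                raise ValueError(f"markers absent from map: {sorted(missing)[:5]}")
        self.values = self.values.astype(np.int8)

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExpressionMatrix:
    """Lines x genes transcript abundances, optionally with cis-link metadata.

    ``gene_info`` (optional) has one row per gene; a ``linked_marker``
    column records which marker drives a cis gene (NaN for trans/noise genes).
    """

    values: pd.DataFrame  # index = line ids, columns = gene ids
    gene_info: pd.DataFrame | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicated line or gene ids in expression matrix")
        if self.gene_info is not None and not self.gene_info.index.equals(self.values.columns):
            self.gene_info = self.gene_info.reindex(self.values.columns)

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PhenotypeVector:
    """One continuous phenotype value per line."""

    values: pd.Series  # index = line ids
    name: str = "phenotype"

    def __post_init__(self):
        self.values = pd.Series(self.values, dtype=float)
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("phenotype contains non-finite values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicated line ids in phenotype")
        if self.name is None:
            self.name = self.values.name or "phenotype"
        self.values.name = self.name

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated phenotype, for recovery tests."""

    intercept: float
    marker_effects: dict[str, float] = field(default_factory=dict)
    gene_effects: dict[str, float] = field(default_factory=dict)
    residual_variance: float = 1.0
    heritability: float = 0.0

    def __post_init__(self):
        if self.residual_variance <= 0:
            raise ValueError("residual variance must be positive")
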