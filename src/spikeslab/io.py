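"""Delimited-text readers and writers for all pipeline artifacts.

Matrices are stored as TSV/CSV with lines as rows: a header row of marker
or gene ids and a first column of line ids. Phenotypes are two-or-more
column tables (line id + one column per phenotype). The format is chosen
by file extension (``.csv`` -> comma, anything else -> tab).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneticMap,
    GenotypeMatrix,
    PhenotypeVector,
    TruthRecord,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_phenotype",
    "write_genetic_map",
    "read_genetic_map",
    "write_truth",
    "read_truth",
]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=_sep(path), index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicated line id {dup!r} in {path}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"duplicated column id {dup!r} in {path}")
    return frame


def read_matrix(path, kind: str, map: GeneticMap | None = None):
    """Read a typed matrix; ``kind`` is genotype, expression or phenotype.

    Genotype entries must be exactly 0 or 1 (errors name the offending
    cell); expression and phenotype entries must be finite numbers.
    """
    if kind == "genotype":
        frame = _read_frame(path)
        arr = frame.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary genotype code {arr[i, j]!r} at line {frame.index[i]!r}, "
                f"marker {frame.columns[j]!r} in {path}"
            )
        return GenotypeMatrix(frame, map=map)
    if kind == "expression":
        return ExpressionMatrix(_read_frame(path))
    if kind == "phenotype":
        return _read_frame(path)
    raise ValueError(f"unknown matrix kind {kind!r}")


def read_phenotype(path, name: str | None = None) -> PhenotypeVector:
    """Read one phenotype column (the first, unless ``name`` is given)."""
    frame = read_matrix(path, "phenotype")
    if name is None:
        name = frame.columns[0]
    if name not in frame.columns:
        raise ValueError(f"phenotype {name!r} not in {path} (has {list(frame.columns)})")
    return PhenotypeVector(frame[name], name=name)


def write_matrix(obj, path) -> None:
    data = getattr(obj, "values", obj)
    frame = data.to_frame() if isinstance(data, pd.Series) else pd.DataFrame(data)
    frame.to_csv(path, sep=_sep(path))


def write_genetic_map(map: GeneticMap, path) -> None:
    """Persist a map as TSV: chromosome, marker, r_to_next (blank on last)."""
    rows = []
    for chrom, (markers, r) in map.chromosomes.items():
        for i, m in enumerate(markers):
            rows.append((chrom, m, r[i] if i < len(r) else np.nan))
    pd.DataFrame(rows, columns=["chromosome", "marker", "r_to_next"]).to_csv(
        path, sep=_sep(path), index=False
    )


def read_genetic_map(path) -> GeneticMap:
    frame = pd.read_csv(path, sep=_sep(path))
    chroms: dict[str, tuple[list[str], np.ndarray]] = {}
    for chrom, sub in frame.groupby("chromosome", sort=False):
        markers = [str(m) for m in sub["marker"]]
        r = sub["r_to_next"].to_numpy(dtype=float)[:-1]
        chroms[str(chrom)] = (markers, r)
    return GeneticMap(chroms)


def write_truth(truth: TruthRecord, path) -> None:
    """Key-value text dump of the simulation ground truth."""
    with open(path, "w") as fh:
        fh.write(f"intercept\t{truth.intercept!r}\n")
        fh.write(f"residual_variance\t{truth.residual_variance!r}\n")
        fh.write(f"heritability\t{truth.heritability!r}\n")
        for mid, b in truth.marker_effects.items():
            fh.write(f"marker_effect\t{mid}\t{b!r}\n")
        for gid, b in truth.gene_effects.items():
            fh.write(f"gene_effect\t{gid}\t{b!r}\n")


def read_truth(path) -> TruthRecord:
    kw = dict(intercept=0.0, residual_variance=1.0, heritability=0.0)
    marker_effects: dict[str, float] = {}
    gene_effects: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split("\t")
        if parts[0] in kw:
            kw[parts[0]] = float(parts[1])
        elif parts[0] == "marker_effect":
            marker_effects[parts[1]] = float(parts[2])
        elif parts[0] == "gene_effect":
            gene_effects[parts[1]] = float(parts[2])
    return TruthRecord(marker_effects=marker_effects, gene_effects=gene_effects, **kw)
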