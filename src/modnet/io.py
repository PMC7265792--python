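"""Readers and writers for the plain-text formats the pipeline touches.

TSV (UTF-8, header row) for matrices and phenotype tables, GMT for gene-set
collections, YAML/JSON for phenotype schemas.  All readers validate on entry
and raise :class:`~modnet.types.FormatError` /
:class:`~modnet.types.ValidationError` with the offending row or column named.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_expression_table(path: PathLike, orientation: str = "genes_by_rows") -> ExpressionMatrix:
    """Read a TSV expression table into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    path
        TSV file with a header row; first column holds gene ids (or sample
        ids when ``orientation="samples_by_rows"``).
    orientation
        ``"genes_by_rows"`` (default) or ``"samples_by_rows"`` (transposed).

    Duplicate gene ids are collapsed by their mean with a logged warning;
    ``NA``/empty cells become explicit missing values.
    """
    path = Path(path)
    if orientation not in ("genes_by_rows", "samples_by_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if raw.shape[1] == 0:
        raise FormatError(f"{path}: header row has no sample columns")
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & ~raw[col].str.strip().isin(["NA", "NaN", "nan", ""])
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        numeric[col] = converted
    if orientation == "samples_by_rows":
        numeric = numeric.T
    if numeric.index.duplicated().any():
        dups = sorted(set(numeric.index[numeric.index.duplicated()]))
        logger.warning("%s: collapsing duplicate gene ids by mean: %s", path, dups)
        order = list(dict.fromkeys(numeric.index))
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(numeric)


def write_expression_table(matrix: ExpressionMatrix, path: PathLike) -> None:
    matrix.data.to_csv(Path(path), sep="\t", index_label="gene")


def read_gene_sets(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Genes repeated within one set are deduplicated (first occurrence kept).
    """
    path = Path(path)
    sets: Dict[str, tuple] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = (description, list(dict.fromkeys(genes)))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: PathLike) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc, genes = collection.sets[name]
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_driver_list(path: PathLike) -> List[str]:
    """One-gene-per-line driver list (blank lines and '#' comments skipped)."""
    genes: List[str] = []
    with open(Path(path), encoding="utf-8") as fh:
        for line in fh:
            gene = line.strip()
            if gene and not gene.startswith("#"):
                genes.append(gene)
    return list(dict.fromkeys(genes))


def _load_schema(schema: Union[PathLike, Mapping[str, str]]) -> Dict[str, str]:
    if isinstance(schema, Mapping):
        return dict(schema)
    path = Path(schema)
    with open(path, encoding="utf-8") as fh:
        loaded = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if isinstance(loaded, list):  # list of {column, type} records
        return {entry["column"]: entry["type"] for entry in loaded}
    if isinstance(loaded, dict):
        return {str(k): str(v) for k, v in loaded.items()}
    raise FormatError(f"{path}: cannot interpret phenotype schema")


def read_phenotype_table(
    path: PathLike, schema: Union[PathLike, Mapping[str, str]]
) -> PhenotypeTable:
    """Read a TSV phenotype table (first column = sample id) with a declared
    per-column statistical type."""
    path = Path(path)
    schema_map = _load_schema(schema)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    return PhenotypeTable(data=table, schema=schema_map)


def write_phenotype_table(table: PhenotypeTable, path: PathLike) -> None:
    table.data.to_csv(Path(path), sep="\t", index_label="sample")


def write_phenotype_schema(table: PhenotypeTable, path: PathLike) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(table.schema, fh, indent=1)
        fh.write("\n")


def filter_most_varying_genes(matrix: ExpressionMatrix, percent: float) -> ExpressionMatrix:
    """Keep the ``ceil(percent * n_genes)`` genes of largest sample variance.

    Zero-variance genes are dropped before ranking (logged).  Ties at the
    cutoff variance are all kept, so slightly more genes than the nominal
    fraction may survive.  Original gene order is preserved.
    """
    if not 0.0 < percent <= 1.0:
        raise ValueError(f"percent must be in (0, 1], got {percent}")
    if matrix.n_samples < 2:
        raise ValidationError("variance filter requires >=2 samples")
    variances = matrix.data.var(axis=1, ddof=1)
    nonconstant = variances > 0.0
    if (~nonconstant).any():
        dropped = list(matrix.data.index[~nonconstant])
        logger.warning("dropping %d zero-variance genes before ranking: %s",
                       len(dropped), dropped[:10])
    variances = variances[nonconstant]
    n_keep = math.ceil(percent * len(variances))
    if n_keep == 0:
        raise ValidationError("no genes survive the variance filter")
    cutoff = np.sort(variances.to_numpy())[::-1][n_keep - 1]
    keep = variances[variances >= cutoff].index
    return matrix.subset_genes([g for g in matrix.gene_ids if g in set(keep)])


def impute_missing(matrix: ExpressionMatrix, max_missing_frac: float = 0.2) -> ExpressionMatrix:
    """Drop genes with more than ``max_missing_frac`` missing samples, then
    mean-impute the remaining missing values per gene (logged)."""
    frac_missing = matrix.data.isna().mean(axis=1)
    keep = frac_missing <= max_missing_frac
    if (~keep).any():
        logger.warning("dropping %d genes with >%d%% missing values",
                       int((~keep).sum()), int(100 * max_missing_frac))
    data = matrix.data.loc[keep]
    if data.isna().any().any():
        n = int(data.isna().sum().sum())
        logger.warning("mean-imputing %d missing expression values", n)
        data = data.apply(lambda row: row.fillna(row.mean()), axis=1)
    return ExpressionMatrix(data)
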