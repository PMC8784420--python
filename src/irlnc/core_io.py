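"""Readers, writers and validated containers for every external format.

Formats
-------
Expression matrices are TSV with genes in rows (first column = gene id) and
samples in columns (header row = sample ids). Gene sets are GMT
(name, description, genes; tab-separated). Tumor purity, tumor/normal labels,
gene biotypes and cell labels are two-column TSVs with a header. All writers
emit TSV with a header and a deterministic (sorted) row order so identical
runs produce byte-identical files.

Gene identifiers are case-sensitive; Ensembl-style version suffixes
(``ENSG00000123456.7`` -> ``ENSG00000123456``) are stripped before matching
against the biotype map and gene sets, because annotation files carry
versioned ids while pathway resources use unversioned symbols.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptySplitError, FormatError

logger = logging.getLogger(__name__)

_ENSEMBL_VERSION = re.compile(r"^(ENS[A-Z]*[GTP]\d{6,})\.\d+$")

VALID_BIOTYPES = ("mRNA", "lncRNA", "other")
VALID_GROUPS = ("tumor", "normal")

#: GENCODE gene_type values folded into the three working biotypes.
_GTF_MRNA_TYPES = {"protein_coding"}
_GTF_LNCRNA_TYPES = {
    "lncRNA",
    "lincRNA",
    "antisense",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncRNA",
    "3prime_overlapping_ncrna",
    "macro_lncRNA",
    "bidirectional_promoter_lncRNA",
}


def strip_version(gene_id: str) -> str:
    """Drop a trailing ``.N`` version from an Ensembl-style identifier.

    Non-Ensembl identifiers (gene symbols, synthetic ids) pass through
    unchanged, so a symbol like ``NKX2.1`` is not mangled.
    """
    m = _ENSEMBL_VERSION.match(gene_id)
    return m.group(1) if m else gene_id


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative expression values.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns. Values must
        be finite, numeric and >= 0; gene and sample ids must be unique.
    cancer_label
        Cancer type the matrix belongs to (free text, may be empty).
    """

    data: pd.DataFrame
    cancer_label: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise FormatError("expression matrix is empty")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            raise FormatError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise FormatError("expression matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        if not keep:
            raise FormatError("gene subset is empty")
        return ExpressionMatrix(self.data.loc[keep], self.cancer_label)


def read_expression(path: str | Path, cancer_label: str = "") -> ExpressionMatrix:
    """Read a genes-by-samples TSV into a validated :class:`ExpressionMatrix`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: non-numeric value in column {col!r}")
    try:
        return ExpressionMatrix(df, cancer_label)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def split_by_biotype(
    expr: ExpressionMatrix, biotype_map: Mapping[str, str]
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Partition a matrix into (mRNA, lncRNA) sub-matrices.

    Genes absent from the map (after version stripping) are dropped with a
    logged count; genes mapped to ``other`` are dropped silently as mapped
    non-targets. Raises :class:`EmptySplitError` if either side is empty.
    """
    mrna_rows: list[str] = []
    lnc_rows: list[str] = []
    n_unmapped = 0
    for gene in expr.gene_ids:
        biotype = biotype_map.get(gene, biotype_map.get(strip_version(gene)))
        if biotype is None:
            n_unmapped += 1
        elif biotype == "mRNA":
            mrna_rows.append(gene)
        elif biotype == "lncRNA":
            lnc_rows.append(gene)
    if n_unmapped:
        logger.warning(
            "split_by_biotype: dropped %d/%d genes absent from the biotype map",
            n_unmapped,
            expr.n_genes,
        )
    if not mrna_rows or not lnc_rows:
        raise EmptySplitError(
            f"biotype split produced {len(mrna_rows)} mRNAs and "
            f"{len(lnc_rows)} lncRNAs; both must be non-empty"
        )
    return (
        ExpressionMatrix(expr.data.loc[mrna_rows], expr.cancer_label),
        ExpressionMatrix(expr.data.loc[lnc_rows], expr.cancer_label),
    )


def read_biotype_map(path: str | Path) -> dict[str, str]:
    """Read a gene -> biotype map from a 2-column TSV or a GTF.

    The TSV dialect (header ``gene_id<TAB>biotype``; biotype one of mRNA,
    lncRNA, other) is canonical. A path ending in ``.gtf`` is parsed for
    ``gene`` features, folding GENCODE ``gene_type`` values into the three
    working biotypes. Version suffixes are stripped from the stored keys.
    """
    path = Path(path)
    if path.suffix.lower() == ".gtf":
        return _biotype_map_from_gtf(path)
    mapping: dict[str, str] = {}
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty biotype map")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        gene, biotype = parts
        gene = strip_version(gene)
        if biotype not in VALID_BIOTYPES:
            raise FormatError(f"{path}:{lineno}: unknown biotype {biotype!r}")
        if gene in mapping and mapping[gene] != biotype:
            raise FormatError(f"{path}:{lineno}: conflicting biotype for {gene!r}")
        mapping[gene] = biotype
    return mapping


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')
_GTF_GENE_TYPE = re.compile(r'gene_type "([^"]+)"')


def _biotype_map_from_gtf(path: Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 GTF fields")
            if fields[2] != "gene":
                continue
            gid = _GTF_GENE_ID.search(fields[8])
            gtype = _GTF_GENE_TYPE.search(fields[8])
            if gid is None or gtype is None:
                raise FormatError(
                    f"{path}:{lineno}: gene feature missing gene_id/gene_type"
                )
            if gtype.group(1) in _GTF_MRNA_TYPES:
                biotype = "mRNA"
            elif gtype.group(1) in _GTF_LNCRNA_TYPES:
                biotype = "lncRNA"
            else:
                biotype = "other"
            mapping[strip_version(gid.group(1))] = biotype
    if not mapping:
        raise FormatError(f"{path}: no gene features found")
    return mapping


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file into ``{pathway_name: frozenset(gene_ids)}``."""
    path = Path(path)
    collection: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
            )
        name = parts[0]
        genes = frozenset(strip_version(g) for g in parts[2:] if g.strip())
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        if name in collection:
            raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        collection[name] = genes
    return collection


def _read_two_column(path: Path, what: str) -> list[tuple[str, str]]:
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty {what} file")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        rows.append((parts[0], parts[1]))
    if not rows:
        raise FormatError(f"{path}: no data rows in {what} file")
    return rows


def read_purity(path: str | Path) -> pd.Series:
    """Read a sample -> tumor purity table; values must lie in [0, 1]."""
    path = Path(path)
    rows = _read_two_column(path, "purity")
    samples, values = [], []
    for lineno, (sample, raw) in enumerate(rows, start=2):
        try:
            value = float(raw)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric purity {raw!r}") from exc
        if not np.isfinite(value) or not 0.0 <= value <= 1.0:
            raise FormatError(f"{path}:{lineno}: purity {value} outside [0, 1]")
        samples.append(sample)
        values.append(value)
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample id in purity table")
    return pd.Series(values, index=pd.Index(samples, name="sample_id"), name="purity")


def read_labels(path: str | Path) -> pd.Series:
    """Read a sample -> group (tumor | normal) table."""
    path = Path(path)
    rows = _read_two_column(path, "labels")
    samples, groups = [], []
    for lineno, (sample, group) in enumerate(rows, start=2):
        if group not in VALID_GROUPS:
            raise FormatError(f"{path}:{lineno}: unknown group {group!r}")
        samples.append(sample)
        groups.append(group)
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample id in label table")
    return pd.Series(groups, index=pd.Index(samples, name="sample_id"), name="group")


def read_cell_labels(path: str | Path) -> pd.Series:
    """Read a cell -> group (immune | non-immune) table."""
    path = Path(path)
    rows = _read_two_column(path, "cell labels")
    cells, groups = [], []
    for lineno, (cell, group) in enumerate(rows, start=2):
        if group not in ("immune", "non-immune"):
            raise FormatError(f"{path}:{lineno}: unknown cell group {group!r}")
        cells.append(cell)
        groups.append(group)
    if len(set(cells)) != len(cells):
        raise FormatError(f"{path}: duplicate cell id in cell label table")
    return pd.Series(groups, index=pd.Index(cells, name="cell_id"), name="group")


def read_infiltration(path: str | Path) -> pd.DataFrame:
    """Read a sample x cell-type immune infiltration table (TSV, numeric)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty infiltration file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: infiltration table has no data")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate sample id in infiltration table")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or not np.isfinite(values).all():
        raise FormatError(f"{path}: infiltration values must be finite numbers")
    df.index = df.index.astype(str)
    return df


def check_labels_in_matrix(labels: pd.Series, expr: ExpressionMatrix) -> None:
    """Raise if any labeled sample is absent from the matrix."""
    missing = set(labels.index) - set(expr.sample_ids)
    if missing:
        raise FormatError(
            f"labeled samples absent from expression matrix: {sorted(missing)[:5]}"
        )


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular result as TSV with a deterministic row order.

    Rows are sorted on the string-typed (identifier) columns so repeated runs
    of the same pipeline emit byte-identical files regardless of iteration
    order upstream.
    """
    path = Path(path)
    df = records.copy()
    sort_cols = [c for c in df.columns if df[c].dtype == object]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_records`."""
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty records file") from exc
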