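"""Readers and writers for the standard file formats the pipeline touches.

Expression matrices travel as GCT 1.2 (the dialect GTEx uses to distribute
gene-level TPM), gene sets as GMT, single-nucleus counts as Matrix Market
coordinate triplets with cell/gene annotation TSVs, and per-sample
annotations as headered TSVs.  All readers validate strictly and raise
:class:`FormatError` with a locator (line/row/column) rather than coercing
malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "SingleNucleusDataset",
    "AnnotationSchema",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_sample_annotations",
    "read_snrna",
    "write_snrna",
]

#: Ordered age-decade levels used in the donor annotation tables.
AGE_GROUP_LEVELS = ["20-29", "30-39", "40-49", "50-59", "60-69", "70-79"]

#: Strings treated as missing in annotation TSVs (GTEx tables mix both).
MISSING_TOKENS = {"", "NA"}


class FormatError(ValueError):
    """Malformed input file; the message carries a line/row/column locator."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    sample_annotations
        DataFrame indexed by sample id, aligned 1:1 with the columns of
        ``values``; must contain a ``tissue`` column.
    unit
        One of ``"TPM"``, ``"counts"`` or ``"logTPM"``.  Unit transitions
        happen only through documented operations (e.g. log-normalisation).
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame
    unit: str = "TPM"

    _VALID_UNITS = ("TPM", "counts", "logTPM")

    def __post_init__(self) -> None:
        if self.unit not in self._VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {self._VALID_UNITS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.values.columns.equals(self.sample_annotations.index):
            raise ValueError("sample_annotations rows must align 1:1 with sample ids")
        if "tissue" not in self.sample_annotations.columns:
            raise ValueError("sample_annotations must carry a 'tissue' column")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def tissues(self) -> pd.Series:
        return self.sample_annotations["tissue"]

    def subset_tissue(self, tissue: str) -> "ExpressionMatrix":
        mask = self.sample_annotations["tissue"] == tissue
        ids = self.sample_annotations.index[mask]
        return ExpressionMatrix(
            self.values.loc[:, ids], self.sample_annotations.loc[ids], unit=self.unit
        )

    def with_values(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        """Documented unit-transition constructor (filter / normalise steps)."""
        return ExpressionMatrix(values, self.sample_annotations.loc[values.columns], unit=unit)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set metadata (e.g. regulator label)."""

    sets: dict[str, list[str]]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            # dedupe preserving order
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class SingleNucleusDataset:
    """Cell x gene integer counts with per-cell tissue/donor/cell-type labels."""

    counts: scipy.sparse.csr_matrix
    cell_annotations: pd.DataFrame  # index = cell id; tissue, donor, cell_type
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_annotations), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_annotations)} cells x {len(self.gene_ids)} genes"
            )
        data = self.counts.data
        if data.size and (data < 0).any():
            raise ValueError("counts must be non-negative")
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("counts must be integers")
        for col in ("tissue", "cell_type"):
            if col not in self.cell_annotations.columns:
                raise ValueError(f"cell_annotations must carry a {col!r} column")
        if self.cell_annotations["cell_type"].isna().any():
            raise ValueError("every cell must have a cell_type label")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_tissue(self, tissue: str) -> "SingleNucleusDataset":
        mask = (self.cell_annotations["tissue"] == tissue).to_numpy()
        return SingleNucleusDataset(
            self.counts[mask], self.cell_annotations.loc[mask], self.gene_ids
        )


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------


def read_gct(path: str | Path, annotations: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a GCT 1.2 expression file into an :class:`ExpressionMatrix`.

    Only version ``#1.2`` is accepted.  The single Description column is
    ignored on read.  If ``annotations`` is None a minimal annotation table
    with ``tissue='unknown'`` is attached.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: line 1: expected GCT version '#1.2'")
    try:
        n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: line 2: malformed dimensions line") from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name":
        raise FormatError(f"{path}: line 3: header must start with 'Name<TAB>Description'")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: line 3: header lists {len(sample_ids)} samples, dims line declares {n_samples}"
        )
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_genes:
        raise FormatError(
            f"{path}: declared {n_genes} genes but file contains {len(body)} data rows"
        )
    genes: list[str] = []
    data = np.empty((n_genes, n_samples))
    for i, ln in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != n_samples + 2:
            raise FormatError(f"{path}: line {i + 4}: expected {n_samples + 2} fields, got {len(parts)}")
        genes.append(parts[0])
        try:
            data[i] = [float(v) for v in parts[2:]]
        except ValueError:
            raise FormatError(f"{path}: line {i + 4}: non-numeric expression value") from None
    idx = pd.Index(genes, name="gene")
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids: {dups}")
    values = pd.DataFrame(data, index=idx, columns=pd.Index(sample_ids, name="sample"))
    if annotations is None:
        annotations = pd.DataFrame({"tissue": "unknown"}, index=values.columns)
    return ExpressionMatrix(values, annotations.loc[values.columns], unit="TPM")


def write_gct(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an :class:`ExpressionMatrix` as GCT 1.2 (Description regenerated)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, expr.sample_ids)) + "\n")
        for gene, row in zip(expr.gene_ids, expr.values.to_numpy()):
            fh.write(f"{gene}\tna\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, members...)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    metadata: dict[str, dict] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, desc = parts[0], parts[1]
            members = [g for g in parts[2:] if g]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate gene set name {name!r}")
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            sets[name] = members
            if desc not in ("", "na"):
                metadata[name] = {"description": desc}
    return GeneSetCollection(sets, metadata)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, members in collection.sets.items():
            desc = collection.metadata.get(name, {}).get("description", "na")
            fh.write("\t".join([name, str(desc), *members]) + "\n")


# ---------------------------------------------------------------------------
# Sample annotation TSV
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSchema:
    """Declares required columns and their types for annotation tables.

    ``numeric`` columns parse to float (missing preserved as NaN),
    ``categorical`` to pandas category, ``ordered`` to ordered categoricals
    with the given level list.
    """

    numeric: Sequence[str] = ()
    categorical: Sequence[str] = ()
    ordered: Mapping[str, Sequence[str]] = field(default_factory=dict)
    required: Sequence[str] = ()


#: Default schema for the donor/sample covariates used by the first model set.
GTEX_PUBLIC_SCHEMA = AnnotationSchema(
    numeric=("SMRIN", "SMATSSCR", "SMTSISCH"),
    categorical=("SEX", "DTHHRDY"),
    ordered={"AGE_GROUP": AGE_GROUP_LEVELS},
    required=("tissue", "SMRIN", "SMATSSCR", "SMTSISCH", "AGE_GROUP", "SEX", "DTHHRDY"),
)


def read_sample_annotations(path: str | Path, schema: AnnotationSchema) -> pd.DataFrame:
    """Read a headered TSV of per-sample annotations, typed per ``schema``.

    Empty strings and ``NA`` both map to missing; missing numeric values
    stay NaN, never zero.
    """
    path = Path(path)
    # dash variants: GTEx writes age decades both as "50-59" and "50–59"
    table = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, index_col=0
    )
    for col in schema.required:
        if col not in table.columns:
            raise FormatError(f"{path}: required column {col!r} absent")
    out = pd.DataFrame(index=table.index)
    for col in table.columns:
        raw = table[col].str.strip()
        raw = raw.where(~raw.isin(MISSING_TOKENS), other=pd.NA)
        if col in schema.numeric:
            try:
                out[col] = pd.to_numeric(raw)
            except (ValueError, TypeError):
                bad = raw.dropna()[pd.to_numeric(raw.dropna(), errors="coerce").isna()]
                rowno = table.index.get_loc(bad.index[0]) + 2  # +1 header, +1 1-based
                raise FormatError(
                    f"{path}: row {rowno}: non-parsable numeric value {bad.iloc[0]!r} in column {col!r}"
                ) from None
        elif col in schema.ordered:
            levels = list(schema.ordered[col])
            norm = raw.str.replace("–", "-", regex=False)
            bad = norm.dropna()[~norm.dropna().isin(levels)]
            if len(bad):
                rowno = table.index.get_loc(bad.index[0]) + 2
                raise FormatError(
                    f"{path}: row {rowno}: value {bad.iloc[0]!r} not an allowed level of {col!r}"
                )
            out[col] = pd.Categorical(norm, categories=levels, ordered=True)
        else:
            out[col] = pd.Categorical(raw)
    return out


# ---------------------------------------------------------------------------
# Single-nucleus counts (Matrix Market triplets + annotation TSVs)
# ---------------------------------------------------------------------------


def read_snrna(
    matrix_path: str | Path, cells_path: str | Path, genes_path: str | Path
) -> SingleNucleusDataset:
    """Read cell x gene counts (MTX coordinate) plus cell/gene annotations."""
    matrix_path = Path(matrix_path)
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"{matrix_path}: not a readable Matrix Market file: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    if mat.data.size and ((mat.data < 0).any() or not np.allclose(mat.data, np.round(mat.data))):
        raise FormatError(f"{matrix_path}: entries must be non-negative integers")
    cells = pd.read_csv(cells_path, sep="\t", index_col=0, dtype=str)
    genes = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)[0]
    if len(cells) != mat.shape[0]:
        raise FormatError(
            f"{cells_path}: {len(cells)} cell annotations for a matrix with {mat.shape[0]} rows"
        )
    if len(genes) != mat.shape[1]:
        raise FormatError(
            f"{genes_path}: {len(genes)} gene ids for a matrix with {mat.shape[1]} columns"
        )
    return SingleNucleusDataset(mat.tocsr(), cells, pd.Index(genes, name="gene"))


def write_snrna(
    data: SingleNucleusDataset,
    matrix_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(data.counts), field="integer")
    data.cell_annotations.to_csv(cells_path, sep="\t")
    pd.Series(data.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
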