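"""Readers and writers for the plain-text formats the pipeline consumes.

Count matrices travel as Matrix Market coordinate files (1-based indices on
disk, 0-based in memory) accompanied by one-column gene and cell label files.
Gene sets use the tab-delimited GMT convention; cell annotations are ordinary
delimited tables with a header row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "CellAnnotation",
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_annotation",
    "write_annotation",
]


class FormatError(ValueError):
    """A file violates the format contract (dimensions, field counts, types)."""


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of nonnegative integer counts.

    ``values`` is CSR with genes as rows. Identifiers are unique and ordered
    exactly as on disk; no reader or writer reorders them.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for a matrix with {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for a matrix with {n_cells} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("cell ids are not unique")
        data = self.values.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise FormatError("count matrix entries must be nonnegative integers")
        self.values.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None

    def subset(self, gene_idx=None, cell_idx=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given positional indices."""
        g = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        c = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        return CountMatrix(
            self.values[g][:, c],
            [self.gene_ids[i] for i in g],
            [self.cell_ids[i] for i in c],
        )


@dataclass
class GeneSetCollection:
    """Named, ordered, duplicate-free gene lists (GMT-representable)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicates")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, genes: list[str], description: str = "") -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            logger.warning("gene set %r: dropped duplicated genes", name)
        if not deduped:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = (description, deduped)


@dataclass
class CellAnnotation:
    """Per-cell metadata: level-1 cell type, condition, donor and study."""

    table: pd.DataFrame

    REQUIRED = ("cell_id", "cell_type_level1", "condition", "donor_id", "study_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation table lacks columns {missing}")
        if self.table["cell_id"].duplicated().any():
            raise FormatError("annotation table has duplicated cell ids")
        self.table = self.table.reset_index(drop=True)

    def aligned_to(self, cell_ids: list[str]) -> "CellAnnotation":
        """Reindex rows to the order of ``cell_ids``; every id must be present."""
        indexed = self.table.set_index("cell_id")
        missing = [c for c in cell_ids if c not in indexed.index]
        if missing:
            raise FormatError(
                f"{len(missing)} cells lack annotation (first: {missing[0]!r})"
            )
        return CellAnnotation(indexed.loc[cell_ids].reset_index())

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Matrix Market + label files


def _read_labels(path: str | Path) -> list[str]:
    labels = [line.rstrip("\n") for line in Path(path).read_text().splitlines()]
    return [l for l in labels if l != ""]


def read_count_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> CountMatrix:
    """Read a Matrix Market coordinate file plus one-column label files.

    Indices are 1-based on disk and 0-based in the returned object. A label
    file whose row count disagrees with the matrix dimensions raises
    :class:`FormatError` naming the offending file.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"{matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise FormatError(f"{matrix_path}: non-integer entries in count matrix")
    genes = _read_labels(genes_path)
    cells = _read_labels(cells_path)
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{genes_path}: {len(genes)} rows but matrix declares {mat.shape[0]} genes"
        )
    if len(cells) != mat.shape[1]:
        raise FormatError(
            f"{cells_path}: {len(cells)} rows but matrix declares {mat.shape[1]} cells"
        )
    return CountMatrix(mat.tocsr(), genes, cells)


def write_count_matrix(
    counts: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    """Write the Matrix Market file (1-based, integer field) and label files."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scipy.io.mmwrite(str(matrix_path), counts.values.tocoo(), field="integer")
    Path(genes_path).write_text("".join(g + "\n" for g in counts.gene_ids))
    Path(cells_path).write_text("".join(c + "\n" for c in counts.cell_ids))


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are dropped (order preserved) with a logged
    warning; a line with fewer than three fields is a parse error. An empty
    file yields an empty collection.
    """
    collection = GeneSetCollection()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if raw.strip() == "":
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno} has {len(fields)} fields, expected >=3"
            )
        name, description, genes = fields[0], fields[1], fields[2:]
        genes = [g for g in genes if g != ""]
        collection.add(name, genes, description)
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, desc] + genes)
        for name, (desc, genes) in collection.sets.items()
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# Annotation tables


def read_annotation(path: str | Path, sep: str | None = None) -> CellAnnotation:
    """Read a delimited annotation table with a header row.

    The separator is sniffed from the extension (.csv -> comma, else tab)
    unless given explicitly.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str)
    return CellAnnotation(table)


def write_annotation(annot: CellAnnotation, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    annot.table.to_csv(path, sep=sep, index=False)
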