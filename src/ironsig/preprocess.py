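"""Cell QC filtering and log-normalization.

Inclusion rules follow the strict-inequality reading of the protocol: a cell
is kept iff its mitochondrial fraction is strictly below ``max_mito_fraction``
and its total molecule count is strictly above ``min_molecules``. Ribosomal
genes (symbol prefix) are dropped from the matrix.

Normalization is plain library-size log-normalization,
``ln(count * scale / cell_total + 1)``: a monotone transform with per-cell
size-factor invariance, which is all the downstream rank-based differential
expression and signature scoring require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCParams",
    "QCMetrics",
    "FilterReport",
    "NormalizedMatrix",
    "compute_qc_metrics",
    "apply_qc_filter",
    "lognormalize",
]


@dataclass
class QCParams:
    max_mito_fraction: float = 0.20
    min_molecules: int = 1000
    mito_prefix: str = "mt-"
    ribo_prefixes: tuple[str, ...] = ("Rps", "Rpl")
    drop_ribosomal: bool = True
    # "molecules detected" read as total UMI-like counts; "genes" counts
    # distinct detected genes instead.
    molecule_definition: str = "total"  # "total" | "genes"

    def __post_init__(self) -> None:
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")
        if self.min_molecules < 0:
            raise ValueError("min_molecules must be nonnegative")
        if not self.mito_prefix or any(not p for p in self.ribo_prefixes):
            raise ValueError("gene-symbol prefixes must be non-empty")
        if self.molecule_definition not in ("total", "genes"):
            raise ValueError("molecule_definition must be 'total' or 'genes'")


@dataclass
class QCMetrics:
    """Per-cell QC metrics, aligned to the matrix column order."""

    mito_fraction: np.ndarray
    total_molecules: np.ndarray
    zero_total: np.ndarray  # degenerate cells flagged, fraction reported as 0
    cell_ids: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "mito_fraction": self.mito_fraction,
                "total_molecules": self.total_molecules,
                "zero_total": self.zero_total,
            }
        )


@dataclass
class FilterReport:
    n_cells_before: int
    n_cells_after: int
    n_removed_mito: int
    n_removed_molecules: int
    n_genes_before: int
    n_genes_after: int
    n_ribo_genes_removed: int
    params: QCParams = field(repr=False, default=None)

    @property
    def n_cells_removed(self) -> int:
        return self.n_cells_before - self.n_cells_after

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "params"}
        d["n_cells_removed"] = self.n_cells_removed
        return d


@dataclass
class NormalizedMatrix:
    """Dense genes x cells matrix of log-normalized expression."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    size_factors: np.ndarray
    scale: float

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present") from None
        return self.values[i]


def _prefix_mask(gene_ids: list[str], prefixes) -> np.ndarray:
    if isinstance(prefixes, str):
        prefixes = (prefixes,)
    return np.array([any(g.startswith(p) for p in prefixes) for g in gene_ids])


def compute_qc_metrics(counts: CountMatrix, params: QCParams | None = None) -> QCMetrics:
    """Per-cell mitochondrial fraction and molecule totals.

    Cells with zero total counts get ``mito_fraction = 0`` and are flagged.
    """
    params = params or QCParams()
    mito = _prefix_mask(counts.gene_ids, params.mito_prefix)
    if not mito.any():
        logger.warning("no genes match mitochondrial prefix %r", params.mito_prefix)
    csc = counts.values.tocsc()
    total = np.asarray(csc.sum(axis=0)).ravel().astype(float)
    mito_counts = np.asarray(csc[mito].sum(axis=0)).ravel().astype(float)
    zero_total = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(zero_total, 0.0, mito_counts / np.where(zero_total, 1, total))
    if params.molecule_definition == "genes":
        molecules = np.asarray((csc > 0).sum(axis=0)).ravel().astype(float)
    else:
        molecules = total
    return QCMetrics(frac, molecules, zero_total, list(counts.cell_ids))


def apply_qc_filter(
    counts: CountMatrix,
    metrics: QCMetrics,
    params: QCParams | None = None,
) -> tuple[CountMatrix, FilterReport]:
    """Keep cells with mito fraction strictly below and molecules strictly
    above the thresholds; drop ribosomal-prefixed genes when configured.

    Raises ``ValueError`` if no cell survives.
    """
    params = params or QCParams()
    if metrics.cell_ids != list(counts.cell_ids):
        raise ValueError("QC metrics were computed on a different matrix")
    pass_mito = metrics.mito_fraction < params.max_mito_fraction
    pass_mol = metrics.total_molecules > params.min_molecules
    keep_cells = pass_mito & pass_mol

    ribo = (
        _prefix_mask(counts.gene_ids, params.ribo_prefixes)
        if params.drop_ribosomal
        else np.zeros(counts.n_genes, dtype=bool)
    )
    report = FilterReport(
        n_cells_before=counts.n_cells,
        n_cells_after=int(keep_cells.sum()),
        n_removed_mito=int((~pass_mito).sum()),
        n_removed_molecules=int((~pass_mol).sum()),
        n_genes_before=counts.n_genes,
        n_genes_after=int((~ribo).sum()),
        n_ribo_genes_removed=int(ribo.sum()),
        params=params,
    )
    if report.n_cells_after == 0:
        raise ValueError("QC filter removed every cell")
    filtered = counts.subset(np.flatnonzero(~ribo), np.flatnonzero(keep_cells))
    return filtered, report


def lognormalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalize then log-transform:
    ``value = ln(count * scale / cell_total + 1)``.

    Cells with zero total counts come out all-zero (and are logged); doubling
    every count of a cell leaves its normalized vector unchanged.
    """
    if counts.n_cells == 0:
        raise ValueError("cannot normalize a matrix with no cells")
    dense = np.asarray(counts.values.todense(), dtype=float)
    totals = dense.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("%d cells have zero total counts; normalized to 0", zero.sum())
    if zero.all():
        raise ValueError("every cell has zero total counts")
    safe_totals = np.where(zero, 1.0, totals)
    values = np.log1p(dense * scale / safe_totals)
    values[:, zero] = 0.0
    return NormalizedMatrix(
        values=values,
        gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
        size_factors=totals / scale,
        scale=scale,
    )
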