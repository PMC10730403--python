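"""Per-cell-type differential expression and cross-cell-type consensus
selection of the iron accumulation signature (IAS).

The differential test is a two-sided Wilcoxon rank-sum on log-normalized
expression, exact by full enumeration of group assignments when the number of
assignments is small (ties handled by enumerating the statistic's
distribution over midranks), otherwise a normal approximation with tie and
continuity corrections. Testing is restricted to genes detected in at least
``min_detect_fraction`` of either group and showing at least the configured
fold difference on the log scale.

The consensus rule: within each major cell type, significant up-regulated
genes are ranked by log2 fold change and truncated to the top ``top_k``;
genes appearing in at least ``min_cell_types`` of these lists form the
signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CellAnnotation, GeneSetCollection
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEParams",
    "ConsensusParams",
    "ConsensusResult",
    "rank_sum_test",
    "differential_expression",
    "derive_consensus_signature",
]

DE_COLUMNS = [
    "cell_type",
    "gene",
    "logfc",
    "log2fc",
    "pct_in",
    "pct_out",
    "p",
    "p_adj",
    "n_in",
    "n_out",
]


@dataclass
class DEParams:
    min_detect_fraction: float = 0.10
    logfc_threshold: float = float(np.log(1.5))  # natural-log scale
    alpha: float = 0.05
    adjust_method: str = "bonferroni"  # or "BH"
    pseudocount: float = 1.0
    logfc_base: str = "natural"  # or "log2"
    exact_enumeration_limit: int = 20000

    def __post_init__(self) -> None:
        if not 0 < self.min_detect_fraction < 1:
            raise ValueError("min_detect_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.adjust_method not in ("bonferroni", "BH"):
            raise ValueError("adjust_method must be 'bonferroni' or 'BH'")
        if self.logfc_base not in ("natural", "log2"):
            raise ValueError("logfc_base must be 'natural' or 'log2'")


@dataclass
class ConsensusParams:
    top_k: int = 500
    min_cell_types: int = 5
    major_cell_types: list[str] = field(default_factory=list)
    direction: str = "up"  # or "both"
    allow_missing_tables: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.direction not in ("up", "both"):
            raise ValueError("direction must be 'up' or 'both'")
        if self.major_cell_types and not (
            1 <= self.min_cell_types <= len(self.major_cell_types)
        ):
            raise ValueError("min_cell_types out of range for the declared cell types")


# ---------------------------------------------------------------------------
# Rank-sum test


def _exact_ranksum_p(ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact p by enumerating every assignment of n1 of the
    (mid)ranks to the test group; tail masses of the rank-sum distribution
    are doubled and capped at 1."""
    w_obs = float(np.sum(ranks[:n1]))
    sums = np.fromiter(
        (sum(c) for c in combinations(ranks.tolist(), n1)),
        dtype=float,
        count=comb(len(ranks), n1),
    )
    eps = 1e-9 * max(1.0, abs(w_obs))
    lo = float(np.mean(sums <= w_obs + eps))
    hi = float(np.mean(sums >= w_obs - eps))
    return min(1.0, 2.0 * min(lo, hi))


def _asymptotic_ranksum_p(ranks: np.ndarray, n1: int) -> float:
    """Normal approximation with tie and continuity corrections."""
    n = len(ranks)
    n2 = n - n1
    w = float(np.sum(ranks[:n1]))
    mu = n1 * (n + 1) / 2.0
    # tie correction from run lengths of the pooled sample
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values tied
        return 1.0
    dev = abs(w - mu) - 0.5  # continuity correction
    z = max(dev, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, exact_limit: int = 20000
) -> tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum p for samples ``x`` vs ``y``.

    Exact enumeration when C(n1+n2, n1) <= ``exact_limit``; otherwise the
    tie/continuity-corrected normal approximation. Returns ``(p, exact)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    if comb(x.size + y.size, x.size) <= exact_limit:
        return _exact_ranksum_p(ranks, x.size), True
    return _asymptotic_ranksum_p(ranks, x.size), False


# ---------------------------------------------------------------------------
# Differential expression


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if m == 0:
        return p
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for i in range(m - 1, -1, -1):
        idx = order[i]
        running_min = min(running_min, p[idx] * m / (i + 1))
        adj[idx] = running_min
    return np.minimum(1.0, adj)


def differential_expression(
    norm: NormalizedMatrix,
    annot: CellAnnotation,
    cell_type: str,
    cond_test: str,
    cond_ref: str,
    params: DEParams | None = None,
) -> pd.DataFrame:
    """Test ``cond_test`` vs ``cond_ref`` within one cell type.

    Returns one row per gene with nonzero expression in at least one group;
    p-values are present only for genes passing the detection-fraction and
    fold-change prefilters, and are adjusted across tested genes within the
    cell type.
    """
    params = params or DEParams()
    annot = annot.aligned_to(norm.cell_ids)
    ct = annot.column("cell_type_level1")
    cond = annot.column("condition")
    known_ct = set(ct)
    if cell_type not in known_ct:
        raise KeyError(f"unknown cell type {cell_type!r}")
    for c in (cond_test, cond_ref):
        if c not in set(cond):
            raise KeyError(f"unknown condition {c!r}")
    in_mask = (ct == cell_type) & (cond == cond_test)
    out_mask = (ct == cell_type) & (cond == cond_ref)
    n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
    if n_in == 0 or n_out == 0:
        raise ValueError(
            f"empty group for cell type {cell_type!r}: n_test={n_in}, n_ref={n_out}"
        )

    x_in = norm.values[:, in_mask]
    x_out = norm.values[:, out_mask]
    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)
    # de-logged group means with pseudocount
    mean_in = np.expm1(x_in).mean(axis=1)
    mean_out = np.expm1(x_out).mean(axis=1)
    logfc_nat = np.log(
        (mean_in + params.pseudocount) / (mean_out + params.pseudocount)
    )
    log2fc = logfc_nat / np.log(2.0)
    logfc = logfc_nat if params.logfc_base == "natural" else log2fc

    nonzero = (pct_in > 0) | (pct_out > 0)
    tested = (
        nonzero
        & (np.maximum(pct_in, pct_out) >= params.min_detect_fraction)
        & (np.abs(logfc) >= params.logfc_threshold)
    )

    p = np.full(norm.n_genes, np.nan)
    for g in np.flatnonzero(tested):
        p[g], _ = rank_sum_test(x_in[g], x_out[g], params.exact_enumeration_limit)
    p_adj = np.full(norm.n_genes, np.nan)
    p_adj[tested] = _adjust(p[tested], params.adjust_method)

    keep = nonzero
    return pd.DataFrame(
        {
            "cell_type": cell_type,
            "gene": np.asarray(norm.gene_ids)[keep],
            "logfc": logfc[keep],
            "log2fc": log2fc[keep],
            "pct_in": pct_in[keep],
            "pct_out": pct_out[keep],
            "p": p[keep],
            "p_adj": p_adj[keep],
            "n_in": n_in,
            "n_out": n_out,
        }
    )[DE_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Consensus signature


@dataclass
class ConsensusResult:
    signature: list[str]
    support: dict[str, int]  # gene -> number of supporting cell types
    mean_rank: dict[str, float]  # gene -> mean 1-based rank over supporting lists
    top_lists: dict[str, list[str]]  # cell type -> ranked top-k candidates
    params: ConsensusParams

    def as_gene_sets(self, name: str = "IAS") -> GeneSetCollection:
        gsc = GeneSetCollection()
        gsc.add(name, self.signature, "consensus iron accumulation signature")
        return gsc


def _candidate_list(table: pd.DataFrame, cp: ConsensusParams, dp: DEParams) -> list[str]:
    t = table.dropna(subset=["p_adj"])
    t = t[t["p_adj"] < dp.alpha]
    if cp.direction == "up":
        t = t[t["log2fc"] > 0]
        key = -t["log2fc"].to_numpy()
    else:
        key = -np.abs(t["log2fc"].to_numpy())
    # ties at the boundary broken by smaller p then gene id, deterministically
    order = np.lexsort((t["gene"].to_numpy(), t["p"].to_numpy(), key))
    ranked = t["gene"].to_numpy()[order]
    return list(ranked[: cp.top_k])


def derive_consensus_signature(
    de_tables: dict[str, pd.DataFrame],
    params: ConsensusParams,
    de_params: DEParams | None = None,
) -> ConsensusResult:
    """Select genes appearing in the per-cell-type top-k candidate lists of at
    least ``min_cell_types`` of the declared major cell types.

    Output is ordered by (supporting cell types desc, mean rank asc, gene id).
    A missing table is an error unless ``allow_missing_tables``, in which case
    it contributes no candidates.
    """
    de_params = de_params or DEParams()
    if not params.major_cell_types:
        raise ValueError("major_cell_types must be declared explicitly")
    top_lists: dict[str, list[str]] = {}
    for ct in params.major_cell_types:
        if ct not in de_tables:
            if not params.allow_missing_tables:
                raise KeyError(f"no DE table for declared major cell type {ct!r}")
            top_lists[ct] = []
            continue
        top_lists[ct] = _candidate_list(de_tables[ct], params, de_params)

    support: dict[str, int] = {}
    ranks: dict[str, list[int]] = {}
    for lst in top_lists.values():
        for r, gene in enumerate(lst, start=1):
            support[gene] = support.get(gene, 0) + 1
            ranks.setdefault(gene, []).append(r)
    selected = [g for g, s in support.items() if s >= params.min_cell_types]
    if not selected:
        logger.warning("consensus selection produced an empty signature")
    mean_rank = {g: float(np.mean(ranks[g])) for g in selected}
    selected.sort(key=lambda g: (-support[g], mean_rank[g], g))
    return ConsensusResult(
        signature=selected,
        support={g: support[g] for g in selected},
        mean_rank=mean_rank,
        top_lists=top_lists,
        params=params,
    )
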