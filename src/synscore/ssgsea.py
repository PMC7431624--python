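"""Single-sample gene-set enrichment scoring.

For each sample, genes are rank-normalized within the sample (highest
expression gets rank N, lowest rank 1; ties broken by ascending gene
symbol) and the enrichment score of a set S of effective size m is the
weighted Kolmogorov-Smirnov-like running-sum statistic

    ES = sum_{i=1..N} [ P_in(i) - P_out(i) ]

where genes are walked in descending rank order,
``P_in(i) = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha`` and
``P_out(i) = |{j<=i, j not in S}| / (N - m)``. Because P_in and P_out are
step functions, the sum collapses to a closed form over member ranks only:

    ES = sum_S r^(alpha+1) / sum_S r^alpha  -  (N(N+1)/2 - sum_S r) / (N - m)

which is what :func:`score_matrix` computes (O(m) per set per sample).
:func:`es_single` exposes the same quantity for one sample. The score is
invariant to any strictly increasing transform of a sample's expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["SsgseaParams", "EnrichmentScoreMatrix", "rank_normalize", "es_single", "score_matrix"]


@dataclass(frozen=True)
class SsgseaParams:
    """Scoring parameters.

    alpha : rank-weight exponent (>= 0). 0.25 matches the common
        single-sample GSEA projection default.
    min_size, max_size : effective-size window for retaining a set (count
        of its members present in the matrix). The 10-1,000 window is the
        screening default; set ``min_size=1`` when scoring nested
        signatures that start at a single gene.
    normalize : "range" divides all raw scores by (max - min) over the
        whole score matrix; "raw" leaves them untouched. Rank-based
        screening statistics are unaffected by the choice.
    tie_break : deterministic rule for equal expression values; only
        "symbol" (ascending gene symbol) is defined.
    """

    alpha: float = 0.25
    min_size: int = 10
    max_size: int = 1000
    normalize: str = "range"
    tie_break: str = "symbol"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError("need 1 <= min_size <= max_size")
        if self.normalize not in ("raw", "range"):
            raise ValueError("normalize must be 'raw' or 'range'")
        if self.tie_break != "symbol":
            raise ValueError("unknown tie_break rule")

    def with_min_size(self, min_size: int) -> "SsgseaParams":
        return replace(self, min_size=min_size)


@dataclass
class EnrichmentScoreMatrix:
    """Sets x samples enrichment scores plus the parameters that made them."""

    es: pd.DataFrame  # set_names x sample_ids
    params: SsgseaParams
    effective_sizes: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def set_names(self) -> list[str]:
        return list(self.es.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.es.columns)


def rank_normalize(
    sample_values: pd.Series, tie_break: str = "symbol"
) -> pd.Series:
    """Integer rank scores for one sample: highest expression -> N, lowest -> 1.

    Ties are broken deterministically by ascending gene symbol (the
    alphabetically first symbol receives the higher rank), so scores are
    reproducible across platforms. An all-equal vector is valid — ordering
    is then purely the tie-break — but is logged as a warning.
    """
    if tie_break != "symbol":
        raise ValueError("unknown tie_break rule")
    if len(sample_values) < 2:
        raise ValueError("need at least 2 genes to rank")
    values = sample_values.to_numpy(dtype=float)
    if np.all(values == values[0]):
        logger.warning("all-equal expression vector: ranking is pure tie-break")
    order = _descending_order(values, np.asarray(sample_values.index, dtype=object))
    n = len(values)
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(n, 0, -1)
    return pd.Series(ranks, index=sample_values.index)


def _descending_order(values: np.ndarray, symbols: np.ndarray) -> np.ndarray:
    """Indices sorting by descending value, ties by ascending symbol."""
    sym_rank = np.argsort(np.argsort(symbols, kind="stable"), kind="stable")
    # lexsort: last key is primary
    return np.lexsort((sym_rank, -values))


def es_single(
    rank_scores: Sequence[float] | pd.Series,
    membership: Sequence[bool],
    alpha: float = 0.25,
) -> float:
    """Enrichment score of one set in one sample from its rank scores.

    ``rank_scores`` are the per-gene rank scores (as from
    :func:`rank_normalize`), ``membership`` the aligned boolean indicator
    of set membership. Requires 1 <= m < N so that both the in-set and
    out-of-set walks are defined.
    """
    r = np.asarray(rank_scores, dtype=float)
    member = np.asarray(membership, dtype=bool)
    n = r.size
    m = int(member.sum())
    if m == 0 or m == n:
        raise ValueError("set must be a proper non-empty subset of the genes")
    r_in = r[member]
    w = r_in ** alpha
    sum_pin = float((w * r_in).sum() / w.sum())
    sum_pout = float((n * (n + 1) / 2.0 - r_in.sum()) / (n - m))
    return sum_pin - sum_pout


def _rank_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """Genes x samples matrix of rank scores (N..1 per column)."""
    values = expr.values.to_numpy(dtype=float)
    symbols = np.asarray(expr.values.index, dtype=object)
    sym_rank = np.argsort(np.argsort(symbols, kind="stable"), kind="stable")
    n, s = values.shape
    ranks = np.empty((n, s), dtype=float)
    descending = np.arange(n, 0, -1, dtype=float)
    for j in range(s):
        order = np.lexsort((sym_rank, -values[:, j]))
        ranks[order, j] = descending
    return ranks


def score_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    params: SsgseaParams | None = None,
) -> EnrichmentScoreMatrix:
    """Score every retained gene set in every sample.

    Sets are first restricted to members present in the matrix and dropped
    if their effective size falls outside ``[min_size, max_size]``. Raw
    scores are optionally rescaled by the global (max - min) of the score
    matrix (``normalize="range"``). Scoring each set is independent of all
    other sets.
    """
    params = params or SsgseaParams()
    retained = sets.filter_by_size(expr.gene_symbols, params.min_size, params.max_size)
    if len(retained) == 0:
        raise ValueError("no gene set survives the size filter")
    ranks = _rank_matrix(expr)
    n = ranks.shape[0]
    gene_pos = {g: i for i, g in enumerate(expr.gene_symbols)}
    total = n * (n + 1) / 2.0
    rows = np.empty((len(retained), ranks.shape[1]), dtype=float)
    eff_sizes: dict[str, int] = {}
    for k, gs in enumerate(retained):
        idx = np.array([gene_pos[g] for g in gs.genes if g in gene_pos], dtype=int)
        m = idx.size
        eff_sizes[gs.name] = m
        if m == n:
            raise ValueError(f"set {gs.name!r} covers every gene in the matrix")
        r_in = ranks[idx, :]  # m x samples
        w = r_in ** params.alpha
        sum_pin = (w * r_in).sum(axis=0) / w.sum(axis=0)
        sum_pout = (total - r_in.sum(axis=0)) / (n - m)
        rows[k] = sum_pin - sum_pout
    if params.normalize == "range":
        span = rows.max() - rows.min()
        if span > 0:
            rows = rows / span
    es = pd.DataFrame(rows, index=retained.names(), columns=expr.sample_ids)
    return EnrichmentScoreMatrix(es, params, pd.Series(eff_sizes))
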