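"""Gene-level screening and greedy nested signature construction.

Genes collected from the selected terms are screened one at a time against
survival in every batch (combined FDR as in the term stage), the
direction-consistent survivors are ordered by ascending combined FDR, and
nested candidate sets — the top 1, top 2, ..., top G genes — are scored by
single-sample enrichment and screened the same way. The nested set
minimizing the combined FDR (smallest n on ties) is the selected
signature. Finding the truly optimal subset is NP-hard; this greedy
forward construction is the method of record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection
from .ssgsea import SsgseaParams, score_matrix
from .survival_screen import rank_records, screen_units

logger = logging.getLogger(__name__)

__all__ = ["GreedyTrace", "collect_genes", "screen_genes", "build_nested_sets"]


@dataclass
class GreedyTrace:
    """Statistics of every nested top-n candidate set.

    ``table`` is indexed by n = 1..G with the per-batch and combined
    screening columns; ``members[n]`` is the top-n gene tuple (strictly
    nested in ``members[n+1]``); ``selected_n`` minimizes
    ``selection_criterion`` over the n whose fits succeeded, ties going to
    the smallest n.
    """

    ranked_genes: list[str]
    table: pd.DataFrame
    members: dict[int, tuple[str, ...]] = field(default_factory=dict)
    selected_n: int = 0
    selection_criterion: str = "combined_fdr"

    @property
    def selected_genes(self) -> tuple[str, ...]:
        return self.members[self.selected_n]

    def selected_gene_set(self, name: str = "selected_signature") -> GeneSet:
        return GeneSet(name, f"greedy nested selection, n={self.selected_n}", self.selected_genes)


def collect_genes(
    selected_terms: GeneSetCollection,
    expr_batches: list[ExpressionMatrix],
) -> list[str]:
    """Deduplicated union of term members present in every batch.

    Order follows first appearance across the terms; genes missing from
    any batch are dropped with a logged count.
    """
    if len(selected_terms) == 0:
        raise ValueError("need at least one selected term")
    union: dict[str, None] = {}
    for gs in selected_terms:
        for g in gs.genes:
            union.setdefault(g)
    shared = set(expr_batches[0].gene_symbols)
    for b in expr_batches[1:]:
        shared &= set(b.gene_symbols)
    genes = [g for g in union if g in shared]
    dropped = len(union) - len(genes)
    if dropped:
        logger.info("collect_genes: %d of %d genes absent from some batch", dropped, len(union))
    if not genes:
        raise ValueError("no collected gene is present in every batch")
    return genes


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0  # zero-variance rows flagged later by the Cox fit
    return pd.DataFrame(
        (arr - arr.mean(axis=1, keepdims=True)) / sd, index=values.index, columns=values.columns
    )


def screen_genes(
    genes: list[str],
    expr_batches: list[ExpressionMatrix],
    clinical_batches: list[ClinicalTable],
    gene_score_mode: str = "expression",
    ssgsea_params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Screen individual genes against survival across batches.

    ``gene_score_mode="expression"`` fits Cox on the gene's per-batch
    z-scored expression row (z-scoring rescales the HR but leaves its
    direction and p-value untouched); ``"single_gene_es"`` instead scores
    each gene as a singleton set by single-sample enrichment. BH is
    applied within each batch across the screened genes. Returns the full
    combined record table (see :func:`synscore.survival_screen.screen_units`);
    feed it to :func:`synscore.survival_screen.rank_records` for the
    direction-consistent ranking.
    """
    if gene_score_mode not in ("expression", "single_gene_es"):
        raise ValueError(f"unknown gene_score_mode {gene_score_mode!r}")
    scores_per_batch: list[pd.DataFrame] = []
    for expr in expr_batches:
        missing = [g for g in genes if g not in set(expr.gene_symbols)]
        if missing:
            raise ValueError(f"genes absent from batch {expr.batch_label!r}: {missing[:5]}")
        if gene_score_mode == "expression":
            scores_per_batch.append(_zscore_rows(expr.values.loc[genes]))
        else:
            params = (ssgsea_params or SsgseaParams()).with_min_size(1)
            singles = GeneSetCollection.from_dict({g: [g] for g in genes})
            scores_per_batch.append(score_matrix(expr, singles, params).es.loc[genes])
    return screen_units(scores_per_batch, clinical_batches)


def select_n(table: pd.DataFrame, criterion: str) -> int:
    """Argmin of ``criterion`` over the rankable nested sets; ties -> smallest n."""
    usable = table[table["rankable"]]
    if usable.empty:
        raise ValueError("every nested set's fit failed; nothing to select")
    crit = usable[criterion].to_numpy(dtype=float)
    return int(usable.index[int(np.argmin(crit))])  # argmin returns the first (smallest n) on ties


def build_nested_sets(
    ranked_genes: list[str],
    expr_batches: list[ExpressionMatrix],
    clinical_batches: list[ClinicalTable],
    criterion: str = "combined_fdr",
    ssgsea_params: SsgseaParams | None = None,
) -> GreedyTrace:
    """Score and screen the nested top-n sets for n = 1..G and select one.

    The enrichment size filter is overridden to ``min_size=1`` (the nested
    sets start at a single gene). BH is applied within each batch across
    the G nested sets. ``criterion`` is ``combined_fdr`` (default) or
    ``combined_p``; n with failed fits are excluded from the argmin.
    """
    if not ranked_genes:
        raise ValueError("need at least one ranked gene")
    if criterion not in ("combined_fdr", "combined_p"):
        raise ValueError(f"unknown selection criterion {criterion!r}")
    g_total = len(ranked_genes)
    members = {n: tuple(ranked_genes[:n]) for n in range(1, g_total + 1)}
    nested = GeneSetCollection.from_dict(
        {f"top_{n}": list(members[n]) for n in range(1, g_total + 1)}
    )
    params = (ssgsea_params or SsgseaParams()).with_min_size(1)
    scores_per_batch = []
    for expr in expr_batches:
        es = score_matrix(expr, nested, params).es
        scores_per_batch.append(es.loc[[f"top_{n}" for n in range(1, g_total + 1)]])
    records = screen_units(scores_per_batch, clinical_batches)
    records.index = pd.Index(range(1, g_total + 1), name="n")

    selected_n = select_n(records, criterion)
    n_failed = int((~records["rankable"].astype(bool)).sum())
    if n_failed:
        logger.info("build_nested_sets: %d of %d nested fits failed", n_failed, g_total)
    return GreedyTrace(
        ranked_genes=list(ranked_genes),
        table=records,
        members=members,
        selected_n=selected_n,
        selection_criterion=criterion,
    )
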