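"""Permutation validation of a candidate signature against random gene sets.

The null is over gene sets, not sample labels: random sets of the same
size are drawn (without replacement within a set; sets may overlap each
other and the candidate) from the universe of genes shared by all batches,
each is scored by single-sample enrichment and screened against survival
exactly like the candidate, BH adjustment is applied jointly across the
candidate plus all null sets within each batch, and the candidate's
combined FDR is ranked among the null combined FDRs. Ties count against
the candidate. Direction consistency is not required of null sets — every
null receives a combined FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection
from .ssgsea import SsgseaParams, score_matrix
from .survival_screen import screen_units

logger = logging.getLogger(__name__)

__all__ = ["PermutationNull", "permutation_test"]


@dataclass
class PermutationNull:
    """Outcome of a gene-set permutation experiment.

    ``rank`` is the candidate's 1-based position among {candidate} and the
    null sets sorted ascending by combined FDR, with equal null values
    placed ahead of the candidate; ``empirical_p = rank / (n_perm + 1)``
    (never exactly 0 by construction).
    """

    candidate_name: str
    set_size: int
    n_perm: int
    seed: int
    candidate_stat: float
    null_stats: np.ndarray
    universe_size: int

    @property
    def rank(self) -> int:
        return 1 + int(np.sum(self.null_stats <= self.candidate_stat))

    @property
    def empirical_p(self) -> float:
        return self.rank / (self.n_perm + 1)

    def summary(self) -> dict:
        q = np.quantile(self.null_stats, [0.0, 0.25, 0.5, 0.75, 1.0])
        return {
            "candidate": self.candidate_name,
            "set_size": self.set_size,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "universe_size": self.universe_size,
            "candidate_combined_fdr": float(self.candidate_stat),
            "rank": self.rank,
            "empirical_p": self.empirical_p,
            "null_quantiles": {k: float(v) for k, v in zip(("min", "q25", "median", "q75", "max"), q)},
        }


def shared_gene_universe(expr_batches: list[ExpressionMatrix]) -> list[str]:
    """Genes present in every batch, in first-batch order."""
    shared = set(expr_batches[0].gene_symbols)
    for b in expr_batches[1:]:
        shared &= set(b.gene_symbols)
    return [g for g in expr_batches[0].gene_symbols if g in shared]


def permutation_test(
    candidate: GeneSet,
    expr_batches: list[ExpressionMatrix],
    clinical_batches: list[ClinicalTable],
    n_perm: int = 10000,
    seed: int = 0,
    ssgsea_params: SsgseaParams | None = None,
) -> PermutationNull:
    """Rank a candidate signature's combined FDR among random equal-size sets.

    A null set whose Cox fit fails in any batch gets the worst possible
    statistic (1.0, logged); a failed candidate fit is a hard error.
    Deterministic for fixed ``(seed, n_perm)``.
    """
    universe = shared_gene_universe(expr_batches)
    uni_set = set(universe)
    missing = [g for g in candidate.genes if g not in uni_set]
    if missing:
        raise ValueError(f"candidate genes absent from shared universe: {missing[:5]}")
    m = len(candidate.genes)
    if m < 1:
        raise ValueError("candidate set is empty")
    if m >= len(universe):
        raise ValueError("candidate as large as the universe")

    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    cand_name = "__candidate__"
    collection.add(GeneSet(cand_name, "candidate signature", tuple(candidate.genes)))
    universe_arr = np.asarray(universe, dtype=object)
    for i in range(n_perm):
        picked = rng.choice(len(universe_arr), size=m, replace=False)
        collection.add(GeneSet(f"null_{i:05d}", "", tuple(universe_arr[picked])))

    params = (ssgsea_params or SsgseaParams()).with_min_size(1)
    scores_per_batch = [score_matrix(expr, collection, params).es for expr in expr_batches]
    records = screen_units(scores_per_batch, clinical_batches)

    cand = records.loc[cand_name]
    if not bool(cand["rankable"]):
        raise RuntimeError("candidate signature's Cox fit failed")
    nulls = records.drop(index=cand_name)
    null_stats = nulls["combined_fdr"].to_numpy(dtype=float)
    n_failed = int((~nulls["rankable"].astype(bool)).sum())
    if n_failed:
        logger.info("permutation_test: %d null sets failed; statistic set to 1.0", n_failed)
        null_stats = np.where(np.isnan(null_stats), 1.0, null_stats)
    return PermutationNull(
        candidate_name=candidate.name,
        set_size=m,
        n_perm=n_perm,
        seed=seed,
        candidate_stat=float(cand["combined_fdr"]),
        null_stats=null_stats,
        universe_size=len(universe),
    )
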