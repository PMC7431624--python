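"""Per-batch survival screening, BH adjustment and cross-batch combination.

Each screened unit (a gene-set enrichment score, a single gene, or a
candidate signature) gets a univariate Cox hazard ratio and Wald p-value
against overall survival in every batch; p-values are Benjamini-Hochberg
adjusted within the batch across all units screened at that stage; the
per-batch FDRs are multiplied into a "combined FDR" used purely as a
ranking statistic (a product of FDRs is not itself an error-rate
estimate); and units whose log hazard ratios disagree in sign across
batches are excluded from ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cox import CoxError, CoxFit, fit_cox
from .data_io import ClinicalTable
from .ssgsea import EnrichmentScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BatchStat",
    "ScreeningRecord",
    "cox_univariate",
    "bh_adjust",
    "combine_batches",
    "screen_units",
    "screen_terms",
]


@dataclass
class BatchStat:
    """One unit's Cox statistics in one batch."""

    hr: float
    ci95: tuple[float, float]
    p: float
    n: int
    fdr: float = np.nan
    ok: bool = True
    reason: str = ""


@dataclass
class ScreeningRecord:
    """One unit across all batches."""

    unit_name: str
    batch_stats: list[BatchStat] = field(default_factory=list)
    combined_fdr: float = np.nan
    combined_p: float = np.nan
    direction_consistent: bool = False
    rankable: bool = False


def cox_univariate(
    score: pd.Series,
    clinical: ClinicalTable,
    covariates: pd.DataFrame | None = None,
) -> BatchStat:
    """Cox PH fit of survival on one score column (plus optional covariates).

    Complete-case: samples missing survival (or any covariate) are dropped
    and the remaining n is reported. Degenerate inputs (zero score
    variance, <2 events) and non-convergent fits come back flagged
    (``ok=False``) rather than raising, so screening loops can skip them.
    """
    surv = clinical.survival_frame()
    cols = pd.DataFrame({"score": score})
    if covariates is not None:
        cols = cols.join(covariates, how="inner")
    df = cols.join(surv, how="inner").dropna()
    n = len(df)
    try:
        if n < 3:
            raise CoxError(f"only {n} complete cases")
        fit = fit_cox(
            df["score"].to_numpy(),
            df["os_time"].to_numpy(),
            df["os_event"].to_numpy().astype(bool),
            covariates=df.drop(columns=["score", "os_time", "os_event"]).to_numpy()
            if covariates is not None
            else None,
        )
    except CoxError as exc:
        return BatchStat(np.nan, (np.nan, np.nan), np.nan, n, ok=False, reason=str(exc))
    if not fit.converged:
        return BatchStat(
            fit.hr, fit.ci95, fit.p, n, ok=False, reason="non-convergence or monotone likelihood"
        )
    return BatchStat(fit.hr, fit.ci95, fit.p, n)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, original order)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def combine_batches(batch_stats: list[BatchStat]) -> tuple[float, float, bool, bool]:
    """Combine one unit's per-batch stats.

    Returns ``(combined_fdr, combined_p, direction_consistent, rankable)``:
    the product of per-batch FDRs, the product of raw p-values, whether
    every batch's log hazard ratio shares one sign (HR exactly 1 counts as
    inconsistent), and whether every batch fit succeeded.
    """
    if len(batch_stats) < 2:
        raise ValueError("need at least 2 batches to combine")
    if not all(b.ok for b in batch_stats):
        return np.nan, np.nan, False, False
    combined_fdr = float(np.prod([b.fdr for b in batch_stats]))
    combined_p = float(np.prod([b.p for b in batch_stats]))
    signs = [np.sign(np.log(b.hr)) for b in batch_stats]
    consistent = all(s == signs[0] and s != 0 for s in signs)
    return combined_fdr, combined_p, consistent, True


def screen_units(
    scores_per_batch: list[pd.DataFrame],
    clinical_per_batch: list[ClinicalTable],
) -> pd.DataFrame:
    """Screen a units x samples score table per batch and combine.

    BH adjustment is applied within each batch across the units screened
    here (the screening family is whatever this call is given). Returns a
    DataFrame indexed by unit with per-batch ``hr_i``/``p_i``/``fdr_i``/
    ``n_i`` columns, ``combined_fdr``, ``combined_p``,
    ``direction_consistent`` and ``rankable``; invariant to batch order up
    to column naming and to sample order within a batch.
    """
    if len(scores_per_batch) != len(clinical_per_batch):
        raise ValueError("one clinical table per score batch required")
    if len(scores_per_batch) < 2:
        raise ValueError("need at least 2 batches")
    units = list(scores_per_batch[0].index)
    for tbl in scores_per_batch[1:]:
        if list(tbl.index) != units:
            raise ValueError("all batches must screen the same units in the same order")

    per_batch: list[list[BatchStat]] = []
    for scores, clinical in zip(scores_per_batch, clinical_per_batch):
        stats = [cox_univariate(scores.loc[u], clinical) for u in units]
        ok = np.array([s.ok for s in stats])
        pvals = np.array([s.p for s in stats])
        fdr = np.full(len(units), np.nan)
        if ok.any():
            fdr[ok] = bh_adjust(pvals[ok])
        for s, f in zip(stats, fdr):
            s.fdr = float(f)
        n_failed = int((~ok).sum())
        if n_failed:
            logger.info("batch screening: %d of %d units flagged unrankable", n_failed, len(units))
        per_batch.append(stats)

    rows = {}
    for i, u in enumerate(units):
        stats = [per_batch[b][i] for b in range(len(per_batch))]
        cfdr, cp, consistent, rankable = combine_batches(stats)
        row: dict[str, float] = {}
        for b, s in enumerate(stats, start=1):
            row[f"hr_{b}"] = s.hr
            row[f"ci_low_{b}"], row[f"ci_high_{b}"] = s.ci95
            row[f"p_{b}"] = s.p
            row[f"fdr_{b}"] = s.fdr
            row[f"n_{b}"] = s.n
        row["combined_fdr"] = cfdr
        row["combined_p"] = cp
        row["direction_consistent"] = consistent
        row["rankable"] = rankable
        rows[u] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def rank_records(records: pd.DataFrame) -> pd.DataFrame:
    """Direction-consistent rankable units, ascending combined FDR.

    Ties in combined FDR are broken by smaller maximum per-batch p-value,
    then lexicographic unit name, so ranking is deterministic.
    """
    ok = records[records["rankable"] & records["direction_consistent"]].copy()
    pcols = [c for c in ok.columns if c.startswith("p_")]
    ok["_max_p"] = ok[pcols].max(axis=1)
    ok["_name"] = ok.index.astype(str)
    ok = ok.sort_values(["combined_fdr", "_max_p", "_name"], kind="stable")
    return ok.drop(columns=["_max_p", "_name"])


def screen_terms(
    es_per_batch: list[EnrichmentScoreMatrix],
    clinical_per_batch: list[ClinicalTable],
    top_k: int = 10,
    exclusions: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank gene-set enrichment scores by survival and pick the top terms.

    Ranks direction-consistent terms ascending by combined FDR, removes
    any excluded names and refills from further down the ranking so that
    ``top_k`` terms survive. Returns ``(full ranked table, selected
    names)``; warns (and returns everything) if fewer than ``top_k``
    consistent terms exist.
    """
    records = screen_units([m.es for m in es_per_batch], clinical_per_batch)
    ranked = rank_records(records)
    excluded = set(exclusions or [])
    selected = [u for u in ranked.index if u not in excluded][:top_k]
    if len(selected) < top_k:
        logger.warning(
            "only %d direction-consistent terms available (top_k=%d)", len(selected), top_k
        )
    return ranked, selected
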