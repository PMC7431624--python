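"""Downstream evaluation of a signature's per-sample score.

Given a per-sample score (the signature's single-sample enrichment score),
this module covers the three clinical read-outs: prognosis (median-split
Kaplan-Meier with log-rank, Cox hazard ratios with optional covariate
adjustment), grading (two-sided Wilcoxon rank-sum between grade groups),
and diagnosis (tumor vs normal ROC/AUC, with normal tissue — which shows
the higher score — as the positive class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import auc as _auc_trapezoid
from sklearn.metrics import roc_curve

from .data_io import ClinicalTable
from .survival_screen import BatchStat, cox_univariate

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "median_split",
    "km_logrank",
    "adjusted_cox",
    "group_rank_tests",
    "diag_roc",
    "evaluate_signature",
]

GRADE_CODES = {"II": 2, "III": 3, "IV": 4}


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    statistic: float
    p: float
    group_sizes: dict[str, int]


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_positive: int
    n_negative: int


@dataclass
class EvaluationReport:
    km: KMResult | None = None
    cox: dict[str, BatchStat] = field(default_factory=dict)
    grade_tests: pd.DataFrame | None = None
    roc: ROCResult | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        if self.km is not None:
            out["km"] = {
                "logrank_statistic": self.km.statistic,
                "logrank_p": self.km.p,
                "group_sizes": self.km.group_sizes,
            }
        out["cox"] = {
            name: {"hr": s.hr, "ci95": list(s.ci95), "p": s.p, "n": s.n, "ok": s.ok}
            for name, s in self.cox.items()
        }
        if self.grade_tests is not None:
            out["grade_tests"] = self.grade_tests.reset_index().to_dict(orient="records")
        if self.roc is not None:
            out["roc"] = {
                "auc": self.roc.auc,
                "n_positive": self.roc.n_positive,
                "n_negative": self.roc.n_negative,
            }
        return out


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples "high"/"low" at the cohort median.

    Scores strictly above the median go high; scores at or below go low
    (samples equal to the median must land on one declared side — low).
    Invariant to sample order; group sizes differ by at most one when the
    scores are distinct.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(scores.to_numpy(dtype=float)) == 0:
        raise ValueError("all scores identical: median split undefined")
    med = float(scores.median())
    labels = pd.Series(np.where(scores > med, "high", "low"), index=scores.index)
    logger.info(
        "median split: %d high, %d low", int((labels == "high").sum()), int((labels == "low").sum())
    )
    return labels


def km_logrank(groups: pd.Series, clinical: ClinicalTable) -> KMResult:
    """Product-limit curves per group and the two-sample log-rank test."""
    surv = clinical.survival_frame()
    df = pd.DataFrame({"group": groups}).join(surv, how="inner").dropna()
    names = sorted(df["group"].unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for name in names:
        sub = df[df["group"] == name]
        if sub.empty:
            raise ValueError(f"group {name!r} is empty")
        if sub["os_event"].sum() < 1:
            raise ValueError(f"group {name!r} has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"], label=name)
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf[name].to_numpy()})
        sizes[name] = len(sub)
    a, b = names
    res = logrank_test(
        df.loc[df["group"] == a, "os_time"], df.loc[df["group"] == b, "os_time"],
        df.loc[df["group"] == a, "os_event"], df.loc[df["group"] == b, "os_event"],
    )
    return KMResult(curves, float(res.test_statistic), float(res.p_value), sizes)


def adjusted_cox(
    scores: pd.Series,
    clinical: ClinicalTable,
    adjustment: str = "none",
    grade_coding: str = "ordinal",
) -> BatchStat:
    """Cox HR of the score with an optional covariate adjustment.

    ``adjustment`` is one of none / grade / idh / codel. Grade is coded
    ordinal (II=2, III=3, IV=4) by default or as categorical dummies with
    ``grade_coding="categorical"``; IDH mutant and 1p/19q codeletion are
    coded 1 against 0. Complete-case per model, so n varies with covariate
    completeness. Returns the score coefficient's statistics.
    """
    if adjustment == "none":
        return cox_univariate(scores, clinical)
    data = clinical.data
    if adjustment == "grade":
        grade = data["grade"].map(GRADE_CODES)
        if grade.dropna().empty:
            raise ValueError("grade covariate entirely missing")
        if grade_coding == "ordinal":
            cov = pd.DataFrame({"grade": grade})
        elif grade_coding == "categorical":
            cov = pd.get_dummies(data["grade"], prefix="grade", drop_first=True, dtype=float)
            cov[data["grade"].isna()] = np.nan
        else:
            raise ValueError(f"unknown grade_coding {grade_coding!r}")
    elif adjustment == "idh":
        cov = pd.DataFrame({"idh": data["idh_status"].map({"mutant": 1.0, "wildtype": 0.0})})
        if cov["idh"].dropna().empty:
            raise ValueError("IDH covariate entirely missing")
    elif adjustment == "codel":
        cov = pd.DataFrame({"codel": data["codel_1p19q"].map({"codel": 1.0, "non-codel": 0.0})})
        if cov["codel"].dropna().empty:
            raise ValueError("1p/19q covariate entirely missing")
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return cox_univariate(scores, clinical, covariates=cov)


def group_rank_tests(scores: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with group medians.

    ``labels`` is any categorical grouping (grades, tissue type). Every
    unordered pair of groups is compared; medians are reported so the
    direction of each difference is auditable. P-values are invariant to
    any strictly monotone transform of the scores.
    """
    df = pd.DataFrame({"score": scores, "label": labels}).dropna()
    groups = {name: sub["score"].to_numpy(dtype=float) for name, sub in df.groupby("label")}
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    rows = []
    for a, b in combinations(sorted(groups), 2):
        stat, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "median_a": float(np.median(groups[a])),
                "median_b": float(np.median(groups[b])),
                "u_statistic": float(stat),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index(["group_a", "group_b"])


def diag_roc(scores: pd.Series, tissue: pd.Series) -> ROCResult:
    """Tumor-vs-normal ROC; normal (higher score) is the positive class.

    The AUC equals the Mann-Whitney probability U/(n_pos * n_neg) that a
    random normal sample scores above a random tumor sample.
    """
    df = pd.DataFrame({"score": scores, "tissue": tissue}).dropna()
    y = (df["tissue"] == "normal").astype(int)
    if y.nunique() < 2:
        raise ValueError("need both tumor and normal samples")
    fpr, tpr, _ = roc_curve(y, df["score"])
    return ROCResult(
        auc=float(_auc_trapezoid(fpr, tpr)),
        fpr=fpr,
        tpr=tpr,
        n_positive=int(y.sum()),
        n_negative=int((1 - y).sum()),
    )


def evaluate_signature(
    scores: pd.Series,
    clinical: ClinicalTable,
    adjustments: tuple[str, ...] = ("none", "grade", "idh", "codel"),
) -> EvaluationReport:
    """Run the full evaluation suite on tumor samples (plus diagnosis if
    normal samples are present).

    Prognosis and grading use tumor samples only; the ROC uses every
    sample with a tissue label.
    """
    report = EvaluationReport()
    data = clinical.data
    tumor_ids = data.index[(data["tissue"] == "tumor") | data["tissue"].isna()]
    tumor_scores = scores.loc[scores.index.intersection(tumor_ids)]
    tumor_clin = clinical.subset([s for s in clinical.sample_ids if s in set(tumor_scores.index)])

    groups = median_split(tumor_scores)
    report.km = km_logrank(groups, tumor_clin)
    for adj in adjustments:
        try:
            report.cox[adj] = adjusted_cox(tumor_scores, tumor_clin, adjustment=adj)
        except ValueError as exc:
            logger.warning("adjustment %r skipped: %s", adj, exc)
    grade = tumor_clin.data["grade"].dropna()
    if grade.nunique() >= 2:
        report.grade_tests = group_rank_tests(tumor_scores.loc[grade.index], grade)
    tissue = data["tissue"].dropna()
    if (tissue == "normal").any() and (tissue == "tumor").any():
        common = scores.index.intersection(tissue.index)
        report.roc = diag_roc(scores.loc[common], tissue.loc[common])
    return report
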