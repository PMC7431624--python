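"""End-to-end pipeline orchestration.

Runs the stages simulate -> score -> screen-terms -> build-set -> permute
-> evaluate from one structured config, writing plain-text outputs plus a
JSON report per stage into an output directory, together with the
resolved config and a manifest of output files with content hashes. A
single top-level seed is fanned out deterministically to the stages.
Existing stage outputs are reused unless ``force`` is set; outputs are
write-once (no stage mutates another stage's files).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import data_io
from .data_io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .permutation import permutation_test
from .score_eval import evaluate_signature
from .set_builder import build_nested_sets, collect_genes, screen_genes
from .ssgsea import SsgseaParams, score_matrix
from .survival_screen import rank_records, screen_terms

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("simulate", "score", "screen_terms", "build_set", "permute", "evaluate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Either point ``expression_paths``/``clinical_paths``/``terms_path`` at
    real inputs, or leave them empty to run on a simulated cohort
    (``simulate`` holds :class:`~synscore.synthetic_data.SyntheticCohortConfig`
    overrides).
    """

    out_dir: str = "synscore_run"
    seed: int = 0
    expression_paths: list[str] = field(default_factory=list)
    clinical_paths: list[str] = field(default_factory=list)
    terms_path: str = ""
    simulate: dict = field(default_factory=dict)
    ssgsea: dict = field(default_factory=dict)
    top_k: int = 10
    exclusions: list[str] = field(default_factory=list)
    criterion: str = "combined_fdr"
    gene_score_mode: str = "expression"
    n_perm: int = 1000
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    # deterministic fan-out of the top-level seed, kept below 2**31
    return int(np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    params = SsgseaParams(**config.ssgsea)
    manifest: dict[str, dict[str, str]] = {}

    def emit(stage: str, name: str, path: Path) -> None:
        manifest.setdefault(stage, {})[name] = _sha256(path)

    # ---- inputs: simulate or load -------------------------------------
    if config.expression_paths:
        stage = "load"
        try:
            if len(config.expression_paths) != len(config.clinical_paths):
                raise ValueError("need one clinical path per expression path")
            expr_batches = [data_io.read_expression(p) for p in config.expression_paths]
            clin_batches = [data_io.read_clinical(p) for p in config.clinical_paths]
            if not config.terms_path:
                raise ValueError("terms_path required with real inputs")
            terms = data_io.read_gmt(config.terms_path)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    else:
        stage = "simulate"
        try:
            from .synthetic_data import SyntheticCohortConfig, simulate_cohorts, simulate_term_collection

            sim_cfg = SyntheticCohortConfig(**config.simulate)
            sim_seed = _stage_seed(config.seed, "simulate")
            cohorts, truth = simulate_cohorts(sim_cfg, seed=sim_seed)
            expr_batches = [e for e, _ in cohorts]
            clin_batches = [c for _, c in cohorts]
            terms = simulate_term_collection(sim_cfg, truth, seed=sim_seed)
            for i, (e, c) in enumerate(cohorts, 1):
                ep, cp = out / f"expr_batch{i}.gct", out / f"clinical_batch{i}.csv"
                if config.force or not ep.exists():
                    data_io.write_expression(e, ep)
                if config.force or not cp.exists():
                    data_io.write_clinical(c, cp)
                emit(stage, ep.name, ep)
                emit(stage, cp.name, cp)
            tp = out / "terms.gmt"
            if config.force or not tp.exists():
                data_io.write_gmt(terms, tp)
            emit(stage, tp.name, tp)
            truth_path = out / "truth.json"
            if config.force or not truth_path.exists():
                truth_path.write_text(
                    json.dumps({"planted_genes": list(truth.planted_genes)}, indent=2)
                )
            emit(stage, truth_path.name, truth_path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # survival analysis uses tumor samples present in both inputs
    aligned = []
    for e, c in zip(expr_batches, clin_batches):
        ea, ca = data_io.align_samples(e, c)
        aligned.append((ea, ca))
    expr_batches = [e for e, _ in aligned]
    clin_batches = [c for _, c in aligned]

    # ---- score: term-level enrichment per batch -----------------------
    try:
        es_batches = [score_matrix(e, terms, params) for e in expr_batches]
        for i, es in enumerate(es_batches, 1):
            p = out / f"es_terms_batch{i}.tsv"
            if config.force or not p.exists():
                es.es.to_csv(p, sep="\t")
            emit("score", p.name, p)
    except Exception as exc:
        raise PipelineError("score", exc) from exc

    # ---- screen-terms --------------------------------------------------
    try:
        ranked_terms, selected_terms = screen_terms(
            es_batches, clin_batches, top_k=config.top_k, exclusions=config.exclusions
        )
        p = out / "terms_ranked.tsv"
        if config.force or not p.exists():
            ranked_terms.to_csv(p, sep="\t", index_label="term")
        emit("screen_terms", p.name, p)
    except Exception as exc:
        raise PipelineError("screen_terms", exc) from exc

    # ---- build-set ------------------------------------------------------
    try:
        genes = collect_genes(terms.subset(selected_terms), expr_batches)
        gene_records = screen_genes(
            genes, expr_batches, clin_batches, gene_score_mode=config.gene_score_mode,
            ssgsea_params=params,
        )
        ranked_genes = list(rank_records(gene_records).index)
        if not ranked_genes:
            raise ValueError("no direction-consistent gene survived screening")
        trace = build_nested_sets(
            ranked_genes, expr_batches, clin_batches, criterion=config.criterion,
            ssgsea_params=params,
        )
        tp = out / "trace.tsv"
        if config.force or not tp.exists():
            table = trace.table.copy()
            table["selected"] = [n == trace.selected_n for n in table.index]
            table.insert(0, "gene_added", trace.ranked_genes)
            table.to_csv(tp, sep="\t", index_label="n")
        emit("build_set", tp.name, tp)
        sig = trace.selected_gene_set("signature")
        sp = out / "signature.gmt"
        if config.force or not sp.exists():
            coll = GeneSetCollection()
            coll.add(sig)
            data_io.write_gmt(coll, sp)
        emit("build_set", sp.name, sp)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("build_set", exc) from exc

    # ---- permute --------------------------------------------------------
    try:
        perm = permutation_test(
            sig, expr_batches, clin_batches, n_perm=config.n_perm,
            seed=_stage_seed(config.seed, "permute"), ssgsea_params=params,
        )
        pp = out / "permutation.json"
        if config.force or not pp.exists():
            pp.write_text(json.dumps(perm.summary(), indent=2))
        emit("permute", pp.name, pp)
    except Exception as exc:
        raise PipelineError("permute", exc) from exc

    # ---- evaluate -------------------------------------------------------
    try:
        reports = {}
        sig_coll = GeneSetCollection()
        sig_coll.add(sig)
        for i, (e, c) in enumerate(zip(expr_batches, clin_batches), 1):
            scores = score_matrix(e, sig_coll, params.with_min_size(1)).es.iloc[0]
            reports[f"batch{i}"] = evaluate_signature(scores, c).to_dict()
        ep = out / "evaluation.json"
        if config.force or not ep.exists():
            ep.write_text(json.dumps(reports, indent=2))
        emit("evaluate", ep.name, ep)
    except Exception as exc:
        raise PipelineError("evaluate", exc) from exc

    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
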