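# synscore

Survival-based gene-set signature discovery for multi-batch transcriptomics,
built around the glioma "synapse score": the single-sample enrichment score
(ssGSEA ES) of a 17-gene synapse-related signature that predicts overall
survival, tracks WHO grade, and separates tumor from normal brain tissue.

The package is for computational biologists who want to (a) apply the
published 17-gene signature to their own expression cohorts, or (b) rerun the
whole discovery pipeline — on their own data or on the bundled synthetic
cohort simulator — to derive and validate a signature from scratch.

## The method

**Scoring.** For each sample, genes are ranked by expression within the
sample (highest → rank *N*, ties broken by gene symbol). The enrichment
score of a gene set *S* (|S| = *m*) is the weighted running-sum statistic

```
ES = Σᵢ [ P_in(i) − P_out(i) ],
P_in(i) = Σ_{j≤i, j∈S} r_j^α / Σ_{j∈S} r_j^α,   P_out(i) = |{j≤i, j∉S}| / (N − m)
```

walked in descending rank order, with weight exponent α = 0.25. Because both
walks are step functions the sum collapses to a closed form over member
ranks, `ES = Σ_S r^(α+1)/Σ_S r^α − (N(N+1)/2 − Σ_S r)/(N−m)`, making scoring
O(m) per set and sample. The ES of the final signature is the synapse score.

**Screening.** Each unit (term ES, single gene, or nested candidate set) is
fit in a Cox proportional-hazards model against overall survival in every
batch separately; Wald p-values are Benjamini–Hochberg adjusted within the
batch across the units screened at that stage; and the per-batch FDRs are
multiplied into a *combined FDR* — a ranking statistic, not an error rate.
Units whose log hazard ratio changes sign between batches are excluded.

**Signature construction.** Genes collected from the top-ranked terms are
screened individually, ordered by ascending combined FDR, and the nested
top-*n* sets (n = 1…G) are scored and screened the same way; the *n*
minimizing the combined FDR is the signature. The candidate signature is
then validated by ranking its combined FDR among thousands of random
equal-size gene sets, and evaluated clinically: median-split Kaplan–Meier
with log-rank, Cox HRs adjusted for WHO grade / IDH mutation / 1p19q
codeletion, Wilcoxon rank-sum across grades, and tumor-vs-normal ROC/AUC.

**Simulator.** A single-factor latent "program activity" per sample drives
a planted gene module, proportional-hazards survival, grade, both molecular
biomarkers, and an elevated-activity normal-tissue group, across batches
with additive batch effects — so every pipeline stage is testable, with
ground truth, without any cohort downloads.

## Worked example

`examples/` contains one short script per capability. Evaluating a
signature score on a simulated cohort (`examples/06_evaluate_signature.py`):

```
log-rank p (median split): 1.36e-12
Cox  none-adjusted: HR=0.0144 (95% CI 0.00532-0.0391), p=7.77e-17, n=300
Cox grade-adjusted: HR=0.0203 (95% CI 0.00705-0.0585), p=5.38e-13, n=300
Cox   idh-adjusted: HR=0.018 (95% CI 0.00628-0.0516), p=7.55e-14, n=300
Cox codel-adjusted: HR=0.0178 (95% CI 0.00605-0.0523), p=2.35e-13, n=300
                 median_a  median_b       p
group_a group_b
II      III        0.1741    0.0781  0.0000
        IV         0.1741    0.0164  0.0000
III     IV         0.0781    0.0164  0.0005
tumor-vs-normal AUC: 0.864
```

HR < 1 under every adjustment means a higher score independently predicts
longer survival (the HR magnitude is per unit of the range-normalized score,
so it is scale-dependent; direction and p are not). The grade medians fall
II > III > IV, and an AUC of 0.86 means a random normal sample outscores a
random tumor sample 86% of the time.

The same pipeline is available from the shell:

```bash
synscore run-all --seed 7 --out-dir run/     # simulate → score → screen →
                                             # build-set → permute → evaluate
synscore score --expr X.gct --sets sets.gmt --out es.tsv
```

The published resources load as `synscore.load_synapse17()` (the 17-gene
signature: PFN1 … IGSF21) and `synscore.load_selected_terms()` (the nine
synapse-related GO term names behind it).

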