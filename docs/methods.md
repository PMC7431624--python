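# Methods

## Single-sample enrichment score

For one sample, genes are rank-normalized: the highest-expressed gene gets
rank score r = N, the lowest r = 1, ties broken by ascending gene symbol so
that results are bit-reproducible across platforms and runs. The enrichment
score of a set S with m of the N genes present is

    ES = Σ_{i=1..N} [ P_in(i) − P_out(i) ]

walking genes in descending rank-score order, where P_in accumulates the
in-set weights r^α (α ≥ 0) and P_out the out-of-set count fraction. Both
running terms are step functions, so the sum reduces exactly to

    ES = Σ_S r^(α+1) / Σ_S r^α − (N(N+1)/2 − Σ_S r) / (N − m),

a function of the member ranks only; `score_matrix` computes this closed
form (O(m) per set per sample), and the test suite verifies it against a
direct position-by-position enumeration to 1e-12. ES is invariant to any
strictly increasing transform of a sample's expression vector, which is why
the readers apply no normalization to incoming matrices beyond recording a
units tag.

Defaults: α = 0.25 and integer-rank weighting, matching the common
single-sample GSEA projection defaults; sets are retained when 10–1,000 of
their genes are present (the screening window), except in the nested-set
builder and signature scoring, where `min_size` is overridden to 1 because
candidate sets start at a single gene. With `normalize="range"` all raw
scores are divided by the global (max − min) of the score matrix; this
rescales Cox hazard ratios but cannot change their direction or p-values,
so reported HR magnitudes for scores should be read as scale-dependent.

## Survival screening and cross-batch combination

Each screened unit is fit by Cox proportional-hazards regression against
overall survival, per batch, complete cases only. P-values are Wald tests
of the score coefficient. Within each batch, Benjamini–Hochberg adjustment
is applied across exactly the family screened at that stage — the terms at
the term stage, the candidate genes at the gene stage, the G nested sets in
the builder, and the candidate-plus-null sets in the permutation test.
The per-batch FDRs are then multiplied into the combined FDR. A product of
FDRs is not itself an FDR; it is used strictly as a ranking statistic, and
no error-rate claim is attached to it. Units whose log hazard ratios
disagree in sign across batches (an HR of exactly 1 counts as
disagreement) are excluded from ranking; ranking ties are broken by the
smaller maximum per-batch p-value and then unit name, so rankings are
deterministic. More than two batches generalize by extending the product
and the all-same-sign rule.

The Cox fits are performed by a package-local Newton–Raphson maximizer of
the Breslow partial likelihood (`synscore.cox`) with step-halving,
column standardization for conditioning, and the observed information for
Wald statistics. The screening and permutation stages fit tens of
thousands of small models, which is why the solver is local and
vectorized; its coefficients, standard errors and p-values are asserted
against lifelines' `CoxPHFitter` in the test suite. Degenerate inputs
(fewer than two events, zero-variance score, non-convergent or monotone
likelihoods, |β| > 50 on standardized inputs) are flagged and the unit is
excluded from ranking rather than reported with an unreliable estimate.

Gene-level screening fits Cox on the gene's per-batch z-scored expression
row. Z-scoring only rescales the HR (direction and p unchanged) and keeps
the Newton steps well-conditioned across platforms. A single-gene
enrichment score is a deterministic monotone transform of the gene's
within-sample rank, so the alternative `gene_score_mode="single_gene_es"`
is retained as a config switch and agrees in direction for clear signals.

## Greedy nested signature construction

Direction-consistent genes are ordered by ascending combined FDR and the
nested prefixes top-1, top-2, …, top-G are scored and screened as sets;
the selected size is the argmin of the combined FDR (ties → smallest n;
`combined_p`, the product of raw per-batch p-values, is reported alongside
and available as the criterion). Finding the best subset is NP-hard; the
nested greedy search is the method of record, and the accompanying
caveat — the same batches are used to rank genes and to evaluate the
nested sets, so the top ranks carry selection luck — is inherent to it.

## Permutation validation

The null is over gene sets: random sets of the candidate's size are drawn
without replacement within a set (sets may overlap each other and the
candidate) from the genes shared by all batches, each receives a combined
FDR through the identical scoring/screening path with BH applied jointly
across candidate and nulls, and the candidate's rank among the nulls is
reported with the add-one empirical p = rank/(n_perm + 1). Ties count
against the candidate — BH's step-up construction produces plateaus of
exactly equal adjusted values, so equal null statistics are placed ahead
of the candidate, and the empirical p can never be zero. Null sets whose
fit fails in any batch are assigned the worst statistic (1.0); a failed
candidate fit is an error. Direction consistency is deliberately not
required of null sets: every null receives a combined FDR.

## Clinical evaluation

Prognosis: samples are split at the cohort median score (scores equal to
the median go to the low group — a side must be chosen, and this one is
documented and tested), Kaplan–Meier curves and the unweighted two-sample
log-rank test come from lifelines, and Cox models adjust the score for WHO
grade (ordinal II=2 / III=3 / IV=4 by default; categorical dummies behind
a switch), IDH status (mutant = 1) or 1p/19q codeletion (codel = 1), one
covariate at a time, complete-case per model so n varies with covariate
completeness. Grading: two-sided Wilcoxon rank-sum between grade groups
with group medians reported so direction is auditable. Diagnosis:
tumor-vs-normal ROC with normal tissue as the positive (higher-scoring)
class; the trapezoidal AUC equals the Mann–Whitney U/(n₁n₂) estimate to
1e-12, and flipping the labels complements it exactly.

## Synthetic cohorts

One latent activity a_s ~ Normal(0, 1) per sample drives everything:

- expression: x_gs = μ_g + shift_gb + λ·a_s·[g planted] + Normal(0, noise_sd),
  with gene baselines μ_g ~ Normal(5, 1) and additive per-gene batch
  offsets shift_gb ~ Normal(0, batch_shift); λ = 1, batch_shift = 0.5.
- survival: T_s ~ Exponential with rate h₀·exp(−β·a_s), β = 0.8 (the
  program is protective: true HR per activity SD = e^−0.8 ≈ 0.45) and
  h₀ = 1/24 events per month (median OS ≈ 17 months at a = 0); a Weibull
  variant sits behind `survival_model="weibull"`. Censoring is an
  independent Exponential whose rate is calibrated by bisection so the
  expected censored fraction matches `censor_rate` (0.3).
- covariates: grade II/III/IV from an ordered logit on −γ·a_s (cutpoints
  ±1), IDH-mutant and 1p/19q-codel from logistic links on +a_s (all link
  strengths 1) — so higher activity means lower grade, IDH-mutant,
  codeleted, and longer survival, one mechanism inducing every
  association at once.
- normal tissue: n_normal samples per batch at activity a + δ (δ = 2) with
  expression only (no survival or tumor covariates), entering the
  diagnostic analyses alone.
- terms: random GO-like sets of 15–40 genes; a designated fraction are
  "enriched", drawing half their members from the planted program.

Default sizes are two batches of 300 tumor + 30 normal samples over 1,000
genes with a 20-gene planted program. `noise_sd = 3` sets each planted
gene's program R² near 10%: single genes are then modest prognostic
markers while the pooled program score is a strong one, which is the
regime multi-gene signature screening exists for (a low-noise setting
makes single genes near-perfect predictors and the greedy search
correctly — but uninformatively — stops at a handful of genes). Generation
is a pure function of (config, seed).

What the simulator does *not* emulate: FPKM library-size mechanics,
probe-level microarray noise, gene–gene correlation beyond the single
factor, copy-number-driven expression (1p/19q acts only through the latent
link), and non-proportional hazards. Passing tests therefore demonstrate
that the pipeline recovers the modeled structure, not that it is robust to
every artifact of real cohorts — rank-based scoring is, however, tested to
be robust to the additive batch effects the model does include.

## Numerical choices and degenerate inputs

- Rank ties: ascending gene symbol; an all-equal expression vector is
  valid (pure tie-break) but logged.
- Duplicate gene rows on load: element-wise median, first-appearance
  order, idempotent.
- ES requires 1 ≤ m < N; sets covering every gene in the matrix are an
  error.
- Newton convergence: max |Δβ| < 1e-9 on standardized inputs, ≤ 100
  iterations with step-halving.
- BH: statsmodels step-up, capped at 1, original order restored.
- Median split: equal-to-median samples to the low group.
- Empirical p: add-one convention, ties unfavorable.
- Pipeline runs fan one top-level seed out to stages through
  `numpy.random.SeedSequence`, and stage outputs are write-once with
  SHA-256 manifests; reruns with the same seed and config are
  bit-identical.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the simulator at the
default scale (two batches × 300 samples × 1,000 genes) for recovery,
permutation (1,000 random sets) and evaluation checks; null-calibration
checks use 150 samples per batch and 200 terms over 10 seeds; the
permutation null-uniformity check uses 500 genes, 500 random sets and 20
seeds. The full suite completes in a few minutes on one CPU.

## Known limitations

- The combined FDR is a heuristic ranking statistic; between-stage
  selection (terms → genes → nested sets) reuses the same cohorts, so the
  selected signature's nominal statistics are optimistic. The permutation
  test is the honest check supplied for exactly this reason.
- HR magnitudes for enrichment scores depend on the score normalization;
  only direction and significance transfer across scalings.
- The greedy builder's selected size is variable when the combined-FDR
  curve is flat in n — nearby n are often statistically indistinguishable.
- No proportional-hazards diagnostics, time-varying covariates, or
  alternative p-combination schemes (Fisher/Stouffer) are provided.
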