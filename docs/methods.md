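# Methods

This note documents the models, numerical choices and limitations behind
`icibiomarkers`. Notation: PreTx = pre-treatment, ICI-4W = after the
four-week ICI-only window; TMC = tumor monocyte content; TMB = tumor
mutational burden (nonsynonymous coding mutations/Mb); CB = clinical
benefit (12 months progression-free survival).

## Normalization

Bulk counts are normalized by the median-of-ratios method: the reference
for gene *g* is its geometric mean across samples, restricted to genes with
no zero count anywhere (the geometric mean vanishes otherwise); the size
factor of sample *j* is the median over those genes of `count_gj / ref_g`.
The log scale used for scoring and differential analysis is
`log2(count/sf + 1)` — a variance-stabilizing stand-in chosen because the
exact transform used by count-model packages is tool-specific, while this
keeps the linear→log contract simple and testable. The linear scale
(`count/sf`) is what deconvolution consumes.

## Differential expression

The paired contrast works on per-patient differences of log-normalized
expression (on-treatment minus pre-treatment), which removes additive
patient effects the way a `~patient + timepoint` design does. Per-gene
variances are moderated with empirical-Bayes shrinkage: a scaled
inverse-chi-square prior `(d0, s0²)` is fitted to the observed variances by
the method of moments on `log s²` (the trigamma-inverse step solved by
Newton iteration), and the moderated t uses
`s²_post = (d0·s0² + d·s²)/(d0 + d)` with `d0 + d` degrees of freedom.
Setting `prior_df=0` recovers the classic paired t exactly (tested against
an independent implementation). This is a deliberate substitution for a
negative-binomial GLM: it preserves the pairing structure and the
moderation spirit while keeping the machinery small enough to verify
against closed forms. Genes are called significant at BH FDR < 0.1; the
same moderation machinery serves the continuous-covariate design
(per-gene regression on a centered, scaled covariate).

The covariate and paired tables share one ordering contract for signature
derivation: ascending FDR, then p, then descending |log fold change|, then
gene ID — fully deterministic.

## Signature scoring and robustness

The per-patient score is the mean signature-gene change divided by the
cohort SD of that mean, without centering, so zero still means "no
change". Reactive/quiescent labels split at the cohort median with ties
assigned reactive (the reactive group holds ⌈n/2⌉ patients); the median
was chosen to mirror the pipeline's other biomarker splits. The
compact-subset sweep adds Gaussian noise (grid of SDs, default
{0.25, 0.5, 1.0} on the log2-change scale) to per-gene changes and keeps
the smallest ranked prefix whose noise-degraded correlation with tumor-size
change retains 90% of the full signature's, with matching sign. The noise
form, grid and 90% retention rule are design choices exposed as
parameters, not assertions about any particular dataset.

## Preranked enrichment

The enrichment score is the extreme of the weighted Kolmogorov–Smirnov
running sum (hit increment ∝ |stat|^p with p = 1 by default, miss decrement
1/(N−|S|)). The null is gene permutation: random same-size sets drawn
without replacement from the ranked universe. p-values condition on the
sign of the observed ES with the +1 correction, so the smallest attainable
p is 1/(n_perm+1); NES divides by the mean |ES| of the same-sign null pool
(the original two-pool normalization — the multilevel/adaptive refinement
of modern implementations is out of scope). With 10-gene toys the
permutation p is verified against exhaustive enumeration of all C(10,3)
null sets.

## Deconvolution and TMC

Reference profiles are per-cell linear-normalized expression (each cell
scaled to the mean library size) averaged within cell type; per-type RNA
content `s_k` is the mean library size of the type's cells. The gene list
is the `top_n = 3000` most variable genes (variance of log1p-normalized
expression) after removing confounder classes — mitochondrial, ribosomal,
sex-specific and TCR/BCR variable-region genes — matched by configurable
ID-pattern lists, since only the classes, not the lists, are canonical.
Types under 10 cells (or named rare types) are excluded.

The implemented method is non-negative least squares of each bulk sample on
the profiles over the selected genes, coefficients renormalized to sum 1
(= RNA fractions). The method registry in the benchmark harness keeps the
comparison protocol intact for any alternative algorithm; a Bayesian
malignant-cell-aware method is deliberately out of scope because the
contribution here is the benchmark protocol and the TMC readout, not a new
solver. Cell fractions are `f_cell,k ∝ f_rna,k / s_k`. Benchmarks report
per-sample Spearman ρ across types and NRMSE = RMSE / (max−min of the
predicted vector), against both truth scales; constant predictions are
recorded as missing rather than scored.

TMC is the monocyte fraction, RNA scale by default (that is the scale the
spike-in validates; both scales are produced because the published readout
does not pin one down). Zeros are floored at half the smallest nonzero
fraction before log10 so median splits stay well defined. Compartment
clustering log10-transforms, column-Z-scores and applies Ward
minimum-variance linkage; merge heights are oracle-tested against a naive
O(n³) Lance–Williams implementation.

## Genomic rules

Variants are keyed on (chrom, pos, ref, alt) after trimming shared allele
suffixes then prefixes (the matching rule across callers is otherwise
unspecified); consensus keeps records supported by ≥ 2 of 3 callers. TMB
is flagged-mutation count / 35.6 Mb per biopsy, averaged across a
patient's biopsies. MSI is score ≥ 3.5 (boundary inclusive). Copy-number
classes: amplified if copies > 2·ploidy, deleted if the loss exceeds half
the baseline with baseline interpreted as ploidy (the alternative — a
gene-specific baseline — is not recoverable from the rule's wording), else
neutral. Consequence annotation (the nonsynonymous-coding flag) is an
upstream input.

## Outcomes and survival

Response bookkeeping: best change ≤ −30% ⇒ responder (irCR at −100%),
any change ≥ +20% or unequivocal new lesions ⇒ irPD, clinical progression
without scans ⇒ irPD, otherwise irSD; the irNN corner case maps to irSD.
CB requires 12 progression-free months; early censoring without
progression is "not assessable", and an exclusion list is supported. Cox
fits use Efron tie handling (switchable to Breslow via an independent
implementation), Wald intervals, and covariates optionally
log10-transformed then scaled and centered. Median survival is the
earliest time with S(t) ≤ 0.5. Median splits send values exactly at the
median to "low" so "high" strictly exceeds the median. The cell-type
screen BH-corrects univariable Cox p-values across all tested types.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

- **Counts** are gamma-Poisson (negative binomial), variance μ + μ²/θ with
  θ = 2 — a standard single-cell parameterization. Each of 6 cell types
  (malignant "EAC", "Monocyte" with a 10:1 classical:non-classical subtype
  split, "T_NK", plus stromal/immune fillers) boosts its 40 marker genes
  8-fold over a lognormal baseline of 2000 genes; per-cell library sizes
  vary lognormally (σ = 0.35) and per-type RNA content spans 0.6–1.8× with
  malignant cells richest, so the RNA- and cell-fraction scales genuinely
  differ.
- **Pseudobulk samples** draw purity uniformly from [0.2, 0.9], split the
  residual over non-malignant types by a symmetric Dirichlet, sample 500
  cells multinomially and sum their counts; sampled cell IDs are logged so
  every truth quantity is recomputable.
- **Cohorts** (default n = 38, the trial's intention-to-treat size) draw
  TMC logit-normal (median ≈ 8%, range ≈ 1–30%) independent of TMB
  (log10-normal, median ≈ 3 muts/Mb, near the trial's CB/NCB medians of
  4.3/2.1). On-treatment samples multiply T/NK marker counts by 2^δ with
  δ ~ N(1, 0.4) for responders (Bernoulli 0.45) and N(0, 0.4) otherwise,
  kept integer by Poisson resampling. Tumor-size change is
  −25δ − 10·z(log10 TMC) + N(0, 15) percent.
- **Survival** is exponential under proportional hazards,
  `h = h0·exp(−a·z(log10 TMC) − b·z(TMB))` with a = 0.97 and b = 0.69 —
  the log-hazard magnitudes matching hazard ratios of 0.38 and 0.50 per SD
  — and h0 = 0.05/month (OS) and 0.076/month (PFS), putting baseline
  medians near 13.9 and 9.1 months. Censoring is independent exponential
  calibrated to censor ≈ 20% of average subjects. A Uniform(0, T)
  censoring time was rejected: it conditions on the subject's own event
  time (informative censoring) and measurably biases Cox recovery, making
  parameter-recovery checks ill-posed.

What the generator does **not** model: batch effects, ambient RNA,
doublets, dissociation artifacts, gene-gene correlation beyond cell-type
structure, non-proportional hazards, or dependent censoring. Passing
recovery tests therefore show the pipeline's statistics are correct under
their own assumptions — not that those assumptions hold in any real
cohort.

## Problem sizes and numerical notes

Acceptance-level simulations use 200-patient cohorts (50 replicates for
Cox coverage, 20 seeds for signature recall, 50 noisy spike-in series) and
an 80-sample pseudobulk benchmark — sizes chosen so the whole suite runs
comfortably on a single CPU while keeping Monte-Carlo error well below the
margins being tested. NNLS is scale-invariant (fractions unchanged under
positive rescaling of a sample); exact mixtures of linearly independent
profiles are recovered to residual < 1e-8; the RNA↔cell fraction
conversion round-trips to 1e-12. Degenerate inputs fail loudly: all-zero
samples, zero cohort SD, constant covariates, empty gene intersections and
non-positive survival times are errors, not silent NaNs.

## Known limitations

- The DE engine is a moderated paired/linear-model t on log-normalized
  data, not a count GLM; very low counts are handled by the +1 offset
  rather than a mean-variance model.
- The gene-permutation GSEA null ignores inter-gene correlation;
  p-values are granular below 1/(n_perm+1).
- NNLS ignores cell-type expression heterogeneity within types and has no
  malignant-cell model; it serves as the reference method for the
  benchmark harness, not as a best-in-class deconvolver.
- CB determination implements only the 12-month PFS criterion plus an
  exclusion list; any additional centralized-review rules are not
  representable.
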