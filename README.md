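# icibiomarkers

Biomarker analysis for immune-checkpoint-inhibitor (ICI) trials in
gastro-esophageal cancer — built around the setting of a first-line trial in
inoperable esophageal adenocarcinoma where a four-week ICI-only window
(ICI-4W) precedes immunochemotherapy, with paired tumor biopsies before and
after that window.

The package implements, as a tested and reusable pipeline:

- **On-treatment T/NK signature.** Paired pre-/on-treatment differential
  expression on log2 median-of-ratios-normalized counts, controlling for
  patient effects, with empirical-Bayes variance moderation
  (`s²_post = (d₀s₀² + d s²)/(d₀+d)`, moderated t with d₀+d df). The
  signature is the top-70 genes at FDR < 0.1; the per-patient score is the
  mean signature-gene change divided by the cohort SD (scaled, without
  centering). Patients split at the median score into signature-reactive /
  -quiescent, and a noise-robustness sweep selects a compact subset.
- **Preranked GSEA** against moderated-effect or correlation rankings:
  weighted Kolmogorov–Smirnov enrichment score, gene-permutation null,
  `p = (1+#{|ES_null| ≥ |ES|, same sign})/(1+#same sign)`,
  `NES = ES / mean|same-sign null ES|`, BH correction across sets.
- **Reference-based deconvolution and tumor monocyte content (TMC).**
  Cell-type profiles from a labeled single-cell atlas (3000 most variable
  genes, confounder gene classes removed), non-negative least squares on
  linear-scale normalized expression, RNA-fraction → cell-fraction
  conversion via per-type RNA content
  (`f_cell,k ∝ f_rna,k / s_k`), a pseudobulk ground-truth benchmark
  (Spearman ρ and NRMSE = RMSE / range of predictions, both scales), Ward
  clustering of the phagocytic compartment, and spike-in validation of the
  TMC readout.
- **Genomic biomarkers.** 2-of-3 caller consensus filtering; TMB =
  nonsynonymous coding mutations per Mb over a 35.6 Mb coding space with
  multi-biopsy averaging; MSI at score ≥ 3.5; amplification (> 2× ploidy)
  and deletion (loss of more than half the baseline copies) calls.
- **Outcomes and survival.** Immune-related RECIST bookkeeping (response =
  −30% target-lesion shrinkage, progression = +20% or new lesions),
  clinical benefit (CB) = 12 months progression-free, Kaplan–Meier,
  log-rank, Cox proportional hazards (Efron ties; covariates
  log10-transformed, scaled and centered), per-cell-type Cox screening with
  BH correction, median splits and TMB×TMC quadrant analysis, and the
  two-proportions z-test.
- **Synthetic cohorts.** A generator producing every input with ground
  truth: negative-binomial single-cell counts with marker structure,
  pseudobulk mixtures with known RNA/cell fractions, paired cohorts with
  responder-specific T/NK upregulation, tumor-size changes coupled to
  signature induction and TMC, and proportional-hazards survival in scaled
  log10(TMC) and TMB.

## Worked example

```python
import pandas as pd
from icibiomarkers import (
    SimulationConfig, simulate_single_cell_reference, simulate_cohort,
    normalize_log, paired_differential_expression, derive_signature,
    score_signature_change, build_reference, deconvolve_nnls,
    normalize_linear, extract_tmc, cox_fit,
)
from icibiomarkers.datatypes import PRETX, ON_TREATMENT

cfg = SimulationConfig(seed=7)                       # 38-patient paired cohort
ref = simulate_single_cell_reference(cfg)            # 1200-cell labeled atlas
counts, outcomes, truth = simulate_cohort(cfg, ref)

log = normalize_log(counts)
de = paired_differential_expression(log)             # ~patient-paired contrast
sig = derive_signature(de, k=70)
pre = log.subset_samples(log.samples.index[log.samples.timepoint == PRETX])
on = log.subset_samples(log.samples.index[log.samples.timepoint == ON_TREATMENT])
scores = score_signature_change(pre, on, sig)
print(len(sig), round(scores.corr(-outcomes.size_change_pct), 2))

comp = deconvolve_nnls(normalize_linear(counts), build_reference(ref))
tmc = extract_tmc(comp).loc[pre.sample_ids, "tmc"]
df = pd.DataFrame({"time": outcomes.os_time, "event": outcomes.os_event,
                   "tmc": tmc.values, "tmb": outcomes.tmb})
print(cox_fit(df, ["tmc", "tmb"], log10_transform=["tmc"])["hr"].round(2))
```

Output:

```
46 0.6
covariate
tmc    0.47
tmb    0.55
Name: hr, dtype: float64
```

At this seed 46 genes pass FDR < 0.1 (the signature truncates below k = 70
with a warning), the signature score tracks on-treatment tumor shrinkage
(r = 0.6 with the negated size change), and the multivariable Cox fit
recovers protective hazard ratios per SD for both deconvolution-assessed
TMC and TMB — at this small trial-size n the point estimates scatter around
their generative values (HR 0.38 and 0.50 per SD).

A `icibiomarkers` command-line tool exposes the same stages
(`simulate`, `signature`, `gsea`, `deconv`, `genomics`, `survival`).

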