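# chondroprofiler

Integrated immune–molecular profiling of chondrosarcoma cohorts.

Chondrosarcoma (ChS) is a rare cartilage-forming bone malignancy graded
G1–G3, with dedifferentiated chondrosarcoma (DD) as its most aggressive
form. Advanced disease has no effective systemic therapy, so identifying
which patients carry a targetable immune context (checkpoint expression,
tertiary lymphoid structures) or a targetable mutation (IDH1/2) is a
central translational question. `chondroprofiler` implements the full
analysis chain used to answer it:

1. **Immunophenotyping** — 20 IHC immune-marker densities (cells/mm²) per
   central and peripheral tumor region are log-transformed, z-scored and
   clustered hierarchically (Ward D2 on Euclidean distances). The number
   of clusters k is chosen by majority vote over nine validity indices,
   and cluster stability is quantified with B bootstrap resamples compared
   by the adjusted Rand index (ARI). Clusters are named by total immune
   density: IMP1 "cold" < IMP3 "intermediate" < IMP2 "hot".
2. **Somatic-variant consensus cascade** — per-sample call sets from three
   caller dialects (TS, GATK/Mutect2, IR) are quality-filtered
   (SNP/MNP: DP ≥ 15, AF ≥ 0.015, TLOD ≥ 14; INDEL: DP ≥ 70,
   0.35 ≤ AF ≤ 0.55), merged as (TS ∩ GATK) ∪ IR, cleaned against a
   pool-of-normals, post-filtered (AF ≥ 0.05, DP ≥ 50) and reduced to
   pathogenic calls (VEP impact/ClinVar, SIFT ∧ PolyPhen-2 or
   AlphaMissense, 1000 Genomes AF ≤ 0.05, ≥ 5 alt reads with ≥ 2 per
   strand). TMB = final variants / 1.7 Mb panel.
3. **Cohort statistics** — exact gene-by-subtype tests with
   Benjamini–Hochberg FDR, Kruskal–Wallis TMB comparisons, pairwise
   mutation co-occurrence, and pathway-level deregulation summaries.
4. **Survival** — Kaplan–Meier and log-rank by stratum; univariate Cox
   screening of gene flags; a LASSO-penalized Cox model over all clinical,
   immune and molecular covariates with 10-fold cross-validation, the
   one-standard-error λ, and an unpenalized refit of the selected set that
   yields hazard ratios (HR) with Wald confidence intervals.
5. **Immunograms** — six-axis per-patient radar scores (suppressive-cell
   density, IDH1 status, TMB status, PD-L1 presence, remaining-marker
   density, checkpoint density).

Because the underlying patient data are not redistributable, the package
ships a synthetic-cohort generator (`chondroprofiler.synth`) that emulates
the study's statistical structure — three latent immunophenotypes,
grade-dependent mutation frequencies, caller outputs with tagged
contaminants, and proportional-hazards survival with known effect sizes —
so every stage can be validated against ground truth.

## Worked example

```bash
chondroprofiler run-all --out run --seed 3
```

simulates a 99-patient cohort and runs every stage. Selected outputs from
this exact command:

* `run/stability.json` — k selection and bootstrap stability:
  `{"k": 3, "B": 1000, "mean_ari": 1.0, ...}`: the index vote found three
  immunophenotypes and the clustering is perfectly stable under
  resampling (mean ARI 1.0 over 1000 bootstrap iterations).
* `run/tmb.csv` — per-sample TMB; this cohort's median is 2.35 mut/Mb
  (4 retained variants / 1.7 Mb).
* `run/gene_subtype_tests.csv` — IDH2 (q = 0.0001) and TP53 (q = 0.003)
  prevalences differ across histological subtypes; flat-frequency genes do
  not.
* `run/final_model.json` — LASSO-selected covariates with refit hazard
  ratios, e.g. in this cohort

  | covariate  | HR   | 95% CI       | p      |
  |------------|------|--------------|--------|
  | subtype_DD | 28.9 | 9.0–92.7     | <0.001 |
  | imp_IMP2   | 2.3  | 1.2–4.7      | 0.016  |
  | IDH1       | 6.1  | 3.1–11.9     | <0.001 |

  i.e. dedifferentiated histology, the "hot" immunophenotype and IDH1
  mutation are selected as independent negative prognostic factors in
  this simulated cohort (single-cohort estimates scatter around the
  configured truths HR 3.3 for IMP2 and 3.8 for IDH1).
* `run/immunograms.csv`, `run/imp_profiles.csv` — per-patient radar axes;
  the IMP2 group mean dominates IMP1 on every density axis, and the cold
  IMP1 group shows no PD-L1 positivity at all.

Every stage can also be run individually (`chondroprofiler simulate`,
`cluster`, `variants`, `stats`, `survive`, `immunogram`), and
`chondroprofiler validate` schema-checks input files. All thresholds are
named keys in a YAML config (`--config`).

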