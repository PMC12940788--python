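# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `chondroprofiler`. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Immunophenotype discovery

Densities (cells/mm², 20 markers × 2 regions) are transformed
`log(1 + x)` and z-scored per feature before clustering; the study's
heatmaps display densities on a log scale, and z-scoring prevents
high-abundance markers from dominating the Euclidean metric. Patients
missing more than 25% of features are excluded; remaining gaps are
imputed with the feature median on the log scale (both logged). A
constant feature keeps scale 1 (with a warning) instead of dividing by
zero.

Clustering is agglomerative Ward D2 (scipy linkage on the raw
observations, which applies the Lance–Williams D2 update to Euclidean
distances). Merge ties are resolved by scipy's first-found rule, so
results are deterministic given row order.

**k selection.** Nine validity indices each nominate one k in
[k_min, k_max] from the same Ward tree: Calinski–Harabasz, silhouette,
Davies–Bouldin, Dunn, C-index, McClain–Rao, point-biserial, the gap
statistic (uniform bounding-box reference, B = 50), and Hartigan's rule
(smallest k with H ≤ 10). The winner is the majority vote, ties broken
toward the smaller k. A known caveat, verified by direct evaluation in
the tests: on data with *no* cluster structure the reference-free ratio
indices drift toward k_max, and only the null-referenced indices (gap,
Hartigan) and Dunn indicate k_min, so the ensemble is informative for
choosing among real structures rather than for testing whether structure
exists at all.

**Stability.** Each of B (default 1000) bootstrap iterations resamples
patients with replacement, re-runs preprocessing and Ward clustering at
fixed k on the resample, and computes the ARI against the original
labels restricted to the distinct resampled patients (first occurrence
per patient — the duplicate-handling rule is unstated in the field's
common protocol, and first-occurrence keeps the comparison one-to-one).
Resamples with fewer than k distinct patients are skipped and logged.

The ARI is computed from the contingency-table formula
(Σ C(n_ij,2) − E)/(M − E); the paired region comparison is a two-sided
Wilcoxon signed-rank test (exact for small n) with Benjamini–Hochberg
correction — a paired nonparametric test consistent with the rest of the
nonparametric toolkit; correlation maps use Spearman's rho with midranks
and BH adjustment over the strict upper triangle.

Cluster naming is by mean total raw density: lowest IMP1 ("cold"),
highest IMP2 ("hot"), middle IMP3 ("intermediate"); for k ≠ 3 clusters
are named IMP1..IMPk in density order with a warning. Equal means are
broken by cluster index (logged).

## Variant cascade

The cascade consumes caller *outputs* (VCF 4.2 with DP/AF/TLOD, strand
support and annotation INFO keys), never reads. Branch rules, all bounds
inclusive:

* GATK branch — SNP/MNP kept iff DP ≥ 15 ∧ AF ≥ 0.015 ∧ TLOD ≥ 14;
  INDEL kept iff DP ≥ 70 ∧ 0.35 ≤ AF ≤ 0.55. Records missing a needed
  quality field are rejected with reason `missing_quality_field`.
* TS branch — no per-variant thresholds; the TS criteria are run-level
  QC (chip loading ≥ 80%, polyclonality ≤ 30%, uniformity ≥ 80%, ≥ 10 M
  reads, coverage ≥ 1000×) implemented as sample-admission checks.
* IR branch — minimum AF 0.05.
* Merge — (keys(TS) ∩ keys(GATK)) ∪ keys(IR) on (chrom, pos, ref, alt);
  provenance is unioned and field values follow precedence
  GATK > TS > IR because GATK supplies TLOD and strand counts needed
  downstream.
* Pool-of-normals subtraction, then post-filtration AF ≥ 0.05 ∧ DP ≥ 50.
* Pathogenicity: drop LOW-impact ∧ ClinVar-benign; keep only
  (SIFT deleterious ∧ PolyPhen-2 damaging) ∨ AlphaMissense pathogenic
  (all three absent → dropped as `unclassifiable`); drop 1000 Genomes
  AF > 0.05; drop < 5 alt reads or < 2 on either strand.

Deamination policy: a sample with deamination score in [10, 25] or
preliminary TMB in [11, 50] mut/Mb switches to strict thresholds — IR AF
floor 0.10, the GATK SNP/MNP AF floor replaced by `strict_gatk_snp_af`,
and the annotation profile flag flips from "Oncomine Extended" to
"Oncomine Variants". The strict GATK AF default is the published 0.75;
the value is surprisingly high for a floor (0.075 would be a more
plausible variant-calling threshold) and is therefore an exposed
configuration knob rather than a hard-coded constant. Samples with
deamination score above 25 fail admission outright.

Every removal is attributed to the first stage that eliminated the key;
the ledger stages partition (input − final) and this is asserted on
every cascade run. TMB is exactly `len(final) / panel_size_mb` with the
1.7 Mb panel default. CNV events are consumed as a table and only
summarized (counts by subtype and type, fraction of patients with ≥ 1
event); a gene counts as "mutated" in the cohort matrix if it carries a
retained small variant or a CNV event.

Normalization trims shared allele context and left-aligns INDELs through
repeat sequence against a supplied reference (vt-style loop); pure
trimming needs no reference, left-shifting without one raises.

## Cohort statistics

Gene-by-subtype tests use a two-sided exact test on the 2 × c
contingency table: the p-value is the total probability of tables with
the observed margins whose probability does not exceed the observed
table's (for 2 × 2 this reproduces the classical two-sided Fisher
test). The 2 × c case is enumerated vectorized; r × c falls back to
recursive enumeration. BH correction runs across tested genes (default
prevalence floor: mutated in ≥ 3 patients). TMB comparisons use the
tie-corrected Kruskal–Wallis H (H = 0, p = 1 when all values are tied);
co-occurrence uses pairwise 2 × 2 Fisher tests with direction from the
odds ratio. The pathway map ships as an editable CSV
(`chondroprofiler/data/pathway_map.csv`); genes missing from the map are
excluded and reported.

## Survival

Kaplan–Meier uses the product-limit estimator (lifelines); the median is
the earliest time with S ≤ 0.5, NaN when never reached. The log-rank
test is the k-sample observed-minus-expected statistic.

Cox regression maximizes the Efron-tie-corrected partial likelihood
(lifelines Newton iterations, then a BFGS polish against this package's
own score function until the gradient's largest component is below
1e-6). Efron handling was chosen because month-scale times produce ties.
Wald CIs are exp(β ± 1.96 se). Monotone likelihood (perfect separation)
is flagged and refit with a small ridge penalty so a bounded coefficient
is still reported.

LASSO-Cox: covariates are standardized internally; the L1 path (100
log-spaced λ values from the all-zero λ_max, glmnet-style coordinate
descent via scikit-survival's Coxnet, Breslow ties on the path) is
cross-validated with event-stratified, seeded 10-fold assignment using
the Verweij–van Houwelingen partial-likelihood deviance
−2·(pl_all(β₋k) − pl₋k(β₋k)). λ_1se is the *largest* λ whose CV loss is
within one standard error of the minimum (the parsimony reading of the
one-SE rule). Covariates with nonzero coefficients at λ_1se are refit by
unpenalized Cox regression; reported HRs and CIs come from that refit,
since penalized point estimates alone do not yield confidence intervals.
Reference levels for categorical covariates: G1 (subtype), axial (site),
R0 (margins), IMP1, F (sex). Fewer events than folds reduces the fold
count with a warning.

A quantified caveat, measured by the recovery experiments: at the study's
size (n = 99, ~70 events, strongly correlated covariates — the "hot"
phenotype concentrates in high-grade tumors), the partial-likelihood MLE
overestimates large log-hazards by roughly 10–15%, and conditioning on
LASSO selection adds a few points more. The acceptance experiments
measure exactly this estimator, so recovered geometric-mean HRs sit above
the configured truths by about that margin; the same behavior applies to
any real cohort of this size analyzed with this workflow.

## Immunograms

Six axes per patient, density axes min–max normalized across the cohort
(the radar scale is not standardized in the field; min–max makes axes
comparable and affine-invariant): a1 mean of Foxp3/CD163/CD68[KP1]
densities (both regions); a2 = 1 iff IDH1-mutant; a3 = 1 iff TMB above
the cohort median (a binarization choice — "TMB status" has no standard
cutoff at panel scale); a4 = 1 iff PD-L1 ordinal score ≥ 1 (scale: 0 if
< 1% positive cells, 1 if 1–30%, 2 if ≥ 30%); a5 mean of all markers not
on axes 1/6, excluding the PD-L1 density stain because axis 4 already
encodes PD-L1; a6 mean of TIM-3/LAG-3/Gal-9/PD-1 densities.

## Synthetic cohort generator

The generator defines the study conditions; all downstream validation is
parameter recovery against it.

* **Composition.** 99 patients; subtypes G1/G2/G3/DD with probabilities
  28/99, 37/99, 24/99, 10/99. Immunophenotype given subtype follows a
  fixed mixture in which IMP1 dominates G1 (80%) and IMP2 dominates DD
  (80%), matching the qualitative prevalence pattern of the phenotypes.
* **Densities.** Log-normal per (marker, region, IMP) with a two-factor
  covariance (macrophage and T-cell factors). The phenotype means are
  deliberately non-collinear: IMP2 is high on all markers, IMP3 is
  lymphoid-rich but myeloid/checkpoint-poor, IMP1 is low everywhere with
  its lymphoid infiltrate shifted to the tumor periphery. Factor
  loadings put Spearman rho between CD68 and CD163 central densities
  above 0.9. PD-L1 percent-positivity occurs only in IMP2/IMP3 with high
  values concentrated in DD; jointly positive TLS component flags occur
  only in G2/G3/DD with a non-cold phenotype. Marker dispersions are
  free parameters (the study reports none); they were chosen once so
  that the three phenotypes are recoverable by the clustering stage —
  real cohorts are noisier, so passing recovery tests demonstrates
  correctness of the machinery, not expected field performance.
* **Mutations.** IDH1 and IDH2 are a single mutually exclusive
  categorical draw with grade-dependent probabilities summing to the
  41% combined frequency (IDH1 ≈ 31%, IDH2 ≈ 10%, IDH2 absent in G1);
  TP53 is grade-dependent (absent in G1, 16% overall); RNF213/TAF1/MN1
  and the remaining panel genes have flat frequencies. TP53 and UBR5
  co-occur with IDH1, PTCH1 with IDH2, via odds multipliers that
  preserve the marginal frequencies. Retained-variant counts follow a
  negative binomial (r = 1.1, p = 0.1646) calibrated so the cohort
  median retained count is 4, i.e. median TMB 4/1.7 ≈ 2.35 mut/Mb, with
  a right tail allowing counts near 57 (TMB ≈ 33.5).
* **Caller sets.** True variants appear in TS and GATK with fields
  passing every threshold in force for the sample (a random half also in
  IR); seven contaminant classes are injected (default 2 each): GATK
  quality failures, INDELs outside the AF window, pool-shared germline
  records (also written to the pool set), LOW/benign annotations,
  1000-Genomes-common records, strand-biased records, and
  post-filtration AF failures — the last class is an addition so that
  the post-filter stage is exercised. Each contaminant carries the stage
  expected to remove it; for strict-policy samples, SNP/MNP contaminants
  below the strict GATK AF floor are tagged to the GATK stage since the
  raised floor catches them first. CNV events are placed on panel genes
  outside the configured driver set so the configured mutation
  frequencies remain exact; carrier probability by subtype averages
  26.4% with a mean of ~5.9 events per carrier (~156 events per cohort).
* **Survival.** Exponential proportional hazards per patient:
  λ = exp(c_subtype + c_IMP + log(3.8)·IDH1 + log(1.07)·(size−7 cm)),
  with c_IMP2 = log 3.3 fixed. The four subtype baselines and the IMP3
  coefficient are solved by weighted least squares so the *marginal*
  mixture survival matches the seven anchors (3-year OS 91.3/77.3/40.7/
  11.4% by subtype; 5-year OS 86/29/44% by IMP). Seven anchors constrain
  five parameters, so the fit is a compromise; residuals stay within
  ±0.02 (asserted in tests). The exponential form makes single-stratum
  calibration closed-form (λ = −ln S(t)/t). A consequence of the anchor
  system worth noting: conditional on subtype and size, the IMP3
  coefficient exceeds IMP2's even though IMP3's marginal survival is
  better — a Simpson-type inversion caused by IMP2 concentrating in DD.
  Censoring is independent (rate 0.30, exponential with 60-month mean
  when censored — a realistic follow-up horizon for a retrospective
  sarcoma cohort); tumor size is log-normal per subtype (5–9.5 cm
  medians). Size effect log(1.07)/cm keeps size a modest but real
  prognostic factor.
* **Determinism.** One seed feeds per-component child streams
  (SeedSequence spawn), so outputs are bit-reproducible and each block
  (clinical, densities, variants, survival) is unchanged by disabling the
  others.

## Problem sizes

The recovery experiments use 50 seeds for k selection, 200 cohorts for
hazard-ratio recovery, 100 for the Kaplan–Meier anchors, ≥ 500 samples
for cascade separation, 20 for TMB and 50 for mutation frequency — sizes
at which the Monte-Carlo error of each average is small relative to its
tolerance. The end-to-end pipeline example runs a single 99-patient
cohort with B = 1000 bootstrap iterations.

## Known limitations

* The generator emulates caller output, not sequencing: no read-level
  error model, no real annotation lookups, and contaminants are clean
  single-rule violations rather than the correlated messiness of FFPE
  artifacts.
* Validity-index behavior on structureless data (drift to k_max for the
  ratio indices) means k selection should be read as "best among
  candidate structures", not a test for the existence of clustering.
* The exact 2 × c test enumerates tables; for cohorts far larger than a
  few hundred patients a network algorithm or simulation would be
  preferable.
* Visual review steps of the original workflow (dbSNP-novel INDEL
  inspection) are replaced by the codified read-support rule; proprietary
  annotation-profile contents ("Oncomine Extended/Variants") are modeled
  only as a named flag.
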