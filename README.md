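# edsig

Discovery and scoring of blood transcriptomic signatures in pulmonary
hypertension (PH) cohorts.

Gene expression profiling of peripheral blood mononuclear cells (PBMCs) can
expose disease processes without a biopsy. In PH — including idiopathic
pulmonary arterial hypertension (IPAH) and scleroderma-associated disease
(SSc-PAH, SSc-PH-ILD) — a correlated module of erythroid-maturation genes
(ALAS2, AHSP/ERAF, hemoglobin genes, …), the *erythroid differentiation
signature* (EDS), appears in the PBMC fraction of a subset of patients,
plausibly reflecting immature red-cell precursors recruited under chronic
hypoxia. `edsig` implements the full analysis workflow that finds such
signatures, scores them in new datasets, and relates them to hemodynamic
disease severity — together with a seeded synthetic cohort generator so
every stage is testable without any data download.

## What the package computes

* **Preprocessing** — per-sample scaling of bead-array intensities to
  median 256 (2⁸), log₂ transform, restriction to probes detected
  (detection p < 0.01) in ≥ 1 sample with a gene symbol, and the two
  z-transformations used downstream (within-sample columns; across-sample
  rows).
* **Differential expression** — a probe is significant between groups when
  (i) the two-sided Welch t-test gives p ≤ 0.01, (ii) the Benjamini–
  Hochberg FDR gives q ≤ 0.1, and (iii) the fold change of geometric means
  is ≥ 1.5 or ≤ 1/1.5; a probe is tested at all only if ≥ 80% of samples
  in the higher-expressing group detect it (p < 0.01). Venn partitioning
  of significant gene lists across contrasts.
* **Signature discovery** — complete-linkage hierarchical clustering of the
  500 most variant probes under uncentered (cosine) correlation; seed
  clusters are expanded to all probes with Pearson r ≥ 0.7 against the
  cluster centroid (the per-sample mean of seed-probe log₂ values), and the
  top members by centroid correlation become single-gene surrogate
  biomarkers.
* **Gene-set enrichment (PAGE)** — a set of effective size m scores
  Z = (S̄ₘ − μ)·√m / δ, with μ, δ the mean and SD of the per-gene metric
  (z-ratio for internal contrasts, simple difference of mean log₂ for
  external data), p from the standard normal; plus the per-sample
  "landscape" variant in which each sample's row-normalized expression
  vector is the metric, giving a sets × samples score matrix averaged by
  group.
* **Clinical association** — Pearson correlation of a surrogate biomarker
  with RAmean, CI, PVRI and PA saturation, tested with
  t = r·√(n−2)/√(1−r²) (df = n−2), within a 120-day
  catheterization-to-blood-draw window; 84% t-based confidence intervals
  for group means; cardiac-index dichotomization at 2.2 L/min/m²; and
  2^−ΔΔCt relative quantification for qPCR validation.
* **Synthetic cohorts** — five subject groups (41 controls, 19 SSc, 30
  IPAH, 42 SSc-PAH, 8 SSc-PH-ILD), 20 000 probes, planted correlated
  modules (EDS, platelet, immune up/down, neutrophil, sex-linked) with
  group-specific penetrance and graded amplitudes, Illumina-style detection
  p-values, and hemodynamics coupled to EDS amplitude in IPAH (r ≈ 0.78
  for RAmean) but decoupled in SSc-PAH.

## Worked example

```python
from edsig import (CohortConfig, generate_cohort, median_scale, log2_transform,
                   expressed_probe_filter, zscore_within_sample, zscore_across_samples,
                   rank_by_variance, hierarchical_cluster, extract_seed_clusters,
                   signature_centroid, expand_signature, biomarker_hemodynamics)

matrix, clinical, truth = generate_cohort(CohortConfig(seed=7))
prep = log2_transform(median_scale(matrix))
prep = prep.subset_probes(expressed_probe_filter(prep))
print(f"expressed probes: {prep.n_probes} / {matrix.n_probes}")

row_z = zscore_across_samples(zscore_within_sample(prep))
top = rank_by_variance(prep.values, k=500)
link, _ = hierarchical_cluster(row_z.loc[top])
clusters = extract_seed_clusters(row_z.loc[top], link, min_size=20, max_clusters=6)
print("seed clusters:", [(len(c), round(c.mean_correlation, 2)) for c in clusters])

eds_seed = clusters[3]   # the cluster dominated by erythroid probes
model = expand_signature(prep.values, signature_centroid(prep.values, eds_seed.probes),
                         r_min=0.7, name="EDS")
n_probes, n_genes = model.gene_counts(prep.probe_annotations)
print(f"expanded EDS: {n_probes} probes / {n_genes} genes")
for probe, r in model.surrogates.items():
    print(f"surrogate {prep.gene_symbol(probe)}: r = {r:.3f}")

table = biomarker_hemodynamics(prep, "ALAS2", clinical,
                               ["RAmean", "PVRI", "PA_sat", "CI"], "IPAH")
print(table.round(3).to_string(index=False))
```

Output:

```
expressed probes: 14000 / 20000
seed clusters: [(272, 0.67), (96, 0.69), (69, 0.66), (33, 0.8), (29, 0.7)]
expanded EDS: 169 probes / 169 genes
surrogate EDSG032: r = 0.930
surrogate EDSG125: r = 0.924
covariate group  n      r      t  df     p
   RAmean  IPAH 12  0.843  4.958  10 0.001
     PVRI  IPAH 12  0.861  5.348  10 0.000
   PA_sat  IPAH 12 -0.638 -2.621  10 0.026
       CI  IPAH 12 -0.467 -1.671  10 0.126
```

Reading it: 14 000 of 20 000 probes pass the detection/symbol filter; the
33-probe seed cluster (mean pairwise r = 0.80) is the erythroid module, and
centroid expansion at r ≥ 0.7 recovers all 169 planted EDS probes; the two
strongest members correlate with the centroid at r ≈ 0.93. Among the 12
IPAH subjects with catheterization within 120 days of the blood draw,
surrogate (ALAS2-analog) expression correlates positively with right-atrial
pressure and vascular resistance and negatively with PA saturation, while
cardiac index (planted at the weakest coupling) does not reach
significance — the severity pattern the analysis is designed to expose.

## Command line

`edsig simulate | preprocess | de | discover | enrich | clinical |
validate-external | run` — each a thin wrapper over the library.
`edsig run --config cfg.yaml` executes all configured stages into one
output directory with a checksum manifest; re-running the same config and
seed reproduces identical artifacts.

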